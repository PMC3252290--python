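"""Two-timepoint field alignment and cell correspondence.

Stage re-positioning and the wash cycle shift the field of view between
the T0 and T1 acquisitions.  The nuclear stain gives a stable reference:
nuclei centroids from the two timepoints are matched by mutual nearest
neighbor, an affine transform is fit by least squares (optionally with
iterative outlier rejection), and matched cells yield one flux record
each carrying the T0 and T1 integrated fluorescence on the well's
selected wavelength.  Unmatched cells (departed, divided, newly in
frame) are reported and excluded from scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.spatial import cKDTree

from .segment import CellObject

__all__ = [
    "AffineEstimate",
    "FluxRecord",
    "match_centroids",
    "fit_affine",
    "estimate_alignment",
    "register_cells",
    "apply_affine",
]


@dataclass
class AffineEstimate:
    matrix: np.ndarray               # 2x3, maps T0 (row, col) -> T1
    pairs: list[tuple[int, int]]     # (index@T0, index@T1)
    residuals: np.ndarray            # per retained pair, px
    inliers: np.ndarray              # bool per pair

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2]

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]


@dataclass
class FluxRecord:
    cell_id: int
    well_id: str
    field_id: str
    compound_id: str
    cell_line: str
    wavelength: str
    f_t0: float
    f_t1: float
    extras: dict = dc_field(default_factory=dict)  # rim/interior stats etc.


def apply_affine(points: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    return points @ matrix[:, :2].T + matrix[:, 2]


def match_centroids(
    a: np.ndarray, b: np.ndarray, max_dist: float = 20.0
) -> list[tuple[int, int]]:
    """One-to-one mutual-nearest-neighbor pairs within ``max_dist`` px."""
    a = np.asarray(a, dtype=float).reshape(-1, 2)
    b = np.asarray(b, dtype=float).reshape(-1, 2)
    if len(a) == 0 or len(b) == 0:
        return []
    ta, tb = cKDTree(a), cKDTree(b)
    d_ab, nn_ab = tb.query(a, distance_upper_bound=max_dist)
    d_ba, nn_ba = ta.query(b, distance_upper_bound=max_dist)
    pairs = []
    for i in range(len(a)):
        j = nn_ab[i]
        if j < len(b) and np.isfinite(d_ab[i]) and nn_ba[j] == i:
            pairs.append((i, int(j)))
    return pairs


def fit_affine(
    a: np.ndarray,
    b: np.ndarray,
    pairs: list[tuple[int, int]],
    robust: bool = True,
    max_rounds: int = 5,
    min_cutoff: float = 1.5,
) -> AffineEstimate:
    """Least-squares affine fit b ~ M a + t over matched centroid pairs.

    With ``robust``, pairs whose residual exceeds 3x the residual
    standard deviation are dropped and the fit repeated (at most
    ``max_rounds`` times).  The rejection cutoff is floored at
    ``min_cutoff`` px so ordinary centroid jitter is never discarded —
    without the floor the loop contracts onto a minimal, high-leverage
    subset.
    """
    a = np.asarray(a, dtype=float).reshape(-1, 2)
    b = np.asarray(b, dtype=float).reshape(-1, 2)
    if len(pairs) < 3:
        raise ValueError(f"need >=3 pairs to fit an affine, got {len(pairs)}")
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    src, dst = a[ia], b[ib]
    if np.linalg.matrix_rank(src - src.mean(axis=0)) < 2:
        raise ValueError("degenerate geometry: matched points are collinear")

    active = np.ones(len(pairs), dtype=bool)
    matrix = None
    for _ in range(max_rounds if robust else 1):
        design = np.hstack([src[active], np.ones((active.sum(), 1))])
        sol, *_ = np.linalg.lstsq(design, dst[active], rcond=None)
        matrix = sol.T  # 2x3
        pred = apply_affine(src, matrix)
        res = np.linalg.norm(pred - dst, axis=1)
        sd = res[active].std()
        if not robust or sd == 0:
            break
        new_active = active & (res <= max(3.0 * sd, min_cutoff))
        if new_active.sum() < 3 or new_active.sum() == active.sum():
            break
        active = new_active
    if abs(np.linalg.det(matrix[:, :2])) < 1e-12:
        raise ValueError("degenerate affine: singular linear part")
    res = np.linalg.norm(apply_affine(src, matrix) - dst, axis=1)
    return AffineEstimate(matrix=matrix, pairs=list(pairs),
                          residuals=res, inliers=active)


def estimate_alignment(
    a: np.ndarray,
    b: np.ndarray,
    max_dist: float = 25.0,
    refine_dist: float = 5.0,
    rounds: int = 2,
) -> AffineEstimate:
    """Match and fit with iterative refinement.

    A first mutual-nearest-neighbor match at ``max_dist`` seeds a least
    squares fit; subsequent rounds re-match through the current
    transform at the tighter ``refine_dist`` and refit, which repairs
    mispairings that occur when the drift approaches the cell spacing.
    """
    a = np.asarray(a, dtype=float).reshape(-1, 2)
    b = np.asarray(b, dtype=float).reshape(-1, 2)
    pairs = match_centroids(a, b, max_dist=max_dist)
    est = fit_affine(a, b, pairs, robust=True)
    for _ in range(rounds):
        mapped = apply_affine(a, est.matrix)
        new_pairs = match_centroids(mapped, b, max_dist=refine_dist)
        if len(new_pairs) < 3:
            break
        refit = fit_affine(a, b, new_pairs, robust=True)
        if sorted(new_pairs) == sorted(est.pairs):
            est = refit
            break
        est = refit
    return est


def register_cells(
    cells_t0: list[CellObject],
    cells_t1: list[CellObject],
    estimate: AffineEstimate | None = None,
    max_dist: float = 20.0,
    wavelength: str = "549",
    compound_id: str = "",
    cell_line: str = "",
):
    """Pair cells across timepoints and emit flux records.

    If an affine estimate is given, T0 centroids are mapped through it
    before the mutual-nearest-neighbor match, so residual drift does not
    break correspondence.

    Returns
    -------
    (records, report)
        ``records`` — one :class:`FluxRecord` per matched pair, reading
        the region_sum of the selected wavelength at both timepoints;
        ``report`` — dict with match counts and unmatched cell ids.
    """
    c0 = np.array([c.centroid for c in cells_t0]).reshape(-1, 2)
    c1 = np.array([c.centroid for c in cells_t1]).reshape(-1, 2)
    mapped = apply_affine(c0, estimate.matrix) if estimate is not None else c0
    pairs = match_centroids(mapped, c1, max_dist=max_dist)
    records = []
    for i, j in pairs:
        t0, t1 = cells_t0[i], cells_t1[j]
        records.append(FluxRecord(
            cell_id=t0.cell_id,
            well_id=t0.well_id,
            field_id=t0.field_id,
            compound_id=compound_id,
            cell_line=cell_line,
            wavelength=wavelength,
            f_t0=t0.readouts[(wavelength, "region_sum")],
            f_t1=t1.readouts[(wavelength, "region_sum")],
            extras={
                "rim_mean_t0": t0.readouts[(wavelength, "rim_mean")],
                "interior_mean_t0": t0.readouts[(wavelength, "interior_mean")],
                "perinuc_mean_t0": t0.readouts[(wavelength, "perinuc_mean")],
                "region_mean_t0": t0.readouts[(wavelength, "region_mean")],
                "nuc_mean_t0": t0.readouts[(wavelength, "nuc_mean")],
                "inner_mean_t0": t0.readouts.get((wavelength, "inner_mean"), 0.0),
                "mid_mean_t0": t0.readouts.get((wavelength, "mid_mean"), 0.0),
                "outer_mean_t0": t0.readouts.get((wavelength, "outer_mean"), 0.0),
                "centroid_t0": t0.centroid,
            },
        ))
    matched0 = {i for i, _ in pairs}
    matched1 = {j for _, j in pairs}
    report = {
        "n_t0": len(cells_t0),
        "n_t1": len(cells_t1),
        "n_matched": len(pairs),
        "match_rate": len(pairs) / max(len(cells_t0), 1),
        "unmatched_t0": [cells_t0[i].cell_id for i in range(len(cells_t0))
                         if i not in matched0],
        "unmatched_t1": [cells_t1[j].cell_id for j in range(len(cells_t1))
                         if j not in matched1],
    }
    return records, report
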