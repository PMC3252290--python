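"""End-to-end screen orchestration, image stacks in, ranked compounds out.

``run_screen`` drives the whole analysis in memory: for every well it
renders (or receives) the two-timepoint channel stacks, corrects
backgrounds, segments nuclei, tessellates cell territories, measures
per-cell fluorescence, registers T0 to T1, selects the response
wavelength, scores every cell's NSI, and finally assembles per-line
heatmaps, the cross-line aggregate, and the compound ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .background import correct_background
from .kinetics import KineticTruth
from .library import CompoundLibrary
from .register import FluxRecord, estimate_alignment, register_cells
from .render import FieldGeometry, NoiseParams, render_field, translation_drift
from .scoring import (
    BehaviorThresholds,
    NsiScore,
    ScoringParams,
    classify_behavior,
    classify_localization,
    score_records,
    well_summary,
)
from .segment import SegmentParams, measure_cells, segment_nuclei, select_channel, tessellate
from . import aggregate as agg

__all__ = [
    "ScreenConfig",
    "ScreenResult",
    "quantify_field",
    "process_field_pair",
    "run_screen",
    "run_plates",
    "territory_mask",
    "uptake_reference",
]


@dataclass
class ScreenConfig:
    cell_lines: tuple[str, ...] = ("line1", "line2", "line3")
    n_fields: int = 3
    geometry: FieldGeometry = dc_field(default_factory=FieldGeometry)
    noise: NoiseParams = dc_field(default_factory=NoiseParams)
    seg: SegmentParams = dc_field(default_factory=SegmentParams)
    scoring: ScoringParams = dc_field(default_factory=ScoringParams)
    bg_method: str = "otsu"      # fast default for full screens
    max_drift: float = 8.0       # px, per-field random stage translation
    match_dist: float = 25.0     # px, candidate pairing radius
    aggregate_method: str = "mean"


@dataclass
class ScreenResult:
    records: list[FluxRecord]
    scores: list[NsiScore]
    well_summaries: list[dict]
    heatmaps: dict[str, pd.DataFrame]
    aggregate: pd.DataFrame
    ranking: pd.DataFrame
    registration_reports: list[dict]

    def compound_nsi(self, cell_line: str | None = None) -> dict[str, float]:
        """Per-compound mean NSI, optionally restricted to one line."""
        acc: dict[str, list[float]] = {}
        for s in self.scores:
            if cell_line is None or s.cell_line == cell_line:
                acc.setdefault(s.compound_id, []).append(s.nsi)
        return {cid: float(np.mean(v)) for cid, v in acc.items()}


def territory_mask(nuclei: np.ndarray, cell_scale: float = 2.2) -> np.ndarray:
    """Cell-body support: pixels within reach of a nucleus.

    The cell body extends roughly ``cell_scale`` nucleus radii from the
    nucleus center, so each pixel is kept if its distance to the
    nearest nucleus is within that nucleus's own reach (scaled by its
    equivalent radius, with a margin for ellipse anisotropy).  This
    approximates the body support without relying on possibly blank
    compound channels.
    """
    from scipy import ndimage as ndi

    nuclei = np.asarray(nuclei)
    n = int(nuclei.max())
    if n == 0:
        return nuclei > 0
    areas = np.bincount(nuclei.ravel(), minlength=n + 1).astype(float)
    radius = np.sqrt(np.maximum(areas, 1.0) / np.pi)
    # 1.35x + 3 px margin absorbs ellipse anisotropy and the smaller
    # masks that dim nuclei get from a global threshold
    reach = (cell_scale - 1.0) * radius * 1.35 + 3.0
    dist, (ir, ic) = ndi.distance_transform_edt(nuclei == 0,
                                                return_indices=True)
    nearest_label = nuclei[ir, ic]
    return dist <= reach[nearest_label]


def quantify_field(images: dict[str, np.ndarray], bg_method: str = "otsu",
                   seg: SegmentParams | None = None,
                   well_id: str = "", field_id: str = "",
                   cell_scale: float = 2.2):
    """Background-correct, segment and measure one timepoint of a field.

    Returns (cells, segmentation, corrected_channels, regions).
    """
    seg_params = seg or SegmentParams()
    nuc_corr, _, _ = correct_background(images["655"], method=bg_method)
    segres = segment_nuclei(nuc_corr, seg_params)
    corrected = {}
    for ch in ("475", "549"):
        corrected[ch], _, _ = correct_background(images[ch], method=bg_method)
    if segres.n_nuclei == 0:
        return [], segres, corrected, np.zeros_like(segres.nuclei)
    fg = territory_mask(segres.nuclei, cell_scale)
    regions = tessellate(fg, segres.nuclei)
    cells = measure_cells(regions, segres.nuclei, corrected,
                          well_id=well_id, field_id=field_id)
    return cells, segres, corrected, regions


def process_field_pair(images_t0, images_t1, bg_method="otsu",
                       seg: SegmentParams | None = None,
                       match_dist: float = 25.0,
                       well_id: str = "", field_id: str = ""):
    """Quantify both timepoints of one field and register them.

    Returns (cells_t0, cells_t1, estimate_or_None, pairing, report).
    """
    cells0, _, _, _ = quantify_field(images_t0, bg_method, seg, well_id, field_id)
    cells1, _, _, _ = quantify_field(images_t1, bg_method, seg, well_id, field_id)
    c0 = np.array([c.centroid for c in cells0]).reshape(-1, 2)
    c1 = np.array([c.centroid for c in cells1]).reshape(-1, 2)
    try:
        estimate = estimate_alignment(c0, c1, max_dist=match_dist)
    except ValueError:
        estimate = None
    return cells0, cells1, estimate


def uptake_reference(scores: list[NsiScore], q: float = 95.0) -> float:
    """Plate-level reference interior density for behavior calls."""
    from .scoring import _interior_density

    vals = [_interior_density(s.extras) for s in scores]
    return float(np.percentile(vals, q)) if vals else 0.0


def _well_records(field_images, config, well_id, compound_id, cell_line):
    """Quantify, register and read out one well's field pairs.

    ``field_images`` is a list of (images_t0, images_t1) channel dicts.
    The response wavelength is chosen once per well from the pooled T0
    cells and applied to every field and both timepoints.
    """
    field_results = []
    for f, (imgs0, imgs1) in enumerate(field_images):
        field_results.append(process_field_pair(
            imgs0, imgs1, config.bg_method, config.seg,
            config.match_dist, well_id, f"f{f}",
        ))
    all_t0 = [c for c0, _, _ in field_results for c in c0]
    if not all_t0:
        return [], []
    wavelength = select_channel(all_t0)
    records, reports = [], []
    for fidx, (cells0, cells1, estimate) in enumerate(field_results):
        recs, report = register_cells(
            cells0, cells1, estimate, max_dist=6.0,
            wavelength=wavelength, compound_id=compound_id,
            cell_line=cell_line,
        )
        records.extend(recs)
        report.update(well_id=well_id, field=fidx)
        reports.append(report)
    return records, reports


def _assemble(records, well_of, library, lines, config):
    """Score records and build summaries, heatmaps and the ranking."""
    scores = score_records(records, config.scoring)
    by_well: dict[str, list[NsiScore]] = {}
    for s in scores:
        by_well.setdefault(s.well_id, []).append(s)
    well_rows = []
    for (cid, line), well_id in well_of.items():
        if well_id in by_well:
            row = well_summary(by_well[well_id])
            row.update(well_id=well_id, compound_id=cid, cell_line=line)
            well_rows.append(row)
    heatmaps = {}
    for line in lines:
        means = agg.compound_means(
            [r for r in well_rows if r["cell_line"] == line]
        )
        heatmaps[line] = agg.build_heatmap(means, library)
    aggregate = agg.aggregate_lines(heatmaps, config.aggregate_method)
    ranking = agg.rank_compounds(aggregate)
    return scores, well_rows, heatmaps, aggregate, ranking


def run_screen(
    library: CompoundLibrary,
    truth: KineticTruth,
    config: ScreenConfig | None = None,
    seed: int = 0,
    cell_lines: tuple[str, ...] | None = None,
) -> ScreenResult:
    """Simulate and analyze the full screen in memory.

    One well per (compound, cell line); each well gets ``n_fields``
    field pairs with independent random stage drift.  The estimated
    pipeline never sees the ground truth — images only.
    """
    config = config or ScreenConfig()
    lines = tuple(cell_lines) if cell_lines is not None else config.cell_lines
    rng = np.random.default_rng(seed)

    records: list[FluxRecord] = []
    reg_reports: list[dict] = []
    well_of: dict[tuple[str, str], str] = {}

    for line in lines:
        for comp in library:
            key = (comp.compound_id, line)
            if key not in truth:
                raise KeyError(f"no kinetics for {key}")
            kin = truth[key]
            well_id = f"{line}:{comp.compound_id}"
            well_of[key] = well_id
            field_images = []
            for _f in range(config.n_fields):
                drift = translation_drift(
                    rng.uniform(-config.max_drift, config.max_drift),
                    rng.uniform(-config.max_drift, config.max_drift),
                )
                field_seed = int(rng.integers(0, 2**31 - 1))
                imgs0, imgs1, _ = render_field(
                    kin, config.geometry, config.noise, drift, seed=field_seed
                )
                field_images.append((imgs0, imgs1))
            recs, reports = _well_records(field_images, config, well_id,
                                          comp.compound_id, line)
            records.extend(recs)
            reg_reports.extend(reports)

    scores, well_rows, heatmaps, aggregate, ranking = _assemble(
        records, well_of, library, lines, config
    )
    return ScreenResult(records, scores, well_rows, heatmaps, aggregate,
                        ranking, reg_reports)


def run_plates(
    plate_dirs: list,
    library: CompoundLibrary,
    config: ScreenConfig | None = None,
) -> ScreenResult:
    """Analyze simulated plates from disk (TIFFs plus manifest.yaml)."""
    from .plate import load_manifest, read_field_images

    config = config or ScreenConfig()
    records: list[FluxRecord] = []
    reg_reports: list[dict] = []
    well_of: dict[tuple[str, str], str] = {}
    lines_seen: list[str] = []

    for pdir in plate_dirs:
        manifest = load_manifest(pdir)
        for w in manifest.wells:
            if w.compound_id is None:
                continue
            if w.cell_line not in lines_seen:
                lines_seen.append(w.cell_line)
            well_id = f"{manifest.plate_id}:{w.well_id}"
            well_of[(w.compound_id, w.cell_line)] = well_id
            field_images = [
                (read_field_images(pdir, manifest.plate_id, w.well_id,
                                   f"f{f}", "T0"),
                 read_field_images(pdir, manifest.plate_id, w.well_id,
                                   f"f{f}", "T1"))
                for f in range(w.n_fields)
            ]
            recs, reports = _well_records(field_images, config, well_id,
                                          w.compound_id, w.cell_line)
            records.extend(recs)
            reg_reports.extend(reports)

    scores, well_rows, heatmaps, aggregate, ranking = _assemble(
        records, well_of, library, tuple(lines_seen), config
    )
    return ScreenResult(records, scores, well_rows, heatmaps, aggregate,
                        ranking, reg_reports)
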