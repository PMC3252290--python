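"""The non-stickiness index (NSI) and per-cell phenotype calls.

The NSI quantifies, per cell, how completely a compound's fluorescence
clears between the uptake readout (T0) and the post-washout readout
(T1).  Within each compound x cell-line group, fluxes are min–max
normalized using the group extrema over both timepoints,

    F_hat_t = (F_t - F_min) / (F_max - F_min + eps),

and the index is the log-ratio

    NSI = ln((F_hat_T1 + mu) / (F_hat_T0 + mu)),

with a small pseudocount mu guarding the logarithm.  Negative NSI means
the signal cleared — the desirable, non-sticky phenotype.  A
percentage-drop variant is provided on an inverted scale so that "more
negative is better" holds for both.

Behavior-class and localization calls concretize the four flux
phenotypes (no membrane entry; membrane-bound; enter-and-accumulate;
enter-and-leave) and the three spatial patterns (nuclear, perinuclear,
diffuse) as threshold rules on the per-cell readouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .register import FluxRecord

__all__ = [
    "ScoringParams",
    "CompoundStats",
    "NsiScore",
    "BehaviorThresholds",
    "compute_stats",
    "compute_nsi",
    "score_records",
    "classify_behavior",
    "classify_localization",
    "well_summary",
]


@dataclass
class ScoringParams:
    mu: float = 0.01         # pseudocount on the normalized flux scale
    variant: str = "log_ratio"  # or "percent_drop"
    epsilon: float = 1e-9    # divide guard

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.variant not in ("log_ratio", "percent_drop"):
            raise ValueError(f"unknown NSI variant {self.variant!r}")


@dataclass
class CompoundStats:
    """Flux extrema of one compound x cell-line group, both timepoints."""

    compound_id: str
    cell_line: str
    f_max: float
    f_min: float

    @property
    def informative(self) -> bool:
        return self.f_max > self.f_min


@dataclass
class NsiScore:
    cell_id: int
    well_id: str
    compound_id: str
    cell_line: str
    nsi: float
    f_hat_t0: float
    f_hat_t1: float
    flagged: bool = False   # True when the group was flat (uninformative)
    extras: dict = dc_field(default_factory=dict)


def compute_stats(records: list[FluxRecord]) -> CompoundStats:
    """Exact extrema over both timepoints' fluxes of one group."""
    if not records:
        raise ValueError("cannot compute stats for an empty group")
    vals = [r.f_t0 for r in records] + [r.f_t1 for r in records]
    cids = {r.compound_id for r in records}
    lines = {r.cell_line for r in records}
    if len(cids) > 1 or len(lines) > 1:
        raise ValueError("stats group must be a single compound x cell line")
    return CompoundStats(
        compound_id=next(iter(cids)),
        cell_line=next(iter(lines)),
        f_max=float(max(vals)),
        f_min=float(min(vals)),
    )


def compute_nsi(
    record: FluxRecord,
    stats: CompoundStats,
    params: ScoringParams | None = None,
) -> NsiScore:
    """Score one cell against its group's flux extrema."""
    params = params or ScoringParams()
    if not stats.informative:
        return NsiScore(record.cell_id, record.well_id, record.compound_id,
                        record.cell_line, nsi=0.0, f_hat_t0=0.0, f_hat_t1=0.0,
                        flagged=True, extras=dict(record.extras))
    span = stats.f_max - stats.f_min + params.epsilon
    f0 = (record.f_t0 - stats.f_min) / span
    f1 = (record.f_t1 - stats.f_min) / span
    if params.variant == "log_ratio":
        nsi = float(np.log((f1 + params.mu) / (f0 + params.mu)))
    else:
        # percent drop of the raw signal, sign-inverted so that a large
        # drop (good clearance) is negative, matching the log_ratio scale
        nsi = -float((record.f_t0 - record.f_t1) / (record.f_t0 + params.epsilon))
    return NsiScore(record.cell_id, record.well_id, record.compound_id,
                    record.cell_line, nsi=nsi, f_hat_t0=float(f0),
                    f_hat_t1=float(f1), extras=dict(record.extras))


def score_records(
    records: list[FluxRecord],
    params: ScoringParams | None = None,
) -> list[NsiScore]:
    """Group records by compound x cell line and score every cell."""
    params = params or ScoringParams()
    groups: dict[tuple[str, str], list[FluxRecord]] = {}
    for r in records:
        groups.setdefault((r.compound_id, r.cell_line), []).append(r)
    scores = []
    for grp in groups.values():
        stats = compute_stats(grp)
        scores.extend(compute_nsi(r, stats, params) for r in grp)
    return scores


@dataclass
class BehaviorThresholds:
    tau_u: float = 0.2    # minimum relative interior uptake to call "entered"
    tau_m: float = 2.0    # rim/interior density ratio calling membrane binding
    tau_r: float = 0.05   # minimum relative rim density for membrane binding
    theta: float = 0.5    # NSI below -theta separates in_and_out from accumulate


def _interior_density(ext: dict) -> float:
    """Mean density over nucleus + inner/mid radial shells at T0."""
    return (ext.get("nuc_mean_t0", 0.0) + ext.get("inner_mean_t0", 0.0)
            + ext.get("mid_mean_t0", 0.0)) / 3.0


def classify_behavior(
    score: NsiScore,
    thresholds: BehaviorThresholds | None = None,
    uptake_scale: float | None = None,
) -> str:
    """Call one of the four flux behavior classes for a scored cell.

    Interior uptake is the mean density over the nucleus and the inner
    two radial shells of the territory; the rim statistic is the outer
    radial shell, where membrane-bound signal concentrates.
    ``uptake_scale`` is a plate-level reference density (the 95th
    percentile of T0 interior densities over all wells) so that dim
    wells are not stretched to full scale by the group normalization.
    """
    thresholds = thresholds or BehaviorThresholds()
    ext = score.extras
    if "interior_mean_t0" not in ext or "rim_mean_t0" not in ext:
        raise ValueError("behavior call needs rim/interior T0 statistics")
    interior = _interior_density(ext)
    rim = ext.get("outer_mean_t0", ext["rim_mean_t0"])
    scale = uptake_scale if uptake_scale and uptake_scale > 0 else max(interior, 1e-9)
    uptake = interior / scale
    rim_ratio = rim / (interior + 1e-9)
    if uptake < thresholds.tau_u:
        if rim_ratio >= thresholds.tau_m and rim >= thresholds.tau_r * scale:
            return "membrane_bound"
        return "no_entry"
    return "in_and_out" if score.nsi < -thresholds.theta else "accumulate"


def classify_localization(score: NsiScore, ratio_threshold: float = 1.5) -> str:
    """Call nuclear / perinuclear / diffuse from T0 density contrasts.

    Densities of the nucleus and of the territory's three radial shells
    are compared against each other rather than against the whole-cell
    mean: the estimated territory includes empty pixels beyond the cell
    body, which dilutes a whole-cell mean and would bias every call
    toward "nuclear".  A compartment must exceed the rest by
    ``ratio_threshold`` to be called; near-uniform profiles fall through
    to diffuse.
    """
    ext = score.extras
    nuc = ext.get("nuc_mean_t0", 0.0)
    inner = ext.get("inner_mean_t0", 0.0)
    mid = ext.get("mid_mean_t0", 0.0)
    outer = ext.get("outer_mean_t0", 0.0)
    if max(nuc, inner, mid, outer) <= 0:
        return "diffuse"
    if nuc >= ratio_threshold * max(inner, mid, 1e-9):
        return "nuclear"
    if max(inner, mid) >= ratio_threshold * max(nuc, outer, 1e-9):
        return "perinuclear"
    return "diffuse"


def well_summary(scores: list[NsiScore]) -> dict:
    """Mean (primary), median, count and dispersion of a well's scores."""
    if not scores:
        raise ValueError("cannot summarize an empty well")
    vals = np.array([s.nsi for s in scores])
    return {
        "mean_nsi": float(vals.mean()),
        "median_nsi": float(np.median(vals)),
        "n_cells": int(len(vals)),
        "sd_nsi": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
    }
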