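"""Ground-truth compound kinetics for the synthetic screen.

Each (compound, cell line) pair is assigned one of four flux behavior
classes observed in live-cell compound screens:

* ``no_entry``       — the compound never crosses the membrane;
* ``membrane_bound`` — it binds the membrane but does not enter;
* ``accumulate``     — it enters and is retained (sticky);
* ``in_and_out``     — it enters and clears over time (non-sticky, the
  desirable phenotype).

The two-timepoint design measures fluorescence right after uptake/wash
(T0) and again after a ~60 min clearance window (T1).  The generator's
per-cell truth follows a simple first-order model: the T0 amplitude is
proportional to the uptake rate ``k_in`` integrated over the incubation
time, and T1 decays (or grows, for accumulating compounds with ongoing
uptake) exponentially at net rate ``growth - k_out``.  The population
true log-ratio ln(F_T1/F_T0) = (growth - k_out) * dt is the quantity the
screen's non-stickiness index estimates.

Structure-activity linkage: with probability ``structure_link`` a
compound's class is inherited from a per-R1-block draw, so structurally
similar compounds (same R1) share flux behavior — the association the
chemoinformatics arm is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .library import CompoundLibrary

__all__ = [
    "BEHAVIOR_CLASSES",
    "LOCALIZATIONS",
    "CompoundKinetics",
    "KineticTruth",
    "assign_kinetics",
    "simulate_secondary_screen",
]

BEHAVIOR_CLASSES = ("no_entry", "membrane_bound", "accumulate", "in_and_out")
LOCALIZATIONS = ("nuclear", "perinuclear", "diffuse")

# Base class mixture for an unlinked compound draw.
CLASS_PROBS = {
    "no_entry": 0.20,
    "membrane_bound": 0.15,
    "accumulate": 0.35,
    "in_and_out": 0.30,
}

UPTAKE_MINUTES = 60.0   # incubation before the T0 wash
CLEARANCE_MINUTES = 60.0  # gap between T0 and T1
AMPLITUDE_SCALE = 30000.0  # a.u. per unit k_in, sets the 16-bit dynamic range


@dataclass(frozen=True)
class CompoundKinetics:
    """Kinetic truth for one (compound, cell line) pair."""

    compound_id: str
    cell_line: str
    behavior_class: str
    k_in: float          # uptake rate, a.u./min (amplitude factor)
    k_out: float         # clearance rate, 1/min
    growth: float        # continued-uptake rate for accumulators, 1/min
    localization: str
    cell_cv: float       # CV of per-cell lognormal amplitude multipliers
    emission: int        # dominant emission channel, 475 or 549 (nm)

    @property
    def true_log_ratio(self) -> float:
        """Population ln(F_T1 / F_T0) under the first-order model."""
        return (self.growth - self.k_out) * CLEARANCE_MINUTES

    @property
    def amplitude(self) -> float:
        """Population-mean integrated T0 signal (a.u.)."""
        return self.k_in * AMPLITUDE_SCALE


class KineticTruth(dict):
    """Mapping (compound_id, cell_line) -> CompoundKinetics."""

    @property
    def cell_lines(self) -> list[str]:
        return sorted({line for (_, line) in self.keys()})

    @property
    def compound_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for cid, _ in self.keys():
            seen.setdefault(cid)
        return list(seen)

    def true_log_ratios(self, cell_line: str | None = None) -> dict[str, float]:
        """Per-compound true log-ratio; averaged over lines if none given."""
        if cell_line is not None:
            return {
                cid: k.true_log_ratio
                for (cid, line), k in self.items()
                if line == cell_line
            }
        acc: dict[str, list[float]] = {}
        for (cid, _), k in self.items():
            acc.setdefault(cid, []).append(k.true_log_ratio)
        return {cid: float(np.mean(v)) for cid, v in acc.items()}


def _draw_class(rng: np.random.Generator) -> str:
    names = list(CLASS_PROBS)
    return names[rng.choice(len(names), p=[CLASS_PROBS[n] for n in names])]


def _draw_rates(cls: str, rng: np.random.Generator) -> tuple[float, float, float]:
    """(k_in, k_out, growth) for a class; continuous so ranks are informative."""
    if cls == "no_entry":
        return rng.uniform(0.0, 0.03), rng.uniform(0.0, 0.003), 0.0
    if cls == "membrane_bound":
        return rng.uniform(0.6, 1.6), rng.uniform(0.0, 0.003), 0.0
    if cls == "accumulate":
        return rng.uniform(0.6, 1.6), 0.0, rng.uniform(0.0, 0.004)
    if cls == "in_and_out":
        return rng.uniform(0.6, 1.6), rng.uniform(0.012, 0.05), 0.0
    raise ValueError(f"unknown behavior class {cls!r}")


def assign_kinetics(
    library: CompoundLibrary,
    cell_lines: list[str] | tuple[str, ...] = ("line1", "line2", "line3"),
    structure_link: float = 0.7,
    cell_cv: float = 0.2,
    seed: int = 0,
) -> KineticTruth:
    """Draw class-conditional kinetic truth for every (compound, line).

    ``structure_link`` in [0, 1] is the probability that a compound's
    behavior class is inherited from its R1 block's class draw rather
    than drawn independently; 1.0 makes every same-R1 compound behave
    identically in a given line, 0.0 removes the structure-activity
    association entirely.
    """
    if not list(cell_lines):
        raise ValueError("cell_lines must be nonempty")
    if not len(library):
        raise ValueError("library must be nonempty")
    if not 0.0 <= structure_link <= 1.0:
        raise ValueError("structure_link must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    truth = KineticTruth()

    # Per-compound emission channel (fixed across lines).
    emission = {
        c.compound_id: int(rng.choice([475, 549])) for c in library
    }
    # Line-specific multipliers on uptake and clearance.
    line_mult = {
        line: (rng.uniform(0.7, 1.3), rng.uniform(0.7, 1.3))
        for line in cell_lines
    }
    for line in cell_lines:
        block_class = {r1: _draw_class(rng) for r1 in library.r1_blocks()}
        for c in library:
            inherited = rng.uniform() < structure_link
            cls = block_class[c.r1] if inherited else _draw_class(rng)
            k_in, k_out, growth = _draw_rates(cls, rng)
            m_in, m_out = line_mult[line]
            loc = LOCALIZATIONS[rng.choice(3)]
            truth[(c.compound_id, line)] = CompoundKinetics(
                compound_id=c.compound_id,
                cell_line=line,
                behavior_class=cls,
                k_in=k_in * m_in,
                k_out=k_out * m_out,
                growth=growth,
                localization=loc,
                cell_cv=cell_cv,
                emission=emission[c.compound_id],
            )
    return truth


def simulate_secondary_screen(
    truth: KineticTruth,
    rho: float = 0.6,
    seed: int = 0,
) -> dict[str, float]:
    """Simulate the scalar secondary-screen readout per compound.

    The secondary system (a root-hair-like assay) reports one NSI-scale
    observation per compound, rank-correlated with the mammalian
    consensus true log-ratio at Spearman ~ ``rho``.  A Gaussian copula
    is used: for bivariate normal scores with correlation r, Spearman's
    rho is (6/pi) asin(r/2), so r = 2 sin(pi*rho/6) calibrates the
    requested rank correlation; observations are then quantile-matched
    back onto the mammalian value distribution so signs and scale remain
    comparable across screens.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    primary = truth.true_log_ratios()
    cids = list(primary)
    x = np.array([primary[c] for c in cids])
    n = len(x)

    # Normal scores of the primary ranks (average ranks for ties).
    from scipy.stats import rankdata, norm

    u = rankdata(x) / (n + 1)
    z1 = norm.ppf(u)
    r = 2.0 * np.sin(np.pi * rho / 6.0)
    z2 = r * z1 + np.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n)
    # Quantile-match z2 onto the primary empirical distribution.
    order = np.argsort(z2, kind="stable")
    y = np.empty(n)
    y[order] = np.sort(x)
    return {cid: float(val) for cid, val in zip(cids, y)}
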