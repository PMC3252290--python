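"""R1 x R2 heatmaps, cross-line aggregation, ranking, and screen agreement.

Well-level NSI summaries are arranged on the combinatorial library's
grid — R1 letters as rows, R2 numbers as columns — one heatmap per cell
line.  Heatmaps are combined elementwise across lines (mean by default;
median and worst-line, i.e. the elementwise maximum implementing "a
compound is only as good as its stickiest line", as alternatives) and
compounds are ranked ascending: the most negative aggregate NSI is the
best candidate.  The secondary (root-hair-like) screen is compared by
rank/linear correlation and by a sign co-occurrence contingency table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .library import CompoundLibrary, R1_LETTERS, R2_NUMBERS

__all__ = [
    "build_heatmap",
    "aggregate_lines",
    "heatmap_to_series",
    "rank_compounds",
    "cooccurrence",
    "correlate_screens",
]

AGG_METHODS = ("mean", "median", "worst_line")


def build_heatmap(
    well_means: dict[str, float],
    library: CompoundLibrary,
) -> pd.DataFrame:
    """Arrange per-compound well means on the R1 x R2 grid.

    ``well_means`` maps compound_id -> well-level mean NSI; replicate
    wells should be averaged by the caller (see
    :func:`compound_means`).  Grid cells for compounds absent from the
    library stay NaN — "missing" is distinct from NSI = 0.
    """
    lib_ids = set(library.ids)
    unknown = set(well_means) - lib_ids
    if unknown:
        raise KeyError(f"compounds not in library: {sorted(unknown)[:5]}")
    hm = pd.DataFrame(np.nan, index=list(R1_LETTERS),
                      columns=list(R2_NUMBERS))
    for c in library:
        if c.compound_id in well_means:
            hm.loc[c.r1, c.r2] = well_means[c.compound_id]
    return hm


def compound_means(summaries: list[dict]) -> dict[str, float]:
    """Average replicate wells of the same compound.

    ``summaries`` rows need keys ``compound_id`` and ``mean_nsi``.
    """
    acc: dict[str, list[float]] = {}
    for row in summaries:
        acc.setdefault(row["compound_id"], []).append(row["mean_nsi"])
    return {cid: float(np.mean(v)) for cid, v in acc.items()}


def aggregate_lines(
    heatmaps: dict[str, pd.DataFrame],
    method: str = "mean",
) -> pd.DataFrame:
    """Elementwise combine per-line heatmaps over non-missing entries."""
    if method not in AGG_METHODS:
        raise ValueError(f"unknown aggregation {method!r}; choose {AGG_METHODS}")
    frames = list(heatmaps.values())
    first = frames[0]
    for f in frames[1:]:
        if not (f.index.equals(first.index) and f.columns.equals(first.columns)):
            raise ValueError("heatmap grids do not match")
    stack = np.stack([f.to_numpy() for f in frames])
    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings():
        # all-NaN grid cells (compounds absent from the library) are kept NaN
        warnings.simplefilter("ignore", category=RuntimeWarning)
        if method == "mean":
            out = np.nanmean(stack, axis=0)
        elif method == "median":
            out = np.nanmedian(stack, axis=0)
        else:  # worst_line: a compound is as sticky as its worst (max) line
            out = np.nanmax(stack, axis=0)
    out[np.isnan(stack).all(axis=0)] = np.nan
    return pd.DataFrame(out, index=first.index, columns=first.columns)


def heatmap_to_series(heatmap: pd.DataFrame) -> pd.Series:
    """Flatten a heatmap to a compound_id -> value series (drops missing)."""
    vals = {}
    for r1 in heatmap.index:
        for r2 in heatmap.columns:
            v = heatmap.loc[r1, r2]
            if not np.isnan(v):
                vals[f"{r1}{r2}"] = float(v)
    return pd.Series(vals)


def rank_compounds(aggregate: pd.DataFrame, top_k: int | None = None) -> pd.DataFrame:
    """Rank compounds ascending by aggregate NSI (most negative first).

    Ties break lexicographically on compound_id; deterministic.
    """
    series = heatmap_to_series(aggregate)
    if series.empty:
        return pd.DataFrame(columns=["compound_id", "nsi", "rank"])
    df = pd.DataFrame({"compound_id": series.index, "nsi": series.values})
    df = df.sort_values(["nsi", "compound_id"], kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    if top_k is not None:
        df = df.head(top_k)
    return df


def cooccurrence(
    primary: dict[str, float],
    secondary: dict[str, float],
    cut: float = 0.0,
) -> dict:
    """Sign co-occurrence of the two screens at a desirability cut.

    Counts compounds by (NSI < cut) in each screen.  Agreement is the
    diagonal fraction; the odds ratio uses a Haldane 0.5 correction when
    any margin is zero.
    """
    shared = sorted(set(primary) & set(secondary))
    if not shared:
        raise ValueError("no shared compounds between screens")
    table = np.zeros((2, 2), dtype=int)
    for cid in shared:
        i = 0 if primary[cid] < cut else 1
        j = 0 if secondary[cid] < cut else 1
        table[i, j] += 1
    agreement = (table[0, 0] + table[1, 1]) / table.sum()
    t = table.astype(float)
    if (t == 0).any():
        t = t + 0.5
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return {
        "table": table,
        "agreement": float(agreement),
        "odds_ratio": float(odds),
        "n": len(shared),
    }


def correlate_screens(
    primary: dict[str, float],
    secondary: dict[str, float],
) -> dict:
    """Pearson and Spearman correlation over shared compounds."""
    shared = sorted(set(primary) & set(secondary))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared compounds")
    x = np.array([primary[c] for c in shared])
    y = np.array([secondary[c] for c in shared])
    out = {"n": len(shared), "compound_ids": shared, "x": x, "y": y}
    if x.std() == 0 or y.std() == 0:
        out.update(pearson=np.nan, spearman=np.nan, degenerate=True)
        return out
    out["pearson"] = float(pearsonr(x, y).statistic)
    out["spearman"] = float(spearmanr(x, y).statistic)
    out["degenerate"] = False
    return out
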