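"""Structure-activity arm: properties, distances, MDS, and correlations.

Molecular structures (SMILES) are turned into physicochemical property
vectors and a pairwise structural dissimilarity matrix — one minus the
Tanimoto similarity of hashed topological-path fingerprints (path length
up to 7 bonds, 2048 bits).  Classical (Torgerson) multidimensional
scaling embeds the compounds in the plane, where the library's R1
blocks should cluster; silhouette and within/between distance
diagnostics quantify that clustering, and property-response
correlations ask which molecular features predict uptake and which (if
any) predict the non-stickiness index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata, spearmanr
from sklearn.metrics import silhouette_score

from rdkit import Chem, DataStructs, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .library import CompoundLibrary

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "FP_MAX_PATH",
    "FP_N_BITS",
    "ChemSpace",
    "compute_properties",
    "pairwise_distance",
    "classical_mds",
    "build_chemspace",
    "block_separation",
    "overlay_nsi",
    "property_correlation",
]

FP_MAX_PATH = 7
FP_N_BITS = 2048

PROPERTY_COLUMNS = (
    "mol_weight", "logp", "tpsa", "rotatable_bonds",
    "hbond_donors", "hbond_acceptors", "ring_count",
)


@dataclass
class ChemSpace:
    compound_ids: list[str]
    distances: np.ndarray     # (n, n), symmetric, zero diagonal, in [0, 1]
    embedding: np.ndarray     # (n, 2)
    eigenvalues: np.ndarray   # full spectrum of the MDS decomposition
    r1_labels: list[str]


def _mol(smiles: str):
    return Chem.MolFromSmiles(smiles)


def compute_properties(library: CompoundLibrary) -> pd.DataFrame:
    """Physicochemical property vector per compound.

    Unparseable SMILES produce a row of NaNs flagged in the ``error``
    column; the run continues.
    """
    rows = []
    for c in library:
        mol = _mol(c.smiles)
        if mol is None:
            rows.append({"compound_id": c.compound_id, "r1": c.r1, "r2": c.r2,
                         "error": True,
                         **{k: np.nan for k in PROPERTY_COLUMNS}})
            continue
        rows.append({
            "compound_id": c.compound_id,
            "r1": c.r1,
            "r2": c.r2,
            "error": False,
            "mol_weight": Descriptors.MolWt(mol),
            "logp": Crippen.MolLogP(mol),
            "tpsa": rdMolDescriptors.CalcTPSA(mol),
            "rotatable_bonds": Lipinski.NumRotatableBonds(mol),
            "hbond_donors": Lipinski.NumHDonors(mol),
            "hbond_acceptors": Lipinski.NumHAcceptors(mol),
            "ring_count": rdMolDescriptors.CalcNumRings(mol),
        })
    return pd.DataFrame(rows).set_index("compound_id")


def fingerprints(library: CompoundLibrary) -> dict[str, object]:
    fps = {}
    for c in library:
        mol = _mol(c.smiles)
        if mol is not None:
            fps[c.compound_id] = Chem.RDKFingerprint(
                mol, maxPath=FP_MAX_PATH, fpSize=FP_N_BITS
            )
    return fps


def pairwise_distance(library: CompoundLibrary) -> tuple[np.ndarray, list[str]]:
    """1 - Tanimoto similarity on topological-path fingerprints."""
    fps = fingerprints(library)
    ids = list(fps)
    if len(ids) < 2:
        raise ValueError("need at least 2 valid compounds")
    n = len(ids)
    dist = np.zeros((n, n))
    fplist = [fps[i] for i in ids]
    for i in range(n):
        sims = DataStructs.BulkTanimotoSimilarity(fplist[i], fplist[i + 1:])
        for k, s in enumerate(sims):
            j = i + 1 + k
            dist[i, j] = dist[j, i] = 1.0 - s
    return dist, ids


def classical_mds(distances: np.ndarray, k: int = 2):
    """Torgerson classical MDS.

    Double-centers the squared distance matrix, eigendecomposes, and
    returns the top-``k`` coordinates from nonnegative eigenpairs plus
    the full eigenvalue spectrum (negative eigenvalues — non-Euclidean
    residual — are truncated to zero in the coordinates but reported).
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = evecs[:, :k] * np.sqrt(np.maximum(evals[:k], 0.0))
    return coords, evals


def build_chemspace(library: CompoundLibrary) -> ChemSpace:
    dist, ids = pairwise_distance(library)
    coords, evals = classical_mds(dist, k=2)
    r1 = [library.get(i).r1 for i in ids]
    return ChemSpace(ids, dist, coords, evals, r1)


def block_separation(
    embedding: np.ndarray,
    labels: list[str],
) -> dict:
    """How well R1 blocks cluster in the embedding.

    Returns the mean silhouette with R1 as the cluster label, plus the
    mean within-block and between-block pairwise embedding distances.
    """
    labels = list(labels)
    if len(set(labels)) < 2:
        raise ValueError("block separation needs at least 2 blocks")
    x = np.asarray(embedding, dtype=float)
    sil = float(silhouette_score(x, labels))
    d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
    lab = np.array(labels)
    same = lab[:, None] == lab[None, :]
    iu = np.triu_indices(len(lab), k=1)
    within = d[iu][same[iu]]
    between = d[iu][~same[iu]]
    return {
        "silhouette": sil,
        "within_mean": float(within.mean()),
        "between_mean": float(between.mean()),
    }


def overlay_nsi(
    space: ChemSpace,
    nsi: dict[str, float],
    top_k: int = 10,
) -> dict:
    """Annotate the embedding with NSI and report hit clustering.

    The ``top_k`` most negative compounds are the hits; the report gives
    the fraction of hits sharing an R1 block with another hit and lists
    isolated hits — compounds that are the only hit in their block, the
    pattern where structural neighbors do *not* share the phenotype.
    """
    shared = [cid for cid in space.compound_ids if cid in nsi]
    if not shared:
        raise ValueError("no compounds shared between embedding and NSI table")
    vals = np.array([nsi[c] for c in shared])
    if np.ptp(vals) == 0:
        return {"degenerate": True, "hits": [], "isolated_hits": [],
                "co_block_fraction": np.nan}
    order = np.argsort(vals, kind="stable")
    hits = [shared[i] for i in order[:top_k]]
    r1_of = dict(zip(space.compound_ids, space.r1_labels))
    hit_blocks = [r1_of[h] for h in hits]
    counts = {b: hit_blocks.count(b) for b in set(hit_blocks)}
    co_block = [h for h in hits if counts[r1_of[h]] > 1]
    isolated = [h for h in hits if counts[r1_of[h]] == 1]
    return {
        "degenerate": False,
        "hits": hits,
        "hit_blocks": hit_blocks,
        "n_hit_blocks": len(counts),
        "co_block_fraction": len(co_block) / len(hits),
        "isolated_hits": isolated,
    }


def property_correlation(
    properties: pd.DataFrame,
    responses: dict[str, dict[str, float]],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Spearman/Pearson of each property against each response.

    Permutation p-values (seeded) are computed for the Spearman
    coefficient; constant property columns are flagged undefined.
    ``responses`` maps response name -> {compound_id: value}.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rname, rvals in responses.items():
        shared = [c for c in properties.index if c in rvals]
        if len(shared) < 3:
            raise ValueError(f"response {rname!r}: fewer than 3 shared compounds")
        y = np.array([rvals[c] for c in shared])
        for prop in PROPERTY_COLUMNS:
            x = properties.loc[shared, prop].to_numpy(dtype=float)
            if np.ptp(x[~np.isnan(x)]) == 0 or np.isnan(x).all():
                rows.append({"response": rname, "property": prop,
                             "spearman": np.nan, "pearson": np.nan,
                             "perm_p": np.nan, "defined": False})
                continue
            ok = ~np.isnan(x)
            xs, ys = x[ok], y[ok]
            rs = float(spearmanr(xs, ys).statistic)
            rp = float(pearsonr(xs, ys).statistic)
            # permutation null on the Spearman statistic
            rx = rankdata(xs)
            ry = rankdata(ys)
            rx = (rx - rx.mean()) / rx.std()
            ry = (ry - ry.mean()) / ry.std()
            obs = abs(np.mean(rx * ry))
            perm = np.empty(n_permutations)
            for i in range(n_permutations):
                perm[i] = abs(np.mean(rx * ry[rng.permutation(len(ry))]))
            p = (1.0 + np.sum(perm >= obs - 1e-12)) / (n_permutations + 1.0)
            rows.append({"response": rname, "property": prop,
                         "spearman": rs, "pearson": rp,
                         "perm_p": float(p), "defined": True})
    return pd.DataFrame(rows)
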