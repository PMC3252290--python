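"""Cheminformatics arm: properties, distances, MDS, block structure."""

import numpy as np
import pytest
from scipy.spatial import procrustes

from nsiscreen import (
    block_separation,
    build_chemspace,
    build_library,
    classical_mds,
    compute_properties,
    overlay_nsi,
    pairwise_distance,
    property_correlation,
)
from nsiscreen.library import Compound, CompoundLibrary


@pytest.fixture(scope="module")
def lib():
    return build_library(seed=42, n_compounds=240)


@pytest.fixture(scope="module")
def chemspace(lib):
    return build_chemspace(lib)


def _toy_library(smiles_list):
    compounds = [
        Compound(f"A{i+1}", "A", i + 1, smi)
        for i, smi in enumerate(smiles_list)
    ]
    return CompoundLibrary(compounds)


class TestProperties:
    def test_reference_molecules_have_forced_descriptor_values(self):
        lib = _toy_library(["C", "c1ccccc1", "CCO"])
        props = compute_properties(lib)
        methane, benzene, ethanol = (props.loc[f"A{i}"] for i in (1, 2, 3))
        assert methane["rotatable_bonds"] == 0
        assert methane["hbond_donors"] == 0
        assert methane["ring_count"] == 0
        assert benzene["ring_count"] == 1
        assert benzene["tpsa"] == 0.0
        assert ethanol["hbond_donors"] == 1
        assert ethanol["hbond_acceptors"] == 1

    def test_bad_smiles_flagged_without_aborting(self):
        lib = _toy_library(["CCO", "not_a_smiles", "c1ccccc1"])
        props = compute_properties(lib)
        assert props.loc["A2", "error"]
        assert not props.loc["A1", "error"]
        assert np.isnan(props.loc["A2", "mol_weight"])

    def test_library_properties_are_complete_and_positive(self, lib):
        props = compute_properties(lib)
        assert not props["error"].any()
        assert (props["mol_weight"] > 0).all()
        assert (props["ring_count"] >= 3).all()  # xanthene core alone has 3


class TestPairwiseDistance:
    def test_identical_structures_have_zero_distance(self):
        lib = _toy_library(["CCO", "CCO", "CCN"])
        dist, ids = pairwise_distance(lib)
        assert dist[0, 1] == 0.0
        assert dist[0, 2] > 0.0

    def test_disjoint_fingerprints_have_unit_distance(self):
        lib = _toy_library(["CCCC", "c1ccncc1"])
        dist, _ = pairwise_distance(lib)
        assert dist[0, 1] == 1.0

    def test_distance_axioms(self, chemspace):
        d = chemspace.distances
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert d.min() >= 0.0 and d.max() <= 1.0

    def test_matrix_matches_bit_set_arithmetic(self):
        """Oracle: recompute Tanimoto from explicit on-bit sets."""
        from rdkit import Chem

        from nsiscreen.chem import FP_MAX_PATH, FP_N_BITS

        lib = build_library(seed=42, n_compounds=10, membership_rule="all")
        dist, ids = pairwise_distance(lib)
        onbits = []
        for cid in ids:
            mol = Chem.MolFromSmiles(lib.get(cid).smiles)
            fp = Chem.RDKFingerprint(mol, maxPath=FP_MAX_PATH,
                                     fpSize=FP_N_BITS)
            onbits.append(set(fp.GetOnBits()))
        for i in range(10):
            for j in range(10):
                inter = len(onbits[i] & onbits[j])
                union = len(onbits[i] | onbits[j])
                assert dist[i, j] == pytest.approx(1 - inter / union)

    def test_single_compound_rejected(self):
        with pytest.raises(ValueError, match="2"):
            pairwise_distance(_toy_library(["CCO"]))


class TestClassicalMds:
    def test_zero_distances_collapse_to_origin(self):
        coords, _ = classical_mds(np.zeros((5, 5)))
        assert np.allclose(coords, 0.0)

    def test_planar_configuration_recovered_exactly(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(12, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        coords, evals = classical_mds(d)
        _, _, disparity = procrustes(pts, coords)
        assert disparity < 1e-12
        # only two meaningful eigenvalues for planar input
        assert np.all(np.abs(evals[2:]) < 1e-8 * evals[0])

    def test_unit_square_has_two_equal_leading_eigenvalues(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        _, evals = classical_mds(d)
        assert evals[0] == pytest.approx(evals[1])

    def test_embedded_distances_match_input_for_euclidean_data(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(15, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        coords, _ = classical_mds(d)
        d2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.allclose(d, d2, atol=1e-6)

    def test_asymmetric_input_rejected(self):
        bad = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            classical_mds(bad)


class TestBlockStructure:
    def test_within_block_distances_smaller_than_between(self, lib, chemspace):
        d = chemspace.distances
        r1 = np.array(chemspace.r1_labels)
        same = r1[:, None] == r1[None, :]
        iu = np.triu_indices(len(r1), k=1)
        within = d[iu][same[iu]].mean()
        between = d[iu][~same[iu]].mean()
        assert within < between

    def test_tight_separated_blocks_have_high_silhouette(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.05, size=(20, 2))
        b = rng.normal(5, 0.05, size=(20, 2))
        emb = np.vstack([a, b])
        labels = ["A"] * 20 + ["B"] * 20
        out = block_separation(emb, labels)
        assert out["silhouette"] > 0.5

    def test_random_binary_labels_center_silhouette_on_zero(self, chemspace):
        """Permutation null: a balanced random 2-way split scores ~0.

        (With many clusters the mean silhouette of random labels is
        biased negative by the min-over-other-clusters term, so the
        zero-centered null is the two-cluster one.)
        """
        rng = np.random.default_rng(3)
        n = len(chemspace.compound_ids)
        base = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
        sils = []
        for _ in range(20):
            out = block_separation(chemspace.embedding,
                                   base[rng.permutation(n)].tolist())
            sils.append(out["silhouette"])
        assert abs(np.mean(sils)) < 0.05

    def test_true_r1_labels_beat_their_permutation_null(self, chemspace):
        rng = np.random.default_rng(4)
        labels = np.array(chemspace.r1_labels)
        true_sil = block_separation(chemspace.embedding,
                                    labels.tolist())["silhouette"]
        null = [
            block_separation(
                chemspace.embedding,
                labels[rng.permutation(len(labels))].tolist(),
            )["silhouette"]
            for _ in range(20)
        ]
        assert true_sil > np.mean(null) + 5 * np.std(null)

    def test_single_block_rejected(self):
        with pytest.raises(ValueError, match="2 blocks"):
            block_separation(np.zeros((5, 2)), ["A"] * 5)


class TestOverlayNsi:
    def test_uniform_nsi_is_degenerate(self, chemspace):
        nsi = {cid: 0.5 for cid in chemspace.compound_ids}
        out = overlay_nsi(chemspace, nsi)
        assert out["degenerate"]

    def test_block_concentrated_hits_are_reported_as_co_blocked(self, chemspace):
        # make every A-block compound a strong hit
        nsi = {cid: (-5.0 if r1 == "A" else 0.0)
               for cid, r1 in zip(chemspace.compound_ids, chemspace.r1_labels)}
        out = overlay_nsi(chemspace, nsi, top_k=10)
        assert out["n_hit_blocks"] == 1
        assert out["co_block_fraction"] == 1.0
        assert out["isolated_hits"] == []

    def test_isolated_hit_is_flagged(self, chemspace):
        nsi = {cid: 0.0 for cid in chemspace.compound_ids}
        nsi["C9"] = -5.0   # lone hit in its block
        for cid, r1 in zip(chemspace.compound_ids, chemspace.r1_labels):
            if r1 == "G" and cid != "C9":
                nsi[cid] = min(nsi[cid], -3.0)
        out = overlay_nsi(chemspace, nsi, top_k=10)
        assert "C9" in out["isolated_hits"]


class TestPropertyCorrelation:
    def test_response_equal_to_property_is_perfectly_correlated(self, lib):
        props = compute_properties(lib)
        resp = {"uptake": dict(zip(props.index, props["mol_weight"]))}
        out = property_correlation(props, resp, n_permutations=2000, seed=0)
        row = out[(out["property"] == "mol_weight")].iloc[0]
        assert row["spearman"] == pytest.approx(1.0)
        assert row["perm_p"] <= 1 / 2001 + 1e-12

    def test_independent_response_shows_no_association(self, lib):
        props = compute_properties(lib)
        coeffs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            resp = {"nsi": {c: float(rng.normal()) for c in props.index}}
            out = property_correlation(props, resp, n_permutations=200,
                                       seed=seed)
            coeffs.extend(out["spearman"].abs().dropna().tolist())
        assert np.mean(coeffs) < 0.2

    def test_coefficients_match_manual_rank_arithmetic(self):
        lib = build_library(seed=42, n_compounds=10, membership_rule="all")
        props = compute_properties(lib)
        rng = np.random.default_rng(5)
        resp_vals = {c: float(rng.normal()) for c in props.index}
        out = property_correlation(props, {"r": resp_vals},
                                   n_permutations=100, seed=0)
        from scipy.stats import rankdata

        y = np.array([resp_vals[c] for c in props.index])
        for prop in ("mol_weight", "logp", "tpsa"):
            x = props[prop].to_numpy(dtype=float)
            rx, ry = rankdata(x), rankdata(y)
            manual = np.corrcoef(rx, ry)[0, 1]
            got = out[out["property"] == prop]["spearman"].iloc[0]
            assert got == pytest.approx(manual, abs=1e-12)
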