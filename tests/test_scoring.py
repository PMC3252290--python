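"""NSI computation, invariances, and phenotype calls."""

import numpy as np
import pytest

from nsiscreen import (
    BehaviorThresholds,
    ScoringParams,
    classify_behavior,
    classify_localization,
    compute_nsi,
    compute_stats,
    score_records,
    well_summary,
)
from nsiscreen.register import FluxRecord
from nsiscreen.scoring import CompoundStats


def _rec(f0, f1, cid="A1", line="line1", cell_id=1, extras=None):
    return FluxRecord(cell_id=cell_id, well_id="w", field_id="f",
                      compound_id=cid, cell_line=line, wavelength="549",
                      f_t0=f0, f_t1=f1, extras=extras or {})


class TestComputeStats:
    def test_singleton_group(self):
        s = compute_stats([_rec(5.0, 2.0)])
        assert (s.f_max, s.f_min) == (5.0, 2.0)

    def test_flat_group_is_degenerate(self):
        s = compute_stats([_rec(3.0, 3.0), _rec(3.0, 3.0, cell_id=2)])
        assert s.f_max == s.f_min == 3.0
        assert not s.informative

    def test_extrema_match_exhaustive_scan(self):
        rng = np.random.default_rng(0)
        recs = [_rec(a, b, cell_id=i)
                for i, (a, b) in enumerate(rng.uniform(0, 100, size=(50, 2)))]
        s = compute_stats(recs)
        allv = [r.f_t0 for r in recs] + [r.f_t1 for r in recs]
        assert s.f_max == max(allv) and s.f_min == min(allv)

    def test_mixed_groups_rejected(self):
        with pytest.raises(ValueError, match="single compound"):
            compute_stats([_rec(1, 2, cid="A1"), _rec(1, 2, cid="B1")])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_stats([])


class TestComputeNsi:
    def test_equal_fluxes_score_exactly_zero(self):
        stats = CompoundStats("A1", "line1", f_max=10.0, f_min=0.0)
        score = compute_nsi(_rec(4.0, 4.0), stats)
        assert score.nsi == 0.0

    def test_full_clearance_matches_direct_formula(self):
        # F_hat_T0 = 1, F_hat_T1 = 0, mu = 0.01 -> ln(0.01/1.01)
        stats = CompoundStats("A1", "line1", f_max=1.0, f_min=0.0)
        params = ScoringParams(mu=0.01, epsilon=1e-15)
        score = compute_nsi(_rec(1.0, 0.0), stats, params)
        assert score.nsi == pytest.approx(np.log(0.01 / 1.01), rel=1e-9)
        assert score.nsi == pytest.approx(-4.615, abs=1e-3)

    def test_accumulation_scores_positive(self):
        stats = CompoundStats("A1", "line1", f_max=10.0, f_min=0.0)
        assert compute_nsi(_rec(2.0, 8.0), stats).nsi > 0

    def test_sign_tracks_flux_difference(self):
        rng = np.random.default_rng(1)
        stats = CompoundStats("A1", "line1", f_max=100.0, f_min=0.0)
        for f0, f1 in rng.uniform(0, 100, size=(100, 2)):
            s = compute_nsi(_rec(f0, f1), stats)
            assert np.sign(s.nsi) == np.sign(f1 - f0)

    def test_flat_group_scores_zero_and_flags(self):
        stats = CompoundStats("A1", "line1", f_max=3.0, f_min=3.0)
        s = compute_nsi(_rec(3.0, 3.0), stats)
        assert s.nsi == 0.0 and s.flagged

    def test_matches_independent_oracle_on_random_records(self):
        """Direct evaluation of the stated formula, separate code path."""
        rng = np.random.default_rng(2)
        params = ScoringParams(mu=0.01)
        for _ in range(1000):
            vals = rng.uniform(0, 1000, size=4)
            f0, f1 = vals[0], vals[1]
            fmax = max(vals.max(), f0, f1)
            fmin = min(vals.min(), f0, f1)
            stats = CompoundStats("A1", "line1", f_max=fmax, f_min=fmin)
            s = compute_nsi(_rec(f0, f1), stats, params)
            span = fmax - fmin + params.epsilon
            expected = np.log(((f1 - fmin) / span + 0.01)
                              / ((f0 - fmin) / span + 0.01))
            assert s.nsi == pytest.approx(expected, abs=1e-12)

    def test_offset_and_scale_invariance_within_a_group(self):
        rng = np.random.default_rng(3)
        recs = [_rec(a, b, cell_id=i)
                for i, (a, b) in enumerate(rng.uniform(10, 90, size=(30, 2)))]
        base = [s.nsi for s in score_records(recs)]
        shifted = [_rec(r.f_t0 + 55.0, r.f_t1 + 55.0, cell_id=r.cell_id)
                   for r in recs]
        scaled = [_rec(r.f_t0 * 7.5, r.f_t1 * 7.5, cell_id=r.cell_id)
                  for r in recs]
        assert np.allclose([s.nsi for s in score_records(shifted)], base,
                           atol=1e-6)
        assert np.allclose([s.nsi for s in score_records(scaled)], base,
                           atol=1e-6)

    def test_percent_drop_variant_agrees_on_sign_convention(self):
        stats = CompoundStats("A1", "line1", f_max=10.0, f_min=0.0)
        params = ScoringParams(variant="percent_drop")
        cleared = compute_nsi(_rec(10.0, 1.0), stats, params)
        retained = compute_nsi(_rec(10.0, 12.0), stats, params)
        assert cleared.nsi < 0 < retained.nsi
        assert cleared.nsi == pytest.approx(-0.9, rel=1e-6)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="mu"):
            ScoringParams(mu=0.0)
        with pytest.raises(ValueError, match="variant"):
            ScoringParams(variant="ratio")


def _score(nsi, nuc=0.0, inner=0.0, mid=0.0, outer=0.0):
    """NsiScore with compartment densities (a.u./px) in its extras."""
    from nsiscreen.scoring import NsiScore

    interior = (nuc + inner + mid) / 3.0
    return NsiScore(
        cell_id=1, well_id="w", compound_id="A1", cell_line="line1",
        nsi=nsi, f_hat_t0=0.5, f_hat_t1=0.5,
        extras={"interior_mean_t0": interior, "rim_mean_t0": outer,
                "region_mean_t0": (nuc + inner + mid + outer) / 4.0,
                "nuc_mean_t0": nuc, "perinuc_mean_t0": inner,
                "inner_mean_t0": inner, "mid_mean_t0": mid,
                "outer_mean_t0": outer},
    )


class TestBehaviorCalls:
    def test_dark_cell_is_no_entry(self):
        assert classify_behavior(_score(0.0), uptake_scale=100.0) == "no_entry"

    def test_faint_rim_alone_is_still_no_entry(self):
        # rim/interior ratio is high but the rim itself is at noise level
        assert classify_behavior(_score(0.0, outer=2.0),
                                 uptake_scale=100.0) == "no_entry"

    def test_bright_rim_dark_interior_is_membrane_bound(self):
        s = _score(0.0, nuc=2.0, inner=3.0, mid=10.0, outer=60.0)
        assert classify_behavior(s, uptake_scale=100.0) == "membrane_bound"

    def test_bright_retained_cell_accumulates(self):
        s = _score(0.1, nuc=80.0, inner=80.0, mid=80.0, outer=40.0)
        assert classify_behavior(s, uptake_scale=100.0) == "accumulate"

    def test_bright_cleared_cell_is_in_and_out(self):
        s = _score(-2.0, nuc=80.0, inner=80.0, mid=80.0, outer=40.0)
        assert classify_behavior(s, uptake_scale=100.0) == "in_and_out"

    def test_missing_rim_statistics_rejected(self):
        from nsiscreen.scoring import NsiScore

        bare = NsiScore(1, "w", "A1", "line1", 0.0, 0.5, 0.5)
        with pytest.raises(ValueError, match="rim"):
            classify_behavior(bare)


class TestLocalizationCalls:
    def test_uniform_signal_is_diffuse(self):
        s = _score(0.0, nuc=10.0, inner=10.0, mid=10.0, outer=8.0)
        assert classify_localization(s) == "diffuse"

    def test_signal_only_in_nucleus_is_nuclear(self):
        s = _score(0.0, nuc=40.0, inner=2.0, mid=1.0, outer=0.5)
        assert classify_localization(s) == "nuclear"

    def test_annulus_signal_is_perinuclear(self):
        s = _score(0.0, nuc=5.0, inner=30.0, mid=12.0, outer=2.0)
        assert classify_localization(s) == "perinuclear"

    def test_blank_cell_defaults_to_diffuse(self):
        assert classify_localization(_score(0.0)) == "diffuse"


class TestWellSummary:
    def test_single_cell_well(self):
        from nsiscreen.scoring import NsiScore

        s = NsiScore(1, "w", "A1", "line1", -1.5, 0.5, 0.1)
        out = well_summary([s])
        assert out["mean_nsi"] == -1.5 and out["n_cells"] == 1

    def test_symmetric_scores_average_to_zero(self):
        from nsiscreen.scoring import NsiScore

        scores = [NsiScore(i, "w", "A1", "line1", v, 0.5, 0.5)
                  for i, v in enumerate((-1.0, 0.0, 1.0))]
        out = well_summary(scores)
        assert out["mean_nsi"] == 0.0 and out["median_nsi"] == 0.0

    def test_mean_matches_direct_arithmetic(self):
        from nsiscreen.scoring import NsiScore

        rng = np.random.default_rng(4)
        vals = rng.normal(size=25)
        scores = [NsiScore(i, "w", "A1", "line1", float(v), 0.5, 0.5)
                  for i, v in enumerate(vals)]
        assert well_summary(scores)["mean_nsi"] == pytest.approx(
            vals.sum() / len(vals), rel=1e-12)

    def test_empty_well_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            well_summary([])
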