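import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from outwelling.isotopes import IsotopeSignature, SourceEndmember, SourceSet
from outwelling.mixing import (
    MixingConfig,
    enumerate_simplex,
    feasible_solutions,
    profile_table,
    sensitivity_resample,
    site_profile,
)


def brute_force_triples(increment):
    """Independent nested-loop enumeration for k=3 (oracle)."""
    out = []
    for a in range(0, 101, increment):
        for b in range(0, 101 - a, increment):
            c = 100 - a - b
            if c % increment == 0:
                out.append((a, b, c))
    return out


class TestEnumeration:
    def test_two_sources_coarse(self):
        grid = enumerate_simplex(2, 50)
        assert sorted(map(tuple, grid.tolist())) == [(0, 100), (50, 50), (100, 0)]

    @pytest.mark.parametrize(
        "k, increment, expected",
        [(3, 10, 66), (3, 5, 231), (4, 10, 286), (5, 20, 126)],
    )
    def test_stars_and_bars_counts(self, k, increment, expected):
        assert enumerate_simplex(k, increment).shape[0] == expected
        assert expected == math.comb(100 // increment + k - 1, k - 1)

    def test_matches_nested_loop_oracle(self):
        grid = set(map(tuple, enumerate_simplex(3, 10).tolist()))
        assert grid == set(brute_force_triples(10))

    def test_rows_sum_to_100_and_unique(self):
        grid = enumerate_simplex(4, 5)
        assert (grid.sum(axis=1) == 100).all()
        assert len(set(map(tuple, grid.tolist()))) == grid.shape[0]

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            enumerate_simplex(1, 10)

    def test_bad_increment_rejected(self):
        with pytest.raises(ValueError):
            enumerate_simplex(3, 3)


class TestFeasibility:
    def test_vertex_mixture_recovers_source(self, three_sources):
        cfg = MixingConfig(increment=1, tol_start=0.1)
        fs = feasible_solutions(three_sources.sources[0].mean, three_sources, cfg)
        assert not fs.indeterminable
        assert any((row == [100, 0, 0]).all() for row in fs.proportions)
        assert fs.summary.loc["a", "p50"] >= 0.9

    def test_two_source_closed_form(self, spom_sources):
        # single informative isotope: analytic p = (mix - s2)/(s1 - s2)
        mix = IsotopeSignature(-21.25, float("nan"))
        fs = feasible_solutions(mix, spom_sources, MixingConfig(increment=1, tol_start=0.1))
        analytic = (-21.25 + 19.2) / (-22.5 + 19.2)
        assert fs.summary.loc["estuary-SPOM", "p50"] == pytest.approx(analytic, abs=0.01)

    def test_outside_polygon_is_indeterminable(self, three_sources):
        fs = feasible_solutions(
            IsotopeSignature(-40.0, 25.0), three_sources, MixingConfig(increment=5)
        )
        assert fs.indeterminable and fs.n_solutions == 0
        assert np.isnan(fs.summary.to_numpy()).all()

    def test_degenerate_identical_sources_flagged_broad(self):
        same = SourceSet(
            "deg",
            (
                SourceEndmember("a", IsotopeSignature(-20, 5)),
                SourceEndmember("b", IsotopeSignature(-20, 5)),
            ),
        )
        fs = feasible_solutions(IsotopeSignature(-20, 5), same, MixingConfig(increment=5))
        assert fs.n_solutions == 21  # everything feasible
        assert fs.indeterminable  # breadth criterion

    def test_tolerance_escalation_recorded(self, three_sources):
        # mixture slightly off the polygon needs a raised tolerance
        mix = IsotopeSignature(-24.3, 3.8)
        fs = feasible_solutions(mix, three_sources, MixingConfig(increment=5))
        assert fs.tolerance_used > 0.1
        assert fs.tolerance_used <= 0.5

    def test_tolerance_monotonicity(self, three_sources):
        mix = IsotopeSignature(-20.3, 7.1)
        sets = []
        for tol in (0.1, 0.3, 0.5):
            cfg = MixingConfig(increment=5, tol_start=tol, tol_max=tol)
            fs = feasible_solutions(mix, three_sources, cfg)
            sets.append(set(map(tuple, fs.proportions.tolist())))
        assert sets[0] <= sets[1] <= sets[2]

    def test_exact_grid_mixture_recovered(self, spom_sources):
        # dual isotope, 2 sources: mixture built exactly on the grid
        means = spom_sources.mean_matrix()
        for p in (0.2, 0.5, 0.8):
            mix = p * means[0] + (1 - p) * means[1]
            fs = feasible_solutions(mix, spom_sources, MixingConfig(increment=1))
            assert fs.summary.loc["estuary-SPOM", "p50"] == pytest.approx(p, abs=0.01)

    def test_permutation_symmetry(self, three_sources):
        mix = IsotopeSignature(-20.0, 7.0)
        cfg = MixingConfig(increment=5)
        fs = feasible_solutions(mix, three_sources, cfg)
        flipped = SourceSet("tri", tuple(reversed(three_sources.sources)))
        fs2 = feasible_solutions(mix, flipped, cfg)
        for name in three_sources.names:
            assert fs.summary.loc[name].equals(fs2.summary.loc[name])

    def test_euclidean_metric_subset_of_per_isotope(self, three_sources):
        mix = IsotopeSignature(-20.3, 7.1)
        per = feasible_solutions(mix, three_sources, MixingConfig(increment=5, tol_start=0.3, tol_max=0.3))
        euc = feasible_solutions(
            mix, three_sources, MixingConfig(increment=5, tol_start=0.3, tol_max=0.3, metric="euclidean")
        )
        assert set(map(tuple, euc.proportions.tolist())) <= set(map(tuple, per.proportions.tolist()))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_feasible_rows_sum_to_100(self, seed):
        sources = SourceSet(
            "tri",
            (
                SourceEndmember("a", IsotopeSignature(-24.0, 4.0)),
                SourceEndmember("b", IsotopeSignature(-16.0, 6.0)),
                SourceEndmember("c", IsotopeSignature(-20.0, 12.0)),
            ),
        )
        rng = np.random.default_rng(seed)
        w = rng.dirichlet(np.ones(3))
        mix = w @ sources.mean_matrix() + rng.normal(0, 0.2, 2)
        fs = feasible_solutions(mix, sources, MixingConfig(increment=5))
        if fs.n_solutions:
            assert (fs.proportions.sum(axis=1) == 100).all()
            s = fs.summary
            assert (s["p05"] <= s["p25"]).all() and (s["p25"] <= s["p50"]).all()
            assert (s["p50"] <= s["p75"]).all() and (s["p75"] <= s["p95"]).all()


class TestSiteProfile:
    def test_single_consumer_equals_direct_run(self, three_sources):
        from outwelling.isotopes import ConsumerSample

        sig = IsotopeSignature(-20.0, 7.0)
        cons = [ConsumerSample("S1", 1, "Dosinia subrosea", "foot muscle", sig)]
        cfg = MixingConfig(increment=5)
        prof = site_profile(cons, three_sources, cfg)
        direct = feasible_solutions(sig, three_sources, cfg)
        assert prof["S1"].summary.equals(direct.summary)

    def test_consumers_averaged_per_site(self, three_sources):
        from outwelling.isotopes import ConsumerSample

        cons = [
            ConsumerSample("S1", 1, "sp", "t", IsotopeSignature(-20, 8)),
            ConsumerSample("S1", 1, "sp", "t", IsotopeSignature(-22, 10)),
        ]
        cfg = MixingConfig(increment=5)
        prof = site_profile(cons, three_sources, cfg)
        direct = feasible_solutions(IsotopeSignature(-21, 9), three_sources, cfg)
        assert prof["S1"].summary.equals(direct.summary)
        assert prof["S1"].metadata["n_consumers"] == 2

    def test_profile_table_shape(self, three_sources):
        from outwelling.isotopes import ConsumerSample

        cons = [
            ConsumerSample(f"S{r}", r, "sp", "t", IsotopeSignature(-20 - 0.2 * r, 7))
            for r in range(1, 4)
        ]
        tab = profile_table(site_profile(cons, three_sources, MixingConfig(increment=5)))
        assert len(tab) == 3 * 3  # sites x sources
        assert list(tab.columns[:3]) == ["site_id", "distance_rank", "source"]
        assert set(tab["tolerance_used"]) <= {0.1, 0.2, 0.3, 0.4, 0.5}


class TestSensitivity:
    def test_zero_se_is_deterministic(self, three_sources):
        mix = IsotopeSignature(-20.0, 7.0)
        cfg = MixingConfig(increment=5)
        out = sensitivity_resample(mix, three_sources, cfg, draws=5, seed=1)
        base = feasible_solutions(mix, three_sources, cfg).summary["p50"]
        assert np.allclose(out.to_numpy(), np.tile(base.to_numpy(), (5, 1)))

    def test_reproducible_under_seed(self):
        noisy = SourceSet(
            "n",
            (
                SourceEndmember("a", IsotopeSignature(-24, 4), (0.2, 0.2)),
                SourceEndmember("b", IsotopeSignature(-16, 6), (0.2, 0.2)),
                SourceEndmember("c", IsotopeSignature(-20, 12), (0.2, 0.2)),
            ),
        )
        mix = IsotopeSignature(-20.0, 7.0)
        cfg = MixingConfig(increment=5)
        a = sensitivity_resample(mix, noisy, cfg, draws=10, seed=7)
        b = sensitivity_resample(mix, noisy, cfg, draws=10, seed=7)
        assert a.equals(b)

    def test_small_se_stays_near_deterministic(self):
        noisy = SourceSet(
            "n",
            (
                SourceEndmember("a", IsotopeSignature(-24, 4), (0.2, 0.2)),
                SourceEndmember("b", IsotopeSignature(-16, 6), (0.2, 0.2)),
                SourceEndmember("c", IsotopeSignature(-20, 12), (0.2, 0.2)),
            ),
        )
        mix = IsotopeSignature(-20.0, 7.0)
        cfg = MixingConfig(increment=2, tol_start=0.2, tol_max=0.5)
        out = sensitivity_resample(mix, noisy, cfg, draws=100, seed=3)
        base = feasible_solutions(mix, noisy, cfg).summary["p50"]
        assert np.abs(out.median() - base).max() <= 0.05
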