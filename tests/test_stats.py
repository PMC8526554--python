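"""Response definition, partial correlation, FDR, and the association layer."""

import numpy as np
import pytest

from dynstates.errors import ComputationError, InputError
from dynstates.stats import (dbs_response, fdr_bh, partial_correlation,
                             associate)
from dynstates.states import TemporalStats
from dynstates.dynamic_fc import WindowSpec
from oracles import bh_adjust_brute, partial_corr_brute


class TestDbsResponse:
    def test_cohort_mean_scores(self):
        # note: a cohort mean of per-patient percentages differs from the
        # percentage computed on cohort-mean scores
        assert dbs_response(27.1, 12.8) == pytest.approx(52.77, abs=0.005)

    def test_no_change_and_full_resolution(self):
        assert dbs_response(10, 10) == 0.0
        assert dbs_response(20, 0) == 100.0

    def test_nonpositive_onoff_rejected(self):
        with pytest.raises(InputError):
            dbs_response(0, 5)


class TestPartialCorrelation:
    def test_reduces_to_pearson_without_covariates(self, rng):
        x, y = rng.standard_normal((2, 30))
        r, _, _ = partial_correlation(x, y)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_self_correlation_is_one(self, rng):
        x = rng.standard_normal(25)
        z = rng.standard_normal((25, 2))
        r, p, _ = partial_correlation(x, x, z)
        assert r == pytest.approx(1.0)
        assert p < 1e-12

    def test_matches_residualization_oracle(self, rng):
        x = rng.standard_normal(20)
        z = rng.standard_normal(20)
        y = 0.5 * x + 0.3 * z + rng.standard_normal(20)
        r, _, _ = partial_correlation(x, y, z)
        assert r == pytest.approx(partial_corr_brute(x, y, z), abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        x = rng.standard_normal(40)
        z = rng.standard_normal((40, 2))
        y = 0.4 * x + 0.2 * z[:, 0] + rng.standard_normal(40)
        df = pd.DataFrame({"x": x, "y": y, "z1": z[:, 0], "z2": z[:, 1]})
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["z1", "z2"])
        r, p, ci = partial_correlation(x, y, z)
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)
        lo, hi = ref["CI95"].iloc[0]
        assert ci[0] == pytest.approx(lo, abs=0.01)
        assert ci[1] == pytest.approx(hi, abs=0.01)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        z = rng.standard_normal((30, 2))
        r1, p1, _ = partial_correlation(x, y, z)
        r2, p2, _ = partial_correlation(3 * x - 1, -2 * y + 5,
                                        np.column_stack([5 * z[:, 0] + 2, z[:, 1]]))
        assert abs(r2) == pytest.approx(abs(r1), abs=1e-10)
        assert p2 == pytest.approx(p1, rel=1e-8)

    def test_ci_contains_r(self, rng):
        x, y = rng.standard_normal((2, 15))
        r, _, (lo, hi) = partial_correlation(x, y)
        assert lo <= r <= hi

    def test_rank_deficient_covariates_rejected(self, rng):
        x, y = rng.standard_normal((2, 20))
        col = rng.standard_normal(20)
        with pytest.raises(ComputationError):
            partial_correlation(x, y, np.column_stack([col, col]))

    def test_insufficient_n_rejected(self, rng):
        with pytest.raises(InputError):
            partial_correlation(rng.standard_normal(4),
                                rng.standard_normal(4),
                                rng.standard_normal((4, 2)))


class TestFdr:
    def test_step_up_hand_example(self):
        adj = fdr_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_single_p_unchanged(self):
        assert fdr_bh([0.2])[0] == pytest.approx(0.2)

    def test_adjusted_at_least_raw_and_rank_preserving(self, rng):
        p = rng.uniform(0.001, 1, 50)
        adj = fdr_bh(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_matches_brute_step_up(self, rng):
        p = rng.uniform(0.001, 1, 23)
        assert np.allclose(fdr_bh(p), bh_adjust_brute(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            fdr_bh([0.0, 0.1])
        with pytest.raises(InputError):
            fdr_bh([1.5])


class TestAssociate:
    def _inputs(self, rng, n=20):
        ids = [f"s{i}" for i in range(n)]
        auc = {"2": {s: {
            "global_efficiency": rng.uniform(0.1, 0.3),
            "assortativity": rng.uniform(-0.1, 0.1),
            "clustering_coeff": rng.uniform(0, 1, 4),
            "betweenness": rng.uniform(0, 0.2, 4),
        } for s in ids}}
        fc = {"2": {s: None for s in ids}}
        spec = WindowSpec(22, 3.0, 1, 2.7)
        temporal = []
        for s in ids:
            f1 = rng.uniform(0.2, 0.8)
            temporal.append(TemporalStats(
                s, np.array([f1, 1 - f1]),
                rng.uniform(0.5, 5.0, 2), int(rng.integers(1, 9))))
        response = {s: rng.uniform(20, 80) for s in ids}
        ofc = {s: rng.uniform(0.1, 0.4) for s in ids}
        return auc, fc, temporal, response, ofc

    def test_families_and_fdr_scoping(self, rng):
        auc, fc, temporal, response, ofc = self._inputs(rng)
        results = associate(auc, fc, temporal, response, ofc,
                            region_labels=("a", "b", "c", "d"))
        fams = {r.family for r in results}
        assert "global/2" in fams
        assert "local/clustering_coeff/2" in fams
        assert "temporal" in fams
        for r in results:
            if r.family.startswith("global") or r.family == "temporal":
                assert r.p_fdr == r.p_value
            assert r.p_fdr >= r.p_value - 1e-15

    def test_zero_variance_response_rejected(self, rng):
        auc, fc, temporal, response, ofc = self._inputs(rng)
        flat = {s: 50.0 for s in response}
        with pytest.raises(ComputationError):
            associate(auc, fc, temporal, flat, ofc)

    def test_missing_state_subjects_excluded_pairwise(self, rng):
        auc, fc, temporal, response, ofc = self._inputs(rng)
        dropped = list(auc["2"])[:3]
        for s in dropped:
            auc["2"][s]["assortativity"] = np.nan
        results = associate(auc, fc, temporal, response, ofc)
        assort = [r for r in results if r.metric_name == "assortativity_auc"]
        assert assort[0].n_used == 17


class TestNullCalibration:
    def test_raw_p_uniform_under_null(self, rng):
        """Type-I behaviour: ~5% of raw p-values below 0.05 on null data."""
        hits = 0
        n_tests = 600
        for _ in range(n_tests):
            x = rng.standard_normal(20)
            y = rng.standard_normal(20)
            z = rng.standard_normal(20)
            _, p, _ = partial_correlation(x, y, z)
            hits += p < 0.05
        assert hits / n_tests == pytest.approx(0.05, abs=0.03)
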