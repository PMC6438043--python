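import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from paritysig import preprocess as pp
from paritysig import synthetic_data as sd
from paritysig.io_config import (
    CohortMetadata,
    ExpressionMatrix,
    PresenceCalls,
    ValidationError,
)


def _meta(parities, batches=None, replicate_of=None):
    n = len(parities)
    batches = batches or ["B1"] * n
    replicate_of = replicate_of or [None] * n
    df = pd.DataFrame(
        {
            "parity": parities,
            "tslp_years": [3.0 if p == "parous" else np.nan for p in parities],
            "age_years": 35.0,
            "bmi": 24.0,
            "smoking_duration_years": 2.0,
            "cycle_iud": "luteal",
            "batch": batches,
            "replicate_of": np.array(replicate_of, dtype=object),
        },
        index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"),
    )
    return CohortMetadata(df)


def _calls_from_fracs(frac_par, frac_nul, n_par=10, n_nul=10):
    """One probe with the stated per-group P fractions (deterministic)."""
    row = ["P"] * int(round(frac_par * n_par)) + ["A"] * (
        n_par - int(round(frac_par * n_par))
    )
    row += ["P"] * int(round(frac_nul * n_nul)) + ["A"] * (
        n_nul - int(round(frac_nul * n_nul))
    )
    calls = PresenceCalls(
        pd.DataFrame([row], index=["probe"], columns=[f"S{i}" for i in range(20)])
    )
    meta = _meta(["parous"] * n_par + ["nulliparous"] * n_nul)
    return calls, meta


class TestPresenceFilter:
    def test_low_presence_small_diff_removed(self):
        calls, meta = _calls_from_fracs(0.7, 0.5)  # overall 60%, diff 20%
        report = pp.filter_by_presence(calls, meta)
        assert report.kept_probe_ids == []

    def test_high_presence_kept(self):
        calls, meta = _calls_from_fracs(0.8, 0.8)
        report = pp.filter_by_presence(calls, meta)
        assert report.kept_probe_ids == ["probe"]

    def test_large_group_difference_rescues(self):
        calls, meta = _calls_from_fracs(0.9, 0.3)  # overall 60%, diff 60%
        report = pp.filter_by_presence(calls, meta)
        assert report.kept_probe_ids == ["probe"]

    def test_marginal_not_counted_as_present(self):
        calls, meta = _calls_from_fracs(0.8, 0.8)
        data = calls.data.copy()
        data.iloc[0, :] = "M"
        report = pp.filter_by_presence(PresenceCalls(data), meta)
        assert report.kept_probe_ids == []

    def test_empty_group_rejected(self):
        calls, _ = _calls_from_fracs(0.8, 0.8)
        meta = _meta(["parous"] * 20)
        with pytest.raises(ValueError):
            pp.filter_by_presence(calls, meta)


class TestCVFilter:
    def _expr_with_cvs(self, cvs):
        # one sample pair per probe scaled to hit the requested linear CV:
        # values (m-d, m+d) have CV = d/m (population-free: ddof=1 over 2
        # samples gives sd = d*sqrt(2)); use 3 samples for a clean ddof=1 CV
        rows = []
        for cv in cvs:
            m = 100.0
            d = cv * m  # sd target
            rows.append([m - d, m, m + d])
        linear = np.array(rows)
        return ExpressionMatrix(
            pd.DataFrame(
                np.log2(linear),
                index=[f"p{i}" for i in range(len(cvs))],
                columns=["S0", "S1", "S2"],
            )
        )

    def test_first_quartile_removed(self):
        expr = self._expr_with_cvs([0.1, 0.2, 0.3, 0.4])
        report = pp.FilterReport(4, 4, None, list(expr.probe_ids), pd.DataFrame(index=expr.probe_ids))
        out = pp.filter_by_cv(expr, report)
        assert out.n_after_cv == 3
        assert "p0" not in out.kept_probe_ids

    def test_ties_survive(self):
        expr = self._expr_with_cvs([0.2, 0.2, 0.2, 0.2])
        report = pp.FilterReport(4, 4, None, list(expr.probe_ids), pd.DataFrame(index=expr.probe_ids))
        out = pp.filter_by_cv(expr, report)
        assert out.n_after_cv == 4

    def test_filter_order_presence_first(self, cohort):
        # the CV quartile must be computed among presence survivors only
        expr, calls, _ = sd.simulate_expression(cohort, 3000, sd.TruthSpec(), seed=31)
        joint = pp.filter_probes(expr, calls, cohort)
        pres = pp.filter_by_presence(calls, cohort)
        recomputed = pp.filter_by_cv(expr, pres)
        assert joint.kept_probe_ids == recomputed.kept_probe_ids
        kept = set(joint.kept_probe_ids)
        assert kept <= set(pres.kept_probe_ids) <= set(expr.probe_ids)

    @pytest.mark.slow
    def test_joint_retention_near_27_percent(self):
        # scaled analogue of the study's 27% post-filter retention
        cohort = sd.simulate_cohort(79, 30, seed=11)
        expr, calls, _ = sd.simulate_expression(cohort, 54_675, sd.TruthSpec(), seed=12)
        report = pp.filter_probes(expr, calls, cohort)
        assert abs(report.n_after_cv / report.n_input_probes - 0.27) < 0.03


class TestCombat:
    def _expr(self, values, samples=None):
        values = np.asarray(values, dtype=float)
        samples = samples or [f"S{i}" for i in range(values.shape[1])]
        return ExpressionMatrix(
            pd.DataFrame(
                values, index=[f"p{i}" for i in range(values.shape[0])], columns=samples
            )
        )

    def test_pure_location_shift_removed(self):
        rng = np.random.default_rng(0)
        base = rng.normal(8, 1, size=(50, 6))
        values = np.concatenate([base, base + 1.0], axis=1)
        expr = self._expr(values)
        batches = ["A"] * 6 + ["B"] * 6
        adj = pp.combat_adjust(expr, batches).adjusted.values
        means_a = adj[:, :6].mean(axis=1)
        means_b = adj[:, 6:].mean(axis=1)
        np.testing.assert_allclose(means_a, means_b, atol=1e-6)

    def test_duplicated_identical_batches_identity(self):
        rng = np.random.default_rng(1)
        half = rng.normal(8, 1, size=(40, 5))
        values = np.concatenate([half, half], axis=1)
        expr = self._expr(values)
        batches = ["A"] * 5 + ["B"] * 5
        adj = pp.combat_adjust(expr, batches).adjusted.values
        np.testing.assert_allclose(adj, values, atol=1e-6)

    def test_grand_mean_preserved_equal_batches(self):
        rng = np.random.default_rng(2)
        values = rng.normal(8, 1, size=(30, 12))
        expr = self._expr(values)
        batches = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        adj = pp.combat_adjust(expr, batches).adjusted.values
        np.testing.assert_allclose(
            adj.mean(axis=1), values.mean(axis=1), atol=1e-6
        )

    def test_single_sample_batch_rejected(self):
        expr = self._expr(np.zeros((5, 3)) + [[1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="single sample"):
            pp.combat_adjust(expr, ["A", "A", "B"])

    def test_single_batch_rejected(self):
        expr = self._expr(np.random.default_rng(3).normal(size=(5, 4)))
        with pytest.raises(ValueError, match="two batches"):
            pp.combat_adjust(expr, ["A"] * 4)

    def test_batch_f_statistic_after_adjustment(self):
        # Monte-Carlo null behavior: batch signal is gone after correction
        cohort = sd.simulate_cohort(79, 30, seed=5)
        expr, _, _ = sd.simulate_expression(
            cohort, 1000, sd.TruthSpec(batch_location_sd=0.3), seed=6
        )
        adj = pp.combat_adjust(expr, cohort.data["batch"]).adjusted
        batches = cohort.data["batch"]
        groups = [
            adj.data[batches.index[batches == b]].to_numpy(float)
            for b in batches.unique()
        ]
        fs = [
            stats.f_oneway(*[g[i] for g in groups]).statistic
            for i in range(adj.data.shape[0])
        ]
        assert np.mean(fs) <= 1.2

    def test_scale_factors_positive(self):
        rng = np.random.default_rng(4)
        expr = self._expr(rng.normal(size=(20, 10)))
        fit = pp.combat_adjust(expr, ["A"] * 5 + ["B"] * 5)
        assert (fit.delta2.to_numpy() > 0).all()


class TestConcordance:
    def test_identical_vectors(self):
        assert pp.lin_ccc(np.arange(5.0), np.arange(5.0)) == pytest.approx(1.0)

    def test_shifted_vector_hand_value(self):
        # x=(1,2,3), y=x+1: CCC = 2*(2/3) / (2/3 + 2/3 + 1) = 4/7
        x = np.array([1.0, 2.0, 3.0])
        assert pp.lin_ccc(x, x + 1.0) == pytest.approx(4.0 / 7.0)

    def test_low_noise_replicates_pass_qc_gate(self):
        # closed form: CCC ~ 1/(1 + sigma^2/s^2) = 1/1.01 with the
        # replicate pair sharing its signal
        rng = np.random.default_rng(6)
        signal = rng.normal(8.0, 1.0, size=5000)
        x = signal + rng.normal(0, 0.1, size=5000)
        y = signal + rng.normal(0, 0.1, size=5000)
        ccc = pp.lin_ccc(x, y)
        assert ccc > 0.98
        assert ccc == pytest.approx(1.0 / 1.01, abs=0.01)

    def test_replicate_concordance_pipeline(self, cohort):
        # cross-batch replicates are compared after batch adjustment
        expr, _, _ = sd.simulate_expression(
            cohort, 3000, sd.TruthSpec(noise_sd=0.1), seed=13
        )
        adjusted = pp.combat_adjust(expr, cohort.data["batch"]).adjusted
        results = pp.replicate_concordance(adjusted, cohort)
        assert len(results) == len(cohort.replicate_pairs())
        assert all(r.ccc > 0.98 and not r.flagged for r in results)

    def test_missing_replicate_sample_rejected(self, cohort):
        expr, _, _ = sd.simulate_expression(cohort, 10, sd.TruthSpec(), seed=14)
        sub = expr.subset_samples(expr.sample_ids[:5])
        with pytest.raises((ValidationError, KeyError)):
            pp.replicate_concordance(sub, cohort)

    @given(
        st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False),
            min_size=3,
            max_size=30,
        ),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_ccc_symmetry_and_permutation_invariance(self, xs, rnd):
        x = np.array(xs)
        y = x + np.linspace(-1, 1, len(x))
        if x.var() == 0:
            return
        assert pp.lin_ccc(x, y) == pytest.approx(pp.lin_ccc(y, x))
        perm = list(range(len(x)))
        rnd.shuffle(perm)
        assert pp.lin_ccc(x[perm], y[perm]) == pytest.approx(pp.lin_ccc(x, y))
        assert -1.0 - 1e-9 <= pp.lin_ccc(x, y) <= 1.0 + 1e-9
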