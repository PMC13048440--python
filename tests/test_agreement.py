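import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qualagree.agreement import (
    BootstrapConfig,
    UndefinedMetricError,
    bootstrap_ci,
    bootstrap_mean_ci,
    cohen_kappa,
    confusion_counts,
    f1,
    gwet_ac1,
    jaccard,
    per_code_kappa,
    percent_agreement,
    resample_metric,
    segment_confusion_counts,
    sensitivity,
    specificity,
    _k_gwet_ac1,
)
from qualagree.coding_data import CodingDataError, ConfusionCounts
from qualagree.simulate import DeductiveSimSpec, generate_reference, simulate_coder

from conftest import matrix_from_array


def _vectors_to_counts(ref, cod):
    ref = np.asarray(ref, bool)
    cod = np.asarray(cod, bool)
    return ConfusionCounts(
        tp=int((ref & cod).sum()),
        fp=int((~ref & cod).sum()),
        fn=int((ref & ~cod).sum()),
        tn=int((~ref & ~cod).sum()),
    )


# ---------------------------------------------------------------------------
# Confusion counts
# ---------------------------------------------------------------------------

class TestConfusionCounts:
    def test_hand_counted_example(self):
        ref = matrix_from_array([1, 0, 0, 0, 0, 0, 0, 0, 0, 0], "ref")
        cod = matrix_from_array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0], "c")
        c = confusion_counts(ref, cod)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 0, 8)

    def test_identity_has_no_discordance(self):
        ref = matrix_from_array([1, 0, 1, 0], "ref")
        c = confusion_counts(ref, matrix_from_array([1, 0, 1, 0], "c"))
        assert c.fp == c.fn == 0

    def test_complement_has_no_concordance(self):
        ref = matrix_from_array([1, 0, 1, 0], "ref")
        c = confusion_counts(ref, matrix_from_array([0, 1, 0, 1], "c"))
        assert c.tp == c.tn == 0

    def test_universe_mismatch_lists_disjoint_ids(self):
        ref = matrix_from_array([1, 0], "ref", seg_ids=["T001", "T002"])
        cod = matrix_from_array([1, 0], "c", seg_ids=["T001", "T003"])
        with pytest.raises(CodingDataError, match="T002"):
            confusion_counts(ref, cod)

    def test_pooled_counts_cover_all_cells(self):
        ref = generate_reference(DeductiveSimSpec(seed=1), "ref")
        cod = simulate_coder(ref, 0.3, 0.98, 42, "c")
        c = confusion_counts(ref, cod)
        assert c.n == 1240


# ---------------------------------------------------------------------------
# Point metrics: frozen hand computations
# ---------------------------------------------------------------------------

class TestPointMetrics:
    c = ConfusionCounts(1, 1, 0, 8)

    def test_hand_values_on_2x2(self):
        assert percent_agreement(self.c) == pytest.approx(0.9)
        assert cohen_kappa(self.c) == pytest.approx(0.16 / 0.26)
        assert gwet_ac1(self.c) == pytest.approx(0.645 / 0.745)
        assert jaccard(self.c) == pytest.approx(0.5)
        assert f1(self.c) == pytest.approx(2 / 3)
        assert sensitivity(self.c) == pytest.approx(1.0)
        assert specificity(self.c) == pytest.approx(8 / 9)

    def test_identity_table_perfect_scores(self):
        c = ConfusionCounts(3, 0, 0, 7)
        for fn in (percent_agreement, cohen_kappa, gwet_ac1, jaccard, f1):
            assert fn(c) == pytest.approx(1.0)

    def test_total_disagreement_zero_agreement(self):
        assert percent_agreement(ConfusionCounts(0, 5, 5, 0)) == 0.0

    def test_empty_table_raises(self):
        with pytest.raises(UndefinedMetricError):
            percent_agreement(ConfusionCounts(0, 0, 0, 0))

    def test_degenerate_kappa_is_nan_not_exception(self):
        # both raters constant and equal: p_e = 1
        assert math.isnan(cohen_kappa(ConfusionCounts(0, 0, 0, 10)))

    def test_zero_positive_overlap(self):
        c = ConfusionCounts(0, 2, 3, 5)
        assert jaccard(c) == 0.0
        assert f1(c) == 0.0

    def test_undefined_denominators_are_nan(self):
        assert math.isnan(jaccard(ConfusionCounts(0, 0, 0, 5)))
        assert math.isnan(sensitivity(ConfusionCounts(0, 3, 0, 5)))
        assert math.isnan(specificity(ConfusionCounts(2, 0, 3, 0)))


# ---------------------------------------------------------------------------
# Oracle equivalence and structural invariants
# ---------------------------------------------------------------------------

def _enumerate_tables(max_n):
    for n in range(1, max_n + 1):
        for tp in range(n + 1):
            for fp in range(n + 1 - tp):
                for fn_ in range(n + 1 - tp - fp):
                    yield ConfusionCounts(tp, fp, fn_, n - tp - fp - fn_)


def _ac1_oracle(ref, cod):
    """Brute-force AC1 from label vectors and proportion definitions."""
    ref = np.asarray(ref, float)
    cod = np.asarray(cod, float)
    p_o = float(np.mean(ref == cod))
    pi = (ref.mean() + cod.mean()) / 2
    gamma_e = 2 * pi * (1 - pi)
    return (p_o - gamma_e) / (1 - gamma_e)


class TestOracleEquivalence:
    def test_kappa_matches_sklearn_on_all_small_tables(self):
        """Exhaustive over every 2x2 table with n <= 6, vs an independent
        implementation applied to the reconstructed label vectors."""
        from sklearn.metrics import cohen_kappa_score

        for c in _enumerate_tables(6):
            ref = [1] * c.tp + [0] * c.fp + [1] * c.fn + [0] * c.tn
            cod = [1] * c.tp + [1] * c.fp + [0] * c.fn + [0] * c.tn
            ours = cohen_kappa(c)
            if math.isnan(ours):  # degenerate marginals: p_e = 1
                continue
            theirs = cohen_kappa_score(ref, cod)
            assert ours == pytest.approx(theirs, abs=1e-12), (c.tp, c.fp, c.fn, c.tn)

    def test_ac1_matches_brute_force_on_all_small_tables(self):
        for c in _enumerate_tables(6):
            ref = [1] * c.tp + [0] * c.fp + [1] * c.fn + [0] * c.tn
            cod = [1] * c.tp + [1] * c.fp + [0] * c.fn + [0] * c.tn
            assert gwet_ac1(c) == pytest.approx(_ac1_oracle(ref, cod), abs=1e-12)

    def test_jaccard_f1_relation_on_all_small_tables(self):
        for c in _enumerate_tables(6):
            j, f = jaccard(c), f1(c)
            if math.isnan(j) or math.isnan(f):
                continue
            assert j == pytest.approx(f / (2 - f), abs=1e-12)

    def test_population_plug_in_shows_kappa_attenuation(self):
        """At the deductive operating point (sensitivity 0.30, specificity
        0.98, prevalence 0.078) the closed-form kappa is ~0.356 while AC1 is
        ~0.918: the low-prevalence attenuation of kappa."""
        from qualagree.simulate import population_metrics

        pop = population_metrics(0.078, 0.30, 0.98)
        assert pop["kappa"] == pytest.approx(0.356, abs=0.001)
        assert pop["ac1"] == pytest.approx(0.918, abs=0.001)

    def test_ac1_exceeds_kappa_in_low_prevalence_regime(self):
        """On batches simulated at study defaults, AC1 dominates kappa."""
        for seed in range(20):
            ref = generate_reference(DeductiveSimSpec(seed=seed), "ref")
            cod = simulate_coder(ref, 0.30, 0.98, 900 + seed, "c")
            c = confusion_counts(ref, cod)
            k, a = cohen_kappa(c), gwet_ac1(c)
            if math.isnan(k):
                continue
            assert a > k

    def test_segment_permutation_leaves_metrics_unchanged(self):
        rng = np.random.default_rng(5)
        ref = generate_reference(DeductiveSimSpec(seed=2), "ref")
        cod = simulate_coder(ref, 0.3, 0.97, 7, "c")
        perm = rng.permutation(len(ref.segment_ids))
        ids = [ref.segment_ids[i] for i in perm]
        ref_p = matrix_from_array(ref.values.loc[ids].values, "ref", seg_ids=ids)
        cod_p = matrix_from_array(cod.values.loc[ids].values, "c", seg_ids=ids)
        for fn in (percent_agreement, cohen_kappa, gwet_ac1, jaccard, f1):
            assert fn(confusion_counts(ref, cod)) == pytest.approx(
                fn(confusion_counts(ref_p, cod_p))
            )


class TestPerCodeKappa:
    def test_identical_and_independent_codes(self):
        """Code A copied from the reference gives kappa 1; an independent
        code drawn at the same rate gives kappa near 0."""
        rng = np.random.default_rng(12)
        n = 4000
        a = rng.random(n) < 0.3
        b = rng.random(n) < 0.3
        b_ind = rng.random(n) < 0.3
        ref = matrix_from_array(np.stack([a, b], 1), "ref", code_ids=["A", "B"])
        cod = matrix_from_array(np.stack([a, b_ind], 1), "c", code_ids=["A", "B"])
        res = per_code_kappa(ref, cod)
        assert res["A"] == 1.0
        assert abs(res["B"]) < 0.05

    def test_all_false_code_is_undefined(self):
        ref = matrix_from_array(np.zeros((10, 1)), "ref", code_ids=["A"])
        cod = matrix_from_array(np.zeros((10, 1)), "c", code_ids=["A"])
        assert math.isnan(per_code_kappa(ref, cod)["A"])

    def test_reference_vs_itself_all_ones(self):
        ref = generate_reference(DeductiveSimSpec(seed=9), "ref")
        res = per_code_kappa(ref, ref)
        for v in res.values():
            if not math.isnan(v):
                assert v == 1.0


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

class TestBootstrap:
    def test_identical_matrices_zero_width_interval(self):
        ref = generate_reference(DeductiveSimSpec(seed=3), "ref")
        res = bootstrap_ci(percent_agreement, ref, ref, BootstrapConfig(b=200, seed=0))
        assert (res.point, res.ci_low, res.ci_high) == (1.0, 1.0, 1.0)

    def test_deterministic_under_seed(self):
        ref = generate_reference(DeductiveSimSpec(seed=3), "ref")
        cod = simulate_coder(ref, 0.3, 0.98, 11, "c")
        cfg = BootstrapConfig(b=300, seed=123)
        r1 = bootstrap_ci(cohen_kappa, ref, cod, cfg)
        r2 = bootstrap_ci(cohen_kappa, ref, cod, cfg)
        assert (r1.point, r1.ci_low, r1.ci_high) == (r2.point, r2.ci_low, r2.ci_high)

    def test_full_weight_resample_recovers_point(self):
        """A B=1 'resample' that takes every segment once reproduces the
        point estimate exactly."""
        ref = generate_reference(DeductiveSimSpec(seed=3), "ref")
        cod = simulate_coder(ref, 0.3, 0.98, 11, "c")
        seg_counts = segment_confusion_counts(ref, cod)
        idx = np.arange(seg_counts.shape[0])[None, :]
        val = resample_metric(_k_gwet_ac1, seg_counts, idx)
        assert val[0] == pytest.approx(gwet_ac1(confusion_counts(ref, cod)))

    def test_interval_brackets_point(self):
        ref = generate_reference(DeductiveSimSpec(seed=4), "ref")
        cod = simulate_coder(ref, 0.3, 0.98, 13, "c")
        res = bootstrap_ci(gwet_ac1, ref, cod, BootstrapConfig(b=500, seed=1))
        assert res.ci_low <= res.point <= res.ci_high

    def test_mostly_undefined_replicates_fail_loudly(self):
        ref = matrix_from_array(np.zeros((10, 1)), "ref")
        cod = matrix_from_array(np.zeros((10, 1)), "c")
        with pytest.raises(UndefinedMetricError, match="replicates"):
            bootstrap_ci(cohen_kappa, ref, cod, BootstrapConfig(b=100, seed=0))

    def test_mean_over_coders_uses_shared_resample(self):
        """The mean-of-coders bootstrap equals the single-coder bootstrap
        when the group has one member."""
        ref = generate_reference(DeductiveSimSpec(seed=6), "ref")
        cod = simulate_coder(ref, 0.34, 0.97, 21, "h1")
        cfg = BootstrapConfig(b=300, seed=77)
        solo = bootstrap_ci(gwet_ac1, ref, cod, cfg)
        grouped = bootstrap_mean_ci(gwet_ac1, ref, [cod], cfg)
        assert grouped.ci_low == pytest.approx(solo.ci_low)
        assert grouped.ci_high == pytest.approx(solo.ci_high)


@given(
    tp=st.integers(0, 30),
    fp=st.integers(0, 30),
    fn=st.integers(0, 30),
    tn=st.integers(0, 30),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_metric_ranges(tp, fp, fn, tn):
    """All metrics stay inside their documented ranges on arbitrary tables."""
    if tp + fp + fn + tn == 0:
        return
    c = ConfusionCounts(tp, fp, fn, tn)
    assert 0 <= percent_agreement(c) <= 1
    for fn_ in (jaccard, f1, sensitivity, specificity):
        v = fn_(c)
        assert math.isnan(v) or 0 <= v <= 1
    for fn_ in (cohen_kappa, gwet_ac1):
        v = fn_(c)
        assert math.isnan(v) or -1 - 1e-12 <= v <= 1 + 1e-12
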