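"""Diagnostic-accuracy statistics: CIs, AUC, DeLong, kappa, reconstruction."""

import numpy as np
import pytest
from scipy.stats import norm

from sect2mdi.readereval import (Confusion2x2, RatingSet, binary_auc,
                                 binary_auc_ci, clopper_pearson, cohen_kappa,
                                 confusion_from_ratings, delong_paired,
                                 evaluate_readings, reconstruct_table,
                                 summarize, verify_reference_arithmetic,
                                 REFERENCE_READER_METRICS)

RNG = np.random.default_rng(7)


def test_summarize_perfect_sensitivity_with_exact_ci():
    s = summarize(Confusion2x2(tp=16, fp=7, fn=0, tn=24))
    assert s.sensitivity.value == 1.0
    # Clopper-Pearson lower bound for 16/16 is 0.025^(1/16)
    assert s.sensitivity.lo == pytest.approx(0.025 ** (1 / 16), abs=1e-9)
    assert round(s.sensitivity.lo, 2) == 0.79
    assert s.accuracy.value == pytest.approx(40 / 47)
    assert s.npv.value == 1.0


def test_summarize_all_correct_and_accuracy_example():
    s = summarize(Confusion2x2(tp=10, fp=0, fn=0, tn=12))
    assert (s.sensitivity.value, s.specificity.value, s.accuracy.value) == (1, 1, 1)
    s2 = summarize(Confusion2x2(tp=18, fp=4, fn=1, tn=3))
    assert s2.accuracy.value == pytest.approx(21 / 26)
    assert round(s2.accuracy.value, 2) == 0.81


def test_zero_denominator_reported_as_undefined():
    s = summarize(Confusion2x2(tp=0, fp=3, fn=0, tn=5))
    assert s.sensitivity is None  # no positives: sensitivity undefined
    assert s.auc is None


def test_binary_auc_examples_and_symmetry():
    assert binary_auc(Confusion2x2(5, 0, 0, 5)) == 1.0
    t = Confusion2x2(tp=16, fp=7, fn=0, tn=24)
    assert binary_auc(t) == pytest.approx((1.0 + 24 / 31) / 2)
    # chance line: spec = 1 - sens
    assert binary_auc(Confusion2x2(tp=3, fp=3, fn=7, tn=7)) == 0.5
    # swapping class labels swaps sens<->spec but leaves the AUC unchanged
    swapped = Confusion2x2(tp=t.tn, fp=t.fn, fn=t.fp, tn=t.tp)
    assert binary_auc(swapped) == pytest.approx(binary_auc(t))
    with pytest.raises(ValueError):
        binary_auc(Confusion2x2(tp=0, fp=3, fn=0, tn=5))


def test_binary_auc_ci_contains_point():
    est = binary_auc_ci(Confusion2x2(16, 7, 0, 24))
    assert est.lo <= est.value <= est.hi
    assert 0.0 <= est.lo and est.hi <= 1.0


def _paired_sets(calls_a, calls_b, gold):
    ids = tuple(f"c{i}" for i in range(len(gold)))
    return (RatingSet(ids, np.array(calls_a), np.array(gold)),
            RatingSet(ids, np.array(calls_b), np.array(gold)))


def test_delong_identical_ratings_give_p_one():
    gold = [1] * 8 + [0] * 12
    calls = [1, 1, 0, 1, 1, 1, 0, 1] + [0] * 10 + [1, 1]
    a, b = _paired_sets(calls, calls, gold)
    res = delong_paired(a, b)
    assert res.difference == 0.0 and res.p_value == 1.0


def test_delong_auc_matches_binary_auc():
    gold = [1] * 10 + [0] * 15
    ca = list(RNG.integers(0, 2, 25))
    cb = list(RNG.integers(0, 2, 25))
    a, b = _paired_sets(ca, cb, gold)
    res = delong_paired(a, b)
    assert res.auc_a == pytest.approx(binary_auc(confusion_from_ratings(a)))
    assert res.auc_b == pytest.approx(binary_auc(confusion_from_ratings(b)))
    assert res.difference == pytest.approx(res.auc_a - res.auc_b)


def test_delong_matches_reference_implementation():
    """Frozen z / p from an independent reference run of the paired test.

    Dataset: 40 paired binary ratings (15 positive), reader A operating at
    (0.85, 0.80) true rates, reader B at (0.60, 0.65); the reference values
    were computed with the pROC implementation of the paired DeLong test.
    """
    rng = np.random.default_rng(21)
    n = 40
    gold = np.array([1] * 15 + [0] * 25)
    ca = np.where(gold == 1, rng.random(n) < 0.85, rng.random(n) < 0.2).astype(int)
    cb = np.where(gold == 1, rng.random(n) < 0.6, rng.random(n) < 0.35).astype(int)
    a, b = _paired_sets(list(ca), list(cb), list(gold))
    res = delong_paired(a, b)
    assert res.auc_a == pytest.approx(0.7066667, abs=1e-6)
    assert res.auc_b == pytest.approx(0.4866667, abs=1e-6)
    assert res.z == pytest.approx(2.157277, abs=1e-5)
    assert res.p_value == pytest.approx(0.03098405, abs=1e-6)


def test_delong_p_agrees_with_permutation_oracle():
    """n=40 paired binary ratings vs. a 1e5-replicate sign-swap oracle."""
    n, n_pos = 40, 15
    gold = np.array([1] * n_pos + [0] * (n - n_pos))
    rng = np.random.default_rng(1)
    ca = np.where(gold == 1, rng.random(n) < 0.95, rng.random(n) < 0.10).astype(int)
    cb = np.where(gold == 1, rng.random(n) < 0.60, rng.random(n) < 0.40).astype(int)
    a, b = _paired_sets(list(ca), list(cb), list(gold))
    res = delong_paired(a, b)

    def auc_from(calls):
        px = calls[gold == 1].mean()
        py = calls[gold == 0].mean()
        return px * (1 - py) + 0.5 * (px * py + (1 - px) * (1 - py))

    obs = abs(auc_from(ca) - auc_from(cb))
    reps = 100_000
    swap = rng.random((reps, n)) < 0.5
    xa = np.where(swap, cb, ca)
    xb = np.where(swap, ca, cb)
    pos, neg = gold == 1, gold == 0
    pxa, pya = xa[:, pos].mean(1), xa[:, neg].mean(1)
    pxb, pyb = xb[:, pos].mean(1), xb[:, neg].mean(1)
    auc_a = pxa * (1 - pya) + 0.5 * (pxa * pya + (1 - pxa) * (1 - pya))
    auc_b = pxb * (1 - pyb) + 0.5 * (pxb * pyb + (1 - pxb) * (1 - pyb))
    p_perm = np.mean(np.abs(auc_a - auc_b) >= obs - 1e-12)
    assert abs(res.p_value - p_perm) < 0.02


def test_kappa_identical_calls():
    calls = np.array([0, 1, 1, 0, 1, 0, 0, 1])
    res = cohen_kappa(calls, calls)
    assert res.kappa == pytest.approx(1.0)


def test_kappa_direct_formula_example():
    # agreement table [[20, 5], [5, 20]]: p_o = 0.8, p_e = 0.5, kappa = 0.6
    c1 = np.array([0] * 25 + [1] * 25)
    c2 = np.array([0] * 20 + [1] * 5 + [0] * 5 + [1] * 20)
    res = cohen_kappa(c1, c2)
    assert res.p_observed == pytest.approx(0.8)
    assert res.p_expected == pytest.approx(0.5)
    assert res.kappa == pytest.approx(0.6)
    assert res.ci[0] < 0.6 < res.ci[1]


def test_kappa_independent_raters_near_zero():
    rng = np.random.default_rng(3)
    c1 = rng.integers(0, 2, 10_000)
    c2 = rng.integers(0, 2, 10_000)
    assert abs(cohen_kappa(c1, c2).kappa) < 0.05


def test_kappa_undefined_when_expected_agreement_is_one():
    res = cohen_kappa(np.ones(10, dtype=int), np.ones(10, dtype=int))
    assert np.isnan(res.kappa)


def test_reconstruct_reference_tables_are_unique():
    internal = REFERENCE_READER_METRICS["internal"]["output"]
    sols = reconstruct_table(47, {k: internal[k] for k in
                                  ("sensitivity", "specificity", "ppv", "npv")})
    assert sols == [Confusion2x2(tp=16, fp=7, fn=0, tn=24)]
    external = REFERENCE_READER_METRICS["external"]["output"]
    sols = reconstruct_table(26, {k: external[k] for k in
                                  ("sensitivity", "specificity", "ppv", "npv")})
    assert sols == [Confusion2x2(tp=18, fp=4, fn=1, tn=3)]


def test_reconstruct_inconsistent_constraints_empty():
    assert reconstruct_table(10, {"sensitivity": 1.00, "npv": 0.00}) == []


def test_reconstruction_roundtrip_re_rounds_to_printed():
    for cohort, data in REFERENCE_READER_METRICS.items():
        for cond in ("input", "output"):
            printed = {k: data[cond][k] for k in
                       ("sensitivity", "specificity", "ppv", "npv")}
            for sol in reconstruct_table(data["n"], printed):
                s = summarize(sol)
                for key, val in printed.items():
                    est = getattr(s, key if key not in ("ppv", "npv") else key)
                    assert round(est.value + 1e-12, 2) == pytest.approx(val)


def test_evaluate_readings_report():
    gold = [1] * 6 + [0] * 10
    ids = tuple(f"c{i}" for i in range(16))
    perfect = RatingSet(ids, np.array(gold), np.array(gold))
    noisy = RatingSet(ids, np.array(gold[:-1] + [1]), np.array(gold))
    out = evaluate_readings({"decomposition": perfect, "sect": noisy},
                            readers_by_condition={"sect": {"r1": noisy,
                                                           "r2": perfect}})
    m = out["metrics"].set_index("condition")
    assert m.loc["decomposition", ["accuracy", "sensitivity", "specificity",
                                   "auc"]].tolist() == [1.0, 1.0, 1.0, 1.0]
    assert ("decomposition", "sect") in out["delong"]
    assert ("sect", "r1", "r2") in out["kappa"]
    # rows recompute from the stored tables
    t = out["tables"]["sect"]
    assert m.loc["sect", "accuracy"] == pytest.approx((t.tp + t.tn) / t.n)


def test_estimated_rates_covered_by_exact_cis():
    """Coverage: CP intervals catch the true sens/spec in >=93% of runs."""
    rng = np.random.default_rng(5)
    sens_true, spec_true = 0.85, 0.70
    n = 500
    cov_sens = cov_spec = 0
    reps = 100
    for _ in range(reps):
        gold = rng.random(n) < 0.4
        calls = np.where(gold, rng.random(n) < sens_true,
                         rng.random(n) < 1 - spec_true)
        table = confusion_from_ratings(
            RatingSet(tuple(map(str, range(n))), calls.astype(int),
                      gold.astype(int)))
        s = summarize(table)
        cov_sens += s.sensitivity.lo <= sens_true <= s.sensitivity.hi
        cov_spec += s.specificity.lo <= spec_true <= s.specificity.hi
    assert cov_sens >= 93 and cov_spec >= 93


def test_verify_reference_arithmetic_matches_printed():
    df = verify_reference_arithmetic()
    assert (df.n_solutions == 1).all()
    assert (df.auc_from_printed_sens_spec == df.printed_auc).all()
    assert (df.accuracy == df.printed_accuracy).all()
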