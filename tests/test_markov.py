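import numpy as np
import pandas as pd
import pytest

from motifkit.io_formats import CohortTable, LabelSeries, ValidationError
from motifkit.markov import (fit_markov, loglik_pooled, loocv_loglik,
                             order_scan, pseudo_bayes, subject_estimates)
from motifkit.synthetic import generate_label_sequence


def _series(labels, m=2, sid="s"):
    return LabelSeries(sid, 25.0, labels, m)


def test_fit_markov_order0_count_ratio():
    model = fit_markov([_series([0, 0, 1, 0])], 0)
    np.testing.assert_allclose(model.p, [0.75, 0.25])
    assert model.n_total == 4


def test_fit_markov_order1_oracle():
    model = fit_markov([_series([0, 0, 1, 0])], 1)
    np.testing.assert_allclose(model.q[(0,)], [0.5, 0.5])
    np.testing.assert_allclose(model.q[(1,)], [1.0, 0.0])
    assert model.state_counts == {(0,): 2, (1,): 1}


def test_fit_markov_order2_states_are_pairs():
    model = fit_markov([_series([0, 1, 0, 1, 1])], 2)
    assert set(model.states) == {(0, 1), (1, 0)}
    np.testing.assert_allclose(model.q[(0, 1)], [0.5, 0.5])


def test_fit_markov_pools_subjects():
    a = _series([0, 1], sid="a")
    b = _series([0, 0], sid="b")
    model = fit_markov([a, b], 1)
    # pooled counts from state (0,): one 1 (a), one 0 (b)
    np.testing.assert_allclose(model.q[(0,)], [0.5, 0.5])


def test_fit_markov_rejects_bad_order():
    with pytest.raises(ValidationError):
        fit_markov([_series([0, 1])], 4)


def test_loocv_closed_form_half():
    # held-out subject sees p' = mean([1,0], [0,1]) = [.5,.5]; 4 frames
    held = _series([0, 1, 0, 1], sid="h")
    b = _series([0, 0, 0, 0], sid="b")
    c = _series([1, 1, 1, 1], sid="c")
    res = loocv_loglik([held, b, c], 0)
    i = res.subject_ids.index("h")
    assert res.loglik[i] == pytest.approx(-2.772588722239781, rel=1e-12)
    assert res.clamps[i] == 0


def test_loocv_closed_form_clamped():
    # others never use label 0 -> p'_0 = 0, clamped to epsilon for 2 events
    held = _series([0, 0], sid="h")
    b = _series([1, 1], sid="b")
    c = _series([1, 1], sid="c")
    res = loocv_loglik([held, b, c], 0, epsilon=1e-10)
    i = res.subject_ids.index("h")
    assert res.loglik[i] == pytest.approx(2 * np.log(1e-10), rel=1e-12)
    assert res.loglik[i] == pytest.approx(-46.051701859880914, rel=1e-12)
    assert res.clamps[i] == 2


def test_loocv_unweighted_mean_not_pooled():
    # subject b: q(0->1) = 1 from 1 event; subject c: q(0->1) = 0 from 9
    # events. Unweighted mean = 0.5 (pooling counts would give 0.1).
    held = _series([0, 1], sid="h")
    b = _series([0, 1, 1], sid="b")
    c = _series([0, 0] * 5, sid="c")
    res = loocv_loglik([held, b, c], 1)
    i = res.subject_ids.index("h")
    assert res.loglik[i] == pytest.approx(np.log(0.5), rel=1e-12)


def test_loocv_uniform_fallback():
    # held-out subject visits state (1,) that no other subject visits
    held = _series([1, 0], sid="h")
    b = _series([0, 0], sid="b")
    c = _series([0, 0], sid="c")
    res = loocv_loglik([held, b, c], 1)
    i = res.subject_ids.index("h")
    assert res.uniform_fallbacks[i] == 1
    assert res.loglik[i] == pytest.approx(np.log(0.5), rel=1e-12)


def test_pseudo_bayes_sums_differences():
    s = [_series([0, 1, 0, 1, 0, 1], sid=f"s{i}") for i in range(3)]
    r0 = loocv_loglik(s, 0, group="g")
    r1 = loocv_loglik(s, 1, group="g")
    pbf = pseudo_bayes(r1, r0)
    assert pbf.attrs["log_pbf"] == pytest.approx(
        float((r1.loglik - r0.loglik).sum()))
    assert list(pbf.columns) == ["subject_id", "group", "order_k", "order_l",
                                 "delta_loglik"]


def test_pseudo_bayes_guards():
    a = [_series([0, 1, 0], sid="a"), _series([1, 0, 1], sid="b")]
    r0 = loocv_loglik(a, 0, group="g1")
    r1 = loocv_loglik(a, 1, group="g2")
    with pytest.raises(ValidationError, match="group"):
        pseudo_bayes(r0, r1)


def test_loglik_pooled_oracle():
    model = fit_markov([_series([0, 0, 1, 0])], 0)
    ll = loglik_pooled(model, [_series([0, 1])])
    assert ll == pytest.approx(np.log(0.75) + np.log(0.25))


def test_order1_chain_prefers_order1():
    # strongly first-order chain: order-1 LOOCV must beat order-0
    T = np.array([[0.05, 0.95], [0.95, 0.05]])
    series = [generate_label_sequence(T, 16 * 400, seed=i, bin_frames=16,
                                      subject_id=f"s{i}")
              for i in range(6)]
    binned = [LabelSeries(s.subject_id, s.fps / 16, s.labels[::16], 2)
              for s in series]
    r0 = loocv_loglik(binned, 0, group="g")
    r1 = loocv_loglik(binned, 1, group="g")
    pbf = pseudo_bayes(r1, r0)
    assert pbf.attrs["log_pbf"] > 100.0


def test_iid_sequence_prefers_order0_or_ties():
    # i.i.d. labels: order-1 gains nothing and pays LOOCV variance
    rng = np.random.default_rng(3)
    binned = [LabelSeries(f"s{i}", 25.0 / 16, rng.integers(0, 3, 400), 3)
              for i in range(6)]
    r0 = loocv_loglik(binned, 0, group="g")
    r1 = loocv_loglik(binned, 1, group="g")
    pbf = pseudo_bayes(r1, r0)
    assert pbf.attrs["log_pbf"] < 10.0


def test_order_scan_structure():
    rng = np.random.default_rng(4)
    groups = {
        g: [LabelSeries(f"{g}{i}", 25.0 / 16, rng.integers(0, 2, 200), 2)
            for i in range(3)]
        for g in ("WT", "MUT")
    }
    out = order_scan(groups, orders=(0, 1))
    assert set(out["loglik"]["order"]) == {0, 1}
    assert len(out["pbf"]) == 2 * 2  # two groups x two ordered pairs
    rows = []
    for g in ("WT", "MUT"):
        for i in range(3):
            rows.append((f"{g}{i}", g, "F" if i % 2 else "M", g, 25.0))
    cohort = CohortTable(pd.DataFrame(rows, columns=[
        "subject_id", "genotype", "sex", "group", "session_minutes"]))
    out2 = order_scan(groups, orders=(0, 1), cohort=cohort)
    assert set(out2["anova"]["order"]) == {0, 1}
    assert out2["anova"]["p_group"].between(0, 1).all()
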