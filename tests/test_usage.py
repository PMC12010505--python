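import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from motifkit.io_formats import CohortTable, LabelSeries, ValidationError
from motifkit.usage import (benjamini_hochberg, habituation_labels,
                            relative_usage, rm_anova_by_label,
                            time_binned_usage, usage_correlation_clustering,
                            usage_table, usage_tests)


def _cohort(n_per_cell=2, genotypes=("WT", "MUT"), sexes=("F", "M")):
    rows = []
    for g in genotypes:
        for s in sexes:
            for k in range(n_per_cell):
                rows.append((f"{g}_{s}_{k}", g, s, f"{g}/{s}", 10.0))
    return CohortTable(pd.DataFrame(rows, columns=[
        "subject_id", "genotype", "sex", "group", "session_minutes"]))


def test_usage_table_oracle():
    s = LabelSeries("a", 25.0, [0, 0, 1, 0], 3)
    tab = usage_table([s], 3)
    row0 = tab[tab.motif == 0].iloc[0]
    assert row0["frames"] == 3
    assert row0["seconds"] == pytest.approx(3 / 25.0)
    assert row0["percent"] == pytest.approx(75.0)
    assert tab[tab.motif == 2]["frames"].item() == 0
    assert tab.groupby("subject_id")["percent"].sum().item() == pytest.approx(100.0)


def test_usage_table_mismatched_fps():
    a = LabelSeries("a", 25.0, [0], 2)
    b = LabelSeries("b", 30.0, [0], 2)
    with pytest.raises(ValidationError, match="fps"):
        usage_table([a, b], 2)


def test_relative_usage_sex_stratified():
    cohort = _cohort()
    # motif-0 percent: WT_F mean = (40+60)/2 = 50, so WT_F_0 relative = 0.8
    pct = {"WT_F_0": 40.0, "WT_F_1": 60.0, "MUT_F_0": 75.0, "MUT_F_1": 25.0,
           "WT_M_0": 10.0, "WT_M_1": 30.0, "MUT_M_0": 40.0, "MUT_M_1": 0.0}
    rows = []
    for sid, v in pct.items():
        rows.append((sid, 0, 0, 0.0, v))
        rows.append((sid, 1, 0, 0.0, 100.0 - v))
    usage = pd.DataFrame(rows, columns=["subject_id", "motif", "frames",
                                        "seconds", "percent"])
    rel = relative_usage(usage, cohort, baseline="WT")
    get = lambda sid, m: rel[(rel.subject_id == sid) & (rel.motif == m)]
    assert get("WT_F_0", 0)["relative"].item() == pytest.approx(0.8)
    assert get("MUT_F_0", 0)["relative"].item() == pytest.approx(1.5)
    # male stratum has its own baseline mean 20
    assert get("MUT_M_0", 0)["relative"].item() == pytest.approx(2.0)
    # control relative values average to 1 within each stratum
    wt_f = rel[rel.subject_id.isin(["WT_F_0", "WT_F_1"]) & (rel.motif == 0)]
    assert wt_f["relative"].mean() == pytest.approx(1.0)


def test_relative_usage_zero_baseline_flagged():
    cohort = _cohort()
    rows = [(sid, 0, 0, 0.0, 0.0 if sid.startswith("WT_F") else 50.0)
            for sid in cohort.subject_ids]
    usage = pd.DataFrame(rows, columns=["subject_id", "motif", "frames",
                                        "seconds", "percent"])
    rel = relative_usage(usage, cohort, baseline="WT")
    f_rows = rel[rel.subject_id.str.contains("_F_")]
    assert f_rows["zero_baseline"].all()
    assert f_rows["relative"].isna().all()


def test_bh_worked_examples():
    # classic example: p = (0.01, 0.02, 0.03, 0.04, 0.05), m = 5
    q, rej = benjamini_hochberg([0.01, 0.02, 0.03, 0.04, 0.05], alpha=0.05)
    np.testing.assert_allclose(q, [0.05, 0.05, 0.05, 0.05, 0.05])
    assert rej.all()
    q2, rej2 = benjamini_hochberg([0.005, 0.011, 0.02, 0.8], alpha=0.05)
    np.testing.assert_allclose(q2, [0.02, 0.022, 0.0266666667, 0.8],
                               rtol=1e-8)
    assert list(rej2) == [True, True, True, False]


def test_bh_matches_statsmodels(rng):
    for _ in range(20):
        p = rng.uniform(0, 1, rng.integers(1, 40))
        q, rej = benjamini_hochberg(p, alpha=0.05)
        sm_rej, sm_q, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(q, sm_q, rtol=1e-12)
        np.testing.assert_array_equal(rej, sm_rej)


def test_bh_rejects_bad_input():
    with pytest.raises(ValidationError):
        benjamini_hochberg([0.5, 1.5])
    with pytest.raises(ValidationError):
        benjamini_hochberg([])


def test_usage_tests_detects_shift(rng):
    cohort = _cohort(n_per_cell=6)
    rows = []
    for sid in cohort.subject_ids:
        mut = sid.startswith("MUT")
        for motif in range(6):
            v = rng.normal(1.0, 0.05)
            if mut and motif == 2:
                v += 1.0  # large shift on one motif
            rows.append((sid, motif, v))
    values = pd.DataFrame(rows, columns=["subject_id", "motif", "relative"])
    rep = usage_tests(values, cohort, test="welch_t", alpha=0.05)
    assert rep[rep.motif == 2]["significant"].item()
    # estimate is levels[1] - levels[0] = WT - MUT, so negative here
    assert rep[rep.motif == 2]["estimate"].item() < -0.5
    assert rep["q"].between(0, 1).all()


def test_usage_tests_degenerate_constant():
    cohort = _cohort()
    rows = [(sid, 0, 1.0) for sid in cohort.subject_ids]
    values = pd.DataFrame(rows, columns=["subject_id", "motif", "relative"])
    rep = usage_tests(values, cohort)
    assert rep["degenerate"].item()
    assert rep["p"].item() == 1.0
    assert not rep["significant"].item()


def test_time_binned_usage_oracle():
    # 2 bins of 2 frames at fps such that bin_minutes*60*fps = 2
    s = LabelSeries("a", 1.0 / 30.0, [0, 0, 1, 1, 0], 2)
    binned = time_binned_usage([s], 2, bin_minutes=1.0)
    # bin 0 = frames 0-1 (all motif 0), bin 1 = frames 2-3 (all motif 1);
    # frame 4 dropped as a partial bin
    assert len(binned) == 4
    g = binned.set_index(["motif", "bin"])["percent"]
    assert g.loc[(0, 0)] == 100.0 and g.loc[(1, 0)] == 0.0
    assert g.loc[(0, 1)] == 0.0 and g.loc[(1, 1)] == 100.0


def test_time_binned_usage_too_short():
    s = LabelSeries("a", 25.0, [0] * 100, 2)
    with pytest.raises(ValidationError, match=">= 2"):
        time_binned_usage([s], 2, bin_minutes=5.0)


def test_rm_anova_matches_statsmodels(rng):
    from statsmodels.stats.anova import AnovaRM
    rows = []
    for sid in range(6):
        base = rng.normal(50, 5)
        for b in range(4):
            rows.append((f"s{sid}", 0, b, base + 2.0 * b + rng.normal(0, 1)))
    binned = pd.DataFrame(rows, columns=["subject_id", "motif", "bin",
                                         "percent"])
    ours = rm_anova_by_label(binned)
    sm_res = AnovaRM(binned, "percent", "subject_id", within=["bin"]).fit()
    f_sm = sm_res.anova_table["F Value"].item()
    p_sm = sm_res.anova_table["Pr > F"].item()
    assert ours["F"].item() == pytest.approx(f_sm, rel=1e-8)
    assert ours["p"].item() == pytest.approx(p_sm, rel=1e-8)
    assert not ours["degenerate"].item()


def test_rm_anova_degenerate():
    rows = [(f"s{sid}", 0, b, 25.0) for sid in range(3) for b in range(3)]
    binned = pd.DataFrame(rows, columns=["subject_id", "motif", "bin",
                                         "percent"])
    out = rm_anova_by_label(binned)
    assert out["degenerate"].item()
    assert np.isnan(out["p"].item())


def test_habituation_classification(rng):
    cohort = _cohort(n_per_cell=4)
    rows = []
    for sid in cohort.subject_ids:
        for b in range(5):
            # motif 0 declines steeply, motif 1 rises, motif 2 flat
            rows.append((sid, 0, b, 60 - 5 * b + rng.normal(0, 0.2)))
            rows.append((sid, 1, b, 10 + 4 * b + rng.normal(0, 0.2)))
            rows.append((sid, 2, b, 30 + rng.normal(0, 0.2)))
    binned = pd.DataFrame(rows, columns=["subject_id", "motif", "bin",
                                         "percent"])
    out = habituation_labels(binned, cohort, control="WT")
    cls = out.set_index("motif")["class"]
    assert cls.loc[0] == "habituating"
    assert cls.loc[1] == "sensitizing"
    assert cls.loc[2] == "flat"


def test_correlation_clustering_groups_correlated_columns(rng):
    n = 40
    base1 = rng.normal(0, 1, n)
    base2 = rng.normal(0, 1, n)
    mat = pd.DataFrame({
        0: base1 + rng.normal(0, 0.05, n),
        1: base2 + rng.normal(0, 0.05, n),
        2: base1 + rng.normal(0, 0.05, n),
        3: base2 + rng.normal(0, 0.05, n),
    }, index=[f"s{i}" for i in range(n)])
    res = usage_correlation_clustering(mat)
    order = res.motif_order
    # the two correlated pairs must be adjacent in leaf order
    assert abs(order.index(0) - order.index(2)) == 1
    assert abs(order.index(1) - order.index(3)) == 1
    assert res.motif_dissimilarity.loc[0, 2] < 0.05
    assert res.motif_dissimilarity.loc[0, 1] > 0.5


def test_correlation_clustering_excludes_constant(rng):
    mat = pd.DataFrame(rng.normal(0, 1, (10, 3)), columns=[0, 1, 2])
    mat[2] = 7.0
    res = usage_correlation_clustering(mat)
    assert res.excluded_motifs == [2]
    assert 2 not in res.motif_order
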