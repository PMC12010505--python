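"""Motif/community usage tables and the statistics run on them.

Usage is the total number of frames (equivalently seconds, or percent of
session) a subject spent in each motif. Group comparisons are run per motif
on sex-normalized values with Benjamini-Hochberg control of the false
discovery rate across motifs; time-binned occupancy supports a
repeated-measures one-way analysis over bins and a habituation /
sensitization call from control-group slopes; usage-correlation clustering
orders motifs and subjects for heatmap layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .io_formats import CohortTable, LabelSeries, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "usage_table", "relative_usage", "benjamini_hochberg", "usage_tests",
    "time_binned_usage", "rm_anova_by_label", "habituation_labels",
    "usage_correlation_clustering", "ClusterResult",
]


def usage_table(series: list[LabelSeries], m: int) -> pd.DataFrame:
    """Frames / seconds / percent of session per (subject, motif).

    Motifs a subject never displayed appear with zero counts, so per-subject
    percents always sum to 100 and seconds sum to the session length.
    """
    if not series:
        raise ValidationError("no label series given")
    fps = series[0].fps
    if any(s.fps != fps for s in series):
        raise ValidationError("all label series must share fps")
    rows = []
    for s in series:
        counts = np.bincount(s.labels, minlength=m)
        if counts.size > m:
            raise ValidationError(
                f"subject {s.subject_id} uses labels >= m={m}")
        total = s.n_frames
        for motif in range(m):
            f = int(counts[motif])
            rows.append((s.subject_id, motif, f, f / fps, 100.0 * f / total))
    df = pd.DataFrame(rows, columns=["subject_id", "motif", "frames",
                                     "seconds", "percent"])
    df.attrs["fps"] = fps
    df.attrs["m"] = m
    return df


def relative_usage(usage: pd.DataFrame, cohort: CohortTable,
                   baseline: str, factor: str = "genotype") -> pd.DataFrame:
    """Usage relative to sex-matched baseline-group subjects.

    ratio = subject percent / mean percent over baseline subjects of the
    same sex (baseline subjects are included in their own stratum mean).
    Motifs whose stratum baseline mean is zero are reported missing with a
    ``zero_baseline`` flag rather than as infinities.
    """
    meta = cohort.table.set_index("subject_id")
    out = usage.merge(meta[[factor, "sex"]], left_on="subject_id",
                      right_index=True)
    rows = []
    for sex in cohort.sexes:
        base_ids = cohort.subjects_where(**{factor: baseline, "sex": sex})
        if not base_ids:
            raise ValidationError(
                f"empty baseline stratum: {factor}={baseline}, sex={sex}")
        stratum = out[out["sex"] == sex]
        base_mean = (stratum[stratum["subject_id"].isin(base_ids)]
                     .groupby("motif")["percent"].mean())
        for _, r in stratum.iterrows():
            bm = base_mean[r["motif"]]
            if bm == 0:
                rows.append((r["subject_id"], r["motif"], np.nan, True))
            else:
                rows.append((r["subject_id"], r["motif"],
                             r["percent"] / bm, False))
    rel = pd.DataFrame(rows, columns=["subject_id", "motif", "relative",
                                      "zero_baseline"])
    return rel.sort_values(["subject_id", "motif"]).reset_index(drop=True)


def benjamini_hochberg(pvals, alpha: float = 0.05):
    """Step-up Benjamini-Hochberg: q_(i) = min_{j>=i} m*p_(j)/j, capped at 1.

    Returns (qvals, reject) in the input order; reject where q <= alpha.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("pvals must be a nonempty 1-D array")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, q <= alpha


def usage_tests(values: pd.DataFrame, cohort: CohortTable,
                factor: str = "genotype", test: str = "welch_t",
                alpha: float = 0.05, value_col: str = "relative",
                absolute_usage: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-motif two-sided group test with BH control across motifs.

    ``values`` is a tidy (subject_id, motif, value) table, normally the
    sex-normalized relative usage. The factor must have exactly two levels.
    Motifs with zero variance in both groups are flagged degenerate with
    p = 1. When ``absolute_usage`` is given, motifs passing q <= alpha get a
    two-factor (factor, sex, interaction) fixed-effects ANOVA appended.
    """
    levels = sorted(cohort.table[factor].unique())
    if len(levels) != 2:
        raise ValidationError(f"{factor} must have two levels, got {levels}")
    meta = cohort.table.set_index("subject_id")[factor]
    df = values.copy()
    df["__g"] = df["subject_id"].map(meta)
    rows = []
    for motif, sub in df.groupby("motif"):
        a = sub.loc[sub["__g"] == levels[0], value_col].dropna().to_numpy()
        b = sub.loc[sub["__g"] == levels[1], value_col].dropna().to_numpy()
        degenerate = (a.size < 2 or b.size < 2
                      or (np.ptp(a) == 0 and np.ptp(b) == 0))
        est = (b.mean() - a.mean()) if a.size and b.size else np.nan
        if degenerate:
            rows.append((motif, est, 1.0, True))
            continue
        if test == "welch_t":
            p = stats.ttest_ind(b, a, equal_var=False).pvalue
        elif test == "mann_whitney":
            p = stats.mannwhitneyu(b, a, alternative="two-sided").pvalue
        else:
            raise ValidationError(f"unknown test {test!r}")
        rows.append((motif, est, float(p), False))
    rep = pd.DataFrame(rows, columns=["motif", "estimate", "p", "degenerate"])
    rep["q"], rep["significant"] = benjamini_hochberg(rep["p"].to_numpy(),
                                                      alpha)
    rep["test"] = test
    if absolute_usage is not None:
        rep = rep.merge(
            _two_factor_followup(rep, absolute_usage, cohort, factor, alpha),
            on="motif", how="left")
    return rep


def _two_factor_followup(report: pd.DataFrame, usage: pd.DataFrame,
                         cohort: CohortTable, factor: str,
                         alpha: float) -> pd.DataFrame:
    """Two-way (factor x sex) fixed-effects ANOVA on absolute usage."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    meta = cohort.table.set_index("subject_id")
    rows = []
    for motif in report.loc[report["significant"], "motif"]:
        sub = usage[usage["motif"] == motif].copy()
        sub["g"] = sub["subject_id"].map(meta[factor])
        sub["sex"] = sub["subject_id"].map(meta["sex"])
        if sub["sex"].nunique() < 2:
            continue
        model = ols("percent ~ C(g) * C(sex)", data=sub).fit()
        if model.df_resid <= 0:
            logger.warning("motif %s: saturated group x sex design, "
                           "skipping follow-up ANOVA", motif)
            continue
        tab = sm.stats.anova_lm(model, typ=2)
        rows.append((motif, tab.loc["C(g)", "PR(>F)"],
                     tab.loc["C(sex)", "PR(>F)"],
                     tab.loc["C(g):C(sex)", "PR(>F)"]))
    return pd.DataFrame(rows, columns=["motif", "anova_p_group",
                                       "anova_p_sex", "anova_p_interaction"])


def time_binned_usage(series: list[LabelSeries], m: int,
                      bin_minutes: float = 5.0) -> pd.DataFrame:
    """Occupancy percent per (subject, motif, time bin).

    The final partial bin is dropped with a log entry; fewer than two whole
    bins is an error.
    """
    rows = []
    for s in series:
        bin_frames = int(round(bin_minutes * 60 * s.fps))
        n_bins = s.n_frames // bin_frames
        if n_bins < 2:
            raise ValidationError(
                f"{s.subject_id}: session yields {n_bins} bins of "
                f"{bin_minutes} min; need >= 2")
        dropped = s.n_frames - n_bins * bin_frames
        if dropped:
            logger.info("%s: dropping %d trailing frames (partial bin)",
                        s.subject_id, dropped)
        for b in range(n_bins):
            chunk = s.labels[b * bin_frames:(b + 1) * bin_frames]
            counts = np.bincount(chunk, minlength=m)
            for motif in range(m):
                rows.append((s.subject_id, motif, b,
                             100.0 * counts[motif] / bin_frames))
    return pd.DataFrame(rows, columns=["subject_id", "motif", "bin",
                                       "percent"])


def rm_anova_by_label(binned: pd.DataFrame) -> pd.DataFrame:
    """Repeated-measures one-way analysis over time bins, per label.

    Subjects are blocks: F = MS_time / MS_error with the standard
    within-subject decomposition (no sphericity correction). Labels whose
    within-error sum of squares is zero are flagged degenerate with a
    missing p.
    """
    rows = []
    for motif, sub in binned.groupby("motif"):
        wide = sub.pivot(index="subject_id", columns="bin", values="percent")
        y = wide.to_numpy(float)
        s_, b_ = y.shape
        grand = y.mean()
        ss_time = s_ * ((y.mean(axis=0) - grand) ** 2).sum()
        resid = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0) + grand
        ss_err = (resid ** 2).sum()
        df_time, df_err = b_ - 1, (s_ - 1) * (b_ - 1)
        if ss_err <= 0 or df_err <= 0:
            rows.append((motif, np.nan, np.nan, True))
            continue
        f = (ss_time / df_time) / (ss_err / df_err)
        p = float(stats.f.sf(f, df_time, df_err))
        rows.append((motif, f, p, False))
    return pd.DataFrame(rows, columns=["motif", "F", "p", "degenerate"])


def habituation_labels(binned: pd.DataFrame, cohort: CohortTable,
                       control: str, factor: str = "genotype",
                       alpha: float = 0.05) -> pd.DataFrame:
    """Classify each label as habituating / sensitizing / flat.

    Per subject, occupancy percent is regressed on bin index by least
    squares; the control group's mean slope is tested against zero with a
    two-sided one-sample t; the sign of a significant mean slope sets the
    class (negative = habituating, positive = sensitizing).
    """
    control_ids = set(cohort.subjects_where(**{factor: control}))
    rows = []
    for motif, sub in binned.groupby("motif"):
        slopes = []
        for sid, traj in sub.groupby("subject_id"):
            if sid not in control_ids:
                continue
            traj = traj.sort_values("bin")
            slopes.append(np.polyfit(traj["bin"], traj["percent"], 1)[0])
        slopes = np.asarray(slopes, float)
        if slopes.size < 2 or np.ptp(slopes) == 0:
            rows.append((motif, float(slopes.mean()) if slopes.size else np.nan,
                         np.nan, "flat"))
            continue
        t = stats.ttest_1samp(slopes, 0.0)
        if t.pvalue <= alpha:
            cls = "habituating" if slopes.mean() < 0 else "sensitizing"
        else:
            cls = "flat"
        rows.append((motif, float(slopes.mean()), float(t.pvalue), cls))
    return pd.DataFrame(rows, columns=["motif", "mean_slope", "p", "class"])


@dataclass
class ClusterResult:
    """Dendrogram leaf orders and dissimilarities for heatmap layout."""

    motif_order: list[int]
    subject_order: list[str]
    motif_dissimilarity: pd.DataFrame
    subject_dissimilarity: pd.DataFrame
    motif_linkage: np.ndarray
    subject_linkage: np.ndarray
    excluded_motifs: list[int]
    excluded_subjects: list[str]


def _corr_cluster(mat: pd.DataFrame, method: str):
    """Cluster columns of ``mat`` by 1 - Pearson r; returns order + extras."""
    var = mat.var(axis=0, ddof=0)
    keep = var[var > 0].index.tolist()
    excluded = var[var == 0].index.tolist()
    if excluded:
        logger.warning("excluding zero-variance columns: %s", excluded)
    sub = mat[keep]
    if sub.shape[1] < 2:
        raise ValidationError("need >= 2 varying columns to cluster")
    r = np.corrcoef(sub.to_numpy(float), rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # exact symmetry against fp noise
    lk = linkage(squareform(np.clip(d, 0, None), checks=False), method=method)
    order = [keep[i] for i in leaves_list(lk)]
    dis = pd.DataFrame(d, index=keep, columns=keep)
    return order, dis, lk, excluded


def usage_correlation_clustering(rel_matrix: pd.DataFrame,
                                 method: str = "average") -> ClusterResult:
    """Order motifs and subjects by correlation of relative-usage patterns.

    ``rel_matrix`` is subjects (rows) x motifs (columns) of relative usage.
    Pearson correlation across the respective dimension is turned into a
    dissimilarity (1 - r) and clustered agglomeratively (average linkage by
    default); leaf orders of both dendrograms are returned.
    """
    if rel_matrix.shape[0] < 2 or rel_matrix.shape[1] < 2:
        raise ValidationError("need >= 2 subjects and >= 2 motifs")
    if float(rel_matrix.to_numpy(float).std()) == 0.0:
        raise ValidationError("relative usage matrix is constant")
    motif_order, mdis, mlk, mex = _corr_cluster(rel_matrix, method)
    subject_order, sdis, slk, sex_ = _corr_cluster(rel_matrix.T, method)
    return ClusterResult(motif_order, subject_order, mdis, sdis, mlk, slk,
                         mex, sex_)
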