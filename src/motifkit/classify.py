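"""Forward-stepwise logistic classification and generic group tests.

The classifier mirrors the conventional phenotyping analysis: starting from
an intercept-only binomial (two classes) or multinomial (three classes)
logistic regression, features (e.g. per-motif usage percents) enter one at a
time by the smallest likelihood-ratio p-value below ``p_enter``, and any
entered feature whose removal LR p exceeds ``p_remove`` is dropped, until a
fixpoint or complete separation. Evaluation is by resubstitution (no held-out
set): confusion matrix, per-class sensitivity/specificity, and
AIC = 2 * n_parameters - 2 * max log-likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CohortTable, ValidationError

__all__ = ["ClassifierReport", "stepwise_logistic", "confusion_metrics",
           "group_tests"]


@dataclass
class ClassifierReport:
    selected: list[str]                  # entry order
    coefficients: pd.DataFrame
    confusion: pd.DataFrame              # rows = actual, cols = predicted
    metrics: pd.DataFrame                # per-class sensitivity/specificity
    aic: float
    loglik: float
    classes: list[str]
    separation: bool
    steps: pd.DataFrame = field(default_factory=pd.DataFrame)


def _fit(y: np.ndarray, X: np.ndarray, n_classes: int):
    """Fit (mn)logit quietly; return (loglik, params, converged)."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if n_classes == 2:
            model = sm.Logit(y, X)
        else:
            model = sm.MNLogit(y, X)
        try:
            res = model.fit(method="bfgs", maxiter=400, disp=0)
        except Exception:
            return None
    return res


def _predict_classes(res, X: np.ndarray, n_classes: int) -> np.ndarray:
    prob = res.predict(X)
    if n_classes == 2:
        return (np.asarray(prob) >= 0.5).astype(int)
    return np.argmax(np.asarray(prob), axis=1)


def stepwise_logistic(features: pd.DataFrame, labels,
                      p_enter: float = 0.05, p_remove: float = 0.05,
                      reference: str | None = None) -> ClassifierReport:
    """Forward-stepwise conditional logistic regression with LR entry/removal.

    ``features`` is subjects x p (column names are feature names); ``labels``
    holds 2 or 3 class labels per subject. The reference (control) class is
    the first sorted level unless given. Complete separation stops the scan:
    the separating model is reported with a flag.
    """
    if not 0 < p_enter <= p_remove <= 1:
        raise ValidationError("need 0 < p_enter <= p_remove <= 1")
    y_raw = pd.Series(list(labels)).astype(str)
    classes = sorted(y_raw.unique())
    if reference is not None:
        if reference not in classes:
            raise ValidationError(f"reference {reference!r} not in {classes}")
        classes = [reference] + [c for c in classes if c != reference]
    if len(classes) not in (2, 3):
        raise ValidationError("labels must have 2 or 3 classes")
    counts = y_raw.value_counts()
    if (counts < 2).any():
        raise ValidationError("every class needs at least 2 subjects")
    y = y_raw.map({c: k for k, c in enumerate(classes)}).to_numpy()
    n, k_classes = len(y), len(classes)
    df_per_term = k_classes - 1

    Xfull = features.to_numpy(float)
    names = list(features.columns)
    selected: list[str] = []
    steps = []
    separation = False

    def design(cols: list[str]) -> np.ndarray:
        idx = [names.index(c) for c in cols]
        return np.column_stack([np.ones(n)] + [Xfull[:, i] for i in idx])

    current = _fit(y, design([]), k_classes)
    if current is None:
        raise ValidationError("intercept-only model failed to fit")

    def is_separated(res, cols) -> bool:
        params = np.asarray(res.params, float)
        if not np.all(np.isfinite(params)):
            return True
        pred = _predict_classes(res, design(cols), k_classes)
        prob = np.asarray(res.predict(design(cols)))
        if k_classes == 2:
            conf = np.where(y == 1, prob, 1 - prob)
        else:
            conf = prob[np.arange(n), y]
        return bool(np.all(pred == y) and conf.min() > 1 - 1e-4)

    while True:
        changed = False
        # entry: smallest LR p below p_enter
        best = None
        for cand in names:
            if cand in selected:
                continue
            trial = _fit(y, design(selected + [cand]), k_classes)
            if trial is None:
                continue
            lr = 2 * (trial.llf - current.llf)
            p = stats.chi2.sf(max(lr, 0.0), df_per_term)
            if p < p_enter and (best is None or p < best[0]):
                best = (p, cand, trial)
        if best is not None:
            p, cand, trial = best
            selected.append(cand)
            current = trial
            steps.append(("enter", cand, p,
                          2 * (1 + len(selected)) * df_per_term
                          - 2 * current.llf))
            changed = True
            if is_separated(current, selected):
                separation = True
                break
        # removal: any included feature whose removal LR p > p_remove
        for feat in list(selected):
            reduced_cols = [c for c in selected if c != feat]
            reduced = _fit(y, design(reduced_cols), k_classes)
            if reduced is None:
                continue
            lr = 2 * (current.llf - reduced.llf)
            p = stats.chi2.sf(max(lr, 0.0), df_per_term)
            if p > p_remove:
                selected.remove(feat)
                current = reduced
                steps.append(("remove", feat, p,
                              2 * (1 + len(selected)) * df_per_term
                              - 2 * current.llf))
                changed = True
        if not changed:
            break

    n_params = (1 + len(selected)) * df_per_term
    aic = 2 * n_params - 2 * float(current.llf)
    pred = _predict_classes(current, design(selected), k_classes)
    conf = pd.DataFrame(0, index=classes, columns=classes)
    for a, b in zip(y, pred):
        conf.iloc[a, b] += 1
    metrics = confusion_metrics(conf)
    params = np.asarray(current.params, float).reshape(1 + len(selected), -1)
    coef = pd.DataFrame(params, index=["intercept"] + selected,
                        columns=[f"logit_{c}" for c in classes[1:]])
    return ClassifierReport(selected, coef, conf, metrics, aic,
                            float(current.llf), classes, separation,
                            pd.DataFrame(steps, columns=["action", "feature",
                                                         "p", "aic"]))


def confusion_metrics(confusion: pd.DataFrame) -> pd.DataFrame:
    """Per-class sensitivity and specificity from a confusion matrix.

    Rows are actual classes, columns predicted. Sensitivity of class c is
    correct_c / actual_c; with two classes the specificity of c is the
    sensitivity of the other class, with more it is one-vs-rest
    TN / (TN + FP). Empty classes yield missing metrics with a flag.
    """
    cm = confusion.to_numpy(float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValidationError("confusion matrix must be square")
    classes = list(confusion.index)
    total = cm.sum()
    rows = []
    for i, c in enumerate(classes):
        actual = cm[i].sum()
        sens = cm[i, i] / actual if actual > 0 else np.nan
        if len(classes) == 2:
            other = 1 - i
            other_actual = cm[other].sum()
            spec = (cm[other, other] / other_actual
                    if other_actual > 0 else np.nan)
        else:
            tn = total - cm[i].sum() - cm[:, i].sum() + cm[i, i]
            fp = cm[:, i].sum() - cm[i, i]
            spec = tn / (tn + fp) if (tn + fp) > 0 else np.nan
        rows.append((c, sens, spec, actual == 0))
    return pd.DataFrame(rows, columns=["class", "sensitivity", "specificity",
                                       "empty"])


def group_tests(values: pd.Series | dict[str, float], cohort: CohortTable,
                design: str = "two_group", factor: str = "genotype") -> dict:
    """Generic per-subject scalar group tests (delta indices, log-likelihoods).

    ``two_group``: Welch two-sided t between the two factor levels.
    ``two_factor``: fixed-effects ANOVA with factor, sex and interaction.
    """
    if isinstance(values, dict):
        values = pd.Series(values)
    meta = cohort.table.set_index("subject_id")
    df = pd.DataFrame({"value": values})
    df[factor] = meta.loc[df.index, factor]
    df["sex"] = meta.loc[df.index, "sex"]
    levels = sorted(df[factor].unique())
    if design == "two_group":
        if len(levels) != 2:
            raise ValidationError(f"two_group design needs 2 levels: {levels}")
        a = df.loc[df[factor] == levels[0], "value"].to_numpy()
        b = df.loc[df[factor] == levels[1], "value"].to_numpy()
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            return {"design": design, "estimate": float(b.mean() - a.mean()),
                    "p": np.nan, "degenerate": True}
        t = stats.ttest_ind(b, a, equal_var=False)
        return {"design": design, "estimate": float(b.mean() - a.mean()),
                "t": float(t.statistic), "p": float(t.pvalue),
                "degenerate": False}
    if design == "two_factor":
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        model = ols(f"value ~ C({factor}) * C(sex)", data=df).fit()
        if model.df_resid <= 0:
            return {"design": design, "p_group": np.nan, "p_sex": np.nan,
                    "p_interaction": np.nan, "degenerate": True}
        tab = sm.stats.anova_lm(model, typ=2)
        return {"design": design,
                "p_group": float(tab.loc[f"C({factor})", "PR(>F)"]),
                "p_sex": float(tab.loc["C(sex)", "PR(>F)"]),
                "p_interaction":
                    float(tab.loc[f"C({factor}):C(sex)", "PR(>F)"]),
                "degenerate": False}
    raise ValidationError(f"unknown design {design!r}")
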