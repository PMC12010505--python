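"""Discrete Markov chain order evaluation with LOOCV and pseudo Bayes factors.

Models of order k = 0..3 are fitted to binned (640-ms) community or motif
sequences. Per-subject maximum-likelihood estimates are count ratios
(p_c = N_c / N for order 0, q_sc = N_sc / N_s for k > 0, states being
ordered k-tuples of labels). The leave-one-out parameters for a held-out
subject are the *unweighted sample mean* of the other subjects' per-subject
estimates — not pooled counts — and the held-out log-likelihood is

    L_k(i) = sum_s sum_c N_sc(i) * log q'_sc       (k > 0; L_0 analogous)

with probabilities below a floor epsilon clamped (and the clamps counted),
since a held-out subject can produce events the average assigns zero mass.
For k > 0 the mean over held-in subjects includes only those that visited
state s; if none did, the predictive distribution falls back to uniform
over labels (logged). The log pseudo Bayes factor between orders k and l is
the sum over subjects of L_k(i) - L_l(i); positive values favor order k.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import LabelSeries, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["MarkovModel", "LoocvResult", "fit_markov", "subject_estimates",
           "loocv_loglik", "pseudo_bayes", "order_scan"]

State = tuple[int, ...]


@dataclass
class MarkovModel:
    """Order-k chain fitted by pooled count ratios."""

    order: int
    alphabet_size: int
    n_total: int
    label_counts: np.ndarray                 # N_c
    state_counts: dict[State, int]           # N_s   (empty for k = 0)
    transition_counts: dict[State, np.ndarray]  # N_sc per state
    p: np.ndarray | None                     # order-0 probabilities
    q: dict[State, np.ndarray]               # state -> label distribution

    @property
    def states(self) -> list[State]:
        return sorted(self.state_counts)


@dataclass
class LoocvResult:
    """Held-out log-likelihood per subject at one order."""

    order: int
    subject_ids: list[str]
    loglik: np.ndarray
    clamps: np.ndarray
    uniform_fallbacks: np.ndarray
    group: str = ""
    epsilon: float = 1e-10

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": self.subject_ids, "group": self.group,
            "order": self.order, "loglik": self.loglik,
            "clamps": self.clamps, "uniform_fallbacks": self.uniform_fallbacks,
        })


def _count_one(labels: np.ndarray, k: int, m: int):
    """(label counts, state->label count vectors) for one subject."""
    n = labels.size
    label_counts = np.bincount(labels, minlength=m)
    trans: dict[State, np.ndarray] = {}
    if k > 0:
        for t in range(k, n):
            s = tuple(int(x) for x in labels[t - k:t])
            vec = trans.get(s)
            if vec is None:
                vec = np.zeros(m, dtype=np.int64)
                trans[s] = vec
            vec[labels[t]] += 1
    return label_counts, trans


def fit_markov(series: list[LabelSeries], order: int) -> MarkovModel:
    """Pooled maximum-likelihood fit over all provided series.

    The state space comprises the k-tuples actually observed in the pooled
    data; probabilities are count ratios.
    """
    if order not in (0, 1, 2, 3):
        raise ValidationError("order must be in {0, 1, 2, 3}")
    if not series:
        raise ValidationError("no series given")
    m = max(s.alphabet_size for s in series)
    short = [s.subject_id for s in series if s.n_frames <= order]
    if short:
        raise ValidationError(f"series too short for order {order}: {short}")
    total = 0
    label_counts = np.zeros(m, dtype=np.int64)
    trans: dict[State, np.ndarray] = {}
    for s in series:
        lc, tr = _count_one(s.labels, order, m)
        label_counts += lc
        total += s.n_frames
        for st, vec in tr.items():
            if st in trans:
                trans[st] += vec
            else:
                trans[st] = vec.copy()
    state_counts = {st: int(vec.sum()) for st, vec in trans.items()}
    p = label_counts / total if order == 0 else None
    q = {st: vec / vec.sum() for st, vec in trans.items()}
    return MarkovModel(order, m, total, label_counts, state_counts, trans,
                       p, q)


def subject_estimates(series: list[LabelSeries], order: int, m: int):
    """Per-subject count and probability estimates (one model per subject)."""
    out = []
    for s in series:
        lc, tr = _count_one(s.labels, order, m)
        p = lc / lc.sum()
        q = {st: vec / vec.sum() for st, vec in tr.items()}
        out.append({"id": s.subject_id, "label_counts": lc, "p": p,
                    "trans": tr, "q": q})
    return out


def loglik_pooled(model: MarkovModel, series: list[LabelSeries],
                  epsilon: float = 1e-12) -> float:
    """Training-data log-likelihood of series under a pooled fit."""
    m = model.alphabet_size
    total = 0.0
    for s in series:
        lc, tr = _count_one(s.labels, model.order, m)
        if model.order == 0:
            total += float(lc @ np.log(np.maximum(model.p, epsilon)))
        else:
            for st, vec in tr.items():
                qs = model.q.get(st)
                if qs is None:
                    qs = np.full(m, 1.0 / m)
                total += float(vec @ np.log(np.maximum(qs, epsilon)))
    return total


def loocv_loglik(series: list[LabelSeries], order: int,
                 epsilon: float = 1e-10, group: str = "") -> LoocvResult:
    """Held-out log-likelihood for every subject under leave-one-out averaging."""
    if len(series) < 2:
        raise ValidationError("LOOCV needs at least two subjects")
    usable = [s for s in series if s.n_frames > order]
    dropped = [s.subject_id for s in series if s.n_frames <= order]
    if dropped:
        logger.warning("excluding subjects too short for order %d: %s",
                       order, dropped)
    m = max(s.alphabet_size for s in usable)
    est = subject_estimates(usable, order, m)
    logliks, clamps, fallbacks = [], [], []
    for i, held in enumerate(est):
        others = [e for j, e in enumerate(est) if j != i]
        ll = 0.0
        n_clamp = 0
        n_fallback = 0
        if order == 0:
            p_prime = np.mean([e["p"] for e in others], axis=0)
            probs = p_prime.copy()
            low = (probs < epsilon) & (held["label_counts"] > 0)
            n_clamp += int(held["label_counts"][low].sum())
            probs = np.maximum(probs, epsilon)
            ll = float(held["label_counts"] @ np.log(probs))
        else:
            for st, vec in held["trans"].items():
                visited = [e["q"][st] for e in others if st in e["q"]]
                if visited:
                    q_prime = np.mean(visited, axis=0)
                else:
                    q_prime = np.full(m, 1.0 / m)
                    n_fallback += 1
                low = (q_prime < epsilon) & (vec > 0)
                n_clamp += int(vec[low].sum())
                q_prime = np.maximum(q_prime, epsilon)
                ll += float(vec @ np.log(q_prime))
        logliks.append(ll)
        clamps.append(n_clamp)
        fallbacks.append(n_fallback)
    return LoocvResult(order, [e["id"] for e in est], np.array(logliks),
                       np.array(clamps), np.array(fallbacks), group, epsilon)


def pseudo_bayes(loocv_k: LoocvResult, loocv_l: LoocvResult) -> pd.DataFrame:
    """log pseudo Bayes factor between two orders: sum of per-subject diffs."""
    if loocv_k.subject_ids != loocv_l.subject_ids:
        raise ValidationError("subject sets differ between LOOCV results")
    if loocv_k.group != loocv_l.group:
        raise ValidationError("LOOCV results come from different groups")
    diff = loocv_k.loglik - loocv_l.loglik
    out = pd.DataFrame({
        "subject_id": loocv_k.subject_ids,
        "group": loocv_k.group,
        "order_k": loocv_k.order,
        "order_l": loocv_l.order,
        "delta_loglik": diff,
    })
    out.attrs["log_pbf"] = float(diff.sum())
    return out


def order_scan(series_by_group: dict[str, list[LabelSeries]],
               orders=(0, 1, 2, 3), epsilon: float = 1e-10,
               cohort=None) -> dict:
    """LOOCV across orders within each group, PBFs, and group contrasts.

    Returns a dict with ``loglik`` (tidy per-subject table), ``pbf`` (one
    row per group and ordered order pair), and, when a cohort with sex
    metadata is supplied, ``anova`` — a two-factor (group, sex, interaction)
    fixed-effects analysis of the held-out log-likelihood per order.
    """
    orders = sorted(orders)
    results: dict[str, dict[int, LoocvResult]] = {}
    for g, series in series_by_group.items():
        if len(series) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 subjects")
        results[g] = {k: loocv_loglik(series, k, epsilon, group=g)
                      for k in orders}
    loglik = pd.concat([results[g][k].table()
                        for g in results for k in orders], ignore_index=True)
    pbf_rows = []
    for g in results:
        for k, l in itertools.permutations(orders, 2):
            diff = pseudo_bayes(results[g][k], results[g][l])
            pbf_rows.append((g, k, l, diff.attrs["log_pbf"]))
    pbf = pd.DataFrame(pbf_rows, columns=["group", "order_k", "order_l",
                                          "log_pbf"])
    out = {"loglik": loglik, "pbf": pbf, "results": results}
    if cohort is not None:
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        meta = cohort.table.set_index("subject_id")
        rows = []
        for k in orders:
            sub = loglik[loglik["order"] == k].copy()
            sub["sex"] = sub["subject_id"].map(meta["sex"])
            if sub["sex"].nunique() < 2 or sub["group"].nunique() < 2:
                continue
            model = ols("loglik ~ C(group) * C(sex)", data=sub).fit()
            if model.df_resid <= 0:
                logger.warning("order %d: saturated group x sex design, "
                               "skipping ANOVA", k)
                continue
            tab = sm.stats.anova_lm(model, typ=2)
            rows.append((k, tab.loc["C(group)", "PR(>F)"],
                         tab.loc["C(sex)", "PR(>F)"],
                         tab.loc["C(group):C(sex)", "PR(>F)"]))
        out["anova"] = pd.DataFrame(rows, columns=[
            "order", "p_group", "p_sex", "p_interaction"])
    return out
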