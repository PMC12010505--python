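"""Transition matrices, top-edge networks, and per-edge group inference.

Label sequences are first discretized into 640-ms bins (16 frames at
25 fps, modal label per bin). Two matrix normalizations are kept explicit
because they answer different questions:

* ``dwell_inclusive`` — edgeweight_ij = transitions_ij / usage_i with
  self-transitions retained; rows sum to 1 wherever the motif was visited,
  and an absorbing motif has a self-probability of exactly 1. Used for
  transition networks and Markov chain models.
* ``switch_only`` — the diagonal is zeroed and each row renormalized over
  the remaining switches. Used for community dendrograms and the transition
  delta index.

Per-edge genotype inference models each subject's (transitions i->j, bins
in i) pair as a binomial with a subject-level random intercept and a fixed
group log-odds-ratio effect, fitted by Gauss-Hermite quadrature maximum
likelihood with Wald p-values and BH correction across tested edges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import CohortTable, LabelSeries, ValidationError
from .usage import benjamini_hochberg

logger = logging.getLogger(__name__)

__all__ = [
    "TransitionMatrix", "bin_labels", "transition_counts", "to_probabilities",
    "cohort_matrix", "transition_difference", "top_edges",
    "fit_binomial_glmm", "edge_group_test", "export_network",
]


@dataclass
class TransitionMatrix:
    """Counts + row-stochastic probabilities with provenance."""

    counts: np.ndarray          # (m, m) nonnegative ints
    probabilities: np.ndarray   # (m, m)
    mode: str                   # dwell_inclusive | switch_only
    usage: np.ndarray           # bins per motif (excluding each final bin)
    timestep: float             # seconds per step
    subjects: list[str] = field(default_factory=list)

    @property
    def m(self) -> int:
        return self.counts.shape[0]


def bin_labels(series: LabelSeries, bin_frames: int = 16) -> LabelSeries:
    """One label per bin: the modal frame label, ties to the earliest label.

    The trailing partial bin is dropped.
    """
    if bin_frames < 1:
        raise ValidationError("bin_frames must be >= 1")
    n_bins = series.n_frames // bin_frames
    if n_bins == 0:
        raise ValidationError("series shorter than one bin")
    lab = series.labels[:n_bins * bin_frames].reshape(n_bins, bin_frames)
    m = series.alphabet_size
    out = np.empty(n_bins, dtype=np.int64)
    for b in range(n_bins):
        counts = np.bincount(lab[b], minlength=m)
        best = counts.max()
        winners = np.flatnonzero(counts == best)
        if winners.size == 1:
            out[b] = winners[0]
        else:
            # tie: earliest-occurring label within the bin wins
            firsts = {w: int(np.argmax(lab[b] == w)) for w in winners}
            out[b] = min(firsts, key=firsts.get)
    return LabelSeries(series.subject_id, series.fps / bin_frames, out, m)


def transition_counts(series: LabelSeries, m: int) -> tuple[np.ndarray, np.ndarray]:
    """2-D histogram of consecutive bin pairs, diagonal included.

    Returns (counts, usage) where usage_i counts bins labeled i excluding
    the final bin, so row i of counts sums to usage_i.
    """
    lab = series.labels
    if lab.size < 2:
        raise ValidationError("need at least two bins to count transitions")
    if lab.max() >= m:
        raise ValidationError(f"labels exceed alphabet size {m}")
    idx = lab[:-1] * m + lab[1:]
    counts = np.bincount(idx, minlength=m * m).reshape(m, m)
    usage = np.bincount(lab[:-1], minlength=m)
    return counts.astype(np.int64), usage.astype(np.int64)


def to_probabilities(counts: np.ndarray, usage: np.ndarray, mode: str,
                     timestep: float = 0.64,
                     subjects: list[str] | None = None) -> TransitionMatrix:
    """Normalize a count matrix into one of the two row-stochastic forms.

    Rows with a zero denominator are left all-zero (and logged): an
    unvisited motif has no outgoing distribution.
    """
    counts = np.asarray(counts)
    usage = np.asarray(usage)
    if (counts < 0).any():
        raise ValidationError("negative transition counts")
    if not np.array_equal(counts.sum(axis=1), usage):
        raise ValidationError("usage inconsistent with count row sums")
    m = counts.shape[0]
    probs = np.zeros((m, m), dtype=float)
    if mode == "dwell_inclusive":
        rows = usage > 0
        probs[rows] = counts[rows] / usage[rows, None]
    elif mode == "switch_only":
        off = counts.astype(float).copy()
        np.fill_diagonal(off, 0.0)
        denom = off.sum(axis=1)
        rows = denom > 0
        probs[rows] = off[rows] / denom[rows, None]
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    if (~rows).any():
        logger.info("rows with zero denominator left all-zero: %s",
                    np.where(~rows)[0].tolist())
    return TransitionMatrix(counts, probs, mode, usage, timestep,
                            subjects or [])


def cohort_matrix(series: list[LabelSeries], m: int,
                  mode: str = "dwell_inclusive",
                  timestep: float = 0.64) -> TransitionMatrix:
    """Pool counts over subjects before normalizing (cohort-level matrix)."""
    if not series:
        raise ValidationError("no series given")
    counts = np.zeros((m, m), dtype=np.int64)
    usage = np.zeros(m, dtype=np.int64)
    for s in series:
        c, u = transition_counts(s, m)
        counts += c
        usage += u
    return to_probabilities(counts, usage, mode, timestep,
                            subjects=[s.subject_id for s in series])


def transition_difference(a: TransitionMatrix,
                          b: TransitionMatrix) -> np.ndarray:
    """Elementwise probability difference a - b (same m, same mode)."""
    if a.mode != b.mode:
        raise ValidationError(f"mode mismatch: {a.mode} vs {b.mode}")
    if a.m != b.m:
        raise ValidationError("matrix size mismatch")
    return a.probabilities - b.probabilities


def top_edges(matrix: TransitionMatrix, quantile: float = 0.2,
              scope: str = "off_diagonal") -> pd.DataFrame:
    """The highest-probability edges: top ceil(quantile * candidates).

    Candidates are entries in scope (off-diagonal by default) with nonzero
    probability; ties at the cutoff are all retained and logged.
    """
    if not 0 < quantile <= 1:
        raise ValidationError("quantile must be in (0, 1]")
    probs = matrix.probabilities
    m = matrix.m
    rows, cols = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    mask = probs > 0
    if scope == "off_diagonal":
        mask &= rows != cols
    elif scope != "all":
        raise ValidationError(f"unknown scope {scope!r}")
    src, dst, p = rows[mask], cols[mask], probs[mask]
    order = np.lexsort((dst, src, -p))
    src, dst, p = src[order], dst[order], p[order]
    n_keep = math.ceil(quantile * p.size)
    if n_keep < p.size:
        cutoff = p[n_keep - 1]
        extra = np.sum(p[n_keep:] == cutoff)
        if extra:
            logger.info("retaining %d tied edges at the cutoff", extra)
        n_keep += int(extra)
    out = pd.DataFrame({"source": src[:n_keep], "target": dst[:n_keep],
                        "probability": p[:n_keep]})
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# Binomial random-intercept GLMM by Gauss-Hermite quadrature

_GH_NODES, _GH_W = np.polynomial.hermite_e.hermegauss(25)
_GH_W = _GH_W / _GH_W.sum()


def _glmm_nll(params: np.ndarray, succ: np.ndarray, fail: np.ndarray,
              X: np.ndarray) -> float:
    """Negative marginal log-likelihood via adaptive Gauss-Hermite quadrature.

    Nodes are recentered at each subject's posterior mode and rescaled by
    the local curvature; without this the fixed grid misses the extremely
    narrow integrand that large binomial counts produce.
    """
    from scipy.special import expit

    beta, log_s = params[:-1], params[-1]
    s = np.exp(log_s)
    eta = X @ beta
    n_tr = succ + fail
    # mode of h(z) = ll(eta + s z) - z^2 / 2 per subject (h is concave)
    z = np.zeros_like(eta)
    for _ in range(100):
        lp = eta + s * z
        mu = expit(lp)
        grad = s * (succ - n_tr * mu) - z
        hess = -s * s * n_tr * mu * (1.0 - mu) - 1.0
        step = grad / hess
        z = z - step
        if np.max(np.abs(step)) < 1e-10:
            break
    lp = eta + s * z
    mu = expit(lp)
    sigma = 1.0 / np.sqrt(s * s * n_tr * mu * (1.0 - mu) + 1.0)
    zk = z[:, None] + sigma[:, None] * _GH_NODES[None, :]
    lpk = eta[:, None] + s * zk
    hk = (succ[:, None] * lpk - n_tr[:, None] * np.logaddexp(0.0, lpk)
          - 0.5 * zk * zk)
    arg = np.log(_GH_W)[None, :] + hk + 0.5 * (_GH_NODES * _GH_NODES)[None, :]
    mx = arg.max(axis=1, keepdims=True)
    ll = (np.log(np.exp(arg - mx).sum(axis=1)) + mx[:, 0] + np.log(sigma))
    return -float(ll.sum())


def fit_binomial_glmm(succ: np.ndarray, trials: np.ndarray,
                      X: np.ndarray) -> dict:
    """Binomial logistic GLMM with one observation per subject.

    Each subject contributes (successes, trials); the linear predictor is
    X @ beta + u with u ~ N(0, sigma^2) a subject random intercept. Returns
    fixed-effect estimates, Wald SEs/p-values, sigma and convergence info.
    """
    succ = np.asarray(succ, float)
    trials = np.asarray(trials, float)
    fail = trials - succ
    X = np.asarray(X, float)
    k = X.shape[1]
    phat = np.clip(succ.sum() / trials.sum(), 1e-6, 1 - 1e-6)
    x0 = np.r_[np.log(phat / (1 - phat)), np.zeros(k - 1), -1.0]
    res = optimize.minimize(_glmm_nll, x0, args=(succ, fail, X),
                            method="L-BFGS-B",
                            options={"ftol": 1e-12, "gtol": 1e-6,
                                     "maxiter": 500})
    params = res.x
    # numerical Hessian (central differences) for Wald SEs
    eps = 1e-4
    n = params.size
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            pp = params.copy(); pp[i] += eps; pp[j] += eps
            pm = params.copy(); pm[i] += eps; pm[j] -= eps
            mp = params.copy(); mp[i] -= eps; mp[j] += eps
            mm = params.copy(); mm[i] -= eps; mm[j] -= eps
            H[i, j] = H[j, i] = (
                _glmm_nll(pp, succ, fail, X) - _glmm_nll(pm, succ, fail, X)
                - _glmm_nll(mp, succ, fail, X) + _glmm_nll(mm, succ, fail, X)
            ) / (4 * eps * eps)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov)[:k], 0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = params[:k] / se
    return {
        "beta": params[:k],
        "se": se,
        "p": 2 * stats.norm.sf(np.abs(z)),
        "sigma": float(np.exp(params[-1])),
        "loglik": -res.fun,
        "converged": (bool(res.success) and np.all(np.isfinite(se))
                      and np.all(se > 0)),
    }


def edge_group_test(per_subject: dict[str, tuple[np.ndarray, np.ndarray]],
                    cohort: CohortTable, factor: str = "genotype",
                    reference: str | None = None, alpha: float = 0.05,
                    case_level: str | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-edge group inference on subject-level transition counts.

    ``per_subject`` maps subject_id -> (counts, usage) from
    :func:`transition_counts`. For each ordered motif pair (i, j) with a
    nonzero pooled numerator and denominator, the subject pairs
    (transitions i->j, bins in i) are modeled as binomial with a subject
    random intercept and fixed level effects (reference = control level;
    with three levels, two dummies are fitted and the contrast reported is
    ``case_level`` vs reference). Reports log odds ratios, Wald p and BH q
    over all tested edges; edges whose model fails to converge fall back to
    a Fisher exact test on pooled counts, flagged. Returns (edge report,
    skipped-edges table).
    """
    meta = cohort.table.set_index("subject_id")[factor]
    subjects = list(per_subject)
    levels = sorted({meta[s] for s in subjects})
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValidationError(f"reference level {reference!r} not in {levels}")
    others = [g for g in levels if g != reference]
    if not 1 <= len(others) <= 2:
        raise ValidationError("edge_group_test needs two or three levels")
    if case_level is None:
        case_level = others[-1]
    ci = others.index(case_level)
    m = next(iter(per_subject.values()))[0].shape[0]
    counts = np.stack([per_subject[s][0] for s in subjects])
    usage = np.stack([per_subject[s][1] for s in subjects])
    X = np.column_stack(
        [np.ones(len(subjects))]
        + [np.array([1.0 if meta[s] == g else 0.0 for s in subjects])
           for g in others])
    pooled_c = counts.sum(axis=0)
    pooled_u = usage.sum(axis=0)
    grp_case = X[:, 1 + ci] == 1.0
    rows, skipped = [], []
    for i in range(m):
        for j in range(m):
            succ = counts[:, i, j].astype(float)
            tri = usage[:, i].astype(float)
            if pooled_c[i, j] == 0 or pooled_u[i] == 0:
                skipped.append((i, j, int(pooled_c[i, j]),
                                int(pooled_u[i]), "zero pooled events"))
                continue
            keep = tri > 0
            p_pool = pooled_c[i, j] / pooled_u[i]
            with np.errstate(divide="ignore", invalid="ignore"):
                p_case = (succ[keep & grp_case].sum()
                          / max(tri[keep & grp_case].sum(), 1))
                p_ref = (succ[keep & (X[:, 1 + ci] == 0)].sum()
                         / max(tri[keep & (X[:, 1 + ci] == 0)].sum(), 1))
            fit = fit_binomial_glmm(succ[keep], tri[keep], X[keep])
            if fit["converged"]:
                logor = float(fit["beta"][1 + ci])
                p = float(fit["p"][1 + ci])
                fallback = False
            else:
                # exact conditional test on pooled 2x2
                a = succ[grp_case].sum(); b = tri[grp_case].sum() - a
                c = succ[~grp_case].sum(); d = tri[~grp_case].sum() - c
                _, p = stats.fisher_exact([[a, b], [c, d]])
                with np.errstate(divide="ignore", invalid="ignore"):
                    logor = float(np.log((a * d) / (b * c))) \
                        if min(a, b, c, d) > 0 else np.nan
                fallback = True
            rows.append((i, j, p_pool, p_ref, p_case, logor, p, fallback))
    rep = pd.DataFrame(rows, columns=[
        "source", "target", "p_pooled", "p_reference", "p_case",
        "log_odds_ratio", "p", "fallback_exact"])
    if len(rep):
        rep["q"], rep["significant"] = benjamini_hochberg(
            rep["p"].to_numpy(), alpha)
        rep["direction"] = np.where(
            rep["significant"],
            np.where(rep["log_odds_ratio"] > 0, "over", "under"), "")
    skip = pd.DataFrame(skipped, columns=["source", "target",
                                          "pooled_transitions", "pooled_bins",
                                          "reason"])
    return rep, skip


def export_network(edges: pd.DataFrame, usage_seconds: dict[int, float],
                   path_graphml: str, path_edges_tsv: str | None = None,
                   communities: dict[int, str] | None = None,
                   node_flags: dict[int, str] | None = None,
                   edge_report: pd.DataFrame | None = None) -> nx.DiGraph:
    """Write the transition network as GraphML plus a plain edge table.

    Nodes carry the motif id, community label, total dwell seconds across
    subjects and any usage significance flag; edges carry the probability
    (also mapped to a width weight) and per-edge significance from the
    group test. Self-transitions are encoded as loops.
    """
    g = nx.DiGraph()
    nodes = sorted(set(edges["source"]) | set(edges["target"])
                   | set(usage_seconds))
    for n in nodes:
        g.add_node(int(n),
                   motif=int(n),
                   community=(communities or {}).get(n, ""),
                   dwell_seconds=float(usage_seconds.get(n, 0.0)),
                   usage_flag=(node_flags or {}).get(n, ""))
    sig = {}
    if edge_report is not None and len(edge_report):
        for _, r in edge_report.iterrows():
            sig[(int(r["source"]), int(r["target"]))] = (
                float(r.get("log_odds_ratio", np.nan)),
                float(r.get("q", np.nan)), str(r.get("direction", "")))
    pmax = float(edges["probability"].max()) if len(edges) else 1.0
    for _, r in edges.iterrows():
        key = (int(r["source"]), int(r["target"]))
        logor, q, direction = sig.get(key, (np.nan, np.nan, ""))
        g.add_edge(*key, probability=float(r["probability"]),
                   width=float(r["probability"]) / pmax,
                   log_odds_ratio=logor if np.isfinite(logor) else 0.0,
                   q=q if np.isfinite(q) else 1.0,
                   direction=direction)
    nx.write_graphml(g, path_graphml)
    if path_edges_tsv is not None:
        rows = [{"source": u, "target": v, **d}
                for u, v, d in g.edges(data=True)]
        from .io_formats import write_tidy
        write_tidy(pd.DataFrame(rows), path_edges_tsv)
    return g
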