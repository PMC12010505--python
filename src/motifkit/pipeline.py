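"""Config-driven orchestration of the full analysis.

A single YAML/JSON config (or a :class:`RunConfig`) drives the stages in
dependency order: data (load files or generate a synthetic cohort) ->
binning -> usage -> transitions -> communities -> markov -> indices ->
inference -> export. Every stage round-trips through tidy files in the
output directory — there is no hidden state — and a machine-readable
manifest records the normalized config, the seed, the package version and a
SHA-256 checksum per output file, so identical config + seed reruns are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import group_tests, stepwise_logistic
from .communities import community_dendrogram, community_sequence, cut_dendrogram
from .deltas import delta_report
from .io_formats import (CohortTable, LabelSeries, ValidationError, read_cohort,
                         read_label_series, write_cohort, write_label_series,
                         write_tidy)
from .kinematics import allocentric_speed
from .markov import order_scan
from .transitions import (bin_labels, cohort_matrix, edge_group_test,
                          export_network, to_probabilities, top_edges,
                          transition_counts, transition_difference)
from .usage import (habituation_labels, relative_usage, rm_anova_by_label,
                    time_binned_usage, usage_correlation_clustering,
                    usage_table, usage_tests)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ["data", "binning", "usage", "transitions", "communities",
              "markov", "indices", "inference", "export"]

_DEFAULTS = dict(
    synthetic=True,
    labels_dir=None, pose_dir=None, cohort_file=None,
    fps=25.0, n_motifs=30, bin_frames=16,
    session_minutes=25.0, n_subjects=8, seed=0,
    bin_minutes=5.0,
    n_communities=10, cost_height=None, community_overrides=None,
    orders=[0, 1, 2, 3], epsilon=1e-10,
    alpha=0.05, edge_quantile=0.2,
    factor="genotype", control="WT",
    likelihood_floor=None,
    out_dir="motifkit_out",
    stages=list(ALL_STAGES),
)


@dataclass
class RunConfig:
    synthetic: bool = True
    labels_dir: str | None = None
    pose_dir: str | None = None
    cohort_file: str | None = None
    fps: float = 25.0
    n_motifs: int = 30
    bin_frames: int = 16
    session_minutes: float = 25.0
    n_subjects: int = 8
    seed: int = 0
    bin_minutes: float = 5.0
    n_communities: int | None = 10
    cost_height: float | None = None
    community_overrides: dict | None = None
    orders: list[int] = field(default_factory=lambda: [0, 1, 2, 3])
    epsilon: float = 1e-10
    alpha: float = 0.05
    edge_quantile: float = 0.2
    factor: str = "genotype"
    control: str = "WT"
    likelihood_floor: float | None = None
    out_dir: str = "motifkit_out"
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))

    def normalized(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d


def validate_config(source: str | Path | dict) -> RunConfig:
    """Parse + validate a config mapping, filling and logging defaults."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
        raw = yaml.safe_load(text)
    else:
        raw = dict(source)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValidationError("config must be a mapping")
    unknown = sorted(set(raw) - set(_DEFAULTS))
    if unknown:
        raise ValidationError(f"unknown config keys: {unknown}")
    merged = dict(_DEFAULTS)
    for key, default in _DEFAULTS.items():
        if key in raw:
            merged[key] = raw[key]
        else:
            logger.info("config default applied: %s = %r", key, default)
    cfg = RunConfig(**merged)
    for name in ("alpha", "edge_quantile"):
        v = getattr(cfg, name)
        if not 0 < v <= 1 or (name == "alpha" and v >= 1):
            raise ValidationError(f"{name} must lie in (0, 1): got {v}")
    if cfg.bin_frames < 1 or cfg.n_motifs < 2:
        raise ValidationError("bin_frames >= 1 and n_motifs >= 2 required")
    bad = sorted(set(cfg.stages) - set(ALL_STAGES))
    if bad:
        raise ValidationError(f"unknown stages: {bad}")
    if not cfg.synthetic:
        for name in ("labels_dir", "cohort_file"):
            p = getattr(cfg, name)
            if p is None or not Path(p).exists():
                raise ValidationError(f"{name} missing or does not exist: {p}")
    return cfg


def _needed(stage: str, requested: list[str]) -> bool:
    """A stage runs if requested or any requested stage depends on it."""
    deps = {
        "data": set(), "binning": {"data"}, "usage": {"data"},
        "transitions": {"data", "binning"},
        "communities": {"data", "binning", "transitions"},
        "markov": {"data", "binning", "transitions", "communities"},
        "indices": {"data", "binning", "transitions", "usage"},
        "inference": {"data", "binning", "transitions"},
        "export": {"data", "binning", "transitions", "inference", "usage",
                   "communities"},
    }
    if stage in requested:
        return True
    return any(stage in deps[r] for r in requested)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig | dict | str | Path) -> dict:
    """Execute the requested stages; return the manifest (also written)."""
    if not isinstance(config, RunConfig):
        config = validate_config(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    flags: dict[str, object] = {}

    def save(df: pd.DataFrame, name: str) -> Path:
        p = out / name
        write_tidy(df, p)
        written.append(p)
        return p

    # -- data -------------------------------------------------------------
    poses = None
    truth = None
    if config.synthetic:
        from .synthetic import default_spec, generate_cohort

        spec = default_spec(
            n_motifs=config.n_motifs, fps=config.fps,
            session_minutes=config.session_minutes,
            bin_frames=config.bin_frames, n_subjects=config.n_subjects,
            seed=config.seed)
        data = generate_cohort(spec)
        cohort, series, poses = data.cohort, data.labels, data.poses
        truth = data.truth_table()
    else:
        cohort = read_cohort(config.cohort_file)
        series = []
        for sid in cohort.subject_ids:
            hits = sorted(Path(config.labels_dir).glob(f"{sid}.*"))
            if not hits:
                raise ValidationError(f"no label file for subject {sid}")
            series.append(read_label_series(hits[0], config.fps,
                                            config.n_motifs, subject_id=sid))
    m = config.n_motifs
    levels = sorted(cohort.table[config.factor].unique())
    case = [g for g in levels if g != config.control]
    if _needed("data", config.stages):
        write_cohort(cohort, out / "cohort.tsv")
        written.append(out / "cohort.tsv")
        if config.synthetic:
            save(truth, "ground_truth.tsv")
            labels_dir = out / "labels"
            labels_dir.mkdir(exist_ok=True)
            for s in series:
                write_label_series(s, labels_dir / f"{s.subject_id}.tsv")
                written.append(labels_dir / f"{s.subject_id}.tsv")

    # -- binning ----------------------------------------------------------
    binned = {s.subject_id: bin_labels(s, config.bin_frames) for s in series}
    timestep = config.bin_frames / config.fps

    # -- usage ------------------------------------------------------------
    usage = usage_table(series, m)
    rel = relative_usage(usage, cohort, config.control, config.factor)
    if _needed("usage", config.stages):
        save(usage, "usage.tsv")
        save(rel, "relative_usage.tsv")
        tests = usage_tests(rel, cohort, config.factor, alpha=config.alpha,
                            absolute_usage=usage)
        save(tests, "usage_tests.tsv")
        tb = time_binned_usage(series, m, config.bin_minutes)
        save(tb, "binned_usage.tsv")
        save(rm_anova_by_label(tb), "binned_usage_anova.tsv")
        save(habituation_labels(tb, cohort, config.control, config.factor,
                                config.alpha), "habituation.tsv")
        rel_mat = rel.pivot(index="subject_id", columns="motif",
                            values="relative").fillna(0.0)
        cl = usage_correlation_clustering(rel_mat)
        save(pd.DataFrame({
            "dimension": (["motif"] * len(cl.motif_order)
                          + ["subject"] * len(cl.subject_order)),
            "position": (list(range(len(cl.motif_order)))
                         + list(range(len(cl.subject_order)))),
            "item": [str(x) for x in cl.motif_order + cl.subject_order],
        }), "cluster_orders.tsv")
    else:
        tests = None

    # -- transitions ------------------------------------------------------
    per_subject = {sid: transition_counts(b, m) for sid, b in binned.items()}
    pooled = cohort_matrix(list(binned.values()), m, "dwell_inclusive",
                           timestep)
    pooled_switch = cohort_matrix(list(binned.values()), m, "switch_only",
                                  timestep)
    if _needed("transitions", config.stages):
        save(pd.DataFrame(pooled.probabilities), "cohort_matrix_dwell.tsv")
        save(pd.DataFrame(pooled_switch.probabilities),
             "cohort_matrix_switch.tsv")
        if len(case) == 1:
            by_group = {
                g: [binned[s] for s in cohort.subjects_where(
                    **{config.factor: g})]
                for g in levels}
            diff = transition_difference(
                cohort_matrix(by_group[case[0]], m, "switch_only", timestep),
                cohort_matrix(by_group[config.control], m, "switch_only",
                              timestep))
            save(pd.DataFrame(diff), "transition_difference.tsv")
    edges = top_edges(pooled, config.edge_quantile, scope="off_diagonal")
    if _needed("transitions", config.stages):
        save(edges, "top_edges.tsv")

    # -- communities ------------------------------------------------------
    dend = community_dendrogram(pooled_switch.counts, pooled_switch.usage)
    assignment = cut_dendrogram(
        dend, n_communities=config.n_communities,
        cost_height=config.cost_height,
        overrides=config.community_overrides)
    comm_series = {sid: community_sequence(b, assignment)
                   for sid, b in binned.items()}
    if _needed("communities", config.stages):
        save(dend.merge_table(), "dendrogram_merges.tsv")
        (out / "dendrogram.nwk").write_text(dend.to_newick() + "\n",
                                            encoding="utf-8")
        written.append(out / "dendrogram.nwk")
        save(pd.DataFrame(sorted(assignment.mapping.items()),
                          columns=["motif", "community"]),
             "communities.tsv")

    # -- markov -----------------------------------------------------------
    if _needed("markov", config.stages):
        series_by_group = {
            g: [comm_series[s] for s in cohort.subjects_where(
                **{config.factor: g})]
            for g in levels}
        scan = order_scan(series_by_group, config.orders, config.epsilon,
                          cohort=cohort)
        save(scan["loglik"], "loglik.tsv")
        save(scan["pbf"], "pbf.tsv")
        if "anova" in scan and len(scan["anova"]):
            save(scan["anova"], "loglik_anova.tsv")

    # -- indices ----------------------------------------------------------
    if _needed("indices", config.stages) and len(case) >= 1:
        matrices = {sid: to_probabilities(*per_subject[sid], "switch_only",
                                          timestep).probabilities
                    for sid in binned}
        usages = {
            sid: usage[usage["subject_id"] == sid]
            .sort_values("motif")["percent"].to_numpy()
            for sid in binned}
        speeds: dict[str, np.ndarray] = {}
        if poses is not None:
            for track, s in zip(poses, series):
                spd = allocentric_speed(track, "center")
                vec = np.full(m, np.nan)
                for motif in range(m):
                    sel = (s.labels == motif) & np.isfinite(spd)
                    if sel.any():
                        vec[motif] = float(spd[sel].mean())
                speeds[track.subject_id] = vec
        else:
            speeds = {sid: np.full(m, 0.0) for sid in binned}
            flags["sdi"] = "no pose data; speeds set to 0 (SDI uninformative)"
        rep = delta_report(cohort, matrices, usages, speeds, config.control,
                           config.factor)
        save(rep.table, "indices.tsv")
        flags["delta_flags"] = rep.flags
        index_tests = []
        if len(case) == 1:
            for col in ("tdi", "udi", "sdi"):
                vals = rep.table.set_index("subject_id")[col]
                res = group_tests(vals, cohort, "two_group", config.factor)
                index_tests.append((col, res["estimate"], res["p"]))
            save(pd.DataFrame(index_tests,
                              columns=["index", "estimate", "p"]),
                 "indices_tests.tsv")
        # stepwise classifier on motif usage percents
        feat = usage.pivot(index="subject_id", columns="motif",
                           values="percent")
        feat.columns = [f"motif_{c}" for c in feat.columns]
        lab = cohort.table.set_index("subject_id")[config.factor]
        clf = stepwise_logistic(feat, lab.loc[feat.index],
                                reference=config.control)
        save(clf.steps if len(clf.steps) else
             pd.DataFrame(columns=["action", "feature", "p", "aic"]),
             "classifier_steps.tsv")
        save(clf.metrics, "classifier_metrics.tsv")
        conf = clf.confusion.reset_index(names="actual")
        save(conf, "classifier_confusion.tsv")
        flags["classifier"] = {"aic": clf.aic, "selected": clf.selected,
                               "separation": clf.separation}

    # -- inference --------------------------------------------------------
    if _needed("inference", config.stages) and len(case) >= 1:
        rep_edges, skipped = edge_group_test(
            per_subject, cohort, config.factor, reference=config.control,
            alpha=config.alpha)
        save(rep_edges, "edge_tests.tsv")
        save(skipped, "edges_skipped.tsv")
    else:
        rep_edges = None

    # -- export -----------------------------------------------------------
    if _needed("export", config.stages):
        dwell = usage.groupby("motif")["seconds"].sum().to_dict()
        node_flags = {}
        if tests is not None:
            for _, r in tests.iterrows():
                if r["significant"]:
                    node_flags[int(r["motif"])] = (
                        "over" if r["estimate"] > 0 else "under")
        export_network(edges, dwell, str(out / "network.graphml"),
                       str(out / "network_edges.tsv"),
                       communities=assignment.mapping,
                       node_flags=node_flags, edge_report=rep_edges)
        written += [out / "network.graphml", out / "network_edges.tsv"]

    manifest = {
        "package": "motifkit",
        "version": __version__,
        "config": config.normalized(),
        "seed": config.seed,
        "files": {str(p.relative_to(out)): _sha256(p)
                  for p in sorted(set(written))},
        "flags": json.loads(json.dumps(flags, default=str, sort_keys=True)),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8")
    return manifest
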