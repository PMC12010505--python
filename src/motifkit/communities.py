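"""Cost-function hierarchical merging of motifs into behavioral communities.

At each agglomeration step the switch-only transition probabilities are
recomputed from the current merged counts (diagonal zeroed, rows
renormalized) and the pair minimizing

    cost(i, j) = (usage_i + usage_j) / (prob_ij + prob_ji)

is merged: high mutual transition probability and low usage merge first, so
communities are groups of motifs the animal flickers between. Merging sums
count rows/columns and usages; probabilities are therefore well-defined at
every level. The recorded dendrogram height is the raw merge cost (no
ultrametric enforcement — costs may invert; plotting should clamp to
running maxima for display only). Pairs with zero mutual transition mass
have infinite cost and merge only when nothing finite remains.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .io_formats import LabelSeries, ValidationError

__all__ = ["Merge", "CommunityDendrogram", "CommunityAssignment",
           "community_dendrogram", "cut_dendrogram", "community_sequence"]


@dataclass
class Merge:
    node_a: int
    node_b: int
    cost: float       # inf when forced (no mutual transitions)
    new_node: int


@dataclass
class CommunityDendrogram:
    """Binary merge tree over motifs with per-merge cost."""

    n_motifs: int
    merges: list[Merge]
    members: dict[int, list[int]]  # node id -> sorted motif leaves

    def leaf_order(self) -> list[int]:
        """Motifs in dendrogram display order (depth-first, a before b)."""
        root = self.merges[-1].new_node if self.merges else 0
        out: list[int] = []

        def visit(node: int) -> None:
            if node < self.n_motifs:
                out.append(node)
                return
            mg = self.merges[node - self.n_motifs]
            visit(mg.node_a)
            visit(mg.node_b)

        visit(root)
        return out

    def to_newick(self) -> str:
        """Newick with branch lengths = parent cost - child cost (clamped)."""
        heights = {i: 0.0 for i in range(self.n_motifs)}
        for mg in self.merges:
            heights[mg.new_node] = mg.cost if np.isfinite(mg.cost) else \
                max(h for h in heights.values() if np.isfinite(h)) * 2 + 1

        def render(node: int, parent_h: float) -> str:
            bl = max(parent_h - heights[node], 0.0)
            if node < self.n_motifs:
                return f"{node}:{bl:.6g}"
            mg = self.merges[node - self.n_motifs]
            h = heights[node]
            return (f"({render(mg.node_a, h)},{render(mg.node_b, h)})"
                    f":{bl:.6g}")

        root = self.merges[-1].new_node
        return render(root, heights[root]).rsplit(":", 1)[0] + ";"

    def merge_table(self):
        import pandas as pd
        return pd.DataFrame(
            [(m.node_a, m.node_b, m.cost, m.new_node) for m in self.merges],
            columns=["node_a", "node_b", "cost", "new_node"])


@dataclass
class CommunityAssignment:
    """Total map motif -> community label, with provenance."""

    mapping: dict[int, str]
    labels: list[str]
    provenance: str
    overrides: dict[int, str] = field(default_factory=dict)

    def index_of(self) -> dict[int, int]:
        order = {lab: k for k, lab in enumerate(self.labels)}
        return {motif: order[lab] for motif, lab in self.mapping.items()}

    @property
    def n_communities(self) -> int:
        return len(self.labels)


def _switch_probs(counts: np.ndarray) -> np.ndarray:
    off = counts.astype(float).copy()
    np.fill_diagonal(off, 0.0)
    denom = off.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(denom > 0, off / denom, 0.0)
    return probs


def community_dendrogram(counts: np.ndarray,
                         usage: np.ndarray) -> CommunityDendrogram:
    """Iteratively merge the motif pair with the minimal usage/probability cost.

    Ties break to the lexicographically smallest (node_a, node_b) pair for
    determinism. Exactly m - 1 merges are recorded.
    """
    counts = np.asarray(counts, float)
    usage = np.asarray(usage, float)
    m = counts.shape[0]
    if counts.ndim != 2 or counts.shape != (m, m):
        raise ValidationError("counts must be square")
    if usage.shape != (m,):
        raise ValidationError("usage length must match counts")
    if m < 2:
        raise ValidationError("need at least two motifs")
    members = {i: [i] for i in range(m)}
    slots = list(range(m))  # slots[k] = node id occupying row/col k
    cur_counts = counts.copy()
    cur_usage = usage.copy()
    merges: list[Merge] = []
    next_id = m
    for _ in range(m - 1):
        probs = _switch_probs(cur_counts)
        best = None  # (cost, node_a, node_b)
        for pa in range(len(slots)):
            for pb in range(pa + 1, len(slots)):
                denom = probs[pa, pb] + probs[pb, pa]
                cost = ((cur_usage[pa] + cur_usage[pb]) / denom
                        if denom > 0 else np.inf)
                a, b = sorted((slots[pa], slots[pb]))
                key = (cost, a, b)
                if best is None or key < best:
                    best = key
        cost, a, b = best
        pa, pb = slots.index(a), slots.index(b)
        # merge b into a's slot: sum rows/cols and usages
        cur_counts[pa, :] += cur_counts[pb, :]
        cur_counts[:, pa] += cur_counts[:, pb]
        cur_counts = np.delete(np.delete(cur_counts, pb, axis=0), pb, axis=1)
        cur_usage[pa] += cur_usage[pb]
        cur_usage = np.delete(cur_usage, pb)
        members[next_id] = sorted(members[a] + members[b])
        merges.append(Merge(a, b, float(cost), next_id))
        slots[pa] = next_id
        del slots[pb]
        next_id += 1
    return CommunityDendrogram(m, merges, members)


def _community_labels(n: int) -> list[str]:
    letters = string.ascii_uppercase
    out = []
    for k in range(n):
        label = ""
        k1 = k
        while True:
            label = letters[k1 % 26] + label
            k1 = k1 // 26 - 1
            if k1 < 0:
                break
        out.append(label)
    return out


def cut_dendrogram(dendrogram: CommunityDendrogram,
                   n_communities: int | None = None,
                   cost_height: float | None = None,
                   overrides: dict[int, str] | None = None
                   ) -> CommunityAssignment:
    """Cut the merge tree into communities.

    Either undo the last ``n_communities - 1`` merges, or keep only merges
    whose recorded cost is <= ``cost_height`` (union-find semantics, so a
    cheap merge below an expensive one still joins its leaves). Communities
    are labeled A, B, ... in dendrogram leaf order. An explicit
    motif -> community override table replaces assignments afterwards
    (supporting manual sub-segmentation, which is never inferred).
    """
    m = dendrogram.n_motifs
    if (n_communities is None) == (cost_height is None):
        raise ValidationError("give exactly one of n_communities, cost_height")
    parent = list(range(m))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    if n_communities is not None:
        if not 1 <= n_communities <= m:
            raise ValidationError(f"n_communities must be in [1, {m}]")
        applied = dendrogram.merges[:m - n_communities]
        if len(applied) < m - n_communities:
            raise ValidationError("not enough merges recorded")
        for mg in applied:
            union(min(dendrogram.members[mg.node_a]),
                  min(dendrogram.members[mg.node_b]))
        provenance = f"k={n_communities}"
    else:
        if cost_height <= 0:
            raise ValidationError("cost_height must be positive")
        for mg in dendrogram.merges:
            if np.isfinite(mg.cost) and mg.cost <= cost_height:
                union(min(dendrogram.members[mg.node_a]),
                      min(dendrogram.members[mg.node_b]))
        provenance = f"height={cost_height}"
    # label communities in dendrogram leaf order
    seen: dict[int, int] = {}
    for motif in dendrogram.leaf_order():
        root = find(motif)
        if root not in seen:
            seen[root] = len(seen)
    labels = _community_labels(len(seen))
    mapping = {motif: labels[seen[find(motif)]] for motif in range(m)}
    if overrides:
        unknown = [k for k in overrides if not 0 <= k < m]
        if unknown:
            raise ValidationError(f"override motifs out of range: {unknown}")
        mapping.update({k: str(v) for k, v in overrides.items()})
        labels = sorted(set(mapping.values()),
                        key=lambda lab: min(k for k, v in mapping.items()
                                            if v == lab))
        provenance += "+overrides"
    return CommunityAssignment(mapping, labels, provenance, overrides or {})


def community_sequence(series: LabelSeries,
                       assignment: CommunityAssignment) -> LabelSeries:
    """Relabel a motif series into its community series."""
    index = assignment.index_of()
    present = np.unique(series.labels)
    missing = [int(v) for v in present if int(v) not in index]
    if missing:
        raise ValidationError(f"motifs without community assignment: {missing}")
    lut = np.full(series.alphabet_size, -1, dtype=np.int64)
    for motif, k in index.items():
        if motif < series.alphabet_size:
            lut[motif] = k
    return LabelSeries(series.subject_id, series.fps, lut[series.labels],
                       assignment.n_communities)
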