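# motifkit

Post-segmentation analytics for per-frame behavioral motif sequences.

Unsupervised segmentation tools turn videos of freely behaving animals into a
per-frame sequence of discrete **motifs** (short stereotyped movements) plus
pose tracks. `motifkit` is everything that comes *after* segmentation: it
quantifies how a cohort of subjects uses those motifs, how motifs chain into
each other, how the chaining organizes into higher-level communities, how much
history the sequences carry, and which of those properties a genotype (or any
two-level grouping) changes — with multiple-comparison control and explicit,
reproducible numerics throughout.

## What it computes

**Usage statistics** (`motifkit.usage`) — time spent per motif; usage relative
to sex-matched controls; per-motif Welch tests with Benjamini–Hochberg (BH)
false-discovery-rate control; time-binned occupancy with repeated-measures
ANOVA; habituation/sensitization classification from control slopes;
usage-correlation clustering.

**Transition networks** (`motifkit.transitions`) — per-frame labels are
reduced to one modal label per 640-ms bin (16 frames at 25 fps), consecutive
bins are counted into transition matrices, normalized either
*dwell-inclusive* (self-transitions kept) or *switch-only* (diagonal removed,
rows renormalized). Top-quantile edges form a directed network (GraphML
export); per-edge group effects are tested with a binomial random-intercept
model fitted by adaptive Gauss–Hermite quadrature, BH-corrected across edges.

**Communities** (`motifkit.communities`) — motifs are merged bottom-up by the
cost

```
cost(i, j) = (usage_i + usage_j) / (p_ij + p_ji)
```

where `p` are switch-only transition probabilities recomputed from merged
counts at every level, so cheap merges join motifs that are individually rare
but mutually connected. The dendrogram is cut at a target community count or
a cost height, with optional manual overrides, and exports to Newick.

**Markov order selection** (`motifkit.markov`) — fixed-order Markov models
(order 0–3) compared by leave-one-out cross-validation: the held-out subject
is scored under the unweighted average of the other subjects' per-subject
estimates, and orders k, l are compared by the log pseudo Bayes factor

```
log PBF(k, l) = Σ_subjects [ LL_k(held out) − LL_l(held out) ]
```

(positive favors order k), with clamp and fallback counts reported so sparse
contexts are visible, never silent.

**Delta indices** (`motifkit.deltas`) — per-subject Transition / Use / Speed
Delta Indices: mean absolute deviation of a subject's switch-only matrix,
usage vector, or per-motif speed vector from the control-group elementwise
average, normalized so the control mean of every index is exactly 1. They
dissect *which* aspect of behavior a manipulation moves.

**Classification** (`motifkit.classify`) — forward-stepwise multinomial
logistic regression with likelihood-ratio entry/removal, complete-separation
detection, confusion matrices and per-class metrics; plus generic two-group
and two-factor (group × sex) scalar tests.

**Kinematics** (`motifkit.kinematics`) — rigid egocentric alignment (center
part to origin, body midline onto the negative y-axis), allocentric speeds,
and per-motif post-onset kinematic profiles.

**Synthetic cohorts** (`motifkit.synthetic`) — a generator with exact,
returned ground truth (per-subject transition matrices, usage, speeds) used
throughout the test suite to validate every estimator against known answers.

**Pipeline + CLI** (`motifkit.pipeline`, `motifkit` command) — one config
runs the whole chain on synthetic or file-based data, writing tidy TSVs, a
GraphML network and a manifest with a SHA-256 per file. Same config and seed
give byte-identical outputs.

## Quick start

```python
from motifkit.synthetic import default_spec, generate_cohort
from motifkit.usage import relative_usage, usage_table, usage_tests

data = generate_cohort(default_spec(n_subjects=4, session_minutes=10.0, seed=7))
usage = usage_table(data.labels, data.spec.n_motifs)
rel = relative_usage(usage, data.cohort, baseline="WT")
tests = usage_tests(rel, data.cohort, factor="genotype", alpha=0.05)
print(tests.sort_values("q").head(3))
```

prints (the generator's default genotype effect enriches motif 9):

```
 motif  estimate        p  degenerate        q  significant    test
     9  0.581655 0.000304       False 0.009111         True welch_t
    12 -0.567076 0.007870       False 0.118046        False welch_t
     6 -0.397436 0.036086       False 0.360858        False welch_t
```

Communities recover the generator's block structure from data alone
(`examples/04_communities.py`):

```
communities at k=10: ['A', 'B', 'C', 'D', 'E', 'F', 'G', 'H', 'I', 'J']
  A: [3, 4, 5]
  B: [21, 22, 23]
  C: [27, 28, 29]
  D: [0, 1, 2]
  ...
```

and the order scan identifies history dependence
(`examples/05_markov_order.py`):

```
group  order_k  order_l       log_pbf
  WT         1        0  10306.998433
  MUT        1        0  10491.310140
```

Or run everything from a config:

```bash
motifkit validate -c config.yaml
motifkit run -c config.yaml -o outdir
motifkit report outdir/manifest.json
```

A minimal synthetic config:

```yaml
synthetic: true
n_subjects: 4          # per genotype x sex cell
session_minutes: 25.0
bin_minutes: 5.0
orders: [0, 1, 2]
n_communities: 10
seed: 2024
out_dir: outdir
```

File-based runs instead take `labels_dir`, `cohort_file` and optionally
`poses_dir` (pose files are needed only for the speed-based outputs; the
pipeline flags and skips them otherwise).

The `examples/` directory has one narrative script per capability
(`python examples/01_synthetic_cohort.py`, …). `docs/methods.md` documents
the statistical model, every default, and the numerical choices.

## Testing

```bash
python -m pytest -o addopts= -p no:cacheprovider -q tests/
```

The suite validates every estimator against hand-worked oracles, closed-form
likelihoods, brute-force reimplementations and generator ground truth, plus
property-based tests (hypothesis) for the format and geometry invariants.
`tests/test_acceptance.py` holds the end-to-end statistical guarantees
(recovery rates, FDR calibration, determinism).

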