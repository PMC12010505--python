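"""Synthetic cohorts of motif sequences and pose tracks.

The generator emulates the statistical structure of an open-arena
phenotyping study: 30 motifs organised into communities of high mutual
transition probability, 25-minute sessions at 25 frames/s, two genotypes and
two sexes with genotype-dependent shifts in transition probabilities, usage
and speed, and sex-dependent baseline differences. Label sequences are drawn
as a first-order Markov chain at the 640-ms bin level (16 frames at 25 fps)
and expanded to identical per-frame labels within each bin, so that
generator truth and the analysis timestep coincide. Ground-truth per-subject
transition matrices, stationary usage and speed profiles are returned
alongside the data so recovery can be tested.

Pose realism is deliberately minimal: the center body part performs a
bounded random walk whose per-frame step length encodes the per-motif mean
speed, and the remaining parts are rigid offsets from the center in the
heading frame plus jitter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CohortTable, LabelSeries, PoseTrack, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "GroupEffect",
    "GeneratorSpec",
    "SyntheticCohort",
    "make_block_transition_matrix",
    "generate_label_sequence",
    "generate_pose_track",
    "generate_cohort",
    "default_spec",
    "stationary_distribution",
    "DEFAULT_PARTS",
]

# Ventral-camera body plan: 9 parts, offsets (x, y) px from center in the
# heading frame (rostral = +y, subject's left = -x).
DEFAULT_PARTS = [
    "nose", "left_forepaw", "right_forepaw", "left_hindpaw",
    "right_hindpaw", "center", "tail_base", "mid_tail", "tail_tip",
]
_BODY_OFFSETS = np.array([
    (0.0, 32.0),    # nose
    (-10.0, 18.0),  # left_forepaw
    (10.0, 18.0),   # right_forepaw
    (-12.0, -12.0),  # left_hindpaw
    (12.0, -12.0),  # right_hindpaw
    (0.0, 0.0),     # center
    (0.0, -22.0),   # tail_base
    (0.0, -45.0),   # mid_tail
    (0.0, -68.0),   # tail_tip
])


@dataclass
class GroupEffect:
    """Multiplicative perturbation applied to one genotype or sex level.

    ``transition_scale`` multiplies selected (row, col) entries of the
    baseline transition matrix before row renormalisation; ``column_scale``
    multiplies whole inflow columns (a usage target); ``speed_scale``
    multiplies per-motif mean speeds.
    """

    transition_scale: dict[tuple[int, int], float] = field(default_factory=dict)
    column_scale: dict[int, float] = field(default_factory=dict)
    speed_scale: dict[int, float] = field(default_factory=dict)


@dataclass
class GeneratorSpec:
    """Full description of a synthetic cohort.

    Defaults emulate the study conditions: m = 30 motifs in 10 communities
    of 3, 25-min sessions at 25 fps, 8 subjects per (genotype, sex) cell,
    per-motif mean allocentric center speeds spanning stationary grooming
    (~20 px/s) to fast ambulation (~220 px/s).
    """

    n_motifs: int = 30
    community_blocks: list[list[int]] = field(
        default_factory=lambda: [list(range(3 * b, 3 * b + 3)) for b in range(10)])
    baseline_transition: np.ndarray | None = None
    genotype_effects: dict[str, GroupEffect] = field(default_factory=dict)
    sex_effects: dict[str, GroupEffect] = field(default_factory=dict)
    speed_means: np.ndarray | None = None   # px/s per motif
    speed_noise: float = 15.0               # px/s, per-frame step noise
    fps: float = 25.0
    session_minutes: float = 25.0
    bin_frames: int = 16
    n_subjects: int = 8                     # per (genotype, sex) cell
    genotypes: tuple[str, ...] = ("WT", "MUT")
    sexes: tuple[str, ...] = ("F", "M")
    arena_radius_px: float = 320.0          # 12-inch arena, ~53 px/inch
    p_self: float = 0.40
    p_within: float = 0.40
    seed: int = 0

    def resolve(self) -> "GeneratorSpec":
        """Fill derived defaults (baseline matrix, speed profile)."""
        if self.baseline_transition is None:
            self.baseline_transition = make_block_transition_matrix(
                self.n_motifs, self.community_blocks, p_within=self.p_within,
                p_self=self.p_self, seed=self.seed)
        if self.speed_means is None:
            self.speed_means = np.linspace(20.0, 220.0, self.n_motifs)
        self.baseline_transition = np.asarray(self.baseline_transition, float)
        self.speed_means = np.asarray(self.speed_means, float)
        _check_stochastic(self.baseline_transition)
        if not np.all(np.isfinite(self.speed_means)):
            raise ValidationError("speed means must be finite")
        return self


@dataclass
class SyntheticCohort:
    """Generated data plus the ground truth it was drawn from."""

    cohort: CohortTable
    labels: list[LabelSeries]
    poses: list[PoseTrack]
    true_matrices: dict[str, np.ndarray]     # subject -> bin-level transition
    true_usage: dict[str, np.ndarray]        # subject -> stationary percent
    true_speeds: dict[str, np.ndarray]       # subject -> per-motif px/s
    spec: GeneratorSpec

    def truth_table(self) -> pd.DataFrame:
        """Ground truth as a tidy sidecar table (subject, motif, usage, speed)."""
        rows = []
        for sid in self.cohort.subject_ids:
            for m in range(self.spec.n_motifs):
                rows.append((sid, m, self.true_usage[sid][m],
                             self.true_speeds[sid][m]))
        return pd.DataFrame(rows, columns=["subject_id", "motif",
                                           "usage_percent", "speed_px_s"])


def _check_stochastic(matrix: np.ndarray, tol: float = 1e-9) -> None:
    matrix = np.asarray(matrix, float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValidationError("transition matrix must be square")
    if (matrix < 0).any():
        raise ValidationError("transition probabilities must be nonnegative")
    bad = np.where(np.abs(matrix.sum(axis=1) - 1.0) > tol)[0]
    if bad.size:
        raise ValidationError(
            f"transition matrix row {int(bad[0])} sums to "
            f"{matrix[bad[0]].sum():.6g}, not 1")


def make_block_transition_matrix(m: int, blocks: list[list[int]],
                                 p_within: float, p_self: float,
                                 seed: int = 0) -> np.ndarray:
    """Row-stochastic matrix with community block structure.

    Each row puts ``p_self`` on the diagonal, spreads ``p_within`` uniformly
    over same-block off-diagonal entries, and the remaining mass uniformly
    over all other motifs. A singleton block has no within-block neighbours;
    its ``p_within`` mass is reassigned to the remainder with a warning.
    """
    if p_self < 0 or p_within < 0 or p_self + p_within > 1 + 1e-12:
        raise ValidationError("need p_self + p_within <= 1 and both >= 0")
    flat = sorted(i for b in blocks for i in b)
    if flat != list(range(m)):
        raise ValidationError(f"blocks must partition [0, {m})")
    block_of = np.empty(m, dtype=int)
    for bi, b in enumerate(blocks):
        block_of[np.array(b, dtype=int)] = bi
    T = np.zeros((m, m))
    for i in range(m):
        mates = [j for j in blocks[block_of[i]] if j != i]
        others = [j for j in range(m) if j != i and block_of[j] != block_of[i]]
        p_rest = 1.0 - p_self - p_within
        within = p_within
        if not mates and p_within > 0:
            warnings.warn(
                f"motif {i} is a singleton block; reassigning its p_within "
                "mass to the remainder", stacklevel=2)
            p_rest += p_within
            within = 0.0
        T[i, i] = p_self
        for j in mates:
            T[i, j] = within / len(mates)
        for j in others:
            T[i, j] = p_rest / len(others)
    # guard against empty 'others' for degenerate partitions
    rs = T.sum(axis=1)
    T /= rs[:, None]
    return T


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Left eigenvector of the chain at eigenvalue 1, normalised to sum 1."""
    vals, vecs = np.linalg.eig(T.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def generate_label_sequence(transition: np.ndarray, n_frames: int,
                            seed: int | np.random.SeedSequence,
                            start: int | str = "stationary",
                            fps: float = 25.0, bin_frames: int = 16,
                            subject_id: str = "sim") -> LabelSeries:
    """Draw a first-order Markov chain at the bin level, expand to frames.

    One state is drawn per ``bin_frames``-frame bin and repeated for every
    frame in the bin; the final partial bin is truncated to reach exactly
    ``n_frames`` frames.
    """
    transition = np.asarray(transition, float)
    _check_stochastic(transition)
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    m = transition.shape[0]
    n_bins = -(-n_frames // bin_frames)  # ceil
    if start == "stationary":
        pi = stationary_distribution(transition)
        state = int(rng.choice(m, p=pi))
    else:
        state = int(start)
        if not 0 <= state < m:
            raise ValidationError(f"start state {state} outside [0, {m})")
    cum = np.cumsum(transition, axis=1)
    u = rng.random(n_bins - 1)
    bins = np.empty(n_bins, dtype=np.int64)
    bins[0] = state
    for t in range(1, n_bins):
        state = int(np.searchsorted(cum[state], u[t - 1], side="right"))
        state = min(state, m - 1)  # guard fp round-off at the top edge
        bins[t] = state
    labels = np.repeat(bins, bin_frames)[:n_frames]
    return LabelSeries(subject_id, fps, labels, m)


def generate_pose_track(labels: LabelSeries, speed_means: np.ndarray,
                        speed_noise: float,
                        seed: int | np.random.SeedSequence,
                        arena_radius_px: float = 320.0,
                        jitter_px: float = 1.0) -> PoseTrack:
    """Pose track whose center moves with per-motif mean speed.

    Heading performs a smooth random walk and reflects off the circular
    arena wall; satellite parts are rigid body-plan offsets rotated into the
    heading frame plus isotropic jitter. Per-frame step length is
    ``(speed + noise)/fps`` clipped at zero, so within-motif mean speed
    recovers ``speed_means`` closely.
    """
    rng = np.random.default_rng(seed)
    n = labels.n_frames
    fps = labels.fps
    speeds = np.asarray(speed_means, float)[labels.labels]
    steps = np.clip(speeds + rng.normal(0.0, speed_noise, n), 0.0, None) / fps
    turn = rng.normal(0.0, 0.25, n)  # rad/frame heading diffusion
    heading = np.empty(n)
    pos = np.empty((n, 2))
    h = rng.uniform(0, 2 * np.pi)
    p = rng.uniform(-0.3, 0.3, 2) * arena_radius_px
    limit = arena_radius_px - 80.0  # keep the body inside the wall
    for t in range(n):
        h += turn[t]
        q = p + steps[t] * np.array([np.cos(h), np.sin(h)])
        if q @ q > limit * limit:
            # reflect heading about the wall normal, keep step length
            nrm = p / np.hypot(*p)
            d = np.array([np.cos(h), np.sin(h)])
            d = d - 2 * (d @ nrm) * nrm
            h = float(np.arctan2(d[1], d[0]))
            q = p + steps[t] * d
        p = q
        heading[t] = h
        pos[t] = p
    # heading frame: rostral (+y of body plan) points along the heading
    c, s = np.cos(heading - np.pi / 2), np.sin(heading - np.pi / 2)
    rot = np.stack([np.stack([c, -s], axis=1),
                    np.stack([s, c], axis=1)], axis=1)  # (n, 2, 2)
    offsets = rot @ _BODY_OFFSETS.T  # (n, 2, n_parts)
    coords = pos[:, None, :] + np.transpose(offsets, (0, 2, 1))
    coords += rng.normal(0.0, jitter_px, coords.shape)
    ci = DEFAULT_PARTS.index("center")
    coords[:, ci, :] = pos  # center carries the exact trajectory
    like = np.clip(rng.beta(20, 1, (n, len(DEFAULT_PARTS))), 0.0, 1.0)
    return PoseTrack(labels.subject_id, fps, list(DEFAULT_PARTS), coords, like)


def _apply_effect(T: np.ndarray, speeds: np.ndarray,
                  effect: GroupEffect) -> tuple[np.ndarray, np.ndarray]:
    T = T.copy()
    for (i, j), f in effect.transition_scale.items():
        T[i, j] *= f
    for j, f in effect.column_scale.items():
        T[:, j] *= f
    if (T < 0).any():
        logger.warning("effect pushed probabilities below 0; clipping")
        T = np.clip(T, 0.0, None)
    T /= T.sum(axis=1, keepdims=True)
    speeds = speeds.copy()
    for m, f in effect.speed_scale.items():
        speeds[m] *= f
    return T, speeds


def default_spec(**overrides) -> GeneratorSpec:
    """Study-condition defaults with a genotype effect on dwell, usage and speed.

    The mutant effect doubles self-dwell of motifs 3-5 (one community),
    halves inflow to motif 9 and speeds up ambulatory motifs 24-29 by 25%;
    females carry a mild baseline usage shift toward motif 0. These mimic
    the kind of community-targeted genotype differences and sex baselines
    the analysis is designed to detect.
    """
    spec = GeneratorSpec(**overrides)
    if not spec.genotype_effects:
        spec.genotype_effects = {
            spec.genotypes[1]: GroupEffect(
                transition_scale={(i, i): 2.0 for i in (3, 4, 5)},
                column_scale={9: 0.5},
                speed_scale={m: 1.25 for m in range(24, 30)},
            )
        }
    if not spec.sex_effects:
        spec.sex_effects = {
            spec.sexes[0]: GroupEffect(column_scale={0: 1.3}),
        }
    return spec.resolve()


def generate_cohort(spec: GeneratorSpec) -> SyntheticCohort:
    """Generate one cohort (labels + poses + metadata + ground truth).

    A single master seed derives per-subject seeds via
    ``numpy.random.SeedSequence.spawn``, so subjects are independent but the
    whole cohort is reproducible bit-exactly.
    """
    spec.resolve()
    master = np.random.SeedSequence(spec.seed)
    n_frames = int(round(spec.session_minutes * 60 * spec.fps))
    rows, labels, poses = [], [], []
    true_matrices, true_usage, true_speeds = {}, {}, {}
    cells = [(g, s) for g in spec.genotypes for s in spec.sexes]
    children = master.spawn(len(cells) * spec.n_subjects * 2)
    idx = 0
    for g, s in cells:
        T, speeds = np.asarray(spec.baseline_transition), np.asarray(spec.speed_means)
        if g in spec.genotype_effects:
            T, speeds = _apply_effect(T, speeds, spec.genotype_effects[g])
        if s in spec.sex_effects:
            T, speeds = _apply_effect(T, speeds, spec.sex_effects[s])
        for k in range(spec.n_subjects):
            sid = f"{g}_{s}_{k:02d}"
            series = generate_label_sequence(
                T, n_frames, children[idx], fps=spec.fps,
                bin_frames=spec.bin_frames, subject_id=sid)
            track = generate_pose_track(
                series, speeds, spec.speed_noise, children[idx + 1],
                arena_radius_px=spec.arena_radius_px)
            idx += 2
            labels.append(series)
            poses.append(track)
            rows.append((sid, g, s, f"{g}/{s}", spec.session_minutes))
            true_matrices[sid] = T
            true_usage[sid] = 100.0 * stationary_distribution(T)
            true_speeds[sid] = speeds.copy()
    cohort = CohortTable(pd.DataFrame(
        rows, columns=["subject_id", "genotype", "sex", "group",
                       "session_minutes"]))
    return SyntheticCohort(cohort, labels, poses, true_matrices, true_usage,
                           true_speeds, spec)
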