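import numpy as np
import pytest

from motifkit.io_formats import ValidationError
from motifkit.synthetic import (DEFAULT_PARTS, GeneratorSpec, GroupEffect,
                                default_spec, generate_cohort,
                                generate_label_sequence, generate_pose_track,
                                make_block_transition_matrix,
                                stationary_distribution)


def test_block_matrix_exact_row():
    # 4 motifs, blocks {0,1} and {2,3}: row 0 = [p_self, p_within, rest/2, rest/2]
    T = make_block_transition_matrix(4, [[0, 1], [2, 3]],
                                     p_within=0.4, p_self=0.5)
    np.testing.assert_allclose(T[0], [0.5, 0.4, 0.05, 0.05])
    np.testing.assert_allclose(T.sum(axis=1), 1.0)


def test_block_matrix_validates_partition():
    with pytest.raises(ValidationError, match="partition"):
        make_block_transition_matrix(4, [[0, 1], [2]], 0.4, 0.5)
    with pytest.raises(ValidationError, match="p_self"):
        make_block_transition_matrix(4, [[0, 1], [2, 3]], 0.7, 0.5)


def test_block_matrix_singleton_warns():
    with pytest.warns(UserWarning, match="singleton"):
        T = make_block_transition_matrix(3, [[0], [1, 2]], 0.4, 0.5)
    np.testing.assert_allclose(T[0], [0.5, 0.25, 0.25])


def test_stationary_distribution_oracle():
    T = np.array([[0.9, 0.1], [0.3, 0.7]])
    # pi solves pi T = pi: pi = (0.75, 0.25)
    np.testing.assert_allclose(stationary_distribution(T), [0.75, 0.25])


def test_label_sequence_respects_chain_support():
    # deterministic cycle 0 -> 1 -> 2 -> 0 at the bin level
    T = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
    series = generate_label_sequence(T, n_frames=96, seed=5, start=0,
                                     bin_frames=16)
    bins = series.labels.reshape(-1, 16)
    assert (bins == bins[:, :1]).all()  # constant within bins
    np.testing.assert_array_equal(bins[:, 0], [0, 1, 2, 0, 1, 2])


def test_label_sequence_empirical_transitions(rng):
    T = np.array([[0.8, 0.2], [0.4, 0.6]])
    series = generate_label_sequence(T, n_frames=16 * 20000, seed=2)
    bins = series.labels[::16]
    counts = np.zeros((2, 2))
    np.add.at(counts, (bins[:-1], bins[1:]), 1)
    emp = counts / counts.sum(axis=1, keepdims=True)
    np.testing.assert_allclose(emp, T, atol=0.01)


def test_label_sequence_partial_final_bin():
    T = np.eye(2)
    series = generate_label_sequence(T, n_frames=20, seed=0, start=1)
    assert series.n_frames == 20
    assert (series.labels == 1).all()


def test_pose_track_shape_and_bounds():
    spec = default_spec(seed=3)
    series = generate_label_sequence(spec.baseline_transition, 2000, seed=3)
    track = generate_pose_track(series, spec.speed_means, spec.speed_noise,
                                seed=4, arena_radius_px=320.0)
    assert track.parts == DEFAULT_PARTS
    assert track.coords.shape == (2000, 9, 2)
    ci = DEFAULT_PARTS.index("center")
    radii = np.hypot(track.coords[:, ci, 0], track.coords[:, ci, 1])
    assert radii.max() <= 320.0
    assert np.isfinite(track.coords).all()


def test_pose_track_speed_recovers_motif_means():
    # single motif at 100 px/s: mean center speed should sit near 100
    T = np.array([[1.0]])
    series = generate_label_sequence(T, n_frames=20000, seed=7, start=0)
    track = generate_pose_track(series, np.array([100.0]), speed_noise=10.0,
                                seed=8)
    ci = DEFAULT_PARTS.index("center")
    xy = track.coords[:, ci, :]
    speed = np.hypot(*np.diff(xy, axis=0).T) * series.fps
    assert abs(speed.mean() - 100.0) < 5.0


def test_generate_cohort_structure(small_cohort):
    cohort = small_cohort
    assert len(cohort.cohort) == 8  # 2 per cell x 4 cells
    assert len(cohort.labels) == len(cohort.poses) == 8
    n_frames = int(10 * 60 * 25)
    for series in cohort.labels:
        assert series.n_frames == n_frames
    ids = cohort.cohort.subject_ids
    assert "WT_F_00" in ids and "MUT_M_01" in ids
    for sid in ids:
        assert cohort.true_matrices[sid].shape == (30, 30)
        np.testing.assert_allclose(cohort.true_usage[sid].sum(), 100.0)


def test_generate_cohort_reproducible():
    spec_a = default_spec(n_subjects=1, session_minutes=2.0, seed=42)
    spec_b = default_spec(n_subjects=1, session_minutes=2.0, seed=42)
    a, b = generate_cohort(spec_a), generate_cohort(spec_b)
    for sa, sb in zip(a.labels, b.labels):
        np.testing.assert_array_equal(sa.labels, sb.labels)
    for pa, pb in zip(a.poses, b.poses):
        np.testing.assert_array_equal(pa.coords, pb.coords)


def test_generate_cohort_seed_changes_data():
    a = generate_cohort(default_spec(n_subjects=1, session_minutes=2.0, seed=1))
    b = generate_cohort(default_spec(n_subjects=1, session_minutes=2.0, seed=2))
    assert any((sa.labels != sb.labels).any()
               for sa, sb in zip(a.labels, b.labels))


def test_genotype_effect_changes_truth(small_cohort):
    wt = small_cohort.true_matrices["WT_M_00"]
    mut = small_cohort.true_matrices["MUT_M_00"]
    # default effect doubles self-dwell of motifs 3-5 before renormalization
    assert mut[3, 3] > wt[3, 3]
    assert mut[:, 9].sum() < wt[:, 9].sum()  # inflow column 9 halved
    np.testing.assert_allclose(
        small_cohort.true_speeds["MUT_M_00"][24:30],
        1.25 * small_cohort.true_speeds["WT_M_00"][24:30])


def test_sex_effect_changes_truth(small_cohort):
    f = small_cohort.true_matrices["WT_F_00"]
    m = small_cohort.true_matrices["WT_M_00"]
    assert f[:, 0].sum() > m[:, 0].sum()


def test_custom_group_effect_transition_scale():
    spec = GeneratorSpec(
        n_motifs=4, community_blocks=[[0, 1], [2, 3]],
        genotype_effects={"MUT": GroupEffect(transition_scale={(0, 1): 2.0})},
        sex_effects={}, n_subjects=1, session_minutes=1.0, seed=0)
    out = generate_cohort(spec)
    wt = out.true_matrices["WT_F_00"]
    mut = out.true_matrices["MUT_F_00"]
    assert mut[0, 1] / mut[0, 0] == pytest.approx(2 * wt[0, 1] / wt[0, 0])
    np.testing.assert_allclose(mut.sum(axis=1), 1.0)


def test_truth_table_tidy(small_cohort):
    tt = small_cohort.truth_table()
    assert list(tt.columns) == ["subject_id", "motif", "usage_percent",
                                "speed_px_s"]
    assert len(tt) == 8 * 30
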