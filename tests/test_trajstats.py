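"""PCA, projections, cosine content, windowed correlations, clustering."""

import numpy as np
import pytest

from dimerflex.trajstats import (pca, project, generalized_dot,
                                 subspace_coverage, cosine_content,
                                 windowed_pearson, cluster_frames)
from dimerflex.synth import (make_mode_trajectory, make_correlated_series,
                             make_toy_dimer)
from dimerflex.structures import SelectionSpec


@pytest.fixture(scope="module")
def planted(toy):
    """Trajectory with two planted orthonormal directions, variance
    ratio 2:1, and 1% noise."""
    n = toy.structure.n_atoms
    rng = np.random.default_rng(0)
    # rigid-body motions are removed by the PCA alignment step, so the
    # planted directions must be internal: project them out first
    coords = toy.structure.coords(0)
    center = coords - coords.mean(axis=0)
    rigid = [np.tile(e, n) for e in np.eye(3)]
    for axis in np.eye(3):
        rigid.append(np.cross(center, axis).ravel())
    rigid = np.linalg.qr(np.column_stack(rigid))[0].T

    def internal(v):
        for r in rigid:
            v = v - (r @ v) * r
        return v / np.linalg.norm(v)

    d1 = internal(rng.standard_normal(3 * n))
    d2 = rng.standard_normal(3 * n)
    d2 = internal(d2 - (d1 @ d2) * d1)
    d2 -= (d1 @ d2) * d1
    d2 /= np.linalg.norm(d2)
    t = np.linspace(0, 1, 300)
    amps = np.column_stack([3 * np.sin(2 * np.pi * 3 * t),
                            np.sqrt(0.5) * 3 * np.cos(2 * np.pi * 5 * t)])
    frames = make_mode_trajectory(toy.structure, np.vstack([d1, d2]), amps,
                                  noise=0.005, seed=1)
    return frames, d1, d2, amps


def test_pca_recovers_planted_direction(planted):
    frames, d1, d2, _ = planted
    result = pca(frames)
    assert abs(result.eigenvectors[:, 0] @ d1) > 0.99
    assert abs(result.eigenvectors[:, 1] @ d2) > 0.99
    assert result.variance_fractions[0] > 0.6


def test_variance_fractions_sum_to_one_and_match_ratio(planted):
    frames, _, _, _ = planted
    result = pca(frames)
    assert result.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)
    # planted amplitude variance ratio 2:1
    f1, f2 = result.variance_fractions[:2]
    assert f1 / f2 == pytest.approx(2.0, rel=0.1)
    assert np.all(np.diff(result.eigenvalues) <= 1e-12)
    assert np.all(result.eigenvalues >= 0)


def test_projection_reconstruction_completeness(planted):
    """Projecting on all PCs and reconstructing recovers the centred
    coordinates."""
    frames, _, _, _ = planted
    result = pca(frames)
    from dimerflex.trajstats import _aligned_coords
    x = _aligned_coords(frames, result.align_indices,
                        result.analyze_indices)
    centered = x - result.mean
    coeffs = centered @ result.eigenvectors
    recon = coeffs @ result.eigenvectors.T
    assert np.abs(recon - centered).max() < 1e-6


def test_projection_basics(planted):
    frames, _, _, amps = planted
    result = pca(frames)
    proj = project(frames, result, 1)
    assert abs(np.corrcoef(proj, amps[:, 0])[0, 1]) > 0.999
    # mean structure projects to ~0
    assert abs(proj.mean()) < 1e-6
    # a trajectory mirrored through its time mean negates the projection
    all_coords = np.asarray(frames.stack.coord, dtype=float)
    mirrored = frames.with_coords(2 * all_coords.mean(axis=0)[None]
                                  - all_coords)
    proj_m = project(mirrored, result, 1)
    np.testing.assert_allclose(proj_m, -proj, atol=1e-3)


def test_pca_degenerate_inputs(toy):
    frames1 = toy.structure
    with pytest.raises(ValueError):
        pca(frames1)  # single frame
    same = toy.structure.with_coords(
        np.repeat(toy.structure.coords(0)[None], 3, axis=0))
    with pytest.raises(ValueError):
        pca(same)


def test_generalized_dot_and_coverage():
    v = np.array([1.0, 0.0])
    assert generalized_dot(v, v) == pytest.approx(1.0)
    assert generalized_dot(v, [0.0, 1.0]) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        generalized_dot(v, np.ones(3))
    # rotated 2D basis spans the same plane: sum of squared dots is 1
    theta = 0.77
    basis = np.array([[np.cos(theta), np.sin(theta)],
                      [-np.sin(theta), np.cos(theta)]])
    assert subspace_coverage(v, basis) == pytest.approx(1.0, abs=1e-12)


def test_cosine_content_closed_forms():
    t = np.linspace(0, 1, 800)
    assert cosine_content(np.cos(np.pi * t)) == pytest.approx(1.0,
                                                              abs=1e-6)
    assert cosine_content(np.sin(2 * np.pi * t), i=2) == \
        pytest.approx(0.0, abs=1e-3)
    # analytic value of the i=1 content of a full-period sine:
    # (4/3)^2 / (pi/2)^2 ~= 0.7205
    assert cosine_content(np.sin(2 * np.pi * t), i=1) == \
        pytest.approx(0.7205, abs=0.01)
    rng = np.random.default_rng(7)
    assert cosine_content(rng.standard_normal(1000)) < 0.2
    assert cosine_content(np.full(100, 3.3)) == 0.0
    with pytest.raises(ValueError):
        cosine_content(np.ones(3))


def test_cosine_content_bounded():
    rng = np.random.default_rng(5)
    for _ in range(20):
        series = rng.standard_normal(rng.integers(10, 200))
        c = cosine_content(series, i=int(rng.integers(1, 4)))
        assert 0.0 <= c <= 1.0 + 1e-12


def test_windowed_pearson_exact_cases():
    x = np.linspace(0, 1, 500) + np.sin(np.arange(500))
    cs = windowed_pearson(x, -x, window=100)
    np.testing.assert_allclose(cs.values, -1.0, atol=1e-12)
    cs_self = windowed_pearson(x, x, window=100)
    np.testing.assert_allclose(cs_self.values, 1.0, atol=1e-12)
    # antisymmetry under negating one series
    y = np.cos(np.arange(500) * 0.1)
    a = windowed_pearson(x, y, window=100).values
    b = windowed_pearson(x, -y, window=100).values
    np.testing.assert_allclose(a, -b, atol=1e-12)


def test_windowed_pearson_independent_noise():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(100_000)
    y = rng.standard_normal(100_000)
    cs = windowed_pearson(x, y, window=1000)
    assert abs(cs.mean) < 0.011


def test_windowed_pearson_recovers_rho():
    x, y = make_correlated_series(10_000, 0.8, seed=3)
    cs = windowed_pearson(x, y, window=1000)
    assert cs.overall == pytest.approx(0.8, abs=0.02)


def test_windowed_pearson_zero_variance_and_burn_in():
    x = np.concatenate([np.zeros(50), np.arange(50.0)])
    y = np.arange(100.0)
    cs = windowed_pearson(x, y, window=50, stride=50)
    assert np.isnan(cs.values[0])
    assert cs.values[1] == pytest.approx(1.0)
    cs_burn = windowed_pearson(x, y, window=50, burn_in=50)
    assert cs_burn.values[0] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        windowed_pearson(x, y, window=200)


def test_cluster_two_state_trajectory(toy):
    rng = np.random.default_rng(4)
    base = toy.structure.coords(0)
    frames = []
    labels = []
    for k in range(14):
        c = base.copy()
        if k % 2:  # interleave the two states
            c[-50:] += [6.0, 0, 0]
        labels.append(k % 2)
        frames.append(c + 0.05 * rng.standard_normal(c.shape))
    traj = toy.structure.with_coords(np.stack(frames))
    medoids, assign, dists = cluster_frames(traj, 2)
    # perfect two-state recovery up to label renaming
    assert len(set(zip(labels, assign))) == 2
    assert len(medoids) == 2


def test_cluster_edge_cases(toy):
    frames = toy.structure.with_coords(
        np.repeat(toy.structure.coords(0)[None], 5, axis=0))
    medoids, assign, dists = cluster_frames(frames, 1)
    assert list(assign) == [0] * 5
    assert len(medoids) == 1
    np.testing.assert_allclose(dists, 0.0, atol=1e-6)
    with pytest.raises(ValueError):
        cluster_frames(frames, 0)
    with pytest.raises(ValueError):
        cluster_frames(frames, 6)


def test_cluster_frame_order_invariance(toy):
    rng = np.random.default_rng(9)
    base = toy.structure.coords(0)
    coords = [base + 0.03 * rng.standard_normal(base.shape)
              for _ in range(6)]
    coords += [base + [5.0, 0, 0] + 0.03 * rng.standard_normal(base.shape)
               for _ in range(6)]
    order = rng.permutation(12)
    t1 = toy.structure.with_coords(np.stack(coords))
    t2 = toy.structure.with_coords(np.stack([coords[i] for i in order]))
    _, a1, _ = cluster_frames(t1, 2)
    _, a2, _ = cluster_frames(t2, 2)
    # same partition after undoing the permutation, up to renaming
    mapping = {}
    for i, orig in enumerate(order):
        assert mapping.setdefault(a2[i], a1[orig]) == a1[orig]
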