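"""Backbone PCA: planted-mode recovery, projection geometry, interpolation, contours."""

import numpy as np
import pytest
from matplotlib.path import Path as MplPath
from scipy.spatial.transform import Rotation

from gcensemble.ensemble_pca import (
    InsufficientDataError,
    ProjectionSet,
    density_contours,
    fit_pca,
    interpolate_along_pc,
    project,
)
from gcensemble.structure_io import Ensemble, select
from gcensemble.synthetic_data import (
    TwoStateSpec,
    _rigid_body_basis,
    generate_two_state,
    make_toy_heterodimer,
)


@pytest.fixture(scope="module")
def two_state_fit():
    sample = generate_two_state(
        TwoStateSpec(n_residues=10, separation=3.0, weight=0.5, sigma=0.3,
                     n_frames=800, seed=11)
    )
    model = fit_pca(sample.ensemble, sample.backbone_selection)
    return sample, model


def _planted_direction(toy, backbone, seed=3):
    rng = np.random.default_rng(seed)
    rigid = _rigid_body_basis(toy.coords[0][backbone.indices])
    v = rng.normal(size=3 * backbone.n_atoms)
    v -= rigid @ (rigid.T @ v)
    return v / np.linalg.norm(v)


def test_planted_one_dimensional_motion_is_pc1(toy):
    backbone = select(toy.topology, backbone=True)
    v = _planted_direction(toy, backbone)
    frames = np.repeat(toy.coords, 3, axis=0)
    for k, s in enumerate((-1.0, 0.0, 1.0)):
        frames[k, backbone.indices, :] += s * v.reshape(-1, 3)
    model = fit_pca(Ensemble(topology=toy.topology, coords=frames), backbone)
    assert model.variance_fractions[0] == pytest.approx(1.0, abs=1e-6)
    assert abs(model.eigenvectors[0] @ v) > 0.999


def test_spectrum_flat_for_pure_isotropic_noise():
    # 12 atoms, pure noise: no direction should dominate the nonzero spectrum
    rng = np.random.default_rng(0)
    base = make_toy_heterodimer(6, seed=0)
    sel = select(base.topology, atom_names=("CA",))  # 12 CA atoms
    n_frames = 5000
    frames = np.repeat(base.coords, n_frames, axis=0)
    frames += rng.normal(0.0, 0.1, size=frames.shape)
    model = fit_pca(Ensemble(topology=base.topology, coords=frames), sel)
    nonzero = model.variance_fractions[model.eigenvalues > 1e-8]
    assert nonzero.max() < 3.0 * nonzero.mean()


def test_variance_fractions_normalised_and_spectrum_ordered(two_state_fit):
    _, model = two_state_fit
    assert model.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(model.eigenvalues) <= 1e-12)
    assert np.all(model.eigenvalues >= 0)
    gram = model.eigenvectors @ model.eigenvectors.T
    assert np.abs(gram - np.eye(gram.shape[0])).max() < 1e-8


def test_planted_mode_recovery_two_state(two_state_fit):
    sample, model = two_state_fit
    assert abs(model.eigenvectors[0] @ sample.displacement) > 0.99
    assert model.variance_fractions[0] > 0.9


def test_rigid_body_motion_leaves_spectrum_unchanged(two_state_fit):
    sample, model = two_state_fit
    rot = Rotation.from_euler("xyz", [20, -35, 60], degrees=True).as_matrix()
    moved = sample.ensemble.coords @ rot.T + np.array([10.0, -4.0, 2.5])
    model2 = fit_pca(
        Ensemble(topology=sample.ensemble.topology, coords=moved),
        sample.backbone_selection,
    )
    assert np.abs(model.eigenvalues[:10] - model2.eigenvalues[:10]).max() < 1e-6


def test_projection_of_mean_is_origin(two_state_fit):
    _, model = two_state_fit
    points = project(model, model.mean).points
    assert np.abs(points).max() < 1e-8


def test_projection_basis_property(two_state_fit):
    _, model = two_state_fit
    for a in (1.0, -2.5):
        pts = project(model, model.mean + a * model.component(0)).points
        assert pts[0, 0] == pytest.approx(a, abs=1e-8)
        assert pts[0, 1] == pytest.approx(0.0, abs=1e-8)


def test_projection_reconstruction_consistency(two_state_fit):
    sample, model = two_state_fit
    frame = sample.ensemble.coords[3][sample.backbone_selection.indices]
    full = project(model, frame, n_components=model.n_components).points[0]
    recon = model.mean.ravel() + full @ model.eigenvectors
    # reconstruction reproduces the superposed frame
    from gcensemble.superpose import kabsch_fit

    fit = kabsch_fit(frame, model.mean)
    superposed = fit.transform(frame)
    assert np.abs(recon.reshape(-1, 3) - superposed).max() < 1e-6


def test_projection_separates_planted_clusters(toy):
    backbone = select(toy.topology, backbone=True)
    v = _planted_direction(toy, backbone, seed=9)
    rng = np.random.default_rng(21)
    n = 400
    labels = rng.random(n) < 0.5
    frames = np.repeat(toy.coords, n, axis=0)
    frames += rng.normal(0.0, 0.05, size=frames.shape)
    frames[:, backbone.indices, :] += np.where(labels, 5.0, -5.0)[
        :, None, None
    ] * v.reshape(-1, 3)
    ens = Ensemble(topology=toy.topology, coords=frames)
    model = fit_pca(ens, backbone)
    pts = project(model, frames[:, backbone.indices, :]).points[:, 0]
    sign = np.sign(np.corrcoef(pts, labels.astype(float))[0, 1])
    up, down = pts[labels].mean() * sign, pts[~labels].mean() * sign
    assert up == pytest.approx(5.0, abs=0.2)
    assert down == pytest.approx(-5.0, abs=0.2)


def test_fit_requires_two_frames(toy):
    backbone = select(toy.topology, backbone=True)
    with pytest.raises(Exception):
        fit_pca(toy, backbone)


def test_interpolation_amplitude_zero_is_mean(two_state_fit):
    _, model = two_state_fit
    ens = interpolate_along_pc(model, 0, [0.0])
    assert np.abs(ens.coords[0] - model.mean).max() == 0.0


def test_interpolation_symmetric_and_projection_consistent(two_state_fit, tmp_path):
    _, model = two_state_fit
    a = 4.0
    ens = interpolate_along_pc(model, 0, [-a, a])
    assert np.abs(ens.coords.mean(axis=0) - model.mean).max() < 1e-10
    pts = project(model, ens.coords[1]).points
    assert pts[0, 0] == pytest.approx(a, abs=1e-8)
    # interpolated extremes are writable as PDB
    from gcensemble.structure_io import read_pdb_models, write_frames_pdb

    path = tmp_path / "extremes.pdb"
    write_frames_pdb(ens, path)
    assert read_pdb_models(path).n_frames == 2


def test_density_contours_enclose_requested_mass(rng):
    pts = rng.normal(size=(1000, 2))
    contours = density_contours(ProjectionSet("g", pts), levels=[0.5, 0.99])
    for level, polylines in contours.items():
        assert polylines, f"no contour extracted at level {level}"
        inside = np.zeros(len(pts), dtype=bool)
        for line in polylines:
            if len(line) > 2:
                inside |= MplPath(line).contains_points(pts)
        fraction = inside.mean()
        if level == 0.99:
            assert fraction >= 0.95
        else:
            assert 0.3 <= fraction <= 0.7
        # cluster mean is inside some contour
        assert any(
            MplPath(line).contains_points([[0.0, 0.0]])[0]
            for line in polylines
            if len(line) > 2
        )


def test_density_contours_need_enough_points(rng):
    with pytest.raises(InsufficientDataError):
        density_contours(ProjectionSet("few", rng.normal(size=(10, 2))))
    with pytest.raises(Exception):
        density_contours(ProjectionSet("empty", np.empty((0, 2))))
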