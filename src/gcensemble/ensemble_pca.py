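"""Principal component analysis of backbone coordinates over ensembles.

The covariance matrix of superposed backbone coordinates characterises
correlated internal motions; its eigenvectors are the principal
components (PCs) and the structural variance along each PC is the
corresponding eigenvalue.  Frames are superposed iteratively onto the
evolving mean conformation (reference-free), which removes the six
rigid-body degrees of freedom from the covariance.  The fitted model can
project external structures — e.g. an inactive crystal structure or an
active-state model — into the PC1-PC2 subspace, and generate
interpolated extreme structures along a chosen PC for visualisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gcensemble.structure_io import (
    Ensemble,
    Selection,
    StructureError,
    Topology,
    match_selections,
)
from gcensemble.superpose import FitError, kabsch_fit

__all__ = [
    "PcaModel",
    "ProjectionSet",
    "fit_pca",
    "project",
    "interpolate_along_pc",
    "density_contours",
]


class InsufficientDataError(ValueError):
    """Not enough frames or points for the requested estimate."""


@dataclass(frozen=True)
class PcaModel:
    """PCA of pooled, superposed selection coordinates.

    ``mean`` is the converged mean conformation (``(n_sel, 3)`` A);
    ``eigenvectors`` has one orthonormal row per component (length
    ``3 * n_sel``); ``eigenvalues`` (A^2) are non-increasing and their
    normalisation gives ``variance_fractions``.
    """

    mean: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    selection_description: str
    topology: Topology
    selection: Selection

    @property
    def n_components(self) -> int:
        return int(self.eigenvalues.size)

    def component(self, i: int) -> np.ndarray:
        """Eigenvector ``i`` reshaped to per-atom displacements (n_sel, 3)."""
        return self.eigenvectors[i].reshape(-1, 3)


@dataclass(frozen=True)
class ProjectionSet:
    """Coordinates of conformations in a PC subspace (A units)."""

    label: str
    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        object.__setattr__(self, "points", pts)


def _superpose_to(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Fit each (n, 3) conformation in ``coords`` onto ``reference``."""
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        fit = kabsch_fit(coords[f], reference)
        out[f] = fit.transform(coords[f])
    return out


def fit_pca(
    ensembles: Ensemble | list[Ensemble],
    selection: Selection,
    frame_windows: list[tuple[int, int] | None] | None = None,
    mean_tol: float = 1e-6,
    max_iter: int = 100,
) -> PcaModel:
    """Fit a pooled PCA over one or more ensembles.

    All ensembles are matched to the first one's topology on ``selection``
    (by chain / residue number / atom name), their windowed frames pooled,
    and the pool superposed iteratively onto the evolving mean until the
    mean shifts by less than ``mean_tol`` (RMS, A).  The covariance of the
    superposed coordinates is then diagonalised.  Component signs are
    fixed so each eigenvector's largest-magnitude loading is positive,
    making projections reproducible across runs.

    ``frame_windows`` restricts each ensemble to ``[start, stop)`` frames
    (``None`` keeps all), mirroring the use of only the equilibrated tail
    of a production trajectory.
    """
    if isinstance(ensembles, Ensemble):
        ensembles = [ensembles]
    if frame_windows is None:
        frame_windows = [None] * len(ensembles)
    if len(frame_windows) != len(ensembles):
        raise ValueError("one frame window per ensemble required")

    first = ensembles[0]
    blocks = []
    for ens, window in zip(ensembles, frame_windows):
        sub = ens.subset(window)
        if ens is first:
            idx = selection.indices
        else:
            own = Selection(selection.description, selection.indices)
            idx_first, idx = match_selections(first.topology, ens.topology, own, _full_selection(ens.topology))
            if len(idx_first) != selection.n_atoms:
                raise StructureError("selection does not fully match across ensembles")
        blocks.append(sub.coords[:, idx, :])
    coords = np.concatenate(blocks, axis=0)
    n_frames, n_sel = coords.shape[0], coords.shape[1]
    if n_frames < 2:
        raise FitError("PCA needs at least 2 frames in total")

    # iterative reference-free superposition onto the evolving mean
    mean = coords[0] - coords[0].mean(axis=0)
    superposed = coords
    for _ in range(max_iter):
        superposed = _superpose_to(superposed, mean)
        new_mean = superposed.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < mean_tol:
            break
    superposed = _superpose_to(superposed, mean)
    mean = superposed.mean(axis=0)

    deviations = (superposed - mean).reshape(n_frames, 3 * n_sel)
    cov = deviations.T @ deviations / n_frames
    eigenvalues, eigenvectors = np.linalg.eigh(cov)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = np.clip(eigenvalues[order], 0.0, None)
    eigenvectors = eigenvectors[:, order].T
    # sign convention: largest-magnitude loading positive
    for i in range(eigenvectors.shape[0]):
        j = int(np.argmax(np.abs(eigenvectors[i])))
        if eigenvectors[i, j] < 0:
            eigenvectors[i] = -eigenvectors[i]
    total = eigenvalues.sum()
    fractions = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    return PcaModel(
        mean=mean,
        eigenvectors=eigenvectors,
        eigenvalues=eigenvalues,
        variance_fractions=fractions,
        selection_description=selection.description,
        topology=first.topology,
        selection=selection,
    )


def _full_selection(topology: Topology) -> Selection:
    return Selection("all", np.arange(topology.n_atoms))


def project(
    model: PcaModel,
    coords: np.ndarray,
    n_components: int = 2,
    label: str = "",
) -> ProjectionSet:
    """Project conformations into the model's PC subspace.

    ``coords`` is ``(n_sel, 3)`` or ``(n_frames, n_sel, 3)`` on the model
    selection.  Each conformation is superposed onto the model mean before
    the inner products are taken, so the model mean itself projects to the
    origin.
    """
    if n_components > model.n_components:
        raise ValueError(
            f"requested {n_components} components, model stores {model.n_components}"
        )
    coords = np.asarray(coords, dtype=float)
    single = coords.ndim == 2
    if single:
        coords = coords[None]
    if coords.shape[1:] != model.mean.shape:
        raise StructureError("coordinates do not match the model selection")
    superposed = _superpose_to(coords, model.mean)
    deviations = (superposed - model.mean).reshape(coords.shape[0], -1)
    points = deviations @ model.eigenvectors[:n_components].T
    return ProjectionSet(label=label, points=points)


def project_ensemble(
    model: PcaModel,
    ensemble: Ensemble,
    frame_window: tuple[int, int] | None = None,
    n_components: int = 2,
) -> ProjectionSet:
    """Project an ensemble's (windowed) frames, matching atoms by identity."""
    sub = ensemble.subset(frame_window)
    own = Selection(model.selection.description, model.selection.indices)
    idx_model, idx_ens = match_selections(
        model.topology, ensemble.topology, own, _full_selection(ensemble.topology)
    )
    if len(idx_model) != model.selection.n_atoms:
        raise StructureError("ensemble does not carry the full model selection")
    return project(
        model, sub.coords[:, idx_ens, :], n_components=n_components, label=ensemble.label
    )


def interpolate_along_pc(
    model: PcaModel,
    pc_index: int,
    amplitudes: list[float],
) -> Ensemble:
    """Structures ``mean + amplitude * PC`` for each amplitude.

    Amplitudes are in A on the PC axis (the same scale as projections),
    e.g. the extreme values observed in the projected ensembles.  The
    result is an ensemble on the selection's atoms, writable as PDB.
    """
    if not 0 <= pc_index < model.n_components:
        raise ValueError(f"pc_index {pc_index} outside stored components")
    direction = model.component(pc_index)
    frames = np.stack([model.mean + a * direction for a in amplitudes])
    top = model.topology
    idx = model.selection.indices
    sub_top = Topology(
        chain_ids=top.chain_ids[idx],
        res_ids=top.res_ids[idx],
        res_names=top.res_names[idx],
        atom_names=top.atom_names[idx],
        elements=top.elements[idx],
        occupancies=top.occupancies[idx],
        altlocs=top.altlocs[idx],
    )
    return Ensemble(topology=sub_top, coords=frames, label=f"pc{pc_index + 1}_interpolation")


def density_contours(
    projections: ProjectionSet,
    levels: list[float] = (0.5, 0.9),
    grid_size: int = 128,
) -> dict[float, list[np.ndarray]]:
    """Probability-density contours of 2-D projections.

    A Gaussian kernel-density estimate (Scott bandwidth) is evaluated on a
    grid; for each requested probability level the iso-density line that
    encloses at least that fraction of the sample points is extracted.
    Returns ``{level: [polyline (k, 2), ...]}``.
    """
    from contourpy import contour_generator
    from scipy.stats import gaussian_kde

    points = projections.points
    if points.shape[0] < 50:
        raise InsufficientDataError("need at least 50 points for density contours")
    if points.shape[1] != 2:
        raise ValueError("density contours are defined for 2-D projections")
    kde = gaussian_kde(points.T)
    sample_density = kde(points.T)

    pad = 0.1 * (points.max(axis=0) - points.min(axis=0) + 1e-9)
    lo, hi = points.min(axis=0) - pad, points.max(axis=0) + pad
    xs = np.linspace(lo[0], hi[0], grid_size)
    ys = np.linspace(lo[1], hi[1], grid_size)
    xx, yy = np.meshgrid(xs, ys)
    zz = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    gen = contour_generator(xx, yy, zz)

    out: dict[float, list[np.ndarray]] = {}
    for level in levels:
        if not 0 < level < 1:
            raise ValueError("probability levels must lie in (0, 1)")
        # iso-density threshold: the (1 - level) quantile of point densities,
        # so a fraction `level` of the sample sits at or above it
        threshold = float(np.quantile(sample_density, 1.0 - level))
        polylines = [np.asarray(line) for line in gen.lines(threshold)]
        out[level] = polylines
    return out
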