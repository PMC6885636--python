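"""Synthetic ensembles and assay tables with planted ground truth.

Microsecond explicit-solvent trajectories of the sGC catalytic domain
are far too expensive to regenerate, and none are deposited; every
pipeline stage is therefore exercised on toy systems whose answer is
known by construction:

* a two-chain polyalanine-like helical heterodimer
  (:func:`make_toy_heterodimer`),
* a two-state conformational mixture along a planted collective
  displacement vector plus isotropic Gaussian noise
  (:func:`generate_two_state`) — PCA must recover the planted direction,
* residue pairs whose contacts flicker as independent Bernoulli streams
  with condition-specific probabilities
  (:func:`generate_contact_flicker`) — contact probabilities and df must
  recover the planted rates,
* a transcription of the published wild-type/mutant assay summary table
  (:func:`write_fixture_assay_table`) for the statistics stage.

All generators are pure functions of their spec including the seed.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np

from gcensemble.contact_analysis import (
    ContactParams,
    ContactProbabilityMap,
    PairKey,
    ResidueKey,
)
from gcensemble.structure_io import Ensemble, Selection, Topology, select

__all__ = [
    "TwoStateSpec",
    "TwoStateSample",
    "ContactFlickerSpec",
    "ContactFlickerSample",
    "make_toy_heterodimer",
    "generate_two_state",
    "generate_contact_flicker",
    "flicker_probability_maps",
    "write_fixture_assay_table",
    "TABLE1_WILDTYPE_LABEL",
]

# contact / no-contact template distances bracket the 4.5 A cutoff with a
# wide safety margin on either side
CONTACT_DISTANCE = 3.8
NO_CONTACT_DISTANCE = 6.5

_RESIDUE_ATOMS = ("N", "CA", "C", "O", "CB")


# ---------------------------------------------------------------------------
# toy heterodimer
# ---------------------------------------------------------------------------


def make_toy_heterodimer(n_residues: int = 10, seed: int = 0) -> Ensemble:
    """A two-chain helical polyalanine-like structure (one frame).

    Each residue carries backbone atoms N, CA, C, O and one side-chain
    heavy atom (CB); chains A and B are parallel helices offset in space.
    Bonded neighbour distances all fall in 1.2-1.8 A; coordinates are a
    deterministic function of ``(n_residues, seed)``.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues per chain")
    rng = np.random.default_rng(seed)

    # gentle spiral with a 4.28 A CA-CA chord, leaving room for a ~1.5 A
    # peptide C-N link between consecutive residues
    rise, radius, turn = 4.2, 2.4, np.deg2rad(20.0)

    def chain_coords(offset: np.ndarray) -> np.ndarray:
        idx = np.arange(n_residues + 1)
        ca = np.stack(
            [
                radius * np.cos(turn * idx),
                radius * np.sin(turn * idx),
                rise * idx,
            ],
            axis=1,
        ) + offset
        atoms = []
        for i in range(n_residues):
            v = ca[i + 1] - ca[i]
            d = np.linalg.norm(v)
            v = v / d
            radial = ca[i] - offset
            radial = radial - radial[2] * np.array([0.0, 0.0, 1.0])
            radial /= np.linalg.norm(radial)
            perp = np.cross(v, radial)
            perp /= np.linalg.norm(perp)
            h = 0.5
            a = np.sqrt(1.52**2 - h**2)   # CA->C along the chord
            b = np.sqrt(1.45**2 - h**2)   # N->CA along the chord
            n_atom = ca[i] - b * v + h * perp
            c_atom = ca[i] + a * v + h * perp
            o_atom = c_atom + 1.23 * radial
            cb_atom = ca[i] - 1.53 * radial
            atoms += [n_atom, ca[i], c_atom, o_atom, cb_atom]
        return np.asarray(atoms)

    coords = np.concatenate(
        [
            chain_coords(np.array([0.0, 0.0, 0.0])),
            chain_coords(np.array([14.0, 0.0, 0.0])),
        ]
    )
    # break exact degeneracies without perturbing bond geometry noticeably
    coords = coords + rng.normal(0.0, 0.002, size=coords.shape)

    n_atoms_chain = n_residues * len(_RESIDUE_ATOMS)
    chain_ids = np.array(["A"] * n_atoms_chain + ["B"] * n_atoms_chain, dtype="U4")
    res_ids = np.concatenate(
        [np.repeat(np.arange(1, n_residues + 1), len(_RESIDUE_ATOMS))] * 2
    )
    atom_names = np.array(list(_RESIDUE_ATOMS) * (2 * n_residues), dtype="U6")
    elements = np.array(
        [name[0] for name in _RESIDUE_ATOMS] * (2 * n_residues), dtype="U4"
    )
    topology = Topology(
        chain_ids=chain_ids,
        res_ids=res_ids.astype(int),
        res_names=np.array(["ALA"] * 2 * n_atoms_chain, dtype="U4")[: 2 * n_atoms_chain],
        atom_names=atom_names,
        elements=elements,
        occupancies=np.ones(2 * n_atoms_chain),
        altlocs=np.array([""] * 2 * n_atoms_chain, dtype="U1"),
    )
    return Ensemble(topology=topology, coords=coords[None], label="toy_heterodimer")


# ---------------------------------------------------------------------------
# two-state conformational mixture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoStateSpec:
    """Conditions for the two-state conformational generator.

    ``separation`` and ``sigma`` are both per-atom RMS displacements in A
    (the same scale an RMSD is quoted on), so their ratio is the per-atom
    signal-to-noise of the planted transition: ``separation`` is the RMS
    atomic displacement between state A and state B along the planted
    collective direction, and ``sigma`` the RMS atomic displacement of
    the isotropic Gaussian noise.  ``weight`` is the fraction of frames
    in state B.
    """

    n_residues: int = 10
    separation: float = 3.0
    weight: float = 0.5
    sigma: float = 0.3
    n_frames: int = 1000
    seed: int = 0
    label: str = "two_state"
    #: seed of the base structure and planted direction; conditions meant to
    #: share one collective mode set the same base_seed with different seeds
    base_seed: int | None = None

    def __post_init__(self) -> None:
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if not 0 <= self.weight <= 1:
            raise ValueError("weight must lie in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class TwoStateSample:
    """Generated ensemble plus its ground truth."""

    ensemble: Ensemble
    state_labels: np.ndarray           # True where the frame is in state B
    displacement: np.ndarray           # planted unit direction, (3 * n_backbone,)
    backbone_selection: Selection
    spec: TwoStateSpec


def _rigid_body_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the 6 rigid-body modes of an (n, 3) structure."""
    n = coords.shape[0]
    centered = coords - coords.mean(axis=0)
    modes = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = 1.0
        modes.append(t.ravel())
    for k in range(3):
        axis = np.zeros(3)
        axis[k] = 1.0
        modes.append(np.cross(np.broadcast_to(axis, (n, 3)), centered).ravel())
    basis, _ = np.linalg.qr(np.stack(modes, axis=1))
    return basis


def generate_two_state(spec: TwoStateSpec) -> TwoStateSample:
    """Frames ``base + b_f * separation * v + noise`` with Bernoulli state draws.

    The planted unit direction ``v`` lives on the backbone atoms and is
    constructed orthogonal to the structure's rigid-body subspace, so
    superposition cannot absorb the planted motion.  The state-B offset
    is scaled so the RMS atomic displacement between the two state
    centres equals ``separation`` (v itself is reported with unit norm in
    the 3N space); noise is isotropic with per-coordinate standard
    deviation ``sigma / sqrt(3)``, i.e. per-atom RMS displacement
    ``sigma``.  Side-chain atoms see only noise.
    """
    base_seed = spec.seed if spec.base_seed is None else spec.base_seed
    base = make_toy_heterodimer(spec.n_residues, seed=base_seed)
    backbone = select(base.topology, backbone=True)
    structure_rng = np.random.default_rng(np.random.SeedSequence([base_seed, 2]))
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 5]))

    bb_coords = base.coords[0][backbone.indices]
    rigid = _rigid_body_basis(bb_coords)
    v = structure_rng.normal(size=3 * backbone.n_atoms)
    v -= rigid @ (rigid.T @ v)
    v /= np.linalg.norm(v)
    amplitude = spec.separation * np.sqrt(backbone.n_atoms)

    states = rng.random(spec.n_frames) < spec.weight
    noise = rng.normal(
        0.0, spec.sigma / np.sqrt(3.0), size=(spec.n_frames, base.n_atoms, 3)
    )
    frames = np.repeat(base.coords, spec.n_frames, axis=0) + noise
    frames[:, backbone.indices, :] += (
        states[:, None, None] * amplitude * v.reshape(-1, 3)
    )
    ensemble = Ensemble(topology=base.topology, coords=frames, label=spec.label)
    return TwoStateSample(
        ensemble=ensemble,
        state_labels=states,
        displacement=v,
        backbone_selection=backbone,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# contact flicker
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContactFlickerSpec:
    """Conditions for the Bernoulli contact-flicker generator.

    ``pair_probabilities`` maps condition label -> {residue pair: contact
    probability}; every condition must list the same pairs.  Each listed
    pair is realised geometrically by placing the partner residue at
    :data:`CONTACT_DISTANCE` (in-contact frames) or
    :data:`NO_CONTACT_DISTANCE` (out-of-contact frames) from its mate —
    both safely on either side of the 4.5 A cutoff.
    """

    pair_probabilities: dict[str, dict[PairKey, float]]
    n_frames: int = 500
    n_residues: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pair_probabilities:
            raise ValueError("at least one condition is required")
        universes = [tuple(sorted(p)) for p in self.pair_probabilities.values()]
        if len(set(universes)) != 1:
            raise ValueError("all conditions must list the same pairs")
        for probs in self.pair_probabilities.values():
            for pair, p in probs.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"probability {p} for {pair} outside [0, 1]")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")

    def pairs(self) -> list[PairKey]:
        first = next(iter(self.pair_probabilities.values()))
        return sorted(first)


@dataclass(frozen=True)
class ContactFlickerSample:
    """Generated per-condition ensembles plus the planted probabilities."""

    ensembles: dict[str, Ensemble]
    true_probabilities: dict[str, dict[PairKey, float]]
    params: ContactParams
    spec: ContactFlickerSpec


def _flicker_topology(n_residues: int) -> Topology:
    """Sparse two-chain scaffold: 2 heavy atoms per residue on a wide grid.

    This is a statistical scaffold for contact counting, not a bonded
    polymer — residues are spaced 20 A apart so only planted pairs can
    ever touch.
    """
    n_atoms = 2 * n_residues * 2
    chain_ids, res_ids, atom_names = [], [], []
    for chain in ("A", "B"):
        for r in range(1, n_residues + 1):
            chain_ids += [chain, chain]
            res_ids += [r, r]
            atom_names += ["CA", "CB"]
    return Topology(
        chain_ids=np.array(chain_ids, dtype="U4"),
        res_ids=np.array(res_ids, dtype=int),
        res_names=np.array(["ALA"] * n_atoms, dtype="U4"),
        atom_names=np.array(atom_names, dtype="U6"),
        elements=np.array(["C"] * n_atoms, dtype="U4"),
        occupancies=np.ones(n_atoms),
        altlocs=np.array([""] * n_atoms, dtype="U1"),
    )


def _anchor(chain: str, resid: int) -> np.ndarray:
    y = 0.0 if chain == "A" else 200.0
    return np.array([20.0 * resid, y, 0.0])


def generate_contact_flicker(spec: ContactFlickerSpec) -> ContactFlickerSample:
    """Geometric realisation of independent Bernoulli contact streams.

    For each listed pair the second residue is moved, frame by frame, to
    the contact or no-contact template distance from the first according
    to its Bernoulli draw.  A residue may appear in at most one listed
    pair (otherwise its position would be over-constrained and a
    construction error is raised).  Unlisted pairs never come anywhere
    near the cutoff.
    """
    pairs = spec.pairs()
    used: set[ResidueKey] = set()
    for a, b in pairs:
        if a in used or b in used:
            raise ValueError(
                "geometric conflict: a residue appears in more than one planted pair"
            )
        used.update((a, b))
    max_resid = max((r for pair in pairs for _, r in pair), default=0)
    n_residues = max(spec.n_residues, max_resid)
    topology = _flicker_topology(n_residues)
    keys = topology.residue_keys()
    atom_slot = {key: 2 * i for i, key in enumerate(keys)}
    cb_offset = np.array([0.0, 0.0, 1.5])

    base = np.empty((topology.n_atoms, 3))
    for key in keys:
        i = atom_slot[key]
        base[i] = _anchor(*key)
        base[i + 1] = _anchor(*key) + cb_offset

    ensembles: dict[str, Ensemble] = {}
    for ci, (condition, probs) in enumerate(sorted(spec.pair_probabilities.items())):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3, ci]))
        frames = np.repeat(base[None], spec.n_frames, axis=0)
        for pair in pairs:
            a, b = pair
            draws = rng.random(spec.n_frames) < probs[pair]
            distance = np.where(draws, CONTACT_DISTANCE, NO_CONTACT_DISTANCE)
            slot = atom_slot[b]
            position = _anchor(*a) + np.array([0.0, 1.0, 0.0]) * distance[:, None]
            frames[:, slot, :] = position
            frames[:, slot + 1, :] = position + cb_offset
        ensembles[condition] = Ensemble(
            topology=topology, coords=frames, label=condition
        )
    return ContactFlickerSample(
        ensembles=ensembles,
        true_probabilities={c: dict(p) for c, p in spec.pair_probabilities.items()},
        params=ContactParams(),
        spec=spec,
    )


def flicker_probability_maps(spec: ContactFlickerSpec) -> dict[str, ContactProbabilityMap]:
    """Contact probability maps sampled directly from the Bernoulli streams.

    Statistically identical to running :func:`generate_contact_flicker`
    through the geometric contact pipeline (same substream draws), but
    without building coordinates — used for large replicate studies of
    df recovery.
    """
    pairs = spec.pairs()
    max_resid = max((r for pair in pairs for _, r in pair), default=0)
    n_residues = max(spec.n_residues, max_resid)
    residues = tuple(
        (chain, r) for chain in ("A", "B") for r in range(1, n_residues + 1)
    )
    out: dict[str, ContactProbabilityMap] = {}
    for ci, (condition, probs) in enumerate(sorted(spec.pair_probabilities.items())):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3, ci]))
        counts: dict[PairKey, int] = {}
        for pair in pairs:
            draws = rng.random(spec.n_frames) < probs[pair]
            counts[pair] = int(draws.sum())
        out[condition] = ContactProbabilityMap(
            label=condition,
            counts=counts,
            n_frames=spec.n_frames,
            params=ContactParams(),
            residues=residues,
        )
    return out


# ---------------------------------------------------------------------------
# assay-table fixture
# ---------------------------------------------------------------------------

TABLE1_WILDTYPE_LABEL = "WT"

# transcription of the published wild-type / mutant summary table:
# (variant, measure, mean, sem); luciferase in RLU/mg protein, cGMP and
# cAMP in pmol/mg protein x 10^3; n is reported only as "three or more".
_TABLE1_ROWS: list[tuple[str, str, float, float]] = [
    ("WT", "luciferase", 274, 86),
    ("aV587I/aV589T", "luciferase", 1220, 229),
    ("aV587I/aV589T/aK590R", "luciferase", 667, 165),
    ("aM591N", "luciferase", 1264, 206),
    ("bI533M", "luciferase", 1298, 245),
    ("bM537N", "luciferase", 738, 132),
    ("bP538Q", "luciferase", 1244, 331),
    ("aV587I/aV589T/aK590R/bM537N", "luciferase", 1062, 72),
    ("ab-flap-deletions", "luciferase", 1688, 101),
    ("aM591N/bM537N", "luciferase", 2623, 496),
    ("aC595S", "luciferase", 579, 135),
    ("aC595S/bT474V", "luciferase", 2668, 463),
    ("bT474V", "luciferase", 1250, 311),
    ("bT474M", "luciferase", 1726, 381),
    ("aC595S/aE526A", "luciferase", 3366, 1315),
    ("aC595Y", "luciferase", 677, 5),
    ("aC595S/bM537N", "luciferase", 965, 246),
    ("aC595S/bM537N/bP538Q", "luciferase", 1925, 241),
    ("aC595S/bP538Q", "luciferase", 439, 124),
    ("bC541G", "luciferase", 1802, 374),
    ("bC541G/aC595S", "luciferase", 2060, 190),
    ("bC541G/aC595S/bM537N", "luciferase", 1958, 344),
    ("bC541G/aC595S/bM537N/bP538Q", "luciferase", 297, 70),
    ("WT", "cgmp", 1.9, 0.5),
    ("aV587I/aV589T", "cgmp", 3.8, 0.9),
    ("aV587I/aV589T/aK590R", "cgmp", 3.7, 1.1),
    ("aM591N", "cgmp", 3.7, 0.5),
    ("bI533M", "cgmp", 2.9, 1.4),
    ("bM537N", "cgmp", 4.2, 0.9),
    ("bP538Q", "cgmp", 2.7, 0.8),
    ("aV587I/aV589T/aK590R/bM537N", "cgmp", 3.5, 2.0),
    ("ab-flap-deletions", "cgmp", 3.2, 0.8),
    ("aM591N/bM537N", "cgmp", 4.5, 1.2),
    ("aC595S", "cgmp", 12.2, 2.0),
    ("aC595S/bT474V", "cgmp", 6.4, 1.3),
    ("bT474V", "cgmp", 3.9, 1.4),
    ("bT474M", "cgmp", 4.4, 0.5),
    ("aC595S/aE526A", "cgmp", 9.4, 1.5),
    ("aC595Y", "cgmp", 0.5, 0.3),
    ("aC595S/bM537N", "cgmp", 19.5, 4.1),
    ("aC595S/bM537N/bP538Q", "cgmp", 9.2, 2.3),
    ("aC595S/bP538Q", "cgmp", 2.0, 0.8),
    ("bC541G", "cgmp", 4.1, 1.2),
    ("bC541G/aC595S", "cgmp", 24.8, 1.4),
    ("aC595S/bM537N/bN548W", "cgmp", 1.5, 0.3),
    ("bC541G/aC595S/bM537N", "cgmp", 28.6, 4.6),
    ("bC541G/aC595S/bM537N/bP538Q", "cgmp", 10.0, 1.7),
    ("WT", "camp", 0.6, 0.1),
    ("aC595Y", "camp", 1.3, 0.4),
    ("bC541G", "camp", 4.5, 1.3),
    ("bC541G/aC595S", "camp", 3.7, 1.5),
    ("bC541G/aC595S/bM537N", "camp", 3.1, 0.8),
    ("bC541G/aC595S/bM537N/bP538Q", "camp", 1.8, 0.4),
]


def fixture_assay_rows() -> list[dict]:
    """The assay summary table as records (n defaults to 3 replicates)."""
    return [
        {"variant": v, "measure": m, "mean": mean, "sem": sem, "n": 3}
        for v, m, mean, sem in _TABLE1_ROWS
    ]


def write_fixture_assay_table(path) -> None:
    """Write the transcribed assay summary table as a CSV fixture.

    Byte-identical on every call (LF line endings, '.' decimals).
    """
    buffer = io.StringIO()
    writer = csv.writer(buffer, lineterminator="\n")
    writer.writerow(["variant", "measure", "mean", "sem", "n"])
    for v, m, mean, sem in _TABLE1_ROWS:
        writer.writerow([v, m, mean, sem, 3])
    with open(path, "w", newline="") as handle:
        handle.write(buffer.getvalue())
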