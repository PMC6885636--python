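"""Reading, writing and selecting atoms from multi-model PDB ensembles.

A conformational ensemble is stored as a :class:`Topology` (atom identity,
shared by all frames) plus a stack of coordinate frames
(:class:`Ensemble`).  One MODEL in a multi-model PDB file maps to one
frame.  Parsing is delegated to :mod:`biotite`; this module adds the
identity checks across models, a deterministic alternate-location policy
and the atom-selection layer every downstream stage relies on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io import pdb as pdbio

__all__ = [
    "BACKBONE_ATOMS",
    "BACKBONE_ATOMS_NO_O",
    "StructureError",
    "ParseError",
    "TopologyMismatchError",
    "EmptySelectionError",
    "Topology",
    "Ensemble",
    "Selection",
    "read_pdb_models",
    "write_frames_pdb",
    "select",
    "parse_selection",
]

#: Protein backbone atom names used for superposition and PCA.  The
#: carbonyl oxygen is included; use :data:`BACKBONE_ATOMS_NO_O` for the
#: N, CA, C convention.
BACKBONE_ATOMS: tuple[str, ...] = ("N", "CA", "C", "O")
BACKBONE_ATOMS_NO_O: tuple[str, ...] = ("N", "CA", "C")


class StructureError(ValueError):
    """Base class for structure I/O and selection errors."""


class ParseError(StructureError):
    """File could not be parsed as a (multi-model) PDB."""


class TopologyMismatchError(StructureError):
    """Models of one file, or two matched structures, disagree in atom identity."""


class EmptySelectionError(StructureError):
    """A selection predicate matched no atoms."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Topology:
    """Ordered atom identities shared by every frame of an ensemble.

    Coordinates never live here; they live in :class:`Ensemble` frames.
    Residues are indexed by author numbering, i.e. by the pair
    ``(chain_id, residue_number)``, which is also how residues are matched
    across conditions.
    """

    chain_ids: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    occupancies: np.ndarray
    altlocs: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        for name in ("chain_ids", "res_ids", "res_names", "elements", "occupancies", "altlocs"):
            if len(getattr(self, name)) != n:
                raise StructureError(f"annotation array {name!r} length mismatch")
        if n and not all(self.elements):
            raise StructureError("empty element after inference")
        keys = list(zip(self.chain_ids, self.res_ids, self.atom_names, self.altlocs))
        if len(set(keys)) != n:
            raise StructureError("duplicate (chain, resid, atom, altloc) in topology")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Unique ``(chain_id, residue_number)`` keys in order of appearance."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chain_ids, self.res_ids):
            seen.setdefault((str(c), int(r)), None)
        return list(seen)

    def residue_index(self) -> dict[tuple[str, int], int]:
        """Map ``(chain_id, residue_number)`` to a compact ordinal from 0."""
        return {key: i for i, key in enumerate(self.residue_keys())}

    def atom_residue_ordinals(self) -> np.ndarray:
        """Per-atom residue ordinal (contiguous from 0)."""
        index = self.residue_index()
        return np.array(
            [index[(str(c), int(r))] for c, r in zip(self.chain_ids, self.res_ids)],
            dtype=np.intp,
        )

    def identity_tuples(self) -> list[tuple[str, int, str]]:
        return [
            (str(c), int(r), str(a))
            for c, r, a in zip(self.chain_ids, self.res_ids, self.atom_names)
        ]


@dataclass
class Ensemble:
    """A stack of coordinate frames over one :class:`Topology`.

    ``coords`` has shape ``(n_frames, n_atoms, 3)`` in Angstrom.
    """

    topology: Topology
    coords: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructureError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise StructureError(
                f"frame has {self.coords.shape[1]} atoms, topology has {self.topology.n_atoms}"
            )
        if self.coords.shape[0] < 1:
            raise StructureError("an ensemble needs at least one frame")
        if not np.isfinite(self.coords).all():
            raise StructureError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[1])

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def subset(self, frame_window: tuple[int, int] | None) -> "Ensemble":
        """Frames ``[start, stop)``; ``None`` keeps everything."""
        if frame_window is None:
            return self
        start, stop = frame_window
        coords = self.coords[start:stop]
        if coords.shape[0] < 1:
            raise StructureError(f"frame window {frame_window} selects no frames")
        return replace(self, coords=coords)


@dataclass(frozen=True)
class Selection:
    """A resolved atom selection: the predicate plus its index list.

    Resolving the same predicate on the same topology always yields the
    same strictly increasing index list.
    """

    description: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.intp)
        object.__setattr__(self, "indices", idx)
        if idx.size == 0:
            raise EmptySelectionError(f"selection {self.description!r} matched no atoms")
        if not (np.diff(idx) > 0).all():
            raise StructureError("selection indices must be strictly increasing")

    @property
    def n_atoms(self) -> int:
        return int(self.indices.size)


# ---------------------------------------------------------------------------
# element inference / altloc resolution
# ---------------------------------------------------------------------------

_NAME_RE = re.compile(r"[0-9']")


def _infer_element(atom_name: str) -> str:
    """Guess the element from a PDB atom name (fallback when the element
    column is blank).  Hydrogen naming variants (HB2, 1HB, HG11...) map to H."""
    stripped = _NAME_RE.sub("", atom_name).strip()
    if not stripped:
        return ""
    # hydrogen naming variants (HB2, 1HB, HG11...) collapse to their first
    # letter after digits are stripped, which is also correct for C/N/O/S
    return stripped[0]


def _resolve_altlocs(arr: struc.AtomArray, policy: str) -> struc.AtomArray:
    """Keep one conformer per (chain, resid, atom name).

    ``occupancy`` keeps the highest-occupancy altloc, breaking ties by the
    lexicographically smallest altloc code.  ``first`` keeps the first
    conformer encountered.
    """
    if policy not in ("occupancy", "first"):
        raise ValueError(f"unknown altloc policy {policy!r}")
    altloc = np.char.strip(arr.altloc_id.astype("U1"))
    keys = list(zip(arr.chain_id, arr.res_id, arr.atom_name))
    best: dict[tuple, int] = {}
    for i, key in enumerate(keys):
        if key not in best:
            best[key] = i
            continue
        if policy == "first":
            continue
        j = best[key]
        occ_i, occ_j = float(arr.occupancy[i]), float(arr.occupancy[j])
        if occ_i > occ_j or (occ_i == occ_j and altloc[i] < altloc[j]):
            best[key] = i
    keep = np.zeros(arr.array_length(), dtype=bool)
    keep[sorted(best.values())] = True
    return arr[keep]


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------


def _topology_from_atom_array(arr: struc.AtomArray) -> Topology:
    elements = np.array(
        [e if e else _infer_element(n) for e, n in zip(arr.element, arr.atom_name)],
        dtype="U4",
    )
    altloc = np.char.strip(arr.altloc_id.astype("U1"))
    return Topology(
        chain_ids=arr.chain_id.astype("U4"),
        res_ids=arr.res_id.astype(int),
        res_names=arr.res_name.astype("U4"),
        atom_names=arr.atom_name.astype("U6"),
        elements=elements,
        occupancies=arr.occupancy.astype(float),
        altlocs=altloc,
    )


def read_pdb_models(path: str | Path, altloc_policy: str = "occupancy", label: str = "") -> Ensemble:
    """Read a (multi-)model PDB file into an :class:`Ensemble`.

    Every MODEL becomes one frame.  All models must carry the identical
    atom identity sequence after altloc resolution; hydrogens are kept
    (drop them with a selection, not at parse time).

    Parameters
    ----------
    path
        PDB file with one or more models.
    altloc_policy
        ``"occupancy"`` (keep highest-occupancy conformer, ties to the
        smallest altloc code) or ``"first"``.
    label
        Condition name attached to the ensemble (defaults to the file stem).
    """
    path = Path(path)
    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        n_models = pdb_file.get_model_count()
    except Exception as exc:  # biotite raises a mix of its own and ValueError
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if n_models < 1:
        raise ParseError(f"{path} contains no models / ATOM records")

    frames: list[np.ndarray] = []
    topology: Topology | None = None
    reference_identity: list[tuple[str, int, str]] | None = None
    for model in range(1, n_models + 1):
        try:
            arr = pdb_file.get_structure(
                model=model, altloc="all", extra_fields=["occupancy"]
            )
        except Exception as exc:
            raise ParseError(f"cannot parse model {model} of {path}: {exc}") from exc
        if np.any(np.char.strip(arr.ins_code.astype("U4")) != ""):
            raise ParseError(f"{path}: insertion codes are not supported")
        arr = _resolve_altlocs(arr, altloc_policy)
        if topology is None:
            topology = _topology_from_atom_array(arr)
            reference_identity = topology.identity_tuples()
        else:
            identity = [
                (str(c), int(r), str(a))
                for c, r, a in zip(arr.chain_id, arr.res_id, arr.atom_name)
            ]
            if identity != reference_identity:
                raise TopologyMismatchError(
                    f"{path}: model {model} atom identities differ from model 1"
                )
        frames.append(np.asarray(arr.coord, dtype=float))
    assert topology is not None
    return Ensemble(topology=topology, coords=np.stack(frames), label=label or path.stem)


def write_frames_pdb(
    ensemble: Ensemble, path: str | Path, force_model_records: bool = False
) -> None:
    """Write an :class:`Ensemble` as a multi-model PDB file.

    The output round-trips through :func:`read_pdb_models` with identical
    topology and coordinates within the PDB format precision (0.001 A).
    A single-frame ensemble is written as bare ATOM records by default,
    or as one MODEL/ENDMDL pair when ``force_model_records`` is set.
    """
    top = ensemble.topology
    template = struc.AtomArray(top.n_atoms)
    template.chain_id = top.chain_ids
    template.res_id = top.res_ids
    template.res_name = top.res_names
    template.atom_name = top.atom_names
    template.element = top.elements
    template.set_annotation("occupancy", top.occupancies)
    template.set_annotation("b_factor", np.zeros(top.n_atoms))
    template.hetero = np.zeros(top.n_atoms, dtype=bool)
    stack = struc.stack([template] * ensemble.n_frames)
    stack.coord = np.asarray(ensemble.coords, dtype=np.float32)
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))
    if ensemble.n_frames == 1 and force_model_records:
        body = Path(path).read_text()
        Path(path).write_text("MODEL        1\n" + body + "ENDMDL\n")


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------


def select(
    topology: Topology,
    chain: str | None = None,
    res_range: tuple[int, int] | None = None,
    atom_names: Sequence[str] | None = None,
    heavy: bool = False,
    backbone: bool = False,
    backbone_atoms: Sequence[str] = BACKBONE_ATOMS,
    description: str | None = None,
) -> Selection:
    """Resolve a predicate over atoms into a :class:`Selection`.

    Criteria combine with logical AND.  ``backbone`` selects the atom
    names in ``backbone_atoms`` (default N, CA, C, O); ``heavy`` excludes
    hydrogen and deuterium; ``res_range`` is an inclusive author-numbering
    interval.
    """
    if topology.n_atoms == 0:
        raise StructureError("cannot select from an empty topology")
    mask = np.ones(topology.n_atoms, dtype=bool)
    parts: list[str] = []
    if chain is not None:
        mask &= topology.chain_ids == chain
        parts.append(f"chain {chain}")
    if res_range is not None:
        lo, hi = res_range
        mask &= (topology.res_ids >= lo) & (topology.res_ids <= hi)
        parts.append(f"resid {lo}-{hi}")
    if atom_names is not None:
        mask &= np.isin(topology.atom_names, list(atom_names))
        parts.append("name " + ",".join(atom_names))
    if backbone:
        mask &= np.isin(topology.atom_names, list(backbone_atoms))
        parts.append("backbone")
    if heavy:
        mask &= ~np.isin(topology.elements, ["H", "D"])
        parts.append("heavy")
    if description is None:
        description = " and ".join(parts) if parts else "all"
    return Selection(description=description, indices=np.flatnonzero(mask))


def parse_selection(expr: str) -> dict:
    """Parse the CLI selection mini-language into :func:`select` keywords.

    Clauses joined by ``and``: ``chain <id>``, ``resid <lo>-<hi>``,
    ``name <A,B,...>``, ``backbone``, ``heavy``, ``all``.
    """
    kwargs: dict = {}
    expr = expr.strip()
    if not expr or expr == "all":
        return kwargs
    for clause in (c.strip() for c in expr.split(" and ")):
        tokens = clause.split()
        head = tokens[0].lower()
        if head == "chain" and len(tokens) == 2:
            kwargs["chain"] = tokens[1]
        elif head == "resid" and len(tokens) == 2 and "-" in tokens[1]:
            lo, hi = tokens[1].split("-", 1)
            kwargs["res_range"] = (int(lo), int(hi))
        elif head == "name" and len(tokens) == 2:
            kwargs["atom_names"] = tuple(tokens[1].split(","))
        elif head == "backbone" and len(tokens) == 1:
            kwargs["backbone"] = True
        elif head == "heavy" and len(tokens) == 1:
            kwargs["heavy"] = True
        else:
            raise ValueError(f"cannot parse selection clause {clause!r}")
    return kwargs


def match_selections(
    topology_a: Topology,
    topology_b: Topology,
    selection_a: Selection,
    selection_b: Selection,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair selected atoms of two topologies by (chain, resid, atom name).

    Returns index arrays ``(idx_a, idx_b)`` of equal length, ordered by the
    appearance in ``selection_a``.  Raises :class:`TopologyMismatchError`
    when no common atoms exist or multiplicity differs.
    """
    ids_a = topology_a.identity_tuples()
    ids_b = topology_b.identity_tuples()
    lookup_b = {ids_b[i]: i for i in selection_b.indices}
    idx_a, idx_b = [], []
    for i in selection_a.indices:
        j = lookup_b.get(ids_a[i])
        if j is not None:
            idx_a.append(i)
            idx_b.append(j)
    if not idx_a:
        raise TopologyMismatchError("selections share no (chain, resid, atom) identities")
    return np.asarray(idx_a, dtype=np.intp), np.asarray(idx_b, dtype=np.intp)
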