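"""Residue-residue heavy-atom contacts and contact-formation probabilities.

Two residues are in contact in a frame when any pair of their heavy
atoms lies within the distance cutoff (default 4.5 A, a tie at the
cutoff counts).  Same-chain pairs closer in sequence than the minimum
separation (default ``|i - j| >= 3``) are excluded; pairs on different
chains are always eligible, since the separation rule is meaningless
across subunits.  The contact-formation probability of a pair over an
ensemble is the fraction of frames in which the contact is present,
kept as an exact rational internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.spatial import cKDTree

from gcensemble.structure_io import Ensemble, Topology, select

__all__ = [
    "ContactParams",
    "ContactProbabilityMap",
    "frame_contacts",
    "contact_probability",
    "neighbor_search",
]

ResidueKey = tuple[str, int]
PairKey = tuple[ResidueKey, ResidueKey]


@dataclass(frozen=True)
class ContactParams:
    """Parameters of contact determination.

    ``cutoff``: heavy-atom distance cutoff in A (contact when the minimum
    inter-residue heavy-atom distance is <= cutoff).
    ``min_separation``: same-chain pairs need ``|i - j| >= min_separation``
    (author numbering); inter-chain pairs are always eligible.
    ``stride``: evaluate every ``stride``-th frame.
    """

    cutoff: float = 4.5
    min_separation: int = 3
    stride: int = 1

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


def _pair_key(a: ResidueKey, b: ResidueKey) -> PairKey:
    return (a, b) if a <= b else (b, a)


def pair_eligible(a: ResidueKey, b: ResidueKey, params: ContactParams) -> bool:
    """Separation rule: different chains always eligible; same chain needs
    ``|i - j| >= min_separation``."""
    if a == b:
        return False
    if a[0] != b[0]:
        return True
    return abs(a[1] - b[1]) >= params.min_separation


@dataclass
class ContactProbabilityMap:
    """Contact-formation probability per eligible residue pair.

    Probabilities are stored as exact frame counts over ``n_frames``;
    pairs never observed in contact are implicit zeros, so maps from
    different conditions stay comparable over the union of their pairs.
    """

    label: str
    counts: dict[PairKey, int]
    n_frames: int
    params: ContactParams
    residues: tuple[ResidueKey, ...]
    chain_of: dict[ResidueKey, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("a probability map needs at least one frame")
        for pair, count in self.counts.items():
            if not 0 <= count <= self.n_frames:
                raise ValueError(f"count {count} outside [0, {self.n_frames}] for {pair}")
            if not pair_eligible(pair[0], pair[1], self.params):
                raise ValueError(f"pair {pair} violates the separation rule")
        self.chain_of = {r: r[0] for r in self.residues}

    def probability(self, a: ResidueKey, b: ResidueKey) -> Fraction:
        """Exact contact probability of a residue pair (0 if never seen)."""
        return Fraction(self.counts.get(_pair_key(a, b), 0), self.n_frames)

    def pairs(self) -> list[PairKey]:
        return sorted(self.counts)

    def to_records(self) -> list[dict]:
        out = []
        for (a, b) in self.pairs():
            out.append(
                {
                    "chain_i": a[0],
                    "resid_i": a[1],
                    "chain_j": b[0],
                    "resid_j": b[1],
                    "probability": float(self.probability(a, b)),
                    "n_frames": self.n_frames,
                }
            )
        return out


def neighbor_search(coords: np.ndarray, cutoff: float) -> set[tuple[int, int]]:
    """All atom index pairs within ``cutoff`` (inclusive), via a k-d tree.

    Exactly equivalent to the brute-force all-pairs scan.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("neighbor search needs at least 2 atoms")
    tree = cKDTree(coords)
    # query_pairs uses strict '<' on r only for p=inf; for euclidean it is
    # inclusive of r, matching the '<= cutoff' contact convention
    return {(min(i, j), max(i, j)) for i, j in tree.query_pairs(cutoff)}


def frame_contacts(
    frame: np.ndarray,
    topology: Topology,
    params: ContactParams = ContactParams(),
    _heavy_cache: dict | None = None,
) -> set[PairKey]:
    """Residue pairs in contact in one frame.

    A pair is reported iff the minimum heavy-atom distance is within the
    cutoff and the pair passes the separation rule.  Hydrogens are never
    considered.
    """
    keys = topology.residue_keys()
    if len(keys) < 2:
        raise ValueError("contact analysis needs at least 2 residues")
    if _heavy_cache is not None and "heavy" in _heavy_cache:
        heavy_idx, atom_res = _heavy_cache["heavy"]
    else:
        heavy_idx = select(topology, heavy=True).indices
        ordinals = topology.atom_residue_ordinals()
        atom_res = ordinals[heavy_idx]
        if _heavy_cache is not None:
            _heavy_cache["heavy"] = (heavy_idx, atom_res)
    coords = np.asarray(frame, dtype=float)[heavy_idx]
    contacts: set[PairKey] = set()
    for i, j in neighbor_search(coords, params.cutoff):
        ri, rj = int(atom_res[i]), int(atom_res[j])
        if ri == rj:
            continue
        a, b = keys[ri], keys[rj]
        if pair_eligible(a, b, params):
            contacts.add(_pair_key(a, b))
    return contacts


def frame_contacts_brute(
    frame: np.ndarray,
    topology: Topology,
    params: ContactParams = ContactParams(),
) -> set[PairKey]:
    """All-pairs reference implementation of :func:`frame_contacts`.

    Independent of the k-d tree path; used to validate it.
    """
    keys = topology.residue_keys()
    heavy_idx = select(topology, heavy=True).indices
    ordinals = topology.atom_residue_ordinals()[heavy_idx]
    coords = np.asarray(frame, dtype=float)[heavy_idx]
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    contacts: set[PairKey] = set()
    n = len(heavy_idx)
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] > params.cutoff:
                continue
            ri, rj = int(ordinals[i]), int(ordinals[j])
            if ri == rj:
                continue
            a, b = keys[ri], keys[rj]
            if pair_eligible(a, b, params):
                contacts.add(_pair_key(a, b))
    return contacts


def contact_probability(
    ensemble: Ensemble,
    params: ContactParams = ContactParams(),
) -> ContactProbabilityMap:
    """Contact-formation probability over an ensemble.

    probability(pair) = (frames with the contact) / (frames evaluated),
    with frames subsampled by ``params.stride``.
    """
    frames = ensemble.coords[:: params.stride]
    if frames.shape[0] < 1:
        raise ValueError("no frames left after applying the stride")
    cache: dict = {}
    counts: dict[PairKey, int] = {}
    for f in range(frames.shape[0]):
        for pair in frame_contacts(frames[f], ensemble.topology, params, _heavy_cache=cache):
            counts[pair] = counts.get(pair, 0) + 1
    return ContactProbabilityMap(
        label=ensemble.label,
        counts=counts,
        n_frames=int(frames.shape[0]),
        params=params,
        residues=tuple(ensemble.topology.residue_keys()),
    )
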