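"""Difference contact network analysis (dCNA).

Contact-probability changes ``df = P(mutant) - P(reference)`` per residue
pair, computed over the union of pairs seen in either condition (a pair
absent from one condition has probability 0 there).  Changes with
``|df|`` at or above a threshold (default 0.1, the customary estimate of
the statistical error of contact probabilities from equilibrated
trajectories) are flagged significant.  The residue graph of persistent
contacts is partitioned into communities by divisive Girvan-Newman
clustering at maximum modularity, and residue-level changes are
coarse-grained into net contact changes between communities, whose total
exactly conserves the sum of residue-level df.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import networkx as nx

from gcensemble.contact_analysis import (
    ContactProbabilityMap,
    PairKey,
    ResidueKey,
    pair_eligible,
)
from gcensemble.structure_io import Ensemble

__all__ = [
    "DifferenceEdge",
    "DifferenceContactNetwork",
    "CommunityPartition",
    "CoarseNetwork",
    "difference_network",
    "filter_intersubunit",
    "detect_communities",
    "coarse_grain",
    "export_visualization",
]


@dataclass(frozen=True)
class DifferenceEdge:
    """One residue pair's contact-probability change."""

    pair: PairKey
    df: Fraction
    significant: bool
    inter_subunit: bool

    def __post_init__(self) -> None:
        if abs(self.df) > 1:
            raise ValueError("|df| cannot exceed 1")


@dataclass(frozen=True)
class DifferenceContactNetwork:
    """All difference edges between one mutant and the reference."""

    reference_label: str
    mutant_label: str
    edges: tuple[DifferenceEdge, ...]
    threshold: float = 0.1

    def __post_init__(self) -> None:
        pairs = [e.pair for e in self.edges]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate residue pairs in network")

    def significant_edges(self) -> list[DifferenceEdge]:
        return [e for e in self.edges if e.significant]

    def residues(self) -> set[ResidueKey]:
        return {r for e in self.edges for r in e.pair}

    def to_records(self, reference: ContactProbabilityMap | None = None,
                   mutant: ContactProbabilityMap | None = None) -> list[dict]:
        out = []
        for e in sorted(self.edges, key=lambda e: e.pair):
            (a, b) = e.pair
            rec = {
                "chain_i": a[0], "resid_i": a[1],
                "chain_j": b[0], "resid_j": b[1],
                "df": float(e.df),
                "significant": e.significant,
                "inter_subunit": e.inter_subunit,
            }
            if reference is not None:
                rec["p_ref"] = float(reference.probability(a, b))
            if mutant is not None:
                rec["p_mut"] = float(mutant.probability(a, b))
            out.append(rec)
        return out


@dataclass(frozen=True)
class CommunityPartition:
    """Residue -> community id mapping (ids contiguous from 0)."""

    assignment: dict[ResidueKey, int]
    modularity: float
    source: str

    def __post_init__(self) -> None:
        ids = sorted(set(self.assignment.values()))
        if ids != list(range(len(ids))):
            raise ValueError("community ids must be contiguous from 0")

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, community: int) -> list[ResidueKey]:
        return sorted(r for r, c in self.assignment.items() if c == community)

    def extended_to(self, residues: set[ResidueKey]) -> "CommunityPartition":
        """Assign residues missing from the partition to fresh singleton
        communities (deterministic order)."""
        missing = sorted(residues - set(self.assignment))
        if not missing:
            return self
        assignment = dict(self.assignment)
        next_id = self.n_communities
        for r in missing:
            assignment[r] = next_id
            next_id += 1
        return CommunityPartition(assignment, self.modularity, self.source + "+singletons")


@dataclass(frozen=True)
class CoarseNetwork:
    """Net contact change between communities (self-loops = intra-community)."""

    weights: dict[tuple[int, int], Fraction]
    partition: CommunityPartition
    description: str

    def total(self) -> Fraction:
        return sum(self.weights.values(), Fraction(0))


def difference_network(
    reference: ContactProbabilityMap,
    mutant: ContactProbabilityMap,
    threshold: float = 0.1,
) -> DifferenceContactNetwork:
    """Per-pair df between two conditions built with identical parameters.

    df is computed over the union of both conditions' pairs; a pair never
    in contact in one condition contributes probability 0 there.
    Significance is ``|df| >= threshold``.
    """
    if reference.params != mutant.params:
        raise ValueError("contact parameters differ between conditions")
    common = set(reference.residues) & set(mutant.residues)
    if not common:
        raise ValueError("conditions share no (chain, resid) residues")
    edges = []
    for pair in sorted(set(reference.counts) | set(mutant.counts)):
        a, b = pair
        if not pair_eligible(a, b, reference.params):
            continue
        df = mutant.probability(a, b) - reference.probability(a, b)
        edges.append(
            DifferenceEdge(
                pair=pair,
                df=df,
                significant=abs(df) >= Fraction(threshold).limit_denominator(10**9),
                inter_subunit=a[0] != b[0],
            )
        )
    return DifferenceContactNetwork(
        reference_label=reference.label,
        mutant_label=mutant.label,
        edges=tuple(edges),
        threshold=threshold,
    )


def filter_intersubunit(network: DifferenceContactNetwork) -> DifferenceContactNetwork:
    """Keep only edges whose residues sit on different chains."""
    return DifferenceContactNetwork(
        reference_label=network.reference_label,
        mutant_label=network.mutant_label,
        edges=tuple(e for e in network.edges if e.inter_subunit),
        threshold=network.threshold,
    )


def _girvan_newman_partitions(graph: nx.Graph):
    """Divisive edge-betweenness clustering with deterministic tie-breaks.

    Yields one residue->community assignment per splitting level.  Among
    edges of equal (within 1e-12) maximal betweenness the lexicographically
    smallest (chain, resid) pair is removed first.  Edge betweenness uses
    the -log(probability) edge length, so persistent contacts are short.
    """
    work = graph.copy()
    while True:
        components = sorted(sorted(c) for c in nx.connected_components(work))
        yield {node: ci for ci, comp in enumerate(components) for node in comp}
        if work.number_of_edges() == 0:
            return
        betweenness = nx.edge_betweenness_centrality(work, weight="length")
        top = max(betweenness.values())
        candidates = [e for e, b in betweenness.items() if b >= top - 1e-12]
        edge = min(tuple(sorted(e)) for e in candidates)
        work.remove_edge(*edge)


def detect_communities(
    probabilities: ContactProbabilityMap,
    edge_min_probability: float = 0.5,
) -> CommunityPartition:
    """Partition the persistent-contact graph into communities.

    The graph has one node per residue appearing in a pair with contact
    probability >= ``edge_min_probability`` and probability-weighted
    edges.  Girvan-Newman divisive clustering is run to completion and
    the partition with maximum modularity (probability weights) is
    returned; ties go to the earliest (coarsest) partition.
    """
    graph = nx.Graph()
    for (a, b), count in sorted(probabilities.counts.items()):
        p = Fraction(count, probabilities.n_frames)
        if p >= Fraction(edge_min_probability).limit_denominator(10**9):
            graph.add_edge(a, b, weight=float(p), length=-math.log(max(float(p), 1e-12)) + 1e-12)
    if graph.number_of_nodes() == 0:
        raise ValueError("no contact pair reaches edge_min_probability")

    best_assignment: dict[ResidueKey, int] | None = None
    best_q = -math.inf
    for assignment in _girvan_newman_partitions(graph):
        groups: dict[int, set] = {}
        for node, c in assignment.items():
            groups.setdefault(c, set()).add(node)
        q = nx.community.modularity(graph, groups.values(), weight="weight")
        if q > best_q + 1e-12:
            best_q = q
            best_assignment = assignment
    assert best_assignment is not None
    return CommunityPartition(
        assignment=best_assignment,
        modularity=best_q,
        source=f"girvan-newman on {probabilities.label} (p >= {edge_min_probability})",
    )


def coarse_grain(
    network: DifferenceContactNetwork,
    partition: CommunityPartition,
) -> CoarseNetwork:
    """Net contact change between communities.

    The weight of coarse edge (A, B) is the exact rational sum of df over
    residue pairs with one end in A and the other in B; intra-community
    changes stay as self-loops, so the coarse total equals the residue
    total exactly.
    """
    weights: dict[tuple[int, int], Fraction] = {}
    for e in network.edges:
        a, b = e.pair
        try:
            ca, cb = partition.assignment[a], partition.assignment[b]
        except KeyError as exc:
            raise ValueError(f"residue {exc.args[0]} missing from partition") from exc
        key = (min(ca, cb), max(ca, cb))
        weights[key] = weights.get(key, Fraction(0)) + e.df
    return CoarseNetwork(
        weights=weights,
        partition=partition,
        description=f"{network.reference_label} -> {network.mutant_label}",
    )


def export_visualization(
    network: DifferenceContactNetwork,
    structure: Ensemble,
    path,
    base_radius: float = 1.0,
    significant_only: bool = True,
    frame: int = 0,
) -> None:
    """Write a PyMOL-style script drawing df edges as cylinders, plus a CSV twin.

    Cylinders connect the CA atoms of the two residues; blue for df > 0,
    red for df < 0, radius = ``base_radius * |df|``.
    """
    from pathlib import Path

    path = Path(path)
    top = structure.topology
    ca_of: dict[ResidueKey, int] = {}
    for i, (c, r, name) in enumerate(
        zip(top.chain_ids, top.res_ids, top.atom_names)
    ):
        if name == "CA":
            ca_of[(str(c), int(r))] = i

    edges = network.significant_edges() if significant_only else list(network.edges)
    lines = [
        f"# difference contact network: {network.reference_label} -> {network.mutant_label}",
        f"# threshold |df| >= {network.threshold}; radius = {base_radius} * |df|",
        "from pymol.cgo import CYLINDER",
        "edges = [",
    ]
    csv_rows = ["chain_i,resid_i,chain_j,resid_j,df,color"]
    coords = structure.coords[frame]
    for e in sorted(edges, key=lambda e: e.pair):
        a, b = e.pair
        for res in (a, b):
            if res not in ca_of:
                raise ValueError(f"residue {res} has no CA atom in the structure")
        xa, xb = coords[ca_of[a]], coords[ca_of[b]]
        df = float(e.df)
        color = (0.0, 0.0, 1.0) if df > 0 else (1.0, 0.0, 0.0)
        radius = base_radius * abs(df)
        lines.append(
            "    [CYLINDER, %.3f, %.3f, %.3f, %.3f, %.3f, %.3f, %.4f, "
            "%.1f, %.1f, %.1f, %.1f, %.1f, %.1f],"
            % (*xa, *xb, radius, *color, *color)
        )
        csv_rows.append(
            f"{a[0]},{a[1]},{b[0]},{b[1]},{df:.6f},{'blue' if df > 0 else 'red'}"
        )
    lines += [
        "]",
        "obj = [item for edge in edges for item in edge]",
        f"cmd.load_cgo(obj, 'dcna_{network.mutant_label}')",
    ]
    path.write_text("\n".join(lines) + "\n")
    path.with_suffix(".csv").write_text("\n".join(csv_rows) + "\n")
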