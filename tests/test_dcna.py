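"""Difference contact networks, community detection and coarse-graining."""

import itertools
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcensemble.contact_analysis import ContactParams, ContactProbabilityMap
from gcensemble.dcna import (
    CommunityPartition,
    coarse_grain,
    detect_communities,
    difference_network,
    export_visualization,
    filter_intersubunit,
)
from gcensemble.synthetic_data import (
    ContactFlickerSpec,
    flicker_probability_maps,
    make_toy_heterodimer,
)

PARAMS = ContactParams()


def _map(label, probs, n_frames=100, residues=None):
    counts = {pair: round(p * n_frames) for pair, p in probs.items()}
    if residues is None:
        residues = tuple(sorted({r for pair in probs for r in pair}))
    return ContactProbabilityMap(
        label=label, counts=counts, n_frames=n_frames, params=PARAMS, residues=residues
    )


def test_df_values_and_significance():
    ref = _map("wt", {(("A", 1), ("B", 2)): 0.70, (("A", 3), ("B", 4)): 0.50})
    mut = _map("m", {(("A", 1), ("B", 2)): 0.85, (("A", 3), ("B", 4)): 0.55})
    net = difference_network(ref, mut, threshold=0.1)
    by_pair = {e.pair: e for e in net.edges}
    e1 = by_pair[(("A", 1), ("B", 2))]
    assert e1.df == Fraction(15, 100)
    assert e1.significant
    e2 = by_pair[(("A", 3), ("B", 4))]
    assert e2.df == Fraction(5, 100)
    assert not e2.significant


def test_union_of_pairs_with_absent_as_zero():
    residues = (("A", 1), ("A", 5), ("B", 2), ("B", 9))
    ref = _map("wt", {(("A", 1), ("B", 2)): 0.4}, residues=residues)
    mut = _map("m", {(("A", 5), ("B", 9)): 0.3}, residues=residues)
    net = difference_network(ref, mut)
    by_pair = {e.pair: float(e.df) for e in net.edges}
    assert by_pair[(("A", 1), ("B", 2))] == pytest.approx(-0.4)
    assert by_pair[(("A", 5), ("B", 9))] == pytest.approx(0.3)


def test_antisymmetry_under_condition_swap():
    rng = np.random.default_rng(8)
    pairs = [(("A", i), ("B", i + 1)) for i in range(1, 8)]
    ref = _map("wt", {p: rng.random() for p in pairs})
    mut = _map("m", {p: rng.random() for p in pairs})
    forward = difference_network(ref, mut)
    backward = difference_network(mut, ref)
    fwd = {e.pair: e for e in forward.edges}
    bwd = {e.pair: e for e in backward.edges}
    assert set(fwd) == set(bwd)
    for pair in fwd:
        assert fwd[pair].df == -bwd[pair].df
        assert fwd[pair].significant == bwd[pair].significant


def test_mismatched_params_rejected():
    ref = _map("wt", {(("A", 1), ("B", 2)): 0.5})
    mut = ContactProbabilityMap(
        label="m", counts={(("A", 1), ("B", 2)): 50}, n_frames=100,
        params=ContactParams(cutoff=5.0), residues=(("A", 1), ("B", 2)),
    )
    with pytest.raises(ValueError):
        difference_network(ref, mut)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(threshold=st.floats(0.05, 0.5), bump=st.floats(0.0, 0.4))
def test_threshold_monotonicity(threshold, bump):
    rng = np.random.default_rng(0)
    pairs = [(("A", i), ("B", i)) for i in range(1, 12)]
    ref = _map("wt", {p: rng.random() for p in pairs})
    mut = _map("m", {p: rng.random() for p in pairs})
    low = difference_network(ref, mut, threshold)
    high = difference_network(ref, mut, threshold + bump)
    assert len(high.significant_edges()) <= len(low.significant_edges())


def test_intersubunit_filter_counts_and_idempotence():
    probs = {
        (("A", 1), ("A", 5)): 0.9,
        (("A", 2), ("A", 6)): 0.9,
        (("A", 1), ("B", 1)): 0.9,
        (("A", 3), ("B", 2)): 0.9,
        (("B", 1), ("B", 5)): 0.9,
    }
    net = difference_network(_map("wt", {p: 0.0 for p in probs},
                                  residues=tuple(sorted({r for p in probs for r in p}))),
                             _map("m", probs,
                                  residues=tuple(sorted({r for p in probs for r in p}))))
    filtered = filter_intersubunit(net)
    assert len(filtered.edges) == 2
    assert all(e.inter_subunit for e in filtered.edges)
    twice = filter_intersubunit(filtered)
    assert twice.edges == filtered.edges


def test_planted_df_recovery_with_false_positive_control():
    """Planted df = 0.25 on 10 pairs is always flagged at threshold 0.1;
    null pairs (df = 0) are flagged in at most 1% of cases across seeds."""
    planted = [(("A", i), ("B", i)) for i in range(1, 11)]
    null = [(("A", i), ("B", i)) for i in range(11, 31)]
    n_rep = 100
    missed = 0
    false_positives = 0
    null_tests = 0
    for seed in range(n_rep):
        probs_ref = {p: 0.5 for p in planted} | {p: 0.4 for p in null}
        probs_mut = {p: 0.75 for p in planted} | {p: 0.4 for p in null}
        spec = ContactFlickerSpec(
            pair_probabilities={"ref": probs_ref, "mut": probs_mut},
            n_frames=2000,
            n_residues=31,
            seed=seed,
        )
        maps = flicker_probability_maps(spec)
        net = difference_network(maps["ref"], maps["mut"], threshold=0.1)
        flagged = {e.pair for e in net.significant_edges()}
        missed += sum(1 for p in planted if p not in flagged)
        false_positives += sum(1 for p in null if p in flagged)
        null_tests += len(null)
    assert missed == 0
    assert false_positives / null_tests <= 0.01


def test_two_cliques_with_bridge_split_into_two_communities():
    # two 5-residue cliques joined by one bridge edge; separation rule
    # relaxed so intra-chain cliques are representable
    residues_a = [("A", i) for i in range(1, 6)]
    residues_b = [("B", i) for i in range(1, 6)]
    params = ContactParams(min_separation=0)
    counts = {}
    for group in (residues_a, residues_b):
        for x, y in itertools.combinations(group, 2):
            counts[(x, y)] = 90
    counts[(("A", 5), ("B", 1))] = 90  # bridge
    cmap = ContactProbabilityMap(
        label="wt", counts=counts, n_frames=100, params=params,
        residues=tuple(residues_a + residues_b),
    )
    partition = detect_communities(cmap, edge_min_probability=0.5)
    assert partition.n_communities == 2
    assert len({partition.assignment[r] for r in residues_a}) == 1
    assert len({partition.assignment[r] for r in residues_b}) == 1
    assert partition.assignment[("A", 1)] != partition.assignment[("B", 1)]


def test_planted_three_block_graph_recovered_exactly():
    rng = np.random.default_rng(42)
    blocks = [[("A", i) for i in range(1, 9)],
              [("B", i) for i in range(1, 9)],
              [("C", i) for i in range(1, 9)]]
    params = ContactParams(min_separation=0)
    counts = {}
    n_frames = 200
    for block in blocks:
        for x, y in itertools.combinations(block, 2):
            counts[(x, y) if x <= y else (y, x)] = int(
                rng.binomial(n_frames, 0.9)
            )
    for ba, bb in itertools.combinations(blocks, 2):
        for x in ba:
            for y in bb:
                draw = rng.binomial(n_frames, 0.05)
                if draw:
                    counts[(x, y) if x <= y else (y, x)] = draw
    cmap = ContactProbabilityMap(
        label="wt", counts=counts, n_frames=n_frames, params=params,
        residues=tuple(r for b in blocks for r in b),
    )
    partition = detect_communities(cmap, edge_min_probability=0.5)
    truth = {r: k for k, block in enumerate(blocks) for r in block}
    from sklearn.metrics import adjusted_rand_score

    keys = sorted(truth)
    ari = adjusted_rand_score(
        [truth[k] for k in keys], [partition.assignment[k] for k in keys]
    )
    assert ari == 1.0


def test_uniform_complete_graph_is_single_community():
    residues = [("A", i) for i in range(1, 7)]
    params = ContactParams(min_separation=0)
    counts = {
        (x, y): 80 for x, y in itertools.combinations(residues, 2)
    }
    cmap = ContactProbabilityMap(
        label="wt", counts=counts, n_frames=100, params=params,
        residues=tuple(residues),
    )
    partition = detect_communities(cmap, edge_min_probability=0.5)
    assert partition.n_communities == 1
    # exhaustive check: no partition of <= 6 nodes beats the single community
    import networkx as nx

    graph = nx.Graph()
    for (x, y), c in counts.items():
        graph.add_edge(x, y, weight=c / 100)
    best = max(
        nx.community.modularity(graph, _as_groups(assignment, residues), weight="weight")
        for assignment in _all_partitions(len(residues))
    )
    assert partition.modularity == pytest.approx(best, abs=1e-12)


def _all_partitions(n):
    # restricted growth strings enumerate all set partitions
    def rec(prefix):
        if len(prefix) == n:
            yield list(prefix)
            return
        m = max(prefix) if prefix else -1
        for k in range(m + 2):
            yield from rec(prefix + [k])

    yield from rec([])


def _as_groups(assignment, residues):
    groups = {}
    for r, c in zip(residues, assignment):
        groups.setdefault(c, set()).add(r)
    return list(groups.values())


def test_empty_community_graph_raises():
    cmap = _map("wt", {(("A", 1), ("B", 2)): 0.2})
    with pytest.raises(ValueError):
        detect_communities(cmap, edge_min_probability=0.5)


def test_coarse_grain_weights_and_cancellation():
    partition = CommunityPartition(
        assignment={("A", 1): 0, ("A", 2): 0, ("B", 1): 1, ("B", 2): 1},
        modularity=0.0,
        source="manual",
    )
    ref = _map("wt", {(("A", 1), ("B", 1)): 0.0, (("A", 2), ("B", 2)): 0.3},
               residues=(("A", 1), ("A", 2), ("B", 1), ("B", 2)))
    mut = _map("m", {(("A", 1), ("B", 1)): 0.2, (("A", 2), ("B", 2)): 0.0},
               residues=(("A", 1), ("A", 2), ("B", 1), ("B", 2)))
    net = difference_network(ref, mut)
    coarse = coarse_grain(net, partition)
    assert coarse.weights[(0, 1)] == Fraction(2, 10) - Fraction(3, 10)
    # single edge between communities
    single = difference_network(
        _map("wt", {(("A", 1), ("B", 1)): 0.0},
             residues=(("A", 1), ("B", 1))),
        _map("m", {(("A", 1), ("B", 1)): 0.2},
             residues=(("A", 1), ("B", 1))),
    )
    assert coarse_grain(single, partition).weights[(0, 1)] == Fraction(2, 10)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 1000), n_communities=st.integers(1, 4))
def test_coarse_conservation_exact_on_random_networks(seed, n_communities):
    """Sum of coarse edge weights equals sum of residue-level df, exactly."""
    rng = np.random.default_rng(seed)
    pairs = [(("A", i), ("B", j)) for i in range(1, 6) for j in range(1, 6)]
    n_frames = 97  # prime: fractions do not simplify away
    ref = _map("wt", {p: rng.integers(0, 98) / 97 for p in pairs}, n_frames=97)
    mut = _map("m", {p: rng.integers(0, 98) / 97 for p in pairs}, n_frames=97)
    net = difference_network(ref, mut)
    residues = sorted(net.residues())
    assignment = {r: int(rng.integers(0, n_communities)) for r in residues}
    used = sorted(set(assignment.values()))
    relabel = {c: i for i, c in enumerate(used)}
    partition = CommunityPartition(
        assignment={r: relabel[c] for r, c in assignment.items()},
        modularity=0.0, source="random",
    )
    coarse = coarse_grain(net, partition)
    assert coarse.total() == sum((e.df for e in net.edges), Fraction(0))


def test_coarse_grain_missing_residue_raises():
    net = difference_network(
        _map("wt", {(("A", 1), ("B", 1)): 0.0}, residues=(("A", 1), ("B", 1))),
        _map("m", {(("A", 1), ("B", 1)): 0.5}, residues=(("A", 1), ("B", 1))),
    )
    partition = CommunityPartition(assignment={("A", 1): 0}, modularity=0.0, source="x")
    with pytest.raises(ValueError):
        coarse_grain(net, partition)


def test_visualization_script_blue_red_and_radius(tmp_path):
    toy = make_toy_heterodimer(6, seed=0)
    residues = tuple(toy.topology.residue_keys())
    ref = _map("wt", {(("A", 1), ("B", 1)): 0.0, (("A", 2), ("B", 2)): 0.6,
                      (("A", 3), ("B", 3)): 0.0},
               residues=residues)
    mut = _map("m", {(("A", 1), ("B", 1)): 0.2, (("A", 2), ("B", 2)): 0.45,
                     (("A", 3), ("B", 3)): 0.1},
               residues=residues)
    net = difference_network(ref, mut)
    path = tmp_path / "viz.pml"
    export_visualization(net, toy, path)
    text = path.read_text()
    csv_text = path.with_suffix(".csv").read_text()
    lines = [l for l in csv_text.splitlines()[1:]]
    assert any("blue" in l for l in lines) and any("red" in l for l in lines)
    # radius proportional to |df|: df=0.2 edge has twice the radius of df=0.1
    import re

    cylinders = re.findall(r"CYLINDER, ([^\]]+)", text)
    values = [[float(x) for x in c.split(",")[:7]] for c in cylinders]
    radius_by_df = {}
    for l, v in zip(sorted(net.significant_edges(), key=lambda e: e.pair), values):
        radius_by_df[abs(float(l.df))] = v[6]
    assert radius_by_df[0.2] == pytest.approx(2 * radius_by_df[0.1])


def test_visualization_empty_network_valid(tmp_path, toy):
    net = difference_network(
        _map("wt", {(("A", 1), ("B", 1)): 0.5}, residues=tuple(toy.topology.residue_keys())),
        _map("m", {(("A", 1), ("B", 1)): 0.5}, residues=tuple(toy.topology.residue_keys())),
    )
    path = tmp_path / "empty.pml"
    export_visualization(net, toy, path)
    assert "edges = [" in path.read_text()
    assert path.with_suffix(".csv").read_text().startswith("chain_i")
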