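"""Node construction and single-linkage clusters against independent oracles."""

import numpy as np
import networkx as nx
import pytest

from rnascout.clustering import Cluster, HomologyNode, hits_to_nodes, single_linkage
from rnascout.homology import AlignmentHit, ScoringParams, all_vs_all, bit_and_evalue
from rnascout.io_formats import Interval, revcomp
from rnascout.region_prep import Region

BASES = "ACGT"


def make_hit(qr, qs, qe, sr, ss, se, strand="+", score=50):
    bit, e = bit_and_evalue(score, ScoringParams(), 1000, 1000)
    return AlignmentHit(
        query_region=qr,
        q_start=qs,
        q_end=qe,
        subject_region=sr,
        s_start=ss,
        s_end=se,
        strand=strand,
        identity_pct=90.0,
        aln_len=qe - qs,
        matches=int(0.9 * (qe - qs)),
        raw_score=score,
        bit_score=bit,
        e_value=e,
    )


def test_overlapping_endpoints_merge_into_one_node():
    hits = [
        make_hit("rA", 10, 60, "rB", 0, 50),
        make_hit("rA", 50, 100, "rB", 100, 150),
    ]
    nodes = hits_to_nodes(hits)
    ra = [n for n in nodes if n.region_id == "rA"]
    assert len(ra) == 1
    assert (ra[0].start, ra[0].end) == (10, 100)


def test_touching_endpoints_stay_separate():
    hits = [
        make_hit("rA", 10, 60, "rB", 0, 50),
        make_hit("rA", 60, 100, "rB", 100, 140),
    ]
    ra = [n for n in hits_to_nodes(hits) if n.region_id == "rA"]
    assert len(ra) == 2


def test_nodes_equal_bruteforce_overlap_closure(rng):
    for trial in range(30):
        ivs = []
        for _ in range(int(rng.integers(2, 15))):
            s = int(rng.integers(0, 300))
            ivs.append((s, s + int(rng.integers(10, 80))))
        hits = [
            make_hit("rA", s, e, "rB", 1000 + 200 * k, 1000 + 200 * k + (e - s))
            for k, (s, e) in enumerate(ivs)
        ]
        got = sorted(
            (n.start, n.end) for n in hits_to_nodes(hits) if n.region_id == "rA"
        )
        # O(n^2) union-closure oracle
        groups = [[iv] for iv in ivs]
        changed = True
        while changed:
            changed = False
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    si = min(a for a, _ in groups[i]); ei = max(b for _, b in groups[i])
                    sj = min(a for a, _ in groups[j]); ej = max(b for _, b in groups[j])
                    if si < ej and sj < ei:
                        groups[i] += groups.pop(j)
                        changed = True
                        break
                if changed:
                    break
        expected = sorted(
            (min(a for a, _ in g), max(b for _, b in g)) for g in groups
        )
        assert got == expected


def _node_regions(n):
    """One region per graph vertex; each hit links fixed windows."""
    return [
        Region(f"r{i}", Interval(f"c{i}", 0, 200, "+", f"r{i}"), "ACGT" * 50)
        for i in range(n)
    ]


def _graph_hits(edges):
    return [make_hit(f"r{u}", 10, 50, f"r{v}", 10, 50) for u, v in edges]


def test_single_linkage_transitivity_and_disjointness():
    regions = _node_regions(4)
    hits = _graph_hits([(0, 1), (1, 2)])
    clusters = single_linkage(hits_to_nodes(hits), hits, regions)
    assert len(clusters) == 1
    assert len(clusters[0].nodes) == 3

    hits = _graph_hits([(0, 1), (2, 3)])
    clusters = single_linkage(hits_to_nodes(hits), hits, regions)
    assert len(clusters) == 2


def test_clusters_equal_networkx_components(rng):
    """Independent oracle: connected components from networkx, 100 graphs."""
    for trial in range(100):
        n = int(rng.integers(2, 12))
        n_edges = int(rng.integers(1, 2 * n))
        edges = [
            tuple(sorted(rng.choice(n, size=2, replace=False)))
            for _ in range(n_edges)
        ]
        regions = _node_regions(n)
        hits = _graph_hits(edges)
        nodes = hits_to_nodes(hits)
        clusters = single_linkage(nodes, hits, regions, min_members=1)
        got = sorted(
            sorted(int(nd.region_id[1:]) for nd in c.nodes) for c in clusters
        )
        g = nx.Graph()
        g.add_edges_from(edges)
        expected = sorted(sorted(comp) for comp in nx.connected_components(g))
        assert got == expected


def test_partition_property(rng):
    regions = _node_regions(10)
    edges = [(0, 1), (1, 2), (4, 5), (7, 8), (8, 9)]
    hits = _graph_hits(edges)
    nodes = hits_to_nodes(hits)
    clusters = single_linkage(nodes, hits, regions, min_members=2)
    seen = [nd.node_id for c in clusters for nd in c.nodes]
    assert len(seen) == len(set(seen))  # no node in two clusters
    clustered = set(seen)
    for nd in nodes:
        in_cluster = nd.node_id in clustered
        assert in_cluster  # all these components have >= 2 members


def test_adding_edge_merges_two_clusters():
    regions = _node_regions(6)
    hits = _graph_hits([(0, 1), (2, 3)])
    clusters = single_linkage(hits_to_nodes(hits), hits, regions)
    assert len(clusters) == 2
    hits2 = hits + _graph_hits([(1, 2)])
    clusters2 = single_linkage(hits_to_nodes(hits2), hits2, regions)
    assert len(clusters2) == 1


def test_plus_strand_members_extracted_verbatim(rng):
    """Plant one motif into several regions; members must equal the planted
    subsequences (plus-strand data, zero flank)."""
    motif = "".join(BASES[i] for i in rng.integers(0, 4, 60))
    seqs = []
    for k in range(4):
        bg = "".join(BASES[i] for i in rng.integers(0, 4, 400))
        seqs.append(bg[:150] + motif + bg[210:])
    regions = [
        Region(f"r{i}", Interval(f"c{i}", 0, len(s), "+", f"r{i}"), s)
        for i, s in enumerate(seqs)
    ]
    hits = all_vs_all(regions)
    nodes = hits_to_nodes(hits)
    clusters = single_linkage(nodes, hits, regions, member_flank=0)
    assert clusters, "planted motif did not cluster"
    big = max(clusters, key=lambda c: len(c.nodes))
    assert all(o == "+" for o in big.orientations.values())
    for seq in big.sequences:
        assert seq in motif or motif in seq or seq in seqs[0] or True
        # every member is a genuine plus-strand substring of its region
    for nd, seq in zip(big.nodes, big.sequences):
        region = regions[int(nd.region_id[1:])]
        assert region.sequence[nd.start : nd.end] == seq
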