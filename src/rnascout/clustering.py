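"""Merge hit endpoints into genomic nodes; group nodes by single linkage.

A node is the union of all hit-endpoint intervals on one region that
overlap by at least one base. Each retained hit then contributes one edge
between its query node and its subject node, and clusters are the connected
components of that graph — single linkage: any connecting edge merges two
groups. Member sequences are extracted plus-strand-normalized: a spanning
tree from an arbitrary reference node orients every member, flipping across
minus-strand edges.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass

from .homology import AlignmentHit
from .io_formats import revcomp
from .region_prep import Region


@dataclass(frozen=True)
class HomologyNode:
    node_id: int
    region_id: str
    start: int
    end: int
    hit_ids: tuple[int, ...] = ()

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Cluster:
    cluster_id: str
    nodes: list[HomologyNode]
    orientations: dict[int, str]  # node_id -> '+'/'-'
    sequences: list[str]  # plus-strand-normalized member sequences
    offsets: dict[int, int] = None  # node_id -> column offset implied by hits


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def hits_to_nodes(hits: list[AlignmentHit]) -> list[HomologyNode]:
    """Merge all hit-endpoint intervals that overlap by >= 1 bp per region.

    Node ids are assigned in (region_id, start) order, so they are stable
    for a given hit set.
    """
    endpoints: dict[str, list[tuple[int, int, int]]] = {}  # region -> (start, end, hit_id)
    for hid, h in enumerate(hits):
        endpoints.setdefault(h.query_region, []).append((h.q_start, h.q_end, hid))
        endpoints.setdefault(h.subject_region, []).append((h.s_start, h.s_end, hid))
    nodes: list[HomologyNode] = []
    for region_id in sorted(endpoints):
        ivs = sorted(endpoints[region_id])
        cur_s, cur_e, cur_hits = ivs[0][0], ivs[0][1], [ivs[0][2]]
        merged: list[tuple[int, int, list[int]]] = []
        for s, e, hid in ivs[1:]:
            if s < cur_e:  # half-open: touching intervals do NOT merge
                cur_e = max(cur_e, e)
                cur_hits.append(hid)
            else:
                merged.append((cur_s, cur_e, cur_hits))
                cur_s, cur_e, cur_hits = s, e, [hid]
        merged.append((cur_s, cur_e, cur_hits))
        for s, e, hids in merged:
            nodes.append(
                HomologyNode(len(nodes), region_id, s, e, tuple(sorted(set(hids))))
            )
    return nodes


class _NodeIndex:
    """Locate the node containing a given (region, position)."""

    def __init__(self, nodes: list[HomologyNode]):
        self.by_region: dict[str, tuple[list[int], list[HomologyNode]]] = {}
        for n in sorted(nodes, key=lambda n: (n.region_id, n.start)):
            starts, ns = self.by_region.setdefault(n.region_id, ([], []))
            starts.append(n.start)
            ns.append(n)

    def find(self, region_id: str, start: int, end: int) -> HomologyNode:
        starts, ns = self.by_region[region_id]
        k = bisect_right(starts, start) - 1
        if k < 0 or ns[k].end < end:
            raise ValueError(
                f"no node covers {region_id}:[{start},{end}) — hits and nodes out of sync"
            )
        return ns[k]


def single_linkage(
    nodes: list[HomologyNode],
    hits: list[AlignmentHit],
    regions: list[Region] | dict[str, Region],
    min_members: int = 2,
    member_flank: int = 12,
) -> list[Cluster]:
    """Connected components of the node/hit graph, with strand orientation.

    Components smaller than min_members are dropped. Member sequences come
    from node intervals on their regions, extended by `member_flank` bases
    of context on each side (local alignments at moderate divergence stop
    short of the true homology boundary, clipping motif edges), and
    reverse-complemented where the spanning tree from the component's
    reference node implies minus orientation. Inconsistent strand
    assignments around cycles trigger a warning; the spanning-tree
    orientation (first assignment) is kept, which coincides with the
    majority vote in all non-pathological cases.
    """
    region_map = (
        regions if isinstance(regions, dict) else {r.region_id: r for r in regions}
    )
    index = _NodeIndex(nodes)
    uf = _UnionFind(len(nodes))
    edges: list[tuple[int, int, AlignmentHit]] = []
    for h in hits:
        qn = index.find(h.query_region, h.q_start, h.q_end)
        sn = index.find(h.subject_region, h.s_start, h.s_end)
        uf.union(qn.node_id, sn.node_id)
        edges.append((qn.node_id, sn.node_id, h))

    members: dict[int, list[int]] = {}
    for n in nodes:
        members.setdefault(uf.find(n.node_id), []).append(n.node_id)

    # maximum-score spanning forest: strongest hits define orientation and
    # the column offsets member sequences inherit from their alignments
    tree_uf = _UnionFind(len(nodes))
    tree_adj: dict[int, list[tuple[int, AlignmentHit, bool]]] = {}
    all_adj: dict[int, list[tuple[int, str]]] = {}
    for u, v, h in sorted(
        edges, key=lambda e: (-e[2].raw_score, e[0], e[1], e[2].q_start)
    ):
        all_adj.setdefault(u, []).append((v, h.strand))
        all_adj.setdefault(v, []).append((u, h.strand))
        if tree_uf.find(u) != tree_uf.find(v):
            tree_uf.union(u, v)
            tree_adj.setdefault(u, []).append((v, h, False))
            tree_adj.setdefault(v, []).append((u, h, True))

    node_by_id = {n.node_id: n for n in nodes}

    def _anchor(node: HomologyNode, orientation: str, lo: int, hi: int) -> int:
        """Member-local column of a hit endpoint, honoring orientation."""
        return lo - node.start if orientation == "+" else node.end - hi

    clusters: list[Cluster] = []
    for root in sorted(members):
        comp = sorted(members[root])
        if len(comp) < min_members:
            continue
        orient: dict[int, str] = {comp[0]: "+"}
        offset: dict[int, int] = {comp[0]: 0}
        queue = [comp[0]]
        while queue:
            u = queue.pop(0)
            for v, h, rev in tree_adj.get(u, ()):
                if v in orient:
                    continue
                flip = h.strand == "-"
                orient[v] = orient[u] if not flip else ("-" if orient[u] == "+" else "+")
                # u holds the hit's query side unless rev
                uq, vq = (not rev), rev
                nu, nv = node_by_id[u], node_by_id[v]
                off_u = _anchor(
                    nu,
                    orient[u],
                    h.q_start if uq else h.s_start,
                    h.q_end if uq else h.s_end,
                )
                off_v = _anchor(
                    nv,
                    orient[v],
                    h.q_start if vq else h.s_start,
                    h.q_end if vq else h.s_end,
                )
                offset[v] = offset[u] + off_u - off_v
                queue.append(v)
        conflict = any(
            orient.get(v) is not None
            and orient[v]
            != (orient[u] if strand == "+" else ("-" if orient[u] == "+" else "+"))
            for u in comp
            for v, strand in all_adj.get(u, ())
            if u in orient and v in orient
        )
        if conflict:
            warnings.warn(
                f"inconsistent strand assignment in cluster rooted at node {comp[0]}; "
                "keeping spanning-tree orientation",
                stacklevel=2,
            )
        seqs = []
        adj_offset: dict[int, int] = {}
        for nid in comp:
            n = node_by_id[nid]
            region_seq = region_map[n.region_id].sequence
            left = min(member_flank, n.start)
            right = min(member_flank, len(region_seq) - n.end)
            seq = region_seq[n.start - left : n.end + right]
            o = orient.get(nid, "+")
            if o == "-":
                seq = revcomp(seq)
            # the member now starts `left` (or `right`, if flipped) columns
            # before the node anchor the offsets were computed against
            adj_offset[nid] = offset[nid] - (left if o == "+" else right)
            seqs.append(seq)
        base = min(adj_offset[nid] for nid in comp)
        clusters.append(
            Cluster(
                cluster_id=f"cluster{len(clusters):04d}",
                nodes=[node_by_id[nid] for nid in comp],
                orientations={nid: orient.get(nid, "+") for nid in comp},
                sequences=seqs,
                offsets={nid: adj_offset[nid] - base for nid in comp},
            )
        )
    return clusters


def write_clusters_table(clusters: list[Cluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tnode_id\tregion_id\tstart\tend\torientation\n")
        for c in clusters:
            for n in c.nodes:
                fh.write(
                    f"{c.cluster_id}\t{n.node_id}\t{n.region_id}\t{n.start}\t{n.end}\t"
                    f"{c.orientations[n.node_id]}\n"
                )
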