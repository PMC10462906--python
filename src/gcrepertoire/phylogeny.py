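"""Per-clone lineage trees rooted on a germline-plus-consensus ancestor.

The root of a clone's tree is the unmutated V and J germline with the
junction filled by the clone's consensus: the best available proxy for the
founder B cell. Unique sequences are collapsed into weighted leaves and
joined by neighbor joining on the normalized Levenshtein distance — clone
members share a junction length, so distances are substitution-dominated
and NJ on these matrices is exact for additive data. The tree is then
re-rooted at the germline taxon.

Likelihood-based phylogenetics is out of scope by design: at thousands of
sequences per clone it is intractable, and the questions asked here
(distance of each GC's sequences to the root, mutations accumulated
before a crippling stop) only need a distance-based topology.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from ._strings import levenshtein, normalized_levenshtein
from .clones import Clone
from .germlines import j_gene_of, v_gene_of
from .io import RearrangementRecord

__all__ = [
    "TreeNode",
    "ClonalTree",
    "build_root",
    "clone_tree",
    "neighbor_joining",
    "root_distance_distribution",
    "mutations_before_crippling",
    "to_newick",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class TreeNode:
    name: str
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    sequence: str | None = None
    gc_counts: dict[str, int] = field(default_factory=dict)
    func_class: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    @property
    def weight(self) -> int:
        return sum(self.gc_counts.values())


@dataclass
class ClonalTree:
    clone_id: str
    root: TreeNode           # the germline+consensus taxon
    root_sequence: str

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.leaves() if n is not self.root]

    def total_length(self) -> float:
        def walk(node):
            return sum(bl + walk(c) for c, bl in node.children)
        return walk(self.root)


def build_root(clone: Clone, germlines_v: dict[str, str],
               germlines_j: dict[str, str]) -> str:
    """Unmutated V + consensus junction insert + unmutated J.

    The clone's consensus junction carries the conserved C and W codons,
    which overlap the last V codon and the first J codon, so those are
    trimmed from the germline parts.
    """
    vg, jg = v_gene_of(clone.v_gene), j_gene_of(clone.j_gene)
    if vg not in germlines_v:
        raise KeyError(f"unknown V germline {vg!r}")
    if jg not in germlines_j:
        raise KeyError(f"unknown J germline {jg!r}")
    return germlines_v[vg][:-3] + clone.consensus_junction + germlines_j[jg][3:]


def neighbor_joining(
    names: list[str], dist: np.ndarray,
) -> tuple[dict[int, TreeNode], list[tuple[int, int, float]]]:
    """Neighbor joining; deterministic (Q-matrix ties broken by node index).

    Returns (node map, undirected edge list (u, v, length)) over node ids;
    ids 0..n-1 are the input taxa in order, higher ids internal.
    """
    n = len(names)
    nodes = {i: TreeNode(names[i]) for i in range(n)}
    edges: list[tuple[int, int, float]] = []
    if n == 1:
        return nodes, edges
    if n == 2:
        edges.append((0, 1, float(dist[0, 1])))
        return nodes, edges
    D = dist.astype(float).copy()
    active = list(range(n))
    index_of = {i: i for i in active}  # node id -> row in D
    next_id = n
    while len(active) > 2:
        r = len(active)
        rows = [index_of[i] for i in active]
        sub = D[np.ix_(rows, rows)]
        R = sub.sum(axis=1)
        Q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest Q; ties -> smallest (node id_i, node id_j)
        flat = np.argwhere(Q == Q.min())
        pairs = sorted((min(active[a], active[b]), max(active[a], active[b]))
                       for a, b in flat)
        ni, nj = pairs[0]
        ai, aj = active.index(ni), active.index(nj)
        dij = sub[ai, aj]
        li = 0.5 * dij + (R[ai] - R[aj]) / (2 * (r - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = next_id
        next_id += 1
        nodes[new] = TreeNode(f"inner{new}")
        edges.append((new, ni, float(li)))
        edges.append((new, nj, float(lj)))
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (sub[ai, :] + sub[aj, :] - dij)
        row_idx = index_of[ni]  # reuse ni's slot
        for k, node_k in enumerate(active):
            D[row_idx, index_of[node_k]] = D[index_of[node_k], row_idx] = new_row[k]
        D[row_idx, row_idx] = 0.0
        index_of[new] = row_idx
        active = [a for a in active if a not in (ni, nj)] + [new]
    i, j = active
    edges.append((i, j, float(D[index_of[i], index_of[j]])))
    return nodes, edges


def _orient(nodes: dict[int, TreeNode], edges, root_id: int) -> TreeNode:
    adj: dict[int, list[tuple[int, float]]] = defaultdict(list)
    for u, v, l in edges:
        adj[u].append((v, l))
        adj[v].append((u, l))
    seen = {root_id}

    def attach(u: int) -> None:
        for v, l in sorted(adj[u]):
            if v not in seen:
                seen.add(v)
                nodes[u].children.append((nodes[v], l))
                attach(v)

    attach(root_id)
    return nodes[root_id]


ROOT_NAME = "germline_root"


def clone_tree(
    clone: Clone,
    root_sequence: str,
    records: dict[str, RearrangementRecord],
    labels: dict[str, str] | None = None,
    max_leaves: int = 300,
) -> ClonalTree:
    """Build the rooted lineage tree of one clone.

    Unique member sequences are collapsed into leaves (weights and per-GC
    counts kept); at most ``max_leaves`` leaves are retained, by
    abundance. The germline root is included as a taxon and the NJ tree
    is re-rooted on it.
    """
    by_seq: dict[str, dict] = {}
    for sid in clone.member_ids:
        rec = records[sid]
        info = by_seq.setdefault(rec.sequence, {
            "name": rec.sequence_id, "gc_counts": defaultdict(int), "class": None})
        info["gc_counts"][rec.gc_id] += rec.duplicate_count
        info["name"] = min(info["name"], rec.sequence_id)
        if labels:
            info["class"] = labels.get(rec.sequence_id, info["class"])
    uniq = sorted(
        by_seq.items(),
        key=lambda kv: (-sum(kv[1]["gc_counts"].values()), kv[1]["name"]),
    )[:max_leaves]

    names = [ROOT_NAME] + [info["name"] for _, info in uniq]
    seqs = [root_sequence] + [s for s, _ in uniq]
    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = normalized_levenshtein(seqs[i], seqs[j])
    nodes, edges = neighbor_joining(names, dist)
    for i, (s, info) in enumerate(uniq, start=1):
        nodes[i].sequence = s
        nodes[i].gc_counts = dict(info["gc_counts"])
        nodes[i].func_class = info["class"]
    nodes[0].sequence = root_sequence
    root = _orient(nodes, edges, 0)
    return ClonalTree(clone.clone_id, root, root_sequence)


def root_distance_distribution(tree: ClonalTree) -> dict[str, list[float]]:
    """Per-GC distribution of leaf-to-root sequence similarity
    (1 - normalized Levenshtein), one entry per cell."""
    out: dict[str, list[float]] = defaultdict(list)
    for leaf in tree.leaves():
        sim = 1.0 - normalized_levenshtein(leaf.sequence, tree.root_sequence)
        for gc, cnt in leaf.gc_counts.items():
            out[gc].extend([sim] * cnt)
    return dict(out)


def _stop_codon_spans(seq: str) -> list[tuple[int, int]]:
    return [(i, i + 3) for i in range(0, len(seq) - 2, 3)
            if seq[i : i + 3] in STOP_CODONS]


def _count_pre_crippling(seq: str, root: str) -> int:
    """Mutations vs the root excluding those inside stop codons the root
    does not carry (the crippling event itself)."""
    if len(seq) != len(root):
        return max(0, levenshtein(seq, root) - 1)
    root_stops = set(_stop_codon_spans(root))
    crippling = [sp for sp in _stop_codon_spans(seq) if sp not in root_stops]
    count = 0
    for i, (a, b) in enumerate(zip(root, seq)):
        if a == b:
            continue
        if any(s <= i < e for s, e in crippling):
            continue
        count += 1
    return count


def mutations_before_crippling(tree: ClonalTree) -> float:
    """Mean number of mutations accumulated before the crippling stop.

    For each maximal subtree whose leaves are all non-functional, the
    member sequence closest to the root represents the earliest sampled
    descendant of the crippling event; its mutation count vs the root —
    excluding the stop-creating mutation itself — estimates how long the
    lineage evolved before being crippled.
    """
    root_seq = tree.root_sequence

    nf_subtrees: list[TreeNode] = []

    def all_nf(node: TreeNode) -> bool:
        leaves = [n for n in node.leaves() if n.name != ROOT_NAME]
        return bool(leaves) and all(
            l.func_class is not None and l.func_class != "functional"
            for l in leaves)

    def walk(node: TreeNode) -> None:
        for child, _ in node.children:
            if all_nf(child):
                nf_subtrees.append(child)
            else:
                walk(child)

    walk(tree.root)
    if not nf_subtrees:
        raise ValueError(f"clone {tree.clone_id}: no non-functional leaves")
    counts = []
    for sub in nf_subtrees:
        leaves = [n for n in sub.leaves() if n.name != ROOT_NAME]
        closest = min(
            leaves, key=lambda l: (levenshtein(l.sequence, root_seq), l.name))
        counts.append(_count_pre_crippling(closest.sequence, root_seq))
    return float(np.mean(counts))


def _escape(label: str) -> str:
    for ch in "();,:[] '\"":
        label = label.replace(ch, "_")
    return label


def to_newick(tree: ClonalTree) -> str:
    """Newick export with branch lengths; leaf labels ``seqid|gc|count``
    (gc = the GC contributing most cells to the leaf)."""

    def label(node: TreeNode) -> str:
        if node.name == ROOT_NAME:
            return ROOT_NAME
        top_gc = max(node.gc_counts.items(), key=lambda kv: (kv[1], kv[0]))[0] \
            if node.gc_counts else "NA"
        return _escape(f"{node.name}|{top_gc}|{node.weight}")

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return label(node)
        inner = ",".join(f"{fmt(c)}:{bl:.6f}" for c, bl in node.children)
        return f"({inner}){label(node) if node.sequence else ''}"

    return fmt(tree.root) + ";"
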