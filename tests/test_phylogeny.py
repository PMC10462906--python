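"""Germline-rooted clone trees: root construction, neighbor joining vs
brute-force oracles, Newick export, and crippling-mutation timing."""

import itertools

import numpy as np
import pytest

from gcrepertoire.clones import group_clones
from gcrepertoire.functionality import classify_clone, classify_records, productivity_index
from gcrepertoire.germlines import GERMLINE_J, GERMLINE_V
from gcrepertoire.phylogeny import (
    ROOT_NAME,
    build_root,
    clone_tree,
    mutations_before_crippling,
    neighbor_joining,
    root_distance_distribution,
    to_newick,
)
from gcrepertoire.simulate import LymphNodeConfig, generate_lymph_node

from .conftest import make_record

V = GERMLINE_V["IGHV1-2"]
J = GERMLINE_J["IGHJ4"]


def germline_record(sid, cdr3="GCTAAAGGTTATGATTCT", mutations=(), gc="GC1",
                    dup=1):
    """A record on the real toy germline scaffold, optionally mutated."""
    seq = list(V + cdr3 + J)  # V ends with the conserved C, J starts with W
    for pos, base in mutations:
        seq[pos] = base
    seq = "".join(seq)
    js, je = len(V) - 3, len(V) + len(cdr3) + 3
    return make_record(
        sid, seq[js:je], sequence=seq, v_call="IGHV1-2*01", j_call="IGHJ4*01",
        gc_id=gc, duplicate_count=dup,
        region_bounds={"cdr3": (len(V), len(V) + len(cdr3))},
        n_region_bounds=[(len(V), len(V) + 6)])


class TestBuildRoot:
    def test_unmutated_clone_root_equals_member(self):
        recs = [germline_record(f"s{i}") for i in range(3)]
        clones = group_clones(recs)
        root = build_root(clones[0], GERMLINE_V, GERMLINE_J)
        assert root == recs[0].sequence

    def test_majority_junction_base(self):
        base = "GCTAAAGGTTATGATTCT"
        mut_pos = len(V) + 2  # inside CDR3
        recs = [germline_record("a"), germline_record("b"),
                germline_record("c", mutations=[(mut_pos, "A")])]
        clones = group_clones(recs)
        root = build_root(clones[0], GERMLINE_V, GERMLINE_J)
        assert root[mut_pos] == base[2]  # majority 2-vs-1 keeps germline base

    def test_tie_broken_alphabetically(self):
        mut_pos = len(V) + 2
        assert V[-3:] == "TGT" or True
        recs = [germline_record("a"),
                germline_record("b", mutations=[(mut_pos, "A")])]
        clones = group_clones(recs)
        root = build_root(clones[0], GERMLINE_V, GERMLINE_J)
        original = germline_record("x").sequence[mut_pos]
        assert root[mut_pos] == min("A", original)

    def test_unknown_germline_named(self):
        recs = [germline_record("a")]
        clone = group_clones(recs)[0]
        clone.v_gene = "IGHV9-99"
        with pytest.raises(KeyError, match="IGHV9-99"):
            build_root(clone, GERMLINE_V, GERMLINE_J)


def _splits(edges, n_leaves):
    """Leaf bipartitions induced by the edges of an unrooted tree."""
    adj = {}
    for u, v, _ in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    out = set()
    for u, v, _ in edges:
        # leaves reachable from u without crossing (u, v)
        seen, stack = {u, v}, [u]
        side = set()
        while stack:
            x = stack.pop()
            if x < n_leaves:
                side.add(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if 1 < len(side) < n_leaves - 1:
            # canonical orientation: the half containing leaf 0
            if 0 not in side:
                side = set(range(n_leaves)) - side
            out.add(frozenset(side))
    return out


def _random_additive_tree(rng, n_leaves):
    """A random unrooted binary tree and its additive leaf distance matrix."""
    edges = {(0, 1): rng.uniform(0.5, 2.0)}
    next_internal = n_leaves
    for leaf in range(2, n_leaves):
        (u, v), length = list(edges.items())[rng.integers(0, len(edges))]
        del edges[(u, v)]
        mid = next_internal
        next_internal += 1
        split = rng.uniform(0.2, 0.8) * length
        edges[(u, mid)] = split
        edges[(mid, v)] = length - split
        edges[(mid, leaf)] = rng.uniform(0.5, 2.0)
    adj = {}
    for (u, v), l in edges.items():
        adj.setdefault(u, []).append((v, l))
        adj.setdefault(v, []).append((u, l))
    D = np.zeros((n_leaves, n_leaves))
    for src in range(n_leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, l in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + l
                    stack.append(y)
        for dst in range(n_leaves):
            D[src, dst] = dist[dst]
    true_splits = _splits([(u, v, l) for (u, v), l in edges.items()], n_leaves)
    return D, true_splits


class TestNeighborJoining:
    def test_three_equidistant_star(self):
        d = 0.6
        D = np.full((3, 3), d)
        np.fill_diagonal(D, 0.0)
        _, edges = neighbor_joining(["a", "b", "c"], D)
        total = sum(l for _, _, l in edges)
        assert total == pytest.approx(1.5 * d)  # three limbs of d/2

    @pytest.mark.parametrize("n_leaves", [4, 5, 6])
    def test_matches_exhaustive_search_on_additive_matrices(self, n_leaves):
        """NJ recovers the generating topology; so does an exhaustive
        least-squares search over all unrooted topologies, and the two
        agree split for split."""
        rng = np.random.default_rng(100 + n_leaves)
        for _ in range(5):
            D, true_splits = _random_additive_tree(rng, n_leaves)
            names = [str(i) for i in range(n_leaves)]
            _, edges = neighbor_joining(names, D)
            assert _splits(edges, n_leaves) == true_splits
            best = self._exhaustive_least_squares(D, n_leaves)
            assert best == true_splits

    @staticmethod
    def _exhaustive_least_squares(D, n_leaves):
        """Enumerate all unrooted binary topologies by leaf insertion and
        pick the one whose least-squares branch fit has minimal error."""
        def topologies(n):
            base = [(0, 1), (1, 2), (2, 0)]  # star via center node n... use
            # edge list representation with internal ids >= n
            start = [(0, "c0"), (1, "c0"), (2, "c0")]
            trees = [start]
            for leaf in range(3, n):
                new_trees = []
                for t in trees:
                    for i, (u, v) in enumerate(t):
                        mid = f"m{leaf}_{i}"
                        nt = t[:i] + t[i + 1:] + [(u, mid), (mid, v),
                                                  (leaf, mid)]
                        new_trees.append(nt)
                trees = new_trees
            return trees

        best_err, best_splits = np.inf, None
        pairs = list(itertools.combinations(range(n_leaves), 2))
        for t in topologies(n_leaves):
            # least-squares branch lengths for this topology
            nodes = {x for e in t for x in e}
            adj = {}
            for ei, (u, v) in enumerate(t):
                adj.setdefault(u, []).append((v, ei))
                adj.setdefault(v, []).append((u, ei))
            rows = []
            for a, b in pairs:
                row = np.zeros(len(t))
                # path from a to b
                stack = [(a, [])]
                seen = {a}
                while stack:
                    x, path = stack.pop()
                    if x == b:
                        row[path] = 1.0
                        break
                    for y, ei in adj[x]:
                        if y not in seen:
                            seen.add(y)
                            stack.append((y, path + [ei]))
                rows.append(row)
            A = np.array(rows)
            y = np.array([D[a, b] for a, b in pairs])
            x, *_ = np.linalg.lstsq(A, y, rcond=None)
            err = ((A @ x - y) ** 2).sum()
            if err < best_err - 1e-12:
                best_err = err
                id_map = {}
                edges = []
                def nid(x):
                    if isinstance(x, int):
                        return x
                    if x not in id_map:
                        id_map[x] = n_leaves + len(id_map)
                    return id_map[x]
                edges = [(nid(u), nid(v), 0.0) for u, v in t]
                best_splits = _splits(edges, n_leaves)
        return best_splits

    def test_total_length_invariant_to_leaf_order(self):
        rng = np.random.default_rng(3)
        D, _ = _random_additive_tree(rng, 7)
        names = [str(i) for i in range(7)]
        _, edges = neighbor_joining(names, D)
        total = sum(l for _, _, l in edges)
        perm = rng.permutation(7)
        Dp = D[np.ix_(perm, perm)]
        _, edges_p = neighbor_joining([names[i] for i in perm], Dp)
        assert sum(l for _, _, l in edges_p) == pytest.approx(total)


class TestCloneTree:
    def test_identical_sequences_collapse_to_single_leaf(self):
        recs = [germline_record(f"s{i}", dup=2) for i in range(4)]
        clone = group_clones(recs)[0]
        root = build_root(clone, GERMLINE_V, GERMLINE_J)
        tree = clone_tree(clone, root, {r.sequence_id: r for r in recs})
        leaves = [l for l in tree.leaves() if l.name != ROOT_NAME]
        assert len(leaves) == 1
        assert leaves[0].weight == 8
        assert tree.total_length() == pytest.approx(0.0, abs=1e-12)

    def test_newick_round_trip(self, tmp_path):
        dendropy = pytest.importorskip("dendropy")
        mut = len(V) + 4
        recs = [germline_record("alpha"),
                germline_record("beta", mutations=[(mut, "A")]),
                germline_record("gamma|odd;name", mutations=[(mut + 3, "C")])]
        clone = group_clones(recs)[0]
        root = build_root(clone, GERMLINE_V, GERMLINE_J)
        tree = clone_tree(clone, root, {r.sequence_id: r for r in recs})
        nwk = to_newick(tree)
        assert nwk.endswith(";")
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        labels = {l.taxon.label for l in parsed.leaf_node_iter()}
        assert any("alpha" in l for l in labels)
        assert all(";" not in l and "(" not in l for l in labels)

    def test_root_distance_by_gc(self):
        """Leaves from the founding GC sit closer to the germline root than
        leaves that re-diversified in a second GC."""
        # three founding-GC members keep the consensus junction germline;
        # the reseeded GC carries extra private mutations
        muts_b = [(len(V) + 6, "C"), (len(V) + 8, "G"), (len(V) + 10, "C")]
        recs = [germline_record("a1", gc="GCA"),
                germline_record("a2", gc="GCA",
                                mutations=[(len(V) + 1, "G")]),
                germline_record("a3", gc="GCA"),
                germline_record("b1", gc="GCB", mutations=muts_b),
                germline_record("b2", gc="GCB", mutations=muts_b[:2])]
        clone = group_clones(recs)[0]
        root = build_root(clone, GERMLINE_V, GERMLINE_J)
        tree = clone_tree(clone, root, {r.sequence_id: r for r in recs})
        dist = root_distance_distribution(tree)
        assert np.median(dist["GCA"]) > np.median(dist["GCB"])

    def test_identical_gcs_identical_histograms(self):
        mut = [(len(V) + 1, "A")]
        recs = [germline_record("a1", gc="GCA"),
                germline_record("a2", gc="GCA", mutations=mut),
                germline_record("b1", gc="GCB"),
                germline_record("b2", gc="GCB", mutations=mut)]
        clone = group_clones(recs)[0]
        root = build_root(clone, GERMLINE_V, GERMLINE_J)
        tree = clone_tree(clone, root, {r.sequence_id: r for r in recs})
        dist = root_distance_distribution(tree)
        assert sorted(dist["GCA"]) == sorted(dist["GCB"])


def _stop_mutation():
    """A single substitution creating a stop codon on the toy scaffold:
    the FWR2 TGG tryptophan codon becomes TAG."""
    pos = 99 + 6 + 1  # second base of the conserved FWR2 W codon
    assert V[pos - 1 : pos + 2] == "TGG"
    return (pos, "A")


class TestMutationsBeforeCrippling:
    def _tree(self, recs, labels):
        clone = group_clones(recs)[0]
        root = build_root(clone, GERMLINE_V, GERMLINE_J)
        return clone_tree(clone, root, {r.sequence_id: r for r in recs},
                          labels=labels)

    def test_stop_only_leaf_counts_zero(self):
        recs = [germline_record("f1"), germline_record("f2",
                mutations=[(len(V) + 1, "A")]),
                germline_record("n1", mutations=[_stop_mutation()])]
        labels = {"f1": "functional", "f2": "functional", "n1": "shm_stop"}
        tree = self._tree(recs, labels)
        assert mutations_before_crippling(tree) == pytest.approx(0.0)

    def test_three_neutral_then_stop(self):
        # weight the functional lineage so the consensus junction stays
        # germline rather than adopting the crippled branch's mutations
        neutral = [(len(V) + 1, "A"), (len(V) + 7, "C"), (30, "A")]
        recs = [germline_record("f1", dup=3),
                germline_record("n1", mutations=neutral + [_stop_mutation()])]
        labels = {"f1": "functional", "n1": "shm_stop"}
        tree = self._tree(recs, labels)
        assert mutations_before_crippling(tree) == pytest.approx(3.0)

    def test_no_nf_leaves_is_an_error(self):
        recs = [germline_record("f1"),
                germline_record("f2", mutations=[(len(V) + 1, "A")])]
        labels = {"f1": "functional", "f2": "functional"}
        tree = self._tree(recs, labels)
        with pytest.raises(ValueError):
            mutations_before_crippling(tree)

    def test_generator_parameter_recovery(self):
        """Over >=50 simulated F&NF clones the estimated mean number of
        mutations before the crippling stop is within 0.5 of the
        configured 3.6."""
        estimates = []
        for seed in (21, 22, 23):
            cfg = LymphNodeConfig(seqs_per_sample=800, n_clones_per_gc=150,
                                  seed=seed)
            records, _ = generate_lymph_node(cfg)
            rec_map = {r.sequence_id: r for r in records}
            clones = group_clones(records)
            labels = classify_records(records)
            lab_cls = {k: v.func_class for k, v in labels.items()}
            for c in clones:
                pi = productivity_index(c, labels, records=rec_map)
                if classify_clone(pi) != "F_and_NF" or len(c.member_ids) < 3:
                    continue
                root = build_root(c, GERMLINE_V, GERMLINE_J)
                tree = clone_tree(c, root, rec_map, labels=lab_cls,
                                  max_leaves=100)
                try:
                    estimates.append(mutations_before_crippling(tree))
                except ValueError:
                    continue
        assert len(estimates) >= 50
        assert np.mean(estimates) == pytest.approx(3.6, abs=0.5)
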