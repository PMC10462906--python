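"""Grouping rearrangements into clones and optimizing the identity threshold.

A clone is the set of sequences presumed to descend from one founder B
cell: same V gene, same J gene, same CDR3 length, and junction nucleotide
identity above a threshold (default 84%, as optimized from the
distance-to-nearest distribution). Because CDR3 length equality is a hard
key, identity within a partition is Hamming-based; clustering is
agglomerative with single linkage by default, which reproduces the
chaining behaviour clonal lineages require.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as _scipy_linkage
from scipy.spatial.distance import squareform
from scipy.stats import gaussian_kde

from ._strings import hamming_identity
from .germlines import j_gene_of, v_gene_of, v_subgroup_of
from .io import RearrangementRecord

logger = logging.getLogger(__name__)

__all__ = [
    "Clone",
    "CDR3Group",
    "ThresholdDiagnostics",
    "junction_identity",
    "group_clones",
    "optimize_threshold",
    "merge_same_subgroup",
    "group_by_cdr3",
]

DEFAULT_THRESHOLD = 0.84


@dataclass
class Clone:
    clone_id: str
    v_subgroup: str
    v_gene: str
    j_gene: str
    junction_length: int
    member_ids: list[str]
    abundance: int
    frequency: float
    consensus_junction: str
    representative_id: str
    representative: RearrangementRecord | None = None
    per_sample_abundance: dict[tuple[str, str], int] = field(default_factory=dict)
    productivity_index: float | None = None
    functionality_class: str | None = None

    def samples(self) -> set[tuple[str, str]]:
        return set(self.per_sample_abundance)

    def gc_abundance(self, gc_id: str) -> int:
        return sum(v for (g, _), v in self.per_sample_abundance.items() if g == gc_id)


@dataclass
class CDR3Group:
    """Exact-match grouping on the translated junction, V/J-agnostic."""

    cdr3_aa: str
    member_ids: list[str]
    abundance: int
    per_sample_abundance: dict[tuple[str, str], int] = field(default_factory=dict)


@dataclass
class ThresholdDiagnostics:
    within_distances: np.ndarray
    negation_distances: np.ndarray
    chosen_threshold: float | None


def junction_identity(j1: str, j2: str) -> float:
    """Fraction of identical positions between two equal-length junctions."""
    return hamming_identity(j1, j2)


def _consensus(strings: list[str], weights: list[int]) -> str:
    """Position-wise weighted majority; ties broken alphabetically."""
    arr = np.array([np.frombuffer(s.encode("ascii"), dtype=np.uint8) for s in strings])
    w = np.asarray(weights, dtype=float)
    out = bytearray()
    for col in arr.T:
        best, best_w = None, -1.0
        totals: dict[int, float] = {}
        for b, wi in zip(col, w):
            totals[int(b)] = totals.get(int(b), 0.0) + wi
        for b in sorted(totals):  # alphabetical tie-break (byte order)
            if totals[b] > best_w:
                best, best_w = b, totals[b]
        out.append(best)
    return out.decode("ascii")


def _cluster_junctions(junctions: list[str], cutoff: float, method: str) -> list[int]:
    """Cluster equal-length junction strings at Hamming distance < cutoff."""
    n = len(junctions)
    if n == 1:
        return [0]
    arr = np.array(
        [np.frombuffer(s.encode("ascii"), dtype=np.uint8) for s in junctions])
    dist = (arr[:, None, :] != arr[None, :, :]).mean(axis=2)
    condensed = squareform(dist, checks=False)
    z = _scipy_linkage(condensed, method=method)
    # merge strictly below the cutoff (identity strictly above threshold)
    labels = fcluster(z, t=cutoff - 1e-9, criterion="distance")
    return [int(x) - 1 for x in labels]


def group_clones(
    records: list[RearrangementRecord],
    threshold: float = DEFAULT_THRESHOLD,
    linkage: str = "single",
) -> list[Clone]:
    """Partition records into clones.

    Records are first split by (V gene, J gene, junction length) — calls
    collapsed to gene level — then clustered on junction distance
    (1 - identity) with the requested agglomerative linkage, cut so that
    members join only above the identity threshold. The result is
    deterministic and invariant to the input order.
    """
    usable = [r for r in records if r.junction]
    skipped = len(records) - len(usable)
    if skipped:
        logger.info("group_clones: excluded %d record(s) without a junction", skipped)
    total = sum(r.duplicate_count for r in usable)

    partitions: dict[tuple[str, str, int], list[RearrangementRecord]] = defaultdict(list)
    for r in usable:
        partitions[(v_gene_of(r.v_call), j_gene_of(r.j_call), r.junction_length)].append(r)

    clones: list[Clone] = []
    for (vg, jg, jl), recs in sorted(partitions.items()):
        # cluster on unique junctions so the outcome cannot depend on
        # record multiplicity or ordering
        uniq = sorted({r.junction for r in recs})
        labels = _cluster_junctions(uniq, 1.0 - threshold, linkage)
        label_of = dict(zip(uniq, labels))
        members: dict[int, list[RearrangementRecord]] = defaultdict(list)
        for r in recs:
            members[label_of[r.junction]].append(r)
        groups = sorted(
            members.values(),
            key=lambda ms: (-sum(m.duplicate_count for m in ms),
                            min(m.sequence_id for m in ms)),
        )
        for k, ms in enumerate(groups):
            ms = sorted(ms, key=lambda m: m.sequence_id)
            abundance = sum(m.duplicate_count for m in ms)
            # most abundant member; tie -> lexicographically smallest id
            best = max(m.duplicate_count for m in ms)
            rep = min((m for m in ms if m.duplicate_count == best),
                      key=lambda m: m.sequence_id)
            per_sample: dict[tuple[str, str], int] = defaultdict(int)
            for m in ms:
                per_sample[(m.gc_id, m.replicate_id)] += m.duplicate_count
            suffix = f"_{k + 1}" if len(groups) > 1 else ""
            clones.append(Clone(
                clone_id=f"{vg}_{jl}_{jg}{suffix}",
                v_subgroup=v_subgroup_of(vg),
                v_gene=vg,
                j_gene=jg,
                junction_length=jl,
                member_ids=[m.sequence_id for m in ms],
                abundance=abundance,
                frequency=abundance / total if total else 0.0,
                consensus_junction=_consensus(
                    [m.junction for m in ms], [m.duplicate_count for m in ms]),
                representative_id=rep.sequence_id,
                representative=rep,
                per_sample_abundance=dict(per_sample),
            ))
    return clones


def _nearest_distances(records, others=None) -> np.ndarray:
    """Distance to the nearest same-(V, J, length) neighbour.

    With ``others`` given, distances are measured against that set
    (negation-table mode); otherwise within the record set itself.
    """
    def parts(recs):
        d = defaultdict(list)
        for r in recs:
            if r.junction:
                d[(v_gene_of(r.v_call), j_gene_of(r.j_call), r.junction_length)].append(
                    r.junction)
        return d

    own = parts(records)
    ref = parts(others) if others is not None else own
    out = []
    for key, juncs in own.items():
        pool = ref.get(key, [])
        arr_own = np.array(
            [np.frombuffer(s.encode("ascii"), dtype=np.uint8) for s in juncs])
        if others is None:
            if len(juncs) < 2:
                continue
            dist = (arr_own[:, None, :] != arr_own[None, :, :]).mean(axis=2)
            np.fill_diagonal(dist, np.inf)
            out.extend(dist.min(axis=1).tolist())
        else:
            if not pool:
                continue
            arr_ref = np.array(
                [np.frombuffer(s.encode("ascii"), dtype=np.uint8) for s in pool])
            dist = (arr_own[:, None, :] != arr_ref[None, :, :]).mean(axis=2)
            out.extend(dist.min(axis=1).tolist())
    return np.asarray(out)


def optimize_threshold(
    records: list[RearrangementRecord],
    negation_records: list[RearrangementRecord],
) -> ThresholdDiagnostics:
    """Choose the clonal identity threshold from nearest-distance modes.

    The within-sample nearest-distance distribution concentrates at small
    distances (clonal relatives); distances to a negation set (sequences
    from a different individual) concentrate at large ones. The threshold
    is 1 - d*, where d* is the density minimum between the two modes of
    the pooled distribution (Gaussian KDE, Silverman bandwidth).
    """
    if len(records) < 100 or len(negation_records) < 100:
        raise ValueError("optimize_threshold requires >= 100 records in each set")
    within = _nearest_distances(records)
    negation = _nearest_distances(records, negation_records)
    grid = np.linspace(0.0, 1.0, 501)
    # equal-weight mixture of per-component KDEs: a pooled-bandwidth KDE
    # oversmooths the (much tighter) clonal mode and drifts the valley
    dens = np.zeros_like(grid)
    for sample in (within, negation):
        if np.ptp(sample) > 0:
            dens += 0.5 * gaussian_kde(sample, bw_method="silverman")(grid)
        else:  # degenerate point mass
            dens += 0.5 * (np.abs(grid - sample[0]) < 2e-3) / 4e-3
    mid = 0.5 * (float(np.median(within)) + float(np.median(negation)))
    within_mode = float(grid[np.argmax(np.where(grid <= mid, dens, -np.inf))])
    neg_mode = float(grid[np.argmax(np.where(grid >= mid, dens, -np.inf))])
    lo = np.searchsorted(grid, within_mode)
    hi = np.searchsorted(grid, neg_mode)
    chosen = None
    if hi > lo + 1:
        valley = dens[lo:hi + 1]
        j = int(np.argmin(valley)) + lo
        # a genuine interior minimum, not a monotone slope
        if dens[j] < dens[lo] and dens[j] < dens[hi]:
            chosen = float(1.0 - grid[j])
    if chosen is None:
        warnings.warn(
            "nearest-distance distribution has no valley between modes; "
            "threshold left unset", stacklevel=2)
    return ThresholdDiagnostics(within, negation, chosen)


def merge_same_subgroup(clones: list[Clone]) -> list[Clone]:
    """Merge clones from the same V subgroup whose representative
    junctions are identical (different V genes can be near-identical and
    mis-called within a subgroup)."""
    by_key: dict[tuple, list[Clone]] = defaultdict(list)
    for c in clones:
        key = (c.v_subgroup, c.j_gene, c.junction_length,
               c.representative.junction if c.representative else c.consensus_junction)
        by_key[key].append(c)
    out: list[Clone] = []
    for key, group in by_key.items():
        if len(group) == 1:
            out.append(group[0])
            continue
        group = sorted(group, key=lambda c: (-c.abundance, c.clone_id))
        keeper = group[0]
        merged = Clone(
            clone_id=keeper.clone_id,
            v_subgroup=keeper.v_subgroup,
            v_gene=keeper.v_gene,
            j_gene=keeper.j_gene,
            junction_length=keeper.junction_length,
            member_ids=sorted(m for c in group for m in c.member_ids),
            abundance=sum(c.abundance for c in group),
            frequency=sum(c.frequency for c in group),
            consensus_junction=keeper.consensus_junction,
            representative_id=keeper.representative_id,
            representative=keeper.representative,
            per_sample_abundance=_sum_maps(c.per_sample_abundance for c in group),
        )
        out.append(merged)
    return out


def _sum_maps(maps) -> dict:
    total: dict = defaultdict(int)
    for m in maps:
        for k, v in m.items():
            total[k] += v
    return dict(total)


def group_by_cdr3(records: list[RearrangementRecord]) -> list[CDR3Group]:
    """Group records by identical translated junction, ignoring V and J.

    Out-of-frame (untranslatable) junctions are excluded with a logged
    count. Used for the shared-CDR3 analysis, where continued SHM in the
    new GC breaks exact identity far more often than it breaks clonal
    identity.
    """
    from Bio.Seq import Seq

    groups: dict[str, list[RearrangementRecord]] = defaultdict(list)
    skipped = 0
    for r in records:
        if not r.in_frame_junction or r.junction_length % 3 != 0:
            skipped += 1
            continue
        aa = str(Seq(r.junction).translate())
        groups[aa].append(r)
    if skipped:
        logger.info("group_by_cdr3: excluded %d untranslatable junction(s)", skipped)
    out = []
    for aa in sorted(groups):
        ms = groups[aa]
        per_sample: dict[tuple[str, str], int] = defaultdict(int)
        for m in ms:
            per_sample[(m.gc_id, m.replicate_id)] += m.duplicate_count
        out.append(CDR3Group(
            cdr3_aa=aa,
            member_ids=sorted(m.sequence_id for m in ms),
            abundance=sum(m.duplicate_count for m in ms),
            per_sample_abundance=dict(per_sample),
        ))
    return out
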