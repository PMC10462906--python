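"""Functionality classification, allele pairing and SHM summaries.

Sequences fall into four classes: functional, out-of-frame (frameshifted
junction), and in-frame non-functional with an early stop codon derived
either from V(D)J recombination (the stop overlaps a non-templated N
region) or from SHM (the stop lies outside the N regions). Frame status
takes precedence over stop scanning. Clones are functional (F) above 95%
productive members, non-functional (NF) below 5%, and F&NF in between —
the F&NF clones are the ones in which a crippling SHM event was caught in
the act.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .clones import Clone
from .io import RearrangementRecord

__all__ = [
    "FunctionalityLabel",
    "AllelePair",
    "MutationSummary",
    "classify_sequence",
    "classify_records",
    "productivity_index",
    "classify_clone",
    "pair_alleles",
    "mutational_spectrum",
    "rs_counts",
    "rs_ratio",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class FunctionalityLabel:
    func_class: str  # functional | out_of_frame | vdj_stop | shm_stop
    stop_positions: list[int] = field(default_factory=list)  # codon indices


@dataclass
class AllelePair:
    functional_clone_id: str
    nonfunctional_clone_id: str
    abundance_ratio: float  # NF / F
    co_occurrence: set = field(default_factory=set)


@dataclass
class MutationSummary:
    """Aggregated SHM profile over clones.

    ``per_position`` has one row per anchored position key with mutation
    and coverage counts; ``substitution_table`` is the 4x4 reference-base
    by observed-base count matrix (A, C, G, T; zero diagonal).
    """

    per_position: pd.DataFrame
    substitution_table: np.ndarray
    n_clones_used: int
    n_singletons_skipped: int

    def region_means(self) -> dict[str, float]:
        df = self.per_position
        out = {}
        for region in ("CDR", "FWR"):
            sub = df[df["region_class"] == region]
            out[region] = float(sub["mutations"].sum() / max(sub["coverage"].sum(), 1))
        return out


def _stop_codon_indices(sequence: str) -> list[int]:
    out = []
    for i in range(0, len(sequence) - 2, 3):
        if sequence[i : i + 3] in STOP_CODONS:
            out.append(i // 3)
    return out


def classify_sequence(record: RearrangementRecord) -> FunctionalityLabel:
    """Assign exactly one functionality class to a rearrangement.

    Precedence: frameshift first; then any in-frame stop codon whose
    3-nt span overlaps an N-region interval by at least one nucleotide
    means a recombination-derived stop (vdj_stop); stops only outside the
    N regions are SHM-derived (shm_stop).
    """
    if not record.in_frame_junction:
        return FunctionalityLabel("out_of_frame")
    stops = _stop_codon_indices(record.sequence)
    if not stops:
        return FunctionalityLabel("functional")
    if not record.n_region_bounds:
        raise ValueError(
            f"{record.sequence_id}: in-frame stop codon but no N-region bounds; "
            "cannot separate recombination-derived from SHM-derived stops")
    for codon_idx in stops:
        s, e = codon_idx * 3, codon_idx * 3 + 3
        for ns, ne in record.n_region_bounds:
            if s < ne and e > ns:
                return FunctionalityLabel("vdj_stop", stops)
    return FunctionalityLabel("shm_stop", stops)


def classify_records(records: list[RearrangementRecord]) -> dict[str, FunctionalityLabel]:
    return {r.sequence_id: classify_sequence(r) for r in records}


def productivity_index(clone: Clone, labels: dict[str, FunctionalityLabel],
                       weighted: bool = True,
                       records: dict[str, RearrangementRecord] | None = None) -> float:
    """Fraction of productive (functional) sequences in the clone."""
    if not clone.member_ids:
        raise ValueError(f"clone {clone.clone_id} has no members")
    num = den = 0
    for sid in clone.member_ids:
        w = records[sid].duplicate_count if (weighted and records) else 1
        den += w
        if labels[sid].func_class == "functional":
            num += w
    return num / den


def classify_clone(index: float) -> str:
    """F above 95% productive members, NF below 5%, F&NF otherwise
    (strict inequalities at both boundaries)."""
    if index > 0.95:
        return "F"
    if index < 0.05:
        return "NF"
    return "F_and_NF"


def pair_alleles(
    f_clones: list[Clone],
    nf_clones: list[Clone],
    max_log2_ratio: float = 1.0,
    replicates: tuple[str, ...] = ("R1", "R2"),
) -> tuple[list[AllelePair], list[str]]:
    """Pair each silenced (NF) allele with the functional clone of the
    same B cell, assuming the two alleles amplify at similar abundance.

    Greedy one-to-one matching within each GC: NF clones in descending
    abundance, each matched to the unmatched F clone minimizing
    |log2(NF/F)|, accepted iff the ratio is within ``max_log2_ratio``
    doublings and both clones are present in both replicates of the GC.
    Returns (pairs sorted by ratio closeness, unmatched NF clone ids).
    """
    def gcs_consistent(clone: Clone) -> set[str]:
        gcs = defaultdict(set)
        for (gc, rep), v in clone.per_sample_abundance.items():
            if v > 0:
                gcs[gc].add(rep)
        return {gc for gc, reps in gcs.items() if set(replicates) <= reps}

    pairs: list[AllelePair] = []
    unmatched: list[str] = []
    by_gc_f: dict[str, list[Clone]] = defaultdict(list)
    for c in f_clones:
        for gc in gcs_consistent(c):
            by_gc_f[gc].append(c)
    taken: set[str] = set()
    for nf in sorted(nf_clones, key=lambda c: (-c.abundance, c.clone_id)):
        nf_gcs = gcs_consistent(nf)
        best = None
        for gc in sorted(nf_gcs):
            for f in by_gc_f.get(gc, []):
                if f.clone_id in taken:
                    continue
                ratio = nf.gc_abundance(gc) / f.gc_abundance(gc)
                score = abs(np.log2(ratio))
                if best is None or score < best[0]:
                    best = (score, ratio, f, gc)
        if best is not None and best[0] <= max_log2_ratio:
            score, ratio, f, gc = best
            taken.add(f.clone_id)
            co = {(gc, rep) for rep in replicates}
            pairs.append(AllelePair(f.clone_id, nf.clone_id, ratio, co))
        else:
            unmatched.append(nf.clone_id)
    pairs.sort(key=lambda p: abs(np.log2(p.abundance_ratio)))
    return pairs, unmatched


# --------------------------------------------------------------------------
# SHM summaries
# --------------------------------------------------------------------------

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _position_key(pos: int, bounds: dict[str, tuple[int, int]]) -> int:
    """Anchor a position so it is comparable across sequences.

    Positions upstream of CDR3 are keyed by their (negative) offset from
    the CDR3 start — robust to FWR1 truncation; CDR3 positions map to
    1000+offset; downstream positions to 2000+offset from the CDR3 end.
    """
    c3s, c3e = bounds["cdr3"]
    if pos < c3s:
        return pos - c3s
    if pos < c3e:
        return 1000 + (pos - c3s)
    return 2000 + (pos - c3e)


def _region_class(pos: int, bounds: dict[str, tuple[int, int]]) -> str:
    for r in ("cdr1", "cdr2", "cdr3"):
        if r in bounds and bounds[r][0] <= pos < bounds[r][1]:
            return "CDR"
    return "FWR"


def mutational_spectrum(
    clones: list[Clone],
    records: dict[str, RearrangementRecord],
) -> MutationSummary:
    """Position-wise SHM frequency and the 4x4 substitution table.

    The per-clone reference is the position-wise most common base among
    the clone's members (duplicate-count weighted); mismatches against it
    are counted per anchored position and aggregated over clones.
    Singleton clones contribute nothing (no consensus contrast).
    """
    mut: dict[int, int] = defaultdict(int)
    cov: dict[int, int] = defaultdict(int)
    region_of: dict[int, str] = {}
    table = np.zeros((4, 4), dtype=np.int64)
    used = skipped = 0
    for clone in clones:
        members = [records[sid] for sid in clone.member_ids]
        if sum(m.duplicate_count for m in members) < 2:
            skipped += 1
            continue
        lengths = [len(m.sequence) for m in members]
        modal = max(set(lengths), key=lambda L: (lengths.count(L), -L))
        members = [m for m in members if len(m.sequence) == modal]
        if len(members) == 0:
            skipped += 1
            continue
        arr = np.array([np.frombuffer(m.sequence.encode(), dtype=np.uint8)
                        for m in members])
        w = np.array([m.duplicate_count for m in members], dtype=np.int64)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        # weighted base counts per column; argmax over the byte-sorted base
        # axis makes ties resolve alphabetically
        base_counts = np.stack([((arr == b) * w[:, None]).sum(axis=0)
                                for b in bases])
        ref = bases[np.argmax(base_counts, axis=0)]
        used += 1
        bounds = members[0].region_bounds
        mismatch = arr != ref[None, :]
        mut_w = (mismatch * w[:, None]).sum(axis=0)
        total_w = int(w.sum())
        for j in range(modal):
            key = _position_key(j, bounds)
            cov[key] += total_w
            if mut_w[j]:
                mut[key] += int(mut_w[j])
            region_of.setdefault(key, _region_class(j, bounds))
        ref_idx = np.argmax(base_counts, axis=0)
        for bi, b in enumerate(bases):
            obs = (arr == b) & mismatch  # observed base b where mutated
            if obs.any():
                per_col = (obs * w[:, None]).sum(axis=0)
                for ri in range(4):
                    sel = per_col[(ref_idx == ri) & (per_col > 0)]
                    table[ri, bi] += int(sel.sum())
    rows = [
        {
            "position_key": k,
            "mutations": mut.get(k, 0),
            "coverage": cov[k],
            "frequency": mut.get(k, 0) / cov[k],
            "region_class": region_of[k],
            "uncovered": cov[k] == 0,
        }
        for k in sorted(cov)
    ]
    return MutationSummary(
        per_position=pd.DataFrame(
            rows, columns=["position_key", "mutations", "coverage",
                           "frequency", "region_class", "uncovered"]),
        substitution_table=table,
        n_clones_used=used,
        n_singletons_skipped=skipped,
    )


def rs_counts(
    record: RearrangementRecord,
    reference: str,
    region_class: str,
) -> tuple[int, int]:
    """Replacement / silent mutation counts vs a codon-aligned reference.

    Each mismatching nucleotide is assessed alone: the reference codon
    with that single substitution applied either changes the encoded
    amino acid (replacement) or not (silent). Restricted to positions in
    ``region_class`` ("CDR" or "FWR")."""
    seq = record.sequence
    if len(seq) != len(reference):
        raise ValueError(
            f"{record.sequence_id}: sequence/reference length mismatch "
            f"({len(seq)} vs {len(reference)})")
    r = s = 0
    for pos, (a, b) in enumerate(zip(reference, seq)):
        if a == b:
            continue
        if _region_class(pos, record.region_bounds) != region_class:
            continue
        c0 = pos - pos % 3
        ref_codon = reference[c0 : c0 + 3]
        if len(ref_codon) < 3:
            continue
        mut_codon = ref_codon[: pos - c0] + b + ref_codon[pos - c0 + 1 :]
        if str(Seq(ref_codon).translate()) != str(Seq(mut_codon).translate()):
            r += 1
        else:
            s += 1
    return r, s


def rs_ratio(
    records: list[RearrangementRecord],
    references: dict[str, str],
    region_class: str,
) -> tuple[float, int, int]:
    """Aggregate R/S over records; returns (ratio, R, S).

    The ratio is ``inf`` when S = 0 with R > 0 and ``nan`` when there are
    no mutations at all (counts are always attached)."""
    total_r = total_s = 0
    for rec in records:
        r, s = rs_counts(rec, references[rec.sequence_id], region_class)
        total_r += r
        total_s += s
    if total_s == 0:
        ratio = float("nan") if total_r == 0 else float("inf")
    else:
        ratio = total_r / total_s
    return ratio, total_r, total_s
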