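"""A small bundled set of toy IGHV / IGHJ germline genes.

The genes are constructed deterministically from a fixed framework
template: all V genes share framework amino acids (with gene-specific
synonymous codon variation) and differ in their CDR1/CDR2 loops, which is
the dominant mode of real V-gene diversity at this resolution. The set is
deliberately small (12 V genes in 6 subgroups, 6 J genes) — enough to
exercise V-gene-usage analyses, subgroup merging and germline-rooted
lineage trees without shipping a real reference database.

Coordinate convention: all bounds are 0-based half-open on the nucleotide
sequence. Every V gene is 288 nt (96 codons) ending in the conserved
2nd-CYS codon; the CDR3 insert follows at position 288. Every J gene is
33 nt beginning with the conserved J-TRP codon (TGG).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = [
    "GERMLINE_V",
    "GERMLINE_J",
    "V_REGION_BOUNDS",
    "V_LENGTH",
    "J_LENGTH",
    "v_gene_of",
    "j_gene_of",
    "v_subgroup_of",
]

# one fixed codon per amino acid (used for back-translation)
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "AGC", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
# one synonymous alternative per amino acid (W and M have none)
_ALT_CODON = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGA", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTT",
    "N": "AAC", "P": "CCA", "Q": "CAG", "R": "CGC", "S": "TCT",
    "T": "ACC", "V": "GTG", "Y": "TAC",
}

_FWR1 = "EVQLVESGGGLVQPGGSLRLSCAAS"          # 25 aa
_FWR2 = "MSWVRQAPGKGLEWVSA"                  # 17 aa
_FWR3 = "YYADSVKGRFTISRDNSKNTLYLQMNSLRAEDTAVYYC"  # 38 aa, ends in 2nd-CYS

_V_GENES = {
    # gene: (CDR1 8 aa, CDR2 8 aa)
    "IGHV1-2":  ("GYTFTGYY", "INPNSGGT"),
    "IGHV1-18": ("GYTFTSYG", "ISAYNGNT"),
    "IGHV1-69": ("GGTFSSYA", "IIPIFGTA"),
    "IGHV1-46": ("GYTFTSYY", "INPSGGST"),
    "IGHV2-5":  ("GFSLSTSG", "IDWDDDKY"),
    "IGHV3-7":  ("GFTFSSYW", "IKQDGSEK"),
    "IGHV3-23": ("GFTFSSYA", "ISGSGGST"),
    "IGHV3-30": ("GFTFSSYG", "ISYDGSNK"),
    "IGHV4-34": ("GGSFSGYY", "INHSGSTN"),
    "IGHV4-39": ("GGSISSSS", "IYYSGSTY"),
    "IGHV4-59": ("GGSISSYY", "IYYSGSTN"),
    "IGHV5-51": ("GYSFTSYW", "IYPGDSDT"),
}

_J_GENES = {
    # gene: FWR4 amino acids after the leading J-TRP
    "IGHJ1": "GQGTLVQVSS",
    "IGHJ2": "GRGTLVTVSS",
    "IGHJ3": "GQGTMVTVSS",
    "IGHJ4": "GQGTLVTVSS",
    "IGHJ5": "GQGTTVTVSS",
    "IGHJ6": "GQGTTVTVSA",
}

V_LENGTH = 3 * (len(_FWR1) + 8 + len(_FWR2) + 8 + len(_FWR3))  # 288
J_LENGTH = 3 * (1 + 10)  # 33

#: region intervals on every V gene (0-based half-open, nt)
V_REGION_BOUNDS = {
    "fwr1": (0, 3 * 25),
    "cdr1": (75, 75 + 24),
    "fwr2": (99, 99 + 51),
    "cdr2": (150, 150 + 24),
    "fwr3": (174, 174 + 114),
}


def _backtranslate(aa: str) -> str:
    return "".join(_CODON[x] for x in aa)


def _with_synonymous_variation(nt: str, gene: str, n_sites: int = 10) -> str:
    """Swap a gene-specific deterministic subset of codons for synonymous ones."""
    rng = np.random.default_rng(zlib.crc32(gene.encode()))
    codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
    candidates = [
        i for i, c in enumerate(codons)
        if _rev(c) in _ALT_CODON
    ]
    for i in rng.choice(candidates, size=min(n_sites, len(candidates)), replace=False):
        codons[i] = _ALT_CODON[_rev(codons[i])]
    return "".join(codons)


_AA_OF = {c: a for a, c in _CODON.items()}
_AA_OF.update({c: a for a, c in _ALT_CODON.items()})


def _rev(codon: str) -> str:
    return _AA_OF[codon]


def _build_v(gene: str) -> str:
    cdr1, cdr2 = _V_GENES[gene]
    nt = _backtranslate(_FWR1 + cdr1 + _FWR2 + cdr2 + _FWR3)
    return _with_synonymous_variation(nt, gene)


def _build_j(gene: str) -> str:
    nt = _backtranslate("W" + _J_GENES[gene])
    return _with_synonymous_variation(nt, gene, n_sites=3)


GERMLINE_V: dict[str, str] = {g: _build_v(g) for g in _V_GENES}
GERMLINE_J: dict[str, str] = {g: _build_j(g) for g in _J_GENES}


def v_gene_of(call: str) -> str:
    """Strip the allele suffix: 'IGHV1-2*02' -> 'IGHV1-2'."""
    return call.split("*")[0]


def j_gene_of(call: str) -> str:
    return call.split("*")[0]


def v_subgroup_of(gene_or_call: str) -> str:
    """Subgroup of a V gene: 'IGHV1-2*02' -> 'IGHV1'."""
    return v_gene_of(gene_or_call).split("-")[0]
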