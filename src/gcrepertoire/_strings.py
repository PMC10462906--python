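"""Low-level string metrics shared across modules.

Levenshtein is implemented here because clone members and CDR loops are
short (tens to a few hundred characters) and the normalisation used
downstream needs the raw edit count, which general-purpose fuzzy-matching
helpers do not expose in this environment.
"""

from __future__ import annotations

import numpy as np

__all__ = ["levenshtein", "normalized_levenshtein", "hamming_identity"]


def levenshtein(s1: str, s2: str) -> int:
    """Edit distance (substitutions, insertions, deletions all cost 1)."""
    if s1 == s2:
        return 0
    if not s1:
        return len(s2)
    if not s2:
        return len(s1)
    a = np.frombuffer(s1.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(s2.encode("ascii"), dtype=np.uint8)
    if a.size < b.size:  # iterate over the shorter string
        a, b = b, a
    m = b.size
    idx = np.arange(m + 1)
    prev = idx.copy()
    cur = np.empty(m + 1, dtype=np.int64)
    for i, ca in enumerate(a, start=1):
        cur[0] = i
        np.minimum(prev[1:] + 1, prev[:-1] + (b != ca), out=cur[1:])
        # propagate the left-neighbour dependency:
        # cur[j] = min_k<=j (cur[k] + (j - k))
        run = np.minimum.accumulate(cur - idx)
        np.minimum(cur, run + idx, out=cur)
        prev, cur = cur, prev
    return int(prev[m])


def normalized_levenshtein(s1: str, s2: str) -> float:
    """Length-normalised edit distance in [0, 1].

    Defined as 2*Lev / (|s1| + |s2| + Lev); it is 0 iff the strings are
    equal, 1 when they share nothing, and satisfies the triangle
    inequality (unlike Lev / max(len)).
    """
    if s1 == s2:
        return 0.0
    lev = levenshtein(s1, s2)
    return 2.0 * lev / (len(s1) + len(s2) + lev)


def hamming_identity(s1: str, s2: str) -> float:
    """Fraction of matching positions between two equal-length strings."""
    if len(s1) != len(s2):
        raise ValueError(
            f"hamming_identity requires equal lengths, got {len(s1)} and {len(s2)}"
        )
    if not s1:
        raise ValueError("hamming_identity is undefined for empty strings")
    a = np.frombuffer(s1.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(s2.encode("ascii"), dtype=np.uint8)
    return float((a == b).mean())
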