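"""Sample similarity and clonal-diversity profiling in Hill's framework.

Each GC sample is summarised by four indices, written in Hill notation
(^qD): dominance (related to ^infD), Chao1 richness (^0D, bias-corrected
for unseen clones), coverage-corrected Shannon entropy (log ^1D, the
Chao–Shen estimator) and evenness (^1D / ^0D). Counts are
duplicate-count-weighted: the material is genomic DNA, so one
rearrangement is one cell.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clones import Clone
from .germlines import v_gene_of
from .io import RearrangementRecord

__all__ = [
    "ClonalAbundance",
    "DiversityProfile",
    "dice_similarity",
    "dominance",
    "chao1_richness",
    "shannon_chao",
    "evenness",
    "diversity_profile",
    "abundance_classes",
    "subsampled_null",
    "vgene_usage",
]


@dataclass
class ClonalAbundance:
    """Clone counts for one sample, with normalised frequencies."""

    sample_id: str
    entries: dict[str, int]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError(f"sample {self.sample_id!r} has no clones")
        if any(v < 1 for v in self.entries.values()):
            raise ValueError("all clone counts must be >= 1")

    @property
    def n(self) -> int:
        return sum(self.entries.values())

    @property
    def normalized(self) -> dict[str, float]:
        n = self.n
        return {k: v / n for k, v in self.entries.items()}

    @classmethod
    def from_clones(cls, sample_id: str, clones: list[Clone],
                    weighted: bool = True) -> "ClonalAbundance":
        entries = {
            c.clone_id: (c.abundance if weighted else len(c.member_ids))
            for c in clones
        }
        return cls(sample_id, entries)


@dataclass
class DiversityProfile:
    sample_id: str
    dominance: float
    richness_obs: int
    richness_chao: float
    shannon_chao: float
    evenness: float
    f1: int
    f2: int
    coverage: float


def dice_similarity(x: ClonalAbundance, y: ClonalAbundance) -> float:
    """Sørensen–Dice similarity of two normalised clonal compositions:
    1 - sum_i |x_i - y_i| / 2 over the union of clones. 1 means identical
    samples; 0 means no shared clones."""
    px, py = x.normalized, y.normalized
    l1 = sum(abs(px.get(k, 0.0) - py.get(k, 0.0)) for k in set(px) | set(py))
    return 1.0 - l1 / 2.0


def dominance(x: ClonalAbundance) -> float:
    """Fraction of cells in the most abundant clone."""
    return max(x.normalized.values())


def _f_counts(x: ClonalAbundance) -> tuple[int, int]:
    counts = list(x.entries.values())
    return counts.count(1), counts.count(2)


def chao1_richness(x: ClonalAbundance) -> float:
    """Bias-corrected Chao1 estimate of total clone richness:
    N_obs + f1 (f1 - 1) / (2 (f2 + 1))."""
    f1, f2 = _f_counts(x)
    return len(x.entries) + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon_chao(x: ClonalAbundance) -> float:
    """Coverage-corrected Shannon entropy (nats), Chao–Shen estimator.

    With coverage C = 1 - f1/n and coverage-adjusted frequencies
    p~ = C p, H = -sum p~ ln p~ / (1 - (1 - p~)^n). When C = 0 (all
    singletons) the estimator degenerates and the plug-in entropy is
    returned with a warning.
    """
    n = x.n
    if n < 2:
        raise ValueError("shannon_chao requires a sample of at least 2 cells")
    p = np.array(list(x.normalized.values()))
    f1, _ = _f_counts(x)
    coverage = 1.0 - f1 / n
    if coverage <= 0.0:
        warnings.warn(
            "sample coverage is 0 (all clones are singletons); "
            "falling back to plug-in entropy", stacklevel=2)
        return float(-(p * np.log(p)).sum())
    pt = coverage * p
    return float(-(pt * np.log(pt) / (1.0 - (1.0 - pt) ** n)).sum())


def evenness(x: ClonalAbundance) -> float:
    """exp(H_Chao) / N_Chao, clipped to [0, 1]; 1 means a perfectly
    homogeneous sample."""
    val = np.exp(shannon_chao(x)) / chao1_richness(x)
    return float(np.clip(val, 0.0, 1.0))


def diversity_profile(x: ClonalAbundance) -> DiversityProfile:
    f1, f2 = _f_counts(x)
    return DiversityProfile(
        sample_id=x.sample_id,
        dominance=dominance(x),
        richness_obs=len(x.entries),
        richness_chao=chao1_richness(x),
        shannon_chao=shannon_chao(x),
        evenness=evenness(x),
        f1=f1,
        f2=f2,
        coverage=1.0 - f1 / x.n,
    )


def abundance_classes(
    x: ClonalAbundance, expanded_threshold: float = 0.01,
) -> dict[str, list[str]]:
    """Partition clones into the dominant clone, expanded clones
    (frequency strictly above the threshold) and non-expanded clones."""
    freqs = x.normalized
    top = max(freqs.values())
    dominant = min(k for k, v in freqs.items() if v == top)  # tie -> clone_id
    expanded = [k for k, v in freqs.items()
                if k != dominant and v > expanded_threshold]
    non_expanded = [k for k in freqs if k != dominant and k not in set(expanded)]
    return {"dominant": [dominant], "expanded": sorted(expanded),
            "non_expanded": sorted(non_expanded)}


def subsampled_null(
    pooled: list[RearrangementRecord],
    membership: dict[str, str],
    n: int,
    seed: int,
) -> ClonalAbundance:
    """An artificial sample of ``n`` cells drawn uniformly without
    replacement from the pooled lymph node.

    ``membership`` maps sequence_id to clone_id (clones grouped on the
    pooled data). Serves as the size-matched null against which real
    per-GC diversity is compared.
    """
    cells = []
    for r in pooled:
        cells.extend([membership[r.sequence_id]] * r.duplicate_count)
    if n > len(cells):
        raise ValueError(f"cannot draw {n} cells from a pool of {len(cells)}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(cells), size=n, replace=False)
    counts: dict[str, int] = defaultdict(int)
    for i in chosen:
        counts[cells[i]] += 1
    return ClonalAbundance(f"null_n{n}_seed{seed}", dict(counts))


def vgene_usage(
    clones_per_gc: dict[str, list[Clone]], top_k: int = 15,
) -> pd.DataFrame:
    """V-gene usage among each GC's ``top_k`` most abundant clones.

    Returns a table with one row per (gc, v_gene): the clone count among
    the top k, the within-GC fraction, and a flag when the GC had fewer
    than ``top_k`` clones (all were used).
    """
    rows = []
    for gc, clones in sorted(clones_per_gc.items()):
        ranked = sorted(clones, key=lambda c: (-c.abundance, c.clone_id))[:top_k]
        truncated = len(clones) < top_k
        counts: dict[str, int] = defaultdict(int)
        for c in ranked:
            counts[v_gene_of(c.v_gene)] += 1
        for vg, cnt in sorted(counts.items()):
            rows.append({
                "gc_id": gc, "v_gene": vg, "count": cnt,
                "fraction": cnt / len(ranked), "all_clones_used": truncated,
            })
    return pd.DataFrame(rows, columns=["gc_id", "v_gene", "count",
                                       "fraction", "all_clones_used"])


def vgene_frequency_by_class(clones: list[Clone]) -> pd.DataFrame:
    """Overall V-gene frequency split by clone functionality class
    (requires ``functionality_class`` to be filled in)."""
    rows: dict[tuple[str, str], int] = defaultdict(int)
    for c in clones:
        cls = c.functionality_class or "unlabeled"
        rows[(v_gene_of(c.v_gene), cls)] += c.abundance
    df = pd.DataFrame(
        [{"v_gene": v, "class": k, "abundance": a} for (v, k), a in sorted(rows.items())])
    if not df.empty:
        df["fraction"] = df.groupby("class")["abundance"].transform(
            lambda s: s / s.sum())
    return df
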