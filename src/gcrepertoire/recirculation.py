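"""Inter-GC clone sharing and the Poisson model of B-cell reactivation.

A clone counts as present in a GC only when it is identified in both
replicate amplifications of that GC (the replicate-consistency gate).
The number of GCs k in which each clone is found is histogrammed; under a
memoryless reactivation process the number of *additional* GCs a clone
seeds is Poisson with mean mu = lambda * t, giving the shifted model
k = 1 + N (every clone occupies at least its founding GC). The fitted mu
yields the per-clone reactivation probability P(N >= 1) = 1 - exp(-mu)
and, given a GC lifetime, a seeding rate per clone per day.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import poisson

from .clones import CDR3Group, Clone

__all__ = [
    "SharingHistogram",
    "PoissonSharingFit",
    "consistent_presence",
    "consistent_gcs",
    "sharing_histogram",
    "fit_poisson",
    "reactivation_probability",
    "seeding_rate",
    "shared_cdr3_fraction",
]


@dataclass
class SharingHistogram:
    counts: dict[int, int]                 # k (GCs occupied) -> clones
    total_clones: int
    expanded_counts: dict[int, int]        # restricted to dominance-gated clones

    def mean_k(self) -> float:
        return sum(k * v for k, v in self.counts.items()) / self.total_clones

    def shared_fraction(self) -> float:
        shared = sum(v for k, v in self.counts.items() if k >= 2)
        return shared / self.total_clones


@dataclass
class PoissonSharingFit:
    mu: float
    fit_method: str
    log_likelihood: float
    degenerate: bool = False
    lifetime_days: float | None = None

    @property
    def p_reactivation(self) -> float:
        return reactivation_probability(self.mu)

    @property
    def lambda_per_day(self) -> float | None:
        if self.lifetime_days is None:
            return None
        return seeding_rate(self.mu, self.lifetime_days)


def consistent_presence(
    clone: Clone | CDR3Group,
    gc_id: str,
    replicates_by_gc: dict[str, set[str]],
) -> bool:
    """True iff the clone has at least one sequence in every replicate of
    the GC. Undefined (error) for a GC sequenced in a single replicate."""
    reps = replicates_by_gc.get(gc_id, set())
    if len(reps) < 2:
        raise ValueError(
            f"GC {gc_id!r} has {len(reps)} replicate(s); the consistency "
            "gate needs at least two")
    present = {rep for (gc, rep), v in clone.per_sample_abundance.items()
               if gc == gc_id and v > 0}
    return reps <= present


def consistent_gcs(clone, replicates_by_gc: dict[str, set[str]]) -> list[str]:
    return [gc for gc in sorted(replicates_by_gc)
            if consistent_presence(clone, gc, replicates_by_gc)]


def replicates_from_clones(clones) -> dict[str, set[str]]:
    """Derive the (gc -> replicates) layout from observed sample keys."""
    out: dict[str, set[str]] = defaultdict(set)
    for c in clones:
        for gc, rep in c.per_sample_abundance:
            out[gc].add(rep)
    return dict(out)


def sharing_histogram(
    clones: list[Clone],
    replicates_by_gc: dict[str, set[str]] | None = None,
    dominance_threshold: float = 0.001,
) -> SharingHistogram:
    """Histogram of the number of GCs each clone occupies (gated).

    Clones failing the gate in every GC are not counted (they were never
    reliably seen anywhere). The ``expanded_counts`` variant keeps only
    clones whose within-GC frequency exceeds ``dominance_threshold``
    (default 0.1%) in the GCs counted.
    """
    if replicates_by_gc is None:
        replicates_by_gc = replicates_from_clones(clones)
    gc_totals: dict[str, int] = defaultdict(int)
    for c in clones:
        for (gc, _), v in c.per_sample_abundance.items():
            gc_totals[gc] += v
    counts: dict[int, int] = defaultdict(int)
    expanded: dict[int, int] = defaultdict(int)
    total = 0
    for c in clones:
        gcs = consistent_gcs(c, replicates_by_gc)
        k = len(gcs)
        if k == 0:
            continue
        total += 1
        counts[k] += 1
        k_exp = sum(
            1 for gc in gcs
            if c.gc_abundance(gc) / gc_totals[gc] > dominance_threshold)
        if k_exp >= 1:
            expanded[k_exp] += 1
    return SharingHistogram(dict(counts), total, dict(expanded))


def fit_poisson(hist: SharingHistogram, method: str = "shifted") -> PoissonSharingFit:
    """Maximum-likelihood Poisson fit to the sharing histogram.

    ``shifted`` (default): k = 1 + N with N ~ Poisson(mu); every observed
    clone occupies its home GC, so mu_hat = mean(k) - 1 in closed form.
    ``zero_truncated``: k itself is a Poisson draw conditioned on k >= 1;
    mu solves mu / (1 - exp(-mu)) = mean(k).
    """
    if hist.total_clones < 10:
        raise ValueError("fit requires at least 10 clones")
    mean_k = hist.mean_k()
    degenerate = all(k == 1 for k in hist.counts)
    if method == "shifted":
        mu = max(0.0, mean_k - 1.0)
        ll = sum(n * poisson.logpmf(k - 1, mu) for k, n in hist.counts.items()) \
            if mu > 0 else (0.0 if degenerate else -math.inf)
    elif method == "zero_truncated":
        if degenerate:
            mu, ll = 0.0, 0.0
        else:
            f = lambda m: m / (1.0 - math.exp(-m)) - mean_k
            mu = brentq(f, 1e-10, max(10.0, 10 * mean_k))
            ll = sum(
                n * (poisson.logpmf(k, mu) - math.log1p(-math.exp(-mu)))
                for k, n in hist.counts.items())
    else:
        raise ValueError(f"unknown fit method {method!r}")
    return PoissonSharingFit(float(mu), method, float(ll), degenerate)


def reactivation_probability(mu: float) -> float:
    """P(N >= 1) = 1 - exp(-mu): probability that a clone seeds at least
    one additional GC over the GC reaction."""
    if mu < 0:
        raise ValueError("mu must be >= 0")
    return 1.0 - math.exp(-mu)


def seeding_rate(mu: float, lifetime_days: float) -> float:
    """lambda = mu / t: seedings per clone per day for a GC lifetime t."""
    if lifetime_days <= 0:
        raise ValueError("lifetime_days must be > 0")
    return mu / lifetime_days


def shared_cdr3_fraction(
    cdr3_groups: list[CDR3Group],
    replicates_by_gc: dict[str, set[str]],
) -> tuple[int, int, float]:
    """Fraction of CDR3 amino-acid groups found (gated) in >= 2 GCs.

    Returns (shared_count, total_count, fraction) over all gated groups.
    """
    shared = total = 0
    for g in cdr3_groups:
        k = len(consistent_gcs(g, replicates_by_gc))
        if k == 0:
            continue
        total += 1
        if k >= 2:
            shared += 1
    return shared, total, (shared / total if total else 0.0)
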