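"""Inter-GC clone sharing and the Poisson reactivation fit.

Applies the replicate-consistency gate, histograms the number of GCs per
clone, fits the shifted Poisson model (k = 1 + N, N ~ Poisson(mu)) and
the zero-truncated alternative, and derives the reactivation probability
P(N >= 1) and the per-clone daily seeding rate for a 20-day GC lifetime.
Also counts CDR3 amino-acid groups shared across GCs, which is expected
to be much rarer than clone sharing (the CDR3 keeps mutating after
recirculation).

Usage: python analysis/05_recirculation.py [--in results/ln] [--out results]
"""

import argparse
import json
from pathlib import Path

from gcrepertoire.clones import group_by_cdr3, group_clones
from gcrepertoire.io import read_rearrangements
from gcrepertoire.recirculation import (
    fit_poisson,
    reactivation_probability,
    replicates_from_clones,
    seeding_rate,
    shared_cdr3_fraction,
    sharing_histogram,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--in", dest="ln", type=Path, default=Path("results/ln"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--lifetime-days", type=float, default=20.0)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    records = []
    for path in sorted(args.ln.glob("GC*_R*.tsv")):
        records.extend(read_rearrangements(path))
    clones = group_clones(records)
    layout = replicates_from_clones(clones)

    hist = sharing_histogram(clones, layout)
    fits = {m: fit_poisson(hist, method=m)
            for m in ("shifted", "zero_truncated")}
    mu = fits["shifted"].mu
    cdr3 = group_by_cdr3([r for r in records if r.in_frame_junction])
    shared, total, frac = shared_cdr3_fraction(cdr3, layout)

    report = {
        "histogram": {str(k): v for k, v in sorted(hist.counts.items())},
        "total_clones": hist.total_clones,
        "shared_clone_fraction": hist.shared_fraction(),
        "fits": {m: {"mu": f.mu, "log_likelihood": f.log_likelihood}
                 for m, f in fits.items()},
        "p_reactivation": reactivation_probability(mu),
        "lifetime_days": args.lifetime_days,
        "seeding_rate_per_clone_per_day": seeding_rate(mu, args.lifetime_days),
        "shared_cdr3": {"shared": shared, "total": total, "fraction": frac},
    }
    (args.out / "sharing.json").write_text(json.dumps(report, indent=2) + "\n")

    print(f"gated clones: {hist.total_clones}; "
          f"shared across >=2 GCs: {100 * hist.shared_fraction():.1f}%")
    print(f"shifted-model mu = {mu:.3f}; "
          f"P(N>=1) = {100 * reactivation_probability(mu):.1f}%; "
          f"lambda = {seeding_rate(mu, args.lifetime_days):.5f} /clone/day")
    print(f"shared CDR3s: {shared}/{total} = {100 * frac:.1f}% "
          "(less than clone sharing, as expected)")


if __name__ == "__main__":
    main()
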