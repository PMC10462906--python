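"""Functionality classes, allele pairing and SHM summaries.

Classifies every sequence (functional / out-of-frame / V(D)J stop / SHM
stop), derives clone classes (F / NF / F&NF), pairs silenced alleles with
their functional counterparts by abundance, and computes the positional
mutation spectrum plus CDR and FWR R/S ratios.

Usage: python analysis/04_functionality.py [--in results/ln] [--out results]
"""

import argparse
from collections import Counter
from pathlib import Path

import pandas as pd

from gcrepertoire.clones import group_clones
from gcrepertoire.functionality import (
    classify_clone,
    classify_records,
    mutational_spectrum,
    pair_alleles,
    productivity_index,
    rs_ratio,
)
from gcrepertoire.germlines import GERMLINE_J, GERMLINE_V
from gcrepertoire.io import read_rearrangements
from gcrepertoire.phylogeny import build_root


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--in", dest="ln", type=Path, default=Path("results/ln"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    records = []
    for path in sorted(args.ln.glob("GC*_R*.tsv")):
        records.extend(read_rearrangements(path))
    rec_map = {r.sequence_id: r for r in records}
    clones = group_clones(records)

    labels = classify_records(records)
    counts = Counter()
    for r in records:
        counts[labels[r.sequence_id].func_class] += r.duplicate_count
    total = sum(counts.values())
    pd.DataFrame(
        [{"class": k, "cells": v, "fraction": v / total}
         for k, v in sorted(counts.items())]
    ).to_csv(args.out / "functional_classes.tsv", sep="\t", index=False)

    for c in clones:
        c.productivity_index = productivity_index(c, labels, records=rec_map)
        c.functionality_class = classify_clone(c.productivity_index)
    clone_cls = Counter(c.functionality_class for c in clones)

    f_clones = [c for c in clones if c.functionality_class == "F"]
    nf_clones = [c for c in clones if c.functionality_class == "NF"]
    pairs, unmatched = pair_alleles(f_clones, nf_clones)
    pd.DataFrame(
        [{"functional": p.functional_clone_id,
          "nonfunctional": p.nonfunctional_clone_id,
          "nf_over_f_ratio": p.abundance_ratio} for p in pairs]
    ).to_csv(args.out / "allele_pairs.tsv", sep="\t", index=False)

    spectrum = mutational_spectrum(clones, rec_map)
    spectrum.per_position.to_csv(args.out / "mutation_spectrum.tsv",
                                 sep="\t", index=False)

    # R/S with the germline-rooted reference, expanded clones vs singletons
    rs_rows = []
    for subset, name in ((
            [c for c in clones if c.frequency > 0.01], "expanded"),
            ([c for c in clones if len(c.member_ids) == 1
              and c.abundance == 1], "singletons")):
        refs, recs = {}, []
        for c in subset:
            try:
                root = build_root(c, GERMLINE_V, GERMLINE_J)
            except KeyError:
                continue
            for sid in c.member_ids:
                if len(rec_map[sid].sequence) == len(root):
                    refs[sid] = root
                    recs.append(rec_map[sid])
        for region in ("CDR", "FWR"):
            ratio, r, s = rs_ratio(recs, refs, region)
            rs_rows.append({"subset": name, "region": region,
                            "R": r, "S": s, "rs_ratio": ratio})
    pd.DataFrame(rs_rows).to_csv(args.out / "rs_ratios.tsv", sep="\t", index=False)

    print("cell-level classes:",
          {k: round(v / total, 3) for k, v in sorted(counts.items())})
    print("clone classes:", dict(sorted(clone_cls.items())))
    print(f"allele pairs accepted: {len(pairs)} (unmatched NF: {len(unmatched)})")
    means = spectrum.region_means()
    print("mean mutation frequency: CDR %.4f vs FWR %.4f"
          % (means["CDR"], means["FWR"]))
    for row in rs_rows:
        print("R/S %(subset)s %(region)s: %(rs_ratio).2f (R=%(R)d, S=%(S)d)" % row)


if __name__ == "__main__":
    main()
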