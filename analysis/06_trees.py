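"""Clonal lineage trees and crippling-mutation timing.

Builds germline-rooted neighbor-joining trees for the largest clones and
for every F&NF clone (a functional clone caught carrying a crippled
sublineage), exports them as Newick, summarises per-GC root proximity for
clones spanning several GCs, and estimates the mean number of mutations
accumulated before the crippling stop codon.

Usage: python analysis/06_trees.py [--in results/ln] [--out results]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from gcrepertoire.clones import group_clones
from gcrepertoire.functionality import classify_clone, classify_records, productivity_index
from gcrepertoire.germlines import GERMLINE_J, GERMLINE_V
from gcrepertoire.io import read_rearrangements
from gcrepertoire.phylogeny import (
    build_root,
    clone_tree,
    mutations_before_crippling,
    root_distance_distribution,
    to_newick,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--in", dest="ln", type=Path, default=Path("results/ln"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--n-top", type=int, default=10)
    ap.add_argument("--max-leaves", type=int, default=100)
    args = ap.parse_args()
    tree_dir = args.out / "trees"
    tree_dir.mkdir(parents=True, exist_ok=True)

    records = []
    for path in sorted(args.ln.glob("GC*_R*.tsv")):
        records.extend(read_rearrangements(path))
    rec_map = {r.sequence_id: r for r in records}
    clones = group_clones(records)
    labels = classify_records(records)
    lab_cls = {k: v.func_class for k, v in labels.items()}
    for c in clones:
        c.functionality_class = classify_clone(
            productivity_index(c, labels, records=rec_map))

    top = sorted(clones, key=lambda c: -c.abundance)[: args.n_top]
    fnf = [c for c in clones
           if c.functionality_class == "F_and_NF" and len(c.member_ids) >= 3]

    estimates = []
    rows = []
    for c in sorted({c.clone_id: c for c in top + fnf}.values(),
                    key=lambda c: c.clone_id):
        root = build_root(c, GERMLINE_V, GERMLINE_J)
        tree = clone_tree(c, root, rec_map, labels=lab_cls,
                          max_leaves=args.max_leaves)
        (tree_dir / f"{c.clone_id}.nwk").write_text(to_newick(tree) + "\n")
        dist = root_distance_distribution(tree)
        for gc, sims in dist.items():
            rows.append({"clone_id": c.clone_id, "gc_id": gc,
                         "n_cells": len(sims),
                         "median_root_similarity": float(np.median(sims))})
        if c.functionality_class == "F_and_NF":
            try:
                estimates.append(mutations_before_crippling(tree))
            except ValueError:
                pass
    pd.DataFrame(rows).to_csv(args.out / "root_similarity.tsv",
                              sep="\t", index=False)

    print(f"wrote {len(list(tree_dir.glob('*.nwk')))} Newick trees to {tree_dir}/")
    if estimates:
        print(f"F&NF clones analysed: {len(estimates)}; mean mutations before "
              f"the crippling stop: {np.mean(estimates):.1f}")
    else:
        print("no F&NF clones with enough members for the crippling analysis")


if __name__ == "__main__":
    main()
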