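"""Group rearrangements into clones and write the clone tables.

Reads the AIRR TSVs produced by 01_simulate.py, pools them, groups
sequences into clones (same V gene, J gene, CDR3 length, >84% junction
identity; single linkage), applies the same-subgroup merge, and writes a
clone summary plus the sequence-to-clone membership table. Also reports
the recovered clone count against the ground truth.

Usage: python analysis/02_group_clones.py [--in results/ln] [--out results]
"""

import argparse
from pathlib import Path

import pandas as pd

from gcrepertoire.clones import group_clones, merge_same_subgroup
from gcrepertoire.io import read_rearrangements


def load_pooled(ln_dir: Path):
    records = []
    for path in sorted(ln_dir.glob("GC*_R*.tsv")):
        records.extend(read_rearrangements(path))
    return records


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--in", dest="ln", type=Path, default=Path("results/ln"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--threshold", type=float, default=0.84)
    args = ap.parse_args()

    records = load_pooled(args.ln)
    clones = merge_same_subgroup(group_clones(records, threshold=args.threshold))
    args.out.mkdir(parents=True, exist_ok=True)

    rows = [{
        "clone_id": c.clone_id, "v_gene": c.v_gene, "j_gene": c.j_gene,
        "junction_length": c.junction_length, "n_members": len(c.member_ids),
        "abundance": c.abundance, "frequency": c.frequency,
        "consensus_junction": c.consensus_junction,
        "representative_id": c.representative_id,
    } for c in clones]
    pd.DataFrame(rows).to_csv(args.out / "clones.tsv", sep="\t", index=False)
    membership = pd.DataFrame(
        [(sid, c.clone_id) for c in clones for sid in c.member_ids],
        columns=["sequence_id", "clone_id"])
    membership.to_csv(args.out / "membership.tsv", sep="\t", index=False)

    truth = pd.read_csv(args.ln / "truth_sequences.tsv", sep="\t")
    n_truth = truth["clone"].nunique()
    print(f"{len(records)} records -> {len(clones)} clones "
          f"(ground truth: {n_truth} sampled founders)")
    print(f"largest clone: {max(c.abundance for c in clones)} cells")


if __name__ == "__main__":
    main()
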