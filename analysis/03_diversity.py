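"""Per-GC clonal diversity profiles, replicate similarity and V-gene usage.

For each GC (replicates pooled) this computes dominance, observed and
Chao1 richness, coverage-corrected Shannon entropy, and evenness; pairs
each GC with a size-matched null sample drawn from the pooled lymph node;
writes the pairwise Dice similarity matrix over samples; and tabulates
V-gene usage among each GC's 15 most abundant clones.

Usage: python analysis/03_diversity.py [--in results/ln] [--out results]
"""

import argparse
from collections import defaultdict
from pathlib import Path

import pandas as pd

from gcrepertoire.clones import group_clones
from gcrepertoire.diversity import (
    ClonalAbundance,
    dice_similarity,
    diversity_profile,
    subsampled_null,
    vgene_usage,
)
from gcrepertoire.io import read_rearrangements


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--in", dest="ln", type=Path, default=Path("results/ln"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    records = []
    for path in sorted(args.ln.glob("GC*_R*.tsv")):
        records.extend(read_rearrangements(path))
    pooled_clones = group_clones(records)
    membership = {sid: c.clone_id for c in pooled_clones for sid in c.member_ids}

    by_gc = defaultdict(list)
    for r in records:
        by_gc[r.gc_id].append(r)

    profiles, null_profiles = [], []
    per_gc_clones = {}
    for gc, recs in sorted(by_gc.items()):
        clones = group_clones(recs)
        per_gc_clones[gc] = clones
        x = ClonalAbundance.from_clones(gc, clones)
        profiles.append(vars(diversity_profile(x)))
        null = subsampled_null(records, membership, n=x.n, seed=args.seed)
        p = vars(diversity_profile(null))
        p["sample_id"] = f"null_for_{gc}"
        null_profiles.append(p)
    pd.DataFrame(profiles + null_profiles).to_csv(
        args.out / "diversity.tsv", sep="\t", index=False)

    # replicate-level Dice matrix
    sample_ab = {}
    by_sample = defaultdict(list)
    for r in records:
        by_sample[(r.gc_id, r.replicate_id)].append(r)
    for key, recs in sorted(by_sample.items()):
        sample_ab["_".join(key)] = ClonalAbundance.from_clones(
            "_".join(key), group_clones(recs))
    names = sorted(sample_ab)
    dice = pd.DataFrame(
        [[dice_similarity(sample_ab[a], sample_ab[b]) for b in names] for a in names],
        index=names, columns=names)
    dice.to_csv(args.out / "dice.tsv", sep="\t")

    vu = vgene_usage(per_gc_clones, top_k=15)
    vu.to_csv(args.out / "vgene_usage.tsv", sep="\t", index=False)

    df = pd.DataFrame(profiles)
    print("per-GC dominance: %.1f%% - %.1f%%"
          % (100 * df["dominance"].min(), 100 * df["dominance"].max()))
    print("per-GC evenness:  %.2f - %.2f"
          % (df["evenness"].min(), df["evenness"].max()))
    same_gc = [dice.loc[f"{g}_R1", f"{g}_R2"] for g in sorted(by_gc)]
    print("replicate Dice similarity (same GC): %.2f - %.2f"
          % (min(same_gc), max(same_gc)))


if __name__ == "__main__":
    main()
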