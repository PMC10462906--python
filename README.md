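# gcrepertoire

Per-germinal-center analysis of B-cell receptor (BCR) heavy-chain
repertoires from a single lymph node, built for laser-capture style data
where every germinal center (GC) is sequenced separately in two replicate
amplifications. The package covers the full chain from annotated
rearrangements to biology-level summaries:

- **Clones** — sequences sharing V gene, J gene, CDR3 length and more than
  84% junction nucleotide identity (single-linkage agglomerative
  clustering), with distance-to-nearest threshold optimization and a
  same-subgroup merge.
- **Diversity** — per-GC profiles in Hill's ^qD framework: dominance,
  bias-corrected Chao1 richness `N̂ = N_obs + f1(f1−1)/(2(f2+1))`,
  coverage-corrected Shannon entropy (Chao–Shen, `C = 1 − f1/n`), and
  evenness `exp(Ĥ)/N̂`; Sørensen–Dice similarity
  `1 − Σ|x_i − y_i|/2` between samples; size-matched null samples.
- **Functionality** — four sequence classes (functional, out-of-frame,
  stop codon in the non-templated N region from V(D)J recombination, stop
  from somatic hypermutation), F / NF / F&NF clone classes at 95% / 5%
  productivity, abundance-based pairing of silenced alleles, positional
  mutation spectra and replacement/silent (R/S) ratios.
- **Recirculation** — replicate-gated clone sharing across GCs and a
  Poisson reactivation model: the number of extra GCs a clone seeds is
  `N ~ Poisson(μ)`, so `P(N≥1) = 1 − e^{−μ}` and the per-day seeding rate
  is `λ = μ/t` for a GC lifetime `t`.
- **Lineage trees** — neighbor joining on the normalized Levenshtein
  distance `2·Lev/(|s1|+|s2|+Lev)`, rooted on the unmutated V/J germline
  with the junction filled by the clone consensus; used to time crippling
  (stop-introducing) mutations.
- **Convergence** — common-epitope prediction by a 2-of-3 vote over CDR
  similarity (> 0.84), paratype identity (> 0.76) and an Ab-Ligity-style
  structural token score (> 0.26), gated on equal CDR3 length; structural
  epitope groups as connected components.

Because the real dataset is external, the package ships a fully
ground-truthed synthetic lymph-node generator (`gcrepertoire.simulate`)
that emulates the stated experimental world — 10 GCs × 2 replicates,
~90% functional sequences with the 78/11/11 non-functional composition,
clone sharing at rate μ = 0.25, CDR-elevated SHM, skewed V-gene usage and
planted common-epitope groups — so every stage is testable end to end.

## Worked example

The analysis is organised as numbered drivers over the library:

```
python analysis/01_simulate.py --seed 1      # synthetic LN -> results/ln/
python analysis/02_group_clones.py           # clones.tsv, membership.tsv
python analysis/03_diversity.py              # diversity.tsv, dice.tsv, vgene_usage.tsv
python analysis/04_functionality.py          # classes, allele pairs, SHM spectra
python analysis/05_recirculation.py          # sharing.json
python analysis/06_trees.py                  # Newick trees, crippling timing
python analysis/07_convergence.py            # predicted pairs, epitope groups
```

A run at the default desk scale (40,000 cells) prints, among other lines:

```
39818 records -> 729 clones (ground truth: 731 sampled founders)
cell-level classes: {'functional': 0.902, 'out_of_frame': 0.077, 'shm_stop': 0.01, 'vdj_stop': 0.011}
gated clones: 556; shared across >=2 GCs: 12.9%
shifted-model mu = 0.144; P(N>=1) = 13.4%; lambda = 0.00719 /clone/day
shared CDR3s: 49/2130 = 2.3% (less than clone sharing, as expected)
F&NF clones analysed: 25; mean mutations before the crippling stop: 3.8
predicted common-epitope pairs: 21 (categories: {'same_vj_divergent_cdr3': 21})
structural groups: 646 total, 5 with >1 clone
```

Reading those numbers: clone grouping recovers essentially every sampled
founder; the cell-level functionality classes land on the configured
90 / 7.8 / 1.1 / 1.1 composition; the *observed* (gated) sharing fit
underestimates the planted μ = 0.25 because a recirculating clone enters
the new GC at low abundance and often stays below the sampling floor —
exactly why shared CDR3s (2.3%) are rarer still; the crippling-mutation
timing estimate (3.8) recovers the configured mean of 3.6; and the five
multi-clone structural groups are the five planted epitope groups.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes, from scratch at run time: the reactivation probability and
seeding rate implied by μ = 0.25 (via the maximum-likelihood fit on a
sharing histogram with the corresponding mean), and the shared-clone and
shared-CDR3 percentages from the study's printed counts; it then runs the
whole synthetic pipeline once as a smoke check. Output is a JSON map of
target id → value.
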