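# Methods

This note documents the models and numerical conventions implemented in
`gcrepertoire`, the design choices made where several readings were
possible, and what the synthetic-data generator does and does not emulate.

## Clonal grouping

A clone is defined as the set of rearrangements sharing V gene, J gene
and CDR3 length whose junction nucleotide identity exceeds a threshold
(default 0.84). Because CDR3-length equality is a hard partition key,
within-partition distances are Hamming distances (edits are
substitutions); clustering is agglomerative with **single linkage** cut
strictly below distance `1 − threshold`. Single linkage reproduces the
chaining that clonal lineages require (A related to B, B related to C
implies one clone even when A and C have drifted apart); `complete` and
`average` are available as options. Clustering operates on the set of
*unique* junctions, which makes the result invariant to record order and
multiplicity. V/J calls are collapsed to gene level before partitioning;
representative-member ties are broken by lexicographic sequence id, and
consensus ties by alphabetical base. Clones from different V genes of the
same subgroup are merged when their representative junctions are
identical (a guard against V-gene mis-calls within a subgroup).

**Threshold optimization.** For each sequence, the distance to its
nearest same-(V, J, length) neighbour is computed within the sample and
against a negation set (sequences from a different individual — by
default a fresh generator seed). The chosen threshold is `1 − d*`, where
`d*` is the density minimum between the within-sample mode and the
negation mode on a 501-point grid. The density is an equal-weight mixture
of per-component Gaussian KDEs with Silverman bandwidths: a single pooled
KDE oversmooths the much tighter clonal mode and drifts the valley
towards the centre of the gap. When no interior minimum exists the
threshold is left unset with a warning.

## Diversity

All indices are computed on duplicate-count-weighted counts (genomic DNA:
one rearrangement is one cell); unique-sequence counting is a switch.
Entropy uses natural logarithms, so `^1D = exp(H)`.

- Dominance: `max_i p_i`.
- Chao1 (bias-corrected): `N_obs + f1(f1−1)/(2(f2+1))`.
- Shannon with coverage correction (Chao–Shen): with `C = 1 − f1/n` and
  `p̃ = C·p`, `Ĥ = −Σ p̃ ln p̃ / (1 − (1−p̃)^n)`. When `C = 0` (all
  singletons) the estimator degenerates and the plug-in entropy is
  returned with a warning.
- Evenness: `exp(Ĥ)/N̂_Chao`, clipped to [0, 1] because the two
  estimators are computed independently and can transiently violate the
  bound.

The published print of the coverage-adjustment equation is typographically
garbled; the implementation follows the standard Chao–Shen construction,
which the coverage definition and Horvitz–Thompson denominator point to
unambiguously.

## Functionality

Sequence classes are assigned with frame status taking precedence: an
out-of-frame junction is `out_of_frame` regardless of stop codons (this
ordering is implied by frameshifts accounting for 78% of non-functional
sequences). In-frame sequences are scanned codon-by-codon from position 0;
a stop codon whose 3-nt span overlaps a non-templated N interval by at
least one nucleotide is `vdj_stop` (the overlap convention is ours; the
source does not define partial overlap), otherwise `shm_stop`. Clones are
`F` above 95% productive members, `NF` below 5%, `F_and_NF` between —
strict inequalities at both boundaries.

**Allele pairing.** Both IGH alleles of one B cell amplify at the same
cell count, so a silenced (non-functional) allele is identified by
abundance: greedy one-to-one matching of NF clones (descending abundance)
to the functional clone minimizing `|log2(NF/F)|` within the same GC,
accepted when the ratio is within one doubling and both clones appear in
both replicates. The tolerance and greedy order are our choices, recorded
in the output. A caveat the tests make explicit: on a dense clone-size
spectrum at desk-scale sampling, several functional clones sit within the
counting noise of any NF clone, so the *identity* of the partner is only
statistically identifiable when abundances are well separated. The
matching algorithm is verified exactly on separated worlds; on dense
worlds the contract (gates, one-to-one, pairability of planted silenced
alleles) is what can be asserted.

**SHM summaries.** The per-clone reference is the position-wise
duplicate-weighted majority base over members (ties alphabetical);
mismatches are aggregated per anchored position — positions upstream of
CDR3 are keyed by their offset from the CDR3 start, which aligns
sequences with truncated FWR1 — into a positional frequency table, a
4×4 substitution matrix, and CDR vs FWR means. Singleton clones carry no
consensus contrast and are skipped (counted). R/S ratios assess each
mismatching nucleotide alone against the codon-aligned reference
(germline V + clone-consensus junction); `S = 0` with `R > 0` reports an
infinity sentinel with counts attached; raw counts are used (per-site
normalization is an option).

## Recirculation

A clone "belongs" to a GC only when found in both replicate
amplifications (the replicate-consistency gate; the gate can only lower a
clone's GC count). With `k` the number of gated GCs per clone, the
default fit is the **shifted model** `k = 1 + N`, `N ~ Poisson(μ)` —
every clone occupies at least its founding GC — whose maximum-likelihood
estimate is closed-form, `μ̂ = mean(k) − 1`. This convention is the one
consistent with deriving the reactivation probability as
`P(N ≥ 1) = 1 − e^{−μ}`. A zero-truncated parameterization (`k` itself
Poisson conditioned on `k ≥ 1`, `μ` solving `μ/(1−e^{−μ}) = mean(k)`) is
provided and labelled, since the source does not state its home-GC
convention; both report log-likelihoods. The seeding rate is `λ = μ/t`
for a lifetime `t` (default 20 days). CDR3 sharing uses exact identity of
the translated junction, V/J-agnostic, with the same gate.

## Lineage trees

The root of a clone's tree is the unmutated germline V and J with the
junction filled by the clone's weighted-majority consensus. Unique
sequences are collapsed into weighted leaves (default cap 300 by
abundance) and joined by neighbor joining on the normalized Levenshtein
distance `2·Lev/(|a|+|b|+Lev)` — length-aware and satisfying the triangle
inequality — with Q-matrix ties broken by node creation index and limb
lengths clamped at zero. The tree is re-rooted on the germline taxon.
NJ is exact on additive matrices, which the test suite verifies against
exhaustive topology search.

**Crippling timing.** For each maximal all-non-functional subtree, the
leaf closest to the root (fewest edits) stands in for the earliest
sampled descendant of the crippling event; its mutation count versus the
root, excluding mismatches inside stop codons the root does not carry,
estimates how many mutations preceded the crippling stop. The mean over
subtrees is reported.

## Convergence

Three symmetric similarity metrics between clone representatives (the
most abundant member sequence; ties lexicographic):

1. **CDR similarity** `1 − (1/3)Σ Lev_norm(Hi_a, Hi_b)` over H1–H3;
   vote above 0.84. Note the floor for non-empty equal-length CDRs is
   1/3, since `Lev_norm ≤ 2/3` for equal-length strings.
2. **Paratype identity**: residues count as identical when both are
   predicted paratope (probability ≥ 0.67) at the same numbered position
   with the same amino acid; denominator is the smaller paratope; vote
   above 0.76. Alignment is by a fixed structural numbering (V-region
   index / CDR3 offset / J offset) rather than global alignment, matching
   the germline-filled fixed frame.
3. **Ab-Ligity-style score**: every unordered triple of paratope residues
   becomes a token (sorted chemical-class triple from the seven classes
   aliphatic/hydroxyl/sulphur/aromatic/acidic/amine/basic; sorted
   pairwise distances in 1 Å bins); the score is the Tanimoto overlap of
   token multisets; vote above 0.26. The tokenization is re-implemented
   from its published description; bin width and the Tanimoto choice are
   config-exposed.

A pair is predicted to share an epitope when at least two metrics vote
**and** the CDR3 lengths are equal. A metric abstains (rather than
voting no) when its inputs are missing — no coordinates, paratope smaller
than 3 residues, empty paratope — and an abstention cannot be
compensated: two positive votes are still required. Structural groups are
connected components of the predicted-pair graph over the top clones per
GC (default 300); the epitope-count estimate reports the raw component
count and the recall-corrected count `raw × recall` (default recall 0.1),
with the recall assumption attached.

## The synthetic lymph node

The generator emits what the stated experimental world describes, with
known ground truth. Default configuration:

| parameter | default | meaning |
|---|---|---|
| `n_gcs`, `n_replicates` | 10, 2 | GCs and replicate amplifications |
| `seqs_per_sample` | 5,000 | cells per sample (experiment ≈ 100,000) |
| `n_clones_per_gc` | 400 | founder clones per GC |
| `sharing_rate_mu` | 0.25 | extra GCs per clone, `1 + Poisson(μ)` |
| `functional_fraction` | 0.90 | cell mass that is functional |
| `nf_composition` | 0.78/0.11/0.11 | frameshift / V(D)J stop / SHM stop |
| `dominance_concentration` | 12 | GEM stick-breaking α; per-GC dominance ≈ 5–30% |
| `shm_mean_mutations` | 5 | substitutions per cell (~1.5% of the read) |
| `shm_rate_cdr_multiplier` | 3 | CDR-elevated mutation rate |
| `mean_mutations_before_crippling` | 3.6 | lineage mutations before the stop |
| `post_crippling_mutations` | 1 | SHM after crippling (apoptosis soon after) |
| `visitor_downscale` | 0.1 | abundance disadvantage in a non-home GC |
| `n_epitopes` × `epitope_group_size` | 5 × 4 | planted convergent groups |
| `paratope_noise` | 0.1 | probability / coordinate jitter |

Design choices that deserve emphasis:

- **Clone sizes** follow a stick-breaking (GEM) law per GC — the source
  reports the dominance range but no generative law; α = 12 reproduces
  the ≈5–30% per-GC dominance span.
- **Functionality composition is a repertoire property.** Clone class
  membership is drawn independently of size, but each class group's
  weights are rescaled per GC so the emitted cell mass matches
  `functional_fraction` and `nf_composition` exactly; clones above 5% of
  a GC stay functional and uncrippled (a cell without a surface BCR
  cannot be positively selected to dominance). Without the rescale, the
  heavy-tailed clone sizes make the realized composition swing by several
  points from seed to seed.
- **Silenced alleles** are emitted for a mid-dominance band (0.4–3%) of
  functional clones under a sub-budget of the out-of-frame mass, at an
  abundance ratio of `2^N(0, 0.25)` to their partner.
- **Crippled lineages** carry `Poisson(3.6)` shared neutral mutations,
  then a single-substitution stop (the conserved FWR2 tryptophan codon
  TGG→TAG), then `Poisson(1)` private mutations per cell — crippled cells
  lose their receptor and die within a couple of divisions, which is also
  what makes the timing estimator unbiased.
- **Planted epitope groups** share V, J, CDR3 length and a paratope
  template; members diverge from the prototype CDR3 by two substitutions
  in each of ~20% of codons, which puts pairwise CDR3 amino-acid
  similarity in the 0.6–0.75 band characteristic of convergent pairs
  while keeping junction identity below the clonal threshold. Their
  CDR1/CDR2 are frozen under SHM (purifying selection on the shared
  binding mode).
- **Replicates** are independent multinomial resamples of the same GC
  pool (optional dropout), so the replicate-consistency gate filters real
  sampling noise.
- **Germlines** are a bundled toy set: 12 V genes in 6 subgroups sharing
  framework amino acids (gene-specific synonymous codon variation) and
  differing in CDR1/2, plus 6 J genes — enough for V-usage, subgroup
  merging and germline-rooted trees without an external database.

What the generator does **not** emulate: indels from SHM (substitutions
only, except the single frameshift deletion defining out-of-frame
clones), affinity maturation dynamics, sequencing error, primer bias,
IMGT gap positions (the spectrum's gap flag is exercised by zero-coverage
positions instead), and FWR1 truncation (full-length reads are emitted).
A green recovery test therefore establishes that the estimators are
correct *under the stated world*, not that they are robust to every
artefact of real repertoire data.

## Known limitations

- Observed (gated) inter-GC sharing underestimates the planted μ at desk
  scale: a visiting clone enters at a 10× abundance disadvantage and is
  often missed by a 5,000-cell sample or dropped by the replicate gate.
  This mirrors the direction of bias expected in the real experiment; the
  μ-recovery guarantees hold for the latent occupancies and for
  histograms drawn from the model itself.
- Allele-pairing partner identity is unidentifiable on dense clone-size
  spectra (see above).
- The epitope-count estimate inherits the recall assumption wholesale;
  only the raw component count is a measurement.
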