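# Methods

`motifsel` quantifies selection on RNA-binding-protein (RBP) target motifs in
protein-coding sequence. This note records the statistical model behind each
stage, the parameters that matter, what the synthetic data generator does and
does not emulate, and the numerical choices a maintainer should know about.

## The inference model

The presence of an RBP motif set at unusual frequency in coding sequence, or
its unusual conservation, is only interpretable against a null that controls
for nucleotide composition: short k-mers differ enormously in their chance
frequency. All three detectors therefore compare an observed statistic with
its distribution over *simulant* motif sets — random sets matched to the real
set in motif number, motif lengths and approximate dinucleotide composition —
and express results as

* a normalized statistic, `(observed − simulant mean) / simulant mean`
  (called ND for density, normalized dS for divergence, normalized gain for
  the avoidance statistic), where 0 means "as expected by chance", 1 "twice
  the expectation", −0.5 "half"; and
* an empirical P value, `P = (n + 1) / (m + 1)`, with `n` the number of
  simulant sets at least as extreme as the observation among `m` simulants
  (weak inequality, so ties count as exceedances and P is never 0).

### Simulant construction (`nulls`)

Each real motif is cut into dinucleotides in both phases (a length-k motif
yields ⌊k/2⌋ phase-0 and ⌊(k−1)/2⌋ phase-1 dinucleotides); the two phases are
pooled with equal weight. A simulant motif of length k concatenates ⌊k/2⌋
dinucleotides sampled with replacement from the pool, plus one base from the
set's mononucleotide composition when k is odd. Rejection constraints:
simulants may not equal a real motif, may not contain a longer mononucleotide
run than the real set's maximum for that base, must be unique within their
set, and can be required to avoid substrings (the stop codons, for the
stop-content control). Generation fails loudly after 10,000 attempts per
motif rather than relaxing a constraint. Homopolymer or fully degenerate
consensuses (poly-A, W-runs) make every possible simulant a real motif; such
sets are flagged un-simulatable at catalog build time and excluded from
normalized statistics.

Each simulant set draws from an independent RNG stream seeded by
`(master_seed, set_index)`, so collections are reproducible and can be
regenerated piecemeal.

**Known approximation.** The shuffle null matches dinucleotide *content*,
not *order*. In a background with strong dinucleotide structure (e.g. CpG
depletion with TpG/CpA excess), a motif whose dinucleotides appear in a
chain-favoured order can be several-fold more frequent than its own
simulants without any selection. Set-level normalized statistics therefore
carry a set-specific offset of this origin; the empirical P calibration is
unaffected when real and simulant sets are exchangeable, and cross-set
*comparisons* (correlations, bimodality of the P distribution) remain
meaningful because the offset is a property of each set, not of the
sequences. This is the same approximation the underlying method class has
always made; it is why the test suite calibrates the median-ND statistic on
a compositionally uniform background and plants recovery signals into motif
sets drawn from the simulant process itself.

### Density and enrichment (`scan`)

Density is the fraction of bases covered by ≥1 motif occurrence, overlaps
collapsed; scanning is exact matching on the sense strand only (motifs act on
the mRNA; the reverse complement is never scanned). Coordinates are 0-based,
half-open. N bases are never covered but stay in the denominator. Per-gene
analyses use the median of family-collapsed per-gene values; per-motif-set
analyses use the pooled form, in which covered-base counts and lengths are
averaged within paralogous families before the final division. Families
collapse either by averaging or by one seed-deterministic random member.
Motif sets too rare to normalize reliably are dropped by the rarity rule:
keep only if real hits reach 100 bp in every required sequence collection,
or at least half the simulant sets do.

Internal coding exons of ≥211 bp (trimmed to whole codons) yield three
non-overlapping 69-bp regions — 5′ flank, centre core, 3′ flank — with the
core placed n codons from the 5′ flank and n−1 from the 3′ when the gap has
no exact midpoint.

### Divergence and conservation (`divergence`)

The conservation statistic is the synonymous rate (dS) of the codons
overlapping a motif set (a codon counts as overlapping when ≥1 of its three
bases is covered), concatenated across genes (one random gene per family)
and compared with the same quantity for each simulant set. The built-in
estimator is Nei–Gojobori (1986) counting with the Jukes–Cantor correction:
synonymous site counts averaged over both sequences, multi-substitution
codons averaged over all mutational pathways with equal weight. Since the
inference is always *relative* (real vs simulant under the same estimator),
first-order estimator bias cancels; an adapter to PAML's `codeml`
(Goldman–Yang ML) exists for users who have it installed and never silently
falls back. Saturation (synonymous proportion ≥ 0.75) and no-data conditions
raise specific errors; failing simulant sets are dropped and counted.

The 4-fold degenerate comparison avoids rate models entirely: at every third
codon position whose codon family is 4-fold degenerate, divergence is the
binary mismatch of the orthologous base. Each site is stratified twice, by
the dinucleotide in which it is the second base and the one in which it is
the first; motif and nonmotif rates are averaged across strata with the
motif-class dinucleotide frequencies as weights for both classes, removing
composition differences (CpG hypermutability in particular). Noncoding
regions use the Kimura two-parameter distance (with a `baseml` adapter).

The global reduction estimate is `density × normalized rate × 100`: the
percentage by which the region's (synonymous) substitution rate is reduced
by the pressure to preserve motifs.

### Gain avoidance (`avoidance`)

For a putatively avoided motif set (enrichment P > 0.9 by convention), every
4-fold degenerate site where a single substitution would create a motif
occurrence is a *one-removed site*. "Creates" means: some (start, length)
window of the mutated sequence is in the set while the same window of the
unmutated sequence is not; replacing one set member by a sibling member at
the same offset is not a gain, and simultaneous destruction of overlapping
occurrences is ignored. The orthologous base at each site scores 0 if equal
to the focal base or non-creating, else 0.75 / 0.5 / 0.25 when 1 / 2 / 3 of
the three possible substitutions would create a motif — the rarer the
creating option, the stronger the evidence carried by the ortholog using
exactly that base. Scores are summed and divided by the number of sites (a
raw presence-count variant is provided); the statistic is normalized against
simulant sets and its lower-tail empirical P is small when substitutions
toward the motifs are avoided. Only the focal site's ortholog base is
consulted; neighbouring differences and outgroup branch assignment are out
of scope (no outgroup is used).

### Summary statistics (`summary`, `dip`)

Bimodality of per-set enrichment P values — enriched sets piling near 0,
avoided sets near 1 — is tested with Hartigans' dip statistic: the smallest
sup-norm distance between the empirical cdf and any unimodal
(convex-then-concave, monotone, continuous) distribution function. The
statistic is computed exactly by bisection on the band half-width, with
greatest-convex-minorant feasibility per block and pairwise slope
certificates for the mode junction; the implementation is validated against
an independent linear-programming oracle built directly from the definition.
Restricting to *continuous* unimodal cdfs is a deliberate convention (no
modal atom); for continuous data it is the standard dip, and heavy ties in
the input inflate the statistic relative to a continuous null — P values on
a coarse grid should be interpreted accordingly. Dip P values are Monte
Carlo against uniform samples of the same size (default 2000 boots, shared
null distributions supported); uniformity is the right reference for
P-value inputs.

The enriched-vs-depleted class comparison uses a Pearson chi-square (1 df,
no continuity correction — counts here are large) on extreme-vs-middle P
classes (boundaries 0.1/0.9 included in the middle), or upper-tail-vs-rest
for depletion specifically. Cross-set relationships (ND vs normalized dS,
enrichment P vs conservation P, ND vs normalized gain) use Spearman rank
correlation with mid-ranks, requiring ≥5 sets. Expression tables (gene ×
tissue TPM) yield breadth (fraction of tissues strictly above 5 TPM),
median, maximum, and median-in-expressed (undefined and flagged for genes
expressed nowhere); correlations of ND with the four parameters are
Bonferroni-corrected for the four tests, capped at 1.

## The synthetic data generator (`simulate`)

The generator produces datasets with the statistical structure the analysis
assumes, with known planted signal:

* **Background CDSs** from a first-order Markov chain over dinucleotides,
  emitted codon-phase-aware so the third base of every internal codon is
  conditionally restricted to non-stop codons. Two corrections make the
  realized dinucleotide composition match the requested table: the table is
  first projected to equal left/right marginals (a stationary sequence
  cannot realize anything else), and the transition matrix is then adjusted
  by a fixed point computed from the exact stationary distribution of the
  48-state (phase, previous base, current base) chain, compensating the
  no-stop conditioning. Default composition: A/T 0.295, C/G 0.205, CpG
  depleted ~4-fold with the removed mass moved to TpG/CpA and taken from
  TpA, i.e. the deamination signature of vertebrate genomes. Verified: a
  ~100 kb batch matches the target within total-variation distance 0.02.
* **Paralog families**: a founder duplicated with substitutions confined to
  4-fold degenerate sites at rate 0.02 (protein identical, ORF intact).
* **Motif planting** to a target density of `multiplier ×` the set's
  nucleotide-controlled expectation, estimated as the mean coverage of an
  internal 30-set simulant collection (an analytic Markov expectation would
  miss the order effects the detector later normalizes against).
  Insertions overwrite random positions, are frame-aware and stop-avoiding,
  and stop within half a motif length of the target so realized coverage is
  centred on it; depletion (`multiplier < 1`) disrupts occurrences by
  single-base edits that create no stop and no new occurrence;
  `multiplier 0` removes every occurrence.
* **Ortholog evolution** only at 4-fold degenerate sites (protein identity
  and gap-free alignments guaranteed; all signal is synonymous, the quantity
  the detectors measure). Per-site substitution probability is `rate_motif`
  inside the conserved region — the codon-expanded coverage mask of the
  conserved sets, matching the codon granularity of the dS statistic — and
  `rate_background` elsewhere (defaults 0.04 / 0.08). A proposed
  substitution that would create an occurrence of the avoided set is
  rejected with probability `gain_suppression`.
* **Expression tables**: gene × 50 tissues; per-gene breadth targets drawn
  from Beta(0.8, 1.2) (or supplied directly); expressed tissues get
  5 + lognormal(ln 30, 1) TPM (strictly above the threshold), the rest
  uniform noise below 2 TPM.

What the generator does *not* emulate: indels and alignment error (pairs are
gap-free by construction), amino-acid-level selection, splice-site or exon
position structure, codon-usage bias beyond what the dinucleotide chain
induces, transcript isoforms, and any dependence between expression and
sequence. Passing recovery tests therefore demonstrate that the estimators
detect the signals they target at realistic effect sizes and data densities
— not that real genomes are free of the confounds the nulls are designed to
absorb.

## Problem sizes used in the test and acceptance runs

Chosen as the smallest sizes at which the planted effects are detectable
with comfortable statistical margin: enrichment recovery uses 50 genes of
200–300 codons with 8-motif sets and 200 simulants; conservation recovery
80 genes of 300–400 codons, 16-motif sets, background synonymous rate 0.16
vs 0.08 in motif regions; avoidance recovery 60 genes, rate 0.15,
suppression 0.9; the null calibrations use 100 runs × 200 simulants
(empirical P) and 20 runs × 200 simulants (median ND). The acceptance
script's empirical-P computation uses 40 genes and the full m = 1000
simulant sets.

## Numerical choices and degenerate inputs

* Consensus expansion caps at 65,536 motifs (guards pathological all-N
  inputs); terminal N bases are trimmed before expansion; parenthesised
  (variable-length) consensuses are rejected. Matrix→consensus thresholds
  are strict (> 0 for PWMs, > 0.25 for PSSMs; no pseudocounts).
* Empirical P uses weak inequality exactly as defined; ND is undefined
  (raised) when the simulant mean is 0; Z is NaN when the simulant SD is 0.
* dS: saturation at synonymous proportion ≥ 0.75; pathway steps between two
  stop codons count as synonymous (the convention of the common reference
  implementation of NG86); codons containing gaps, ambiguity or stops are
  excluded from counting.
* Dip: ties are collapsed into step heights; samples of 1 distinct value
  have dip 0; bisection terminates at 1e−11, far below any decision
  threshold in use.
* The family random-pick and all simulation streams are
  `numpy.random.Generator`-seeded; identical seeds give byte-identical
  outputs, including FASTA files.
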