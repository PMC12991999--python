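# Methods

This note documents the statistical models behind `tcrgvhd`, the defaults
and why they were chosen, what the synthetic cohort generator does and does
not emulate, and the numerical conventions that make results reproducible.

## Repertoire representation

A clonotype is identified by the triple (CDR3 amino-acid sequence, V
segment, J segment).  Nucleotide-level identity is carried through when a
`cdr3_nt` column is present but is not the default key: every downstream
comparison in the pipeline (motif clustering, cross-sample sharing,
annotation matching) operates on amino-acid CDR3s, so an amino-acid key
keeps the unit of analysis consistent end to end.  Gene calls are stripped
of allele suffixes (`TRBV15*01` → `TRBV15`) at ingestion so that usage
tallies aggregate at the segment level.  Frequencies are never stored; they
are always derived as `count / total_reads`, which makes depth
renormalization trivially consistent.

Ingestion keeps only productive rows whose CDR3 passes the 20-letter
amino-acid alphabet check (uppercase, no stops/frameshift symbols), merges
duplicate keys by summing counts, and reports dropped rows through the
logging system.  When an AIRR table carries both `duplicate_count` and
`consensus_count`, `duplicate_count` wins.

## Depth normalization

All statistics are computed after down-sampling each sample to a common
number of productive reads (default 1,000,000; a "minimum over the cohort"
policy is also provided).  Down-sampling draws reads **without replacement**
(multivariate hypergeometric over the clonotype counts): this is the
distribution of physically resampling reads, hits the target exactly, never
increases a count, and never invents a clonotype.  A multinomial mode
exists behind a flag for speed comparisons but is not the default.  Samples
already at or below the target are returned unchanged and flagged, not
dropped — exclusion thresholds are a cohort-level judgment that belongs to
the analyst.

Each sample derives its down-sampling seed from (master seed, sample id),
so normalization is independent of cohort ordering and of which other
samples are present.

## Diversity and clonality statistics

For counts `c_i` with total `T` and frequencies `p_i = c_i / T`:

* richness `S_obs` — clonotypes with at least one read;
* Chao1 — `S_obs + f₁²/(2 f₂)` from singletons `f₁` and doubletons `f₂`,
  falling back to the bias-corrected `S_obs + f₁(f₁−1)/2` when `f₂ = 0`;
* inverse Simpson index — `1 / Σ p_i²`, an evenness-weighted effective
  number of clonotypes, bounded by `[1, S_obs]` and invariant to uniform
  count rescaling;
* expanded clonotypes — counts are z-scored and clones with `z > 2`
  (strict) are counted.  The sample standard deviation (n−1) is used, the
  convention of standard statistical software; a population-SD flag is
  available.  Because z-scores are affine-invariant, counts and frequencies
  give identical results;
* low-frequency clones — `count < 100`, strict;
* rank-band masses — read fractions in abundance ranks 1–10, 11–100,
  101–1000 and beyond, with ties broken lexicographically (CDR3, then V) so
  the partition is deterministic;
* frequency-band richness — clone counts at ≤ 0.1% and > 0.1% frequency;
  the boundary clone belongs to the low band;
* CDR3 length distributions and V/J usage, read-weighted by default
  (matching "per productive read" reporting), clonotype-weighted on demand.

Group comparisons (rank-sum, signed-rank, Kolmogorov–Smirnov, Fisher's
exact) delegate to scipy, are two-sided, and refuse to return silent NaNs:
fewer than two values per group is an error, and degenerate all-equal
inputs return p = 1.  Where many tests run at once in the pipeline report
(one per metric-contrast, one per V segment), Benjamini–Hochberg adjusted
q-values are emitted alongside raw p-values.

## Specificity-group clustering

Pooled input: per sample, clonotypes whose frequency strictly exceeds
0.01% of reads and whose CDR3 is at least 8 residues long; the pool spans
all samples simultaneously.  The first and last 3 residues of each CDR3 are
trimmed before motif work, since the termini are germline-dominated and
uninformative about antigen contact.

**Local (motif) groups.**  For every interior k-mer (k ∈ {2, 3, 4}) with
support in at least 3 distinct pooled CDR3s, enrichment is assessed against
a naive reference repertoire by simulating the null: draw
`simulation_depth` (default 1000) random subsets of the reference of the
same unique-CDR3 count as the pool and record the motif's support in each.
The support of a *fixed* motif in a uniform random size-`n` subset of `N`
reference CDR3s, `K` of which carry the motif, is exactly
Hypergeometric(N, K, n), so the subsets are simulated as hypergeometric
draws — the same distribution at a small fraction of the cost.  The
empirical p-value uses add-one smoothing,
`p = (1 + #{subset support ≥ observed}) / (depth + 1)`, so p is never 0 and
never below `1/(depth+1)`; the fold enrichment is the observed support over
the simulated mean (floored at `1/depth`).  A motif is retained when
`fold ≥ 10` and `p ≤ 0.05`; both thresholds are configuration fields, as
are all the others.  Each motif draws from an RNG stream keyed on
(seed, k, motif), making results independent of iteration order.

*Calibration and its limits.*  Per motif, the empirical p is exact-or-
conservative unconditionally.  The screen, however, only *tests* motifs
whose observed support reaches the minimum-depth cutoff, and for motifs
whose null support lies mostly below that cutoff the selection and the
significance events largely coincide — among such tested motifs small
p-values are over-represented.  This selection effect is inherent to
motif screens of this family; the 10× fold filter confines its practical
impact to sparsely-supported motifs.  Consequently the package's null-
calibration check (`experiments.null_motif_calibration`) runs where the
premise of the check holds: 2-mers, whose median null support (~11) sits
far above the cutoff of 3.  There the p ≤ 0.05 fraction stays at the
nominal level (0.03–0.07 across seeds) and a one-sided KS test never
rejects super-uniformity.

**Global groups.**  Unique CDR3s of equal length whose trimmed interiors
differ at no more than one position are linked; connected components with
at least two CDR3s become groups.  The implementation buckets interiors by
(length, masked position) and unions within buckets, which is exactly
equivalent to all-pairs Hamming-distance-≤1 clustering (verified against an
O(n²) oracle in the tests).

Group identifiers are content hashes of (kind, signature), so identical
inputs give identical ids regardless of ordering.

This is a faithful-in-spirit reimplementation of the local/global
decomposition used by GLIPH-family algorithms, not a port: published
GLIPH2 combines additional probability components (V-gene bias, HLA
association, clonal expansion weighting) that are out of scope here, and
only the simulation depth, minimum k-mer support and CDR3 length cutoff are
pinned to conventional values; everything else is exposed configuration.

## Cross-sample similarity and classification

Each sample reduces to the set of group ids in which it has at least one
member clonotype.  Pairwise similarity is the Jaccard index
`|A∩B| / |A∪B|`; two empty profiles score 0, not 1 — an uninformative
sample should not look similar to anything.  Group-level contrasts compare
within-group pair similarities (and each group against cross-group pairs)
by rank-sum test.

A pre-symptomatic query is classified by its median Jaccard similarity to
the GVHD library versus the no-GVHD library, with a rank-sum p-value over
the two similarity sets.  The median is the primary score because it is
robust to a single highly similar relative in either library.  Sparse
membership profiles produce frequent exact median ties (typically 0 vs 0);
the classifier then falls back to the mean, and only a full tie is reported
as `indeterminate`.  Under a symmetric null (no group-specific motifs
anywhere) the two labels are assigned at equal rates — the package checks
this at 200 simulated queries — while queries carrying the GVHD motif panel
are assigned to the GVHD library essentially always.  Classification uses
group-membership sets; a clonotype-set mode would be a straightforward
variant but membership sets are the default because they match how the
similarity matrix is defined.

## Longitudinal tracking and stage overlap

The top-N clonotypes (default 100, deterministic tie-breaks) of a chosen
reference stage are looked up in every stage of the same subject; absent
clones report frequency 0 and status `absent`.  Either disease stage can
serve as reference, which changes the tracked key set on asymmetric data.

Between-stage overlap uses the **Morisita–Horn** index

    C = 2 Σ x_i y_i / ((d_x + d_y) · X · Y),   d_x = Σ x_i²/X²,

chosen over the classical count-based Morisita index because it is a
function of relative abundances only (robust to unequal depths) and is the
standard choice in repertoire-overlap tooling; the classical variant is
available behind a flag.  C is 1 for proportional count vectors, 0 for
disjoint supports, symmetric, and scale-invariant.

## Synthetic cohort generator

The generator exists so that every pipeline stage can be exercised, and its
statistical behavior verified, without sequencing data.  Defaults encode
the study design the pipeline targets: 15 GVHD, 13 no-GVHD and 15
healthy-individual samples plus 3 pre-symptomatic subjects; ~1.2 M reads
per sample before normalization to 1 M; group richness 20,000 (GVHD),
18,000 (healthy), 6,000 (no-GVHD) and 20,000 (pre-GVHD) unique clonotypes —
i.e. active-GVHD and healthy repertoires comparably rich, the no-GVHD group
markedly poorer, the contrast the diversity statistics are expected to
recover.

* **Clone sizes** follow a rank-abundance power law `count(r) ∝ r^(−a)`
  (default exponent 1.0), scaled and rounded to the configured depth; a
  configuration whose tail would round to zero reads is rejected with a
  suggestion.  Power laws are the standard empirical description of TCR
  clone-size distributions; the generator only needs to reproduce the
  qualitative contrasts the statistics test, not a mechanistic V(D)J model.
* **CDR3s** are framed `C…F` with interiors drawn from a fixed amino-acid
  profile (small/polar residues common, W/C/M rare) and lengths from a
  rounded normal (mean 14.5, SD 1.5, floor 8).
* **Motif spiking**: designated groups (GVHD and pre-GVHD by default)
  carry a panel of interior motifs — built from rare residues so chance
  occurrence elsewhere is negligible — inserted into 5% of clonotypes at
  uniformly random interior offsets, never touching the trim-protected
  termini.  Spiked clonotypes land at random abundance ranks.
* **Planted shared clones**: the same groups receive a small panel of
  full-length CDR3s at 0.05% frequency each, a synthetic stand-in for the
  tissue- and pathogen-associated clones that annotation scoring
  intersects; the generator exports matching annotation records.
* **Stage dynamics**: for longitudinal subjects, stage 1 (active disease)
  is generated directly; stage 0 (pre-symptomatic) is a lightly jittered
  copy, reflecting the observation that repertoires shortly before onset
  closely resemble onset; stage 2 (resolution) multiplies the stage-1 top-20
  clones by 0.05, applies mild lognormal jitter elsewhere, and promotes a
  fresh random set of 20 clones to a new power-law head holding 55% of
  reads.  The new head encodes the oligoclonal expansions that accompany
  resolution; without it, contraction of the old dominants alone would
  *even out* the distribution and raise the inverse Simpson index, the
  opposite of the diversity decline the resolution phase shows.  With it,
  diversity falls from stage 1 to stage 2 and stage 0/1 overlap exceeds
  stage 1/2 overlap for essentially every subject.
* **Determinism**: every subject and every reference repertoire draws from
  an RNG stream derived from the master seed and its own label (via a CRC
  of the label), so adding or removing a subject never changes any other
  subject's data, and two master seeds produce essentially disjoint
  cohorts.

What the generator does **not** emulate: junctional nucleotide biology (no
D segments, no insertion/deletion modelling), HLA restriction, CD4/CD8 or
naive/memory substructure, sequencing error, or PCR amplification noise.
Passing tests on synthetic cohorts therefore demonstrate that the
*statistics and decision rules* behave as designed under the assumed
repertoire structure — not that the biological effect sizes of any real
cohort will match.

## Validation experiment sizes

The `experiments` module fixes the problem sizes used by the test suite and
`scripts/acceptance.py`; they are chosen as the smallest sizes at which
each effect is unambiguous:

* formula oracles: 1,000 random repertoires/sets, richness ≤ 50, compared
  at 1e-12 relative tolerance;
* down-sampling: counts {3, 1} to depth 2 over 10,000 seeds, means within
  3 standard errors of the hypergeometric expectations (1.5, 0.5);
* null motif calibration: pool of 600 CDR3s subset from a 6,000-CDR3
  reference, 2-mers, simulation depth 200;
* motif recovery: 10 spiked samples (richness 400, 25,000 reads), 3-motif
  panel at 5% spike fraction, motif-free 10,000-CDR3 reference, 5 seeds;
* group contrast: richness 20,000 vs 6,000, 10 samples per group,
  normalized to 200,000 reads, 20 seeds;
* classification: 8+8 libraries with one spiked query, 20 seeds; null
  symmetry with 10+10 libraries and 200 motif-free queries (label rate
  computed over queries receiving a library label);
* stage dynamics: 10 three-stage subjects, richness 3,000, 120,000 reads;
* annotation contrast: 10 vs 10 samples with the planted panel as the
  annotation set.

## Known limitations

* The local-motif screen inherits the selection effect described above:
  raw empirical p-values for sparsely-supported (k ≥ 3) motifs are
  anti-conservative *as a population of tested motifs*, even though each is
  individually exact; downstream retention leans on the fold filter for
  that regime.
* Classification is a two-library comparison with a median/mean decision
  rule; it does not produce calibrated class probabilities and has no
  notion of time-to-onset.
* Chao1 assumes the singleton/doubleton counts of the *normalized*
  repertoire are informative about unseen richness; heavy down-sampling
  compresses that information.
* The pipeline analyzes one chain at a time (TRA or TRB); paired-chain
  analyses are out of scope.
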