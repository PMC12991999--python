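# tcrgvhd

T-cell receptor (TCR) repertoire analysis for acute graft-versus-host
disease (aGVHD) studies after allogeneic hematopoietic stem cell
transplantation.

After transplantation, donor T cells reconstitute the recipient's immune
system; when they recognize host tissue as foreign they cause aGVHD, a major
source of post-transplant morbidity.  Bulk TCR sequencing of the
hypervariable CDR3 region turns each blood sample into a *repertoire* — a
table of clonotypes (CDR3 amino-acid sequence + V + J gene segments) with
read counts — and the structure of that repertoire carries clinical signal:
active-aGVHD repertoires are broader and more polyclonal than those of
patients without GVHD, patients with aGVHD share CDR3 sequence motifs with
one another, and the clones that dominate at disease onset contract as
symptoms resolve.

`tcrgvhd` implements the full analysis chain such a study needs, for
immunologists and bioinformaticians working with AIRR-format clonotype
tables:

* **I/O** — AIRR Rearrangement TSV and a simple 5-column clonotype dialect;
  VDJdb-style annotation tables; productive-read and amino-acid-alphabet
  filtering; allele-suffix stripping; duplicate-clonotype merging.
* **Depth normalization** — down-sampling of every sample to a common number
  of productive reads (default 10⁶) by multivariate hypergeometric
  (without-replacement) sampling.
* **Diversity and clonality** — richness, Chao1
  (`S_obs + f₁²/2f₂`), inverse Simpson index (`1/Σpᵢ²`), z-score–based
  expanded-clone counts (z > 2), low-frequency clone counts (count < 100),
  rank-band read masses (ranks 1–10 / 11–100 / 101–1000), frequency-band
  richness, CDR3 length distributions, V/J segment usage, and two-sided
  group tests (Wilcoxon rank-sum / signed-rank, Kolmogorov–Smirnov,
  Fisher's exact).
* **Specificity-group clustering** — GLIPH-style grouping of pooled
  high-frequency CDR3s (> 0.01% of reads, length ≥ 8): *local* groups from
  interior k-mer motifs enriched against a naive reference repertoire via a
  resampled null (simulation depth 1000, minimum k-mer support 3), and
  *global* groups of equal-length CDR3s whose trimmed interiors differ at
  most at one position.
* **Similarity and prediction** — Jaccard index over samples'
  group-membership sets, within/between-group contrasts, and classification
  of pre-symptomatic samples against GVHD and no-GVHD libraries.
* **Longitudinal tracking** — top-100 clonotype tracking across disease
  stages and Morisita–Horn overlap between stages.
* **Antigen annotation** — exact-match intersection of high-frequency clones
  with annotated CDR3 sets (tissue-derived or pathogen-specific), scored as
  the summed frequency of shared clones.
* **Synthetic cohorts** — a generator producing labeled multi-sample,
  multi-stage cohorts with power-law clone sizes, group-structured richness,
  spiked CDR3 motifs and planted shared clones, so the entire pipeline is
  testable without any sequencing data.

## Worked example

```python
import tcrgvhd as t

cfg = t.CohortConfig(
    n_per_group={"GVHD": 5, "NO_GVHD": 5, "GVHD_PRE": 1},
    richness={"GVHD": 2000, "NO_GVHD": 600, "GVHD_PRE": 2000},
    total_reads=120_000,
    seed=1,
)
cohort = t.generate_cohort(cfg)
cohort, _ = t.normalize_cohort(cohort, target_reads=100_000, seed=1)

for rep in cohort[:3]:
    print(f"{rep.sample_id}: richness={rep.richness}, "
          f"chao1={t.chao1(rep):.0f}, ISI={t.inverse_simpson(rep):.1f}, "
          f"expanded(z>2)={t.expanded_count_z2(rep)}")

rich = {g: [r.richness for r in cohort if r.group == g]
        for g in ("GVHD", "NO_GVHD")}
print(f"richness GVHD vs NO_GVHD: rank-sum p = {t.compare_groups(rich).p:.4f}")

reference = t.generate_reference(30_000, seed=2)
groups = t.build_gliph_groups(cohort, reference,
                              t.GliphConfig(simulation_depth=200, seed=1))
print(f"{len(groups)} specificity groups "
      f"({sum(g.kind == 'local' for g in groups)} local motifs)")

profiles = t.membership_profiles(groups, cohort)
gv = {r.sample_id: profiles[r.sample_id] for r in cohort if r.group == "GVHD"}
ng = {r.sample_id: profiles[r.sample_id] for r in cohort if r.group == "NO_GVHD"}
query = next(r for r in cohort if r.group == "GVHD_PRE")
res = t.classify_query(profiles[query.sample_id], gv, ng)
print(f"{query.sample_id}: label={res.label}, "
      f"median Jaccard vs GVHD={res.score_gvhd:.3f}, "
      f"vs NO_GVHD={res.score_nogvhd:.3f}")
```

Output:

```
GVHD_01: richness=2000, chao1=2000, ISI=40.8, expanded(z>2)=16
GVHD_02: richness=2000, chao1=2000, ISI=40.7, expanded(z>2)=16
GVHD_03: richness=2000, chao1=2000, ISI=40.8, expanded(z>2)=16
richness GVHD vs NO_GVHD: rank-sum p = 0.0040
399 specificity groups (383 local motifs)
GVHD_PRE_01: label=GVHD, median Jaccard vs GVHD=0.327, vs NO_GVHD=0.069
```

The configured GVHD-group repertoires are richer than the no-GVHD ones (the
rank-sum test recovers the difference at p = 0.004), the shared motif panel
spiked into GVHD-like samples is recovered as local specificity groups, and
the pre-symptomatic query — which carries the same motifs — is classified
into the GVHD library by its far higher median Jaccard similarity.

## Command line

Every stage is also a subcommand of the `tcrgvhd` CLI, connected by manifest
TSVs (`sample_id, subject_id, group, stage, path`), so real AIRR data can
enter at any point:

```bash
tcrgvhd simulate  --config cohort.yaml --out-dir run/samples --seed 1
tcrgvhd normalize --manifest run/samples/manifest.tsv --out-dir run/norm \
                  --target-reads 1000000
tcrgvhd diversity --manifest run/norm/manifest.tsv --out-dir run/div
tcrgvhd gliph     --manifest run/norm/manifest.tsv --out-dir run/gliph
tcrgvhd similarity --manifest run/norm/manifest.tsv \
                   --members run/gliph/gliph_members.tsv --out-dir run/sim
tcrgvhd track     --manifest run/norm/manifest.tsv --out-dir run/track
tcrgvhd annotate  --manifest run/norm/manifest.tsv \
                  --annotations cmv=cmv.tsv --out-dir run/ann
tcrgvhd run-all   --config pipeline.yaml --out-dir run/all --seed 1
```

`run-all` executes the whole chain and writes a consolidated `report.json`;
re-running with the same config and seed reproduces every output byte for
byte.

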