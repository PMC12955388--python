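# famshare

Family-level analysis of gut-microbiome macro- and microdiversity:
which species populations are shared within families, how much of the
community and intraspecies genetic variation the family factor explains,
and what selective pressure and functional potential the shared genomes
carry. A synthetic-cohort generator with planted ground truth (family
abundance effects, within-family strain transmissions) stands in for raw
sequencing data, so every statistic in the pipeline can be validated
against a known answer.

## What's inside

| module | role |
|---|---|
| `famshare.cohort` | domain types (samples, families, genomes, distance matrices, SNV profiles, gene models) and quality filtering (completeness ≥ 50%, contamination ≤ 10%) |
| `famshare.io` | readers/writers for the plain-text input bundle (FASTA + TSVs) |
| `famshare.simulate` | synthetic family cohorts: per-species ancestors, host strains by point mutation, planted transmissions, log-normal family-correlated abundance, codon-aware gene models and SNV tables |
| `famshare.quantify` | RPKM, Shannon (nats), Bray-Curtis, within/between-family comparisons, child-parent and diversity-similarity trends |
| `famshare.permanova` | distance-based ANOVA: single-factor tests and marginal (by-margin) effects with Freedman-Lane residual permutation |
| `famshare.ani` | fragment-based ANI (k-mer placement, ungapped identity), 1−ANI distance matrices, two-stage dereplication (coarse sketch + complete-linkage) |
| `famshare.sharing` | candidate-population selection (≥2 members in ≥30% of families), family-association flagging (R² > 0.5, p < 0.05), sharing-event counts, classical MDS, intraspecies genetic-composition distance |
| `famshare.microdiversity` | nucleotide diversity π and per-gene pN/pS with NG86-style site counting (genetic code 11) |
| `famshare.funcmodules` | metabolic-module presence calling at a coverage cutoff (default 0.66), with a packaged SCFA-module fixture |
| `famshare.network` | Spearman co-occurrence networks (0.6 < \|rho\| < 1, p < 0.05) and core-node extraction |
| `famshare.pipeline` / `famshare.cli` | end-to-end orchestration with a reproducibility manifest |
| `famshare.validation` | calibration/recovery experiments backing the acceptance report |

## CLI

```bash
famshare simulate --config sim.yaml --out bundle/        # synthetic bundle + truth.tsv
famshare run --bundle bundle/ --out report/ --seed 0     # full pipeline
famshare demo --out demo/ --seed 0                       # simulate + run, <1 min
# stage-level commands:
famshare diversity --abundance a.tsv --metadata m.tsv --out d/
famshare permanova --distance d.tsv --metadata m.tsv --out perm.tsv
famshare ani --genomes bundle/ --species sp1 --out ani.tsv
famshare share --genomes bundle/ --metadata m.tsv --out share/
famshare microdiv --snv snv.tsv --genes genes.tsv --genomes bundle/ --out md/
famshare modules --ko ko.tsv --cutoff 0.66 --out presence.tsv
famshare network --profiles taxa_by_samples.tsv --out edges.tsv
```

The report directory contains one TSV per stage (Shannon, Bray-Curtis
matrix, PERMANOVA table at both the composition and genetic levels,
per-population sharing statistics, MDS coordinates for flagged
populations, π, per-gene pN/pS, module presence, network edges) plus
`manifest.json` recording the seed, every threshold and the SHA-256 of
each input — two runs with the same seed are byte-identical.

## Conventions worth knowing

- Coordinates are 1-based inclusive; `N` bases are legal and excluded
  from ANI/SNV computations.
- Shannon uses natural log; Spearman uses average ranks (all-tied
  vectors are defined as rho = 0, p = 1).
- The ANI cutoff defining a sharing event (default **99.5%**) is a
  configurable convention — the analysis this package models does not
  state one.
- Fragment ANI uses ungapped scoring: exact for the indel-free
  synthetic data model, an underestimate for real genomes with indels.
- SNV sites are filtered at total count ≥ 5 and minor frequency ≥ 0.05
  (configurable) before π / pN/pS.
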