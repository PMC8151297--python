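# capspop

CAPS-marker genotyping and population-genetic analysis toolkit for small
germplasm panels.

A CAPS (cleaved amplified polymorphic sequence) marker genotypes a SNP by
digesting a PCR amplicon with a restriction enzyme whose recognition site is
created or destroyed by the SNP, and reading the resulting gel band pattern.
`capspop` covers the full downstream analysis of such a panel:

- **`genotype_data`** — data model and TSV/CSV I/O for codominant diploid
  genotype matrices (cells like `A/G`, missing `-/-`) and marker-definition
  tables; packaged reference tables for a 70-marker button-mushroom panel.
- **`caps_insilico`** — substitution classification (transition /
  transversion), IUPAC motif scanning on both strands, in-silico digestion,
  per-allele fragment-pattern assessment, and genotype calling from observed
  band patterns; ships a small editable enzyme table (name, motif, cut offset).
- **`diversity_stats`** — per-locus MAF, number of genotypes/alleles, gene
  diversity (1 − Σp²) and observed heterozygosity; panel summaries and the
  (k−1)/k rescaling for cross-marker-type diversity comparison.
- **`distance_clustering`** — Nei's standard distance between diploid
  individuals (within-individual allele frequencies, pairwise deletion) and
  size-weighted UPGMA with Newick output.
- **`ordination`** — principal coordinates analysis (Gower double-centering,
  positive-eigenvalue axes, optional Cailliez correction).
- **`amova`** — three-level codominant AMOVA (among populations / among
  individuals / within individuals) with unequal-size coefficients,
  negative-component truncation, F\_ST, and a whole-individual permutation
  test.
- **`structure_admixture`** — admixture-model Gibbs sampler (origin, allele
  frequency, q and alpha updates), STRUCTURE-style log-evidence
  (mean − var/2), Evanno's delta-K across replicate runs, and membership
  classification with an "Admix" class.
- **`marker_selection`** — multilocus-genotype counting, genotype
  accumulation curves, greedy minimum-marker-set selection and an exhaustive
  optimality oracle for small panels.
- **`synthetic_data`** — seeded Balding–Nichols generator of genotype
  matrices (known F\_ST, homozygote excess, admixed individuals, monomorphic
  loci), plus amplicon/marker panels guaranteed to digest differentially.
- **`pipeline`** / **`cli`** — one-config orchestration of the whole
  analysis with deterministic per-stage seeds.

## CLI

```bash
capspop simulate --seed 7 --out-prefix demo          # synthetic panel
capspop stats demo_genotypes.tsv --markers demo_markers.tsv --out stats.tsv
capspop distance demo_genotypes.tsv --out dist.tsv
capspop tree demo_genotypes.tsv --out tree.nwk
capspop pcoa demo_genotypes.tsv --out pcoa.tsv
capspop amova demo_genotypes.tsv --pops demo_pops.tsv --perms 1000 --seed 1 --out amova.tsv
capspop structure demo_genotypes.tsv --kmin 1 --kmax 4 --reps 5 \
    --burnin 2000 --iters 5000 --seed 1 --out-prefix demo
capspop select-markers demo_genotypes.tsv --out-prefix demo
capspop digest demo_amplicons.fasta --markers demo_markers.tsv
capspop run --config pipeline.toml                   # full pipeline
```

A pipeline TOML names the inputs and per-stage parameters:

```toml
genotype_table = "demo_genotypes.tsv"
population_column = "demo_pops.tsv"
out_dir = "results"
seed = 7
stages = ["stats", "distance", "tree", "pcoa", "amova", "structure", "select_markers"]
```

## Notes and limitations

- The admixture sampler implements the vanilla admixture model with a
  uniform allele-frequency prior; location-informed priors (LOCPRIOR) and
  correlated-frequency priors are not implemented.
- Enzyme motifs in `capspop/data/enzymes.tsv` are a convenience table meant
  to be edited/extended; outside-cutters are modeled by a cut offset beyond
  the motif with end-of-sequence cuts skipped.
- Observed heterozygosity is the heterozygous-call proportion; no unbiased
  (n/(n−1)) corrections are applied.
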