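# clonepop

Population genomics and epigenomics of facultatively asexual plant
populations, at desk scale.

Many plants — the giant duckweed is the canonical example — reproduce
clonally by default and flower only rarely. The fraction of sexual
generations, σ, then controls the *effective* recombination rate of a
population (ρ_eff = ρ·σ), and through it linkage disequilibrium, the
efficacy of selection, and even the maintenance of DNA methylation, which is
reinforced during meiosis and embryogenesis. `clonepop` implements the full
analysis arc that a resequencing + whole-genome-bisulfite study of such a
species needs, together with a built-in coalescent simulator of partially
clonal populations so that every estimator can be validated against known
truth:

* **Variant filtering** — GATK-style hard filters
  (`QD < 2, QUAL < 30, SOR > 3, FS > 60, MQ < 40, MQRankSum < −12.5,
  ReadPosRankSum < −8`) followed by an ordered cascade (organelle contigs,
  missingness > 20%, mean depth outside [8, 41], non-biallelic, MAF < 1%,
  ≥ 3-SNP clusters per 10 bp) with first-rule attribution.
* **Clonal structure** — clonal families as connected components of pairs
  differing at ≤ 0.01% of jointly homozygous and ≤ 2% of heterozygous
  sites; least-missing representatives; per-individual heterozygosity; HWE +
  LD pruning masks for structure analyses.
* **Diversity and LD** — π (unbiased pairwise heterozygosity over a callable
  length), π_N/π_S with Nei–Gojobori site counting, Tajima's D, composite
  (dosage-correlation) r², and the LD-decay distance at r² = 0.2.
* **Sweep scans** — a composite likelihood ratio contrasting the genome
  background SFS with a sweep-transformed SFS (lineages escape with
  probability p_e = 1 − e^{−αd}), and a μ-type statistic multiplying
  diversity-reduction, SFS-skew and LD-partition factors; top-1% window
  calling and gene overlap/intersection.
* **Branch-specific selection** — a three-population scan that models linked
  allele-frequency differentiation as Gaussian drift (variance ω·p(1−p))
  and detects branch-local, distance-decaying variance inflation; candidates
  validated by low π and negative Tajima's D.
* **Methylome** — bisulfite non-conversion from an unmethylated chloroplast
  control, per-cytosine binomial calling (BH-corrected), mC proportion and
  weighted methylation level (wML = Σm / Σ(m+u)) by CpG/CHG/CHH context and
  region, metagene profiles with 2 kb flanks, methylome clustering and
  Mantel concordance with genetic distance.
* **Demography** — rejection ABC over three four-population scenarios
  (asia-ancestral, america-ancestral, or an unsampled "ghost" ancestor),
  with per-population σ among the inferred parameters.
* **Simulator** — a structured sequentially-Markov coalescent in which each
  population recombines at its own rate ρ·σ(p); hard sweeps are injected
  post hoc; fixtures with planted filter violations, known methylation
  states, and valid annotated genomes are generated programmatically.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1
```

```
simulated 32 diploids, 5750 SNPs over 300000 bp
population  sigma       Ne       pi
   america  0.010 200000.0 0.001327
      asia  0.100 600000.0 0.002980
     india  0.030 300000.0 0.002812
    europe  0.003 100000.0 0.002562
asia most diverse: True
```

The most sexual population (asia, σ = 0.1, Ne = 6·10⁵) carries the most
diversity, as theory predicts. Downstream drivers follow the same pattern —
`analysis/05_sweep_scans.py` injects a hard sweep at 150 kb and reports

```
sweep injected at 150000; CLR max at 150081 (CLR = 30.9); mu max at 155921 (mu = 4.89)
intersection of both methods: ['g025', 'g026', 'g027']
```

i.e. both scans localize the sweep to within a window and agree on the
overlapped genes, while `analysis/09_demography_abc.py` fits the three
demographic scenarios by rejection ABC and reports the posterior over
scenarios and the split-time posteriors:

```
model posterior: {'asia_ancestral': 0.32, 'america_ancestral': 0.31, 'ghost_ancestral': 0.37}
winning scenario: ghost_ancestral (truth: ghost_ancestral)
```

The numbered scripts under `analysis/` run each stage end-to-end
(simulation → filtering → clonal structure → diversity/LD → sweeps → branch
scans → methylome → enrichment → ABC) and write their tables under
`results/`. Every number they print is recomputed at run time.

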