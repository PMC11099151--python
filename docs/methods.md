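# Methods

## The simulator: a structured coalescent with per-population recombination

Partial clonality enters the model in exactly one place. A lineage residing
in population *p* recombines at ρ·σ(*p*) per base pair per generation,
where ρ is the sexual-phase recombination rate and σ(*p*) ∈ [0, 1] the
fraction of generations that are sexual. Everything else is a standard
pure-split coalescent: four contemporary populations (america, asia, india,
europe) with diploid sizes N(*p*), europe merging into the asia lineage most
recently, india next, and the deepest event either asia-ancestral,
america-ancestral, or a merger of both into an unsampled ghost population,
depending on the scenario.

The engine is a sequentially-Markov coalescent (SMC). The genealogy at the
left chromosome end is drawn from the structured coalescent (pairwise rate
1/(2N) within each population, no migration); the distance to the next
breakpoint is exponential with rate equal to the recombination-weighted
branch length of the current tree, where each branch segment is weighted by
the σ of the population it occupies at that time; at a breakpoint, the
lineage above the chosen branch-time point is detached and re-coalesced
under the structured rates. Because there is no migration, the population a
branch occupies is a deterministic function of the sample populations below
it and the split schedule, which keeps this bookkeeping exact. Mutations
follow the infinite-sites model on integer coordinates (collisions are
dropped); the ancestral allele is the REF allele, so polarization truth is
exact. σ = 0 yields a single genealogy per chromosome by construction.

The SMC approximation (versus the full ancestral recombination graph) is
standard for this regime; marginal single-site statistics are exact, and
two-site statistics are accurate at the distances that matter for LD decay.
A cross-check against msprime's Hudson model in the one regime where the two
processes coincide (single population, σ = 1) is part of the test suite —
mean segregating sites and π agree within Monte Carlo error.

`theta_site` is the expected pairwise diversity 4·N_ref·μ at a reference
size (the mean of contemporary sizes unless given explicitly), so
single-population calibration experiments are exact by construction; with an
explicit fixed `reference_size` (as in ABC) the mutation rate is a constant
and per-population diversity identifies N(*p*).

**What the simulator does not emulate.** Clonality is modelled *only*
through effective recombination. Consequences: single-site statistics
(SFS, per-individual heterozygosity) are σ-invariant, so the simulator does
not reproduce clonal heterozygosity accumulation (the Meselson effect); an
optional heterozygosity offset existed as a design alternative and was left
out of scope. There is no gene conversion, no selection during the
coalescent (sweeps are injected post hoc), no sequencing-error model for
genotypes, and no read-level simulation. Passing tests therefore validate
the estimators and the recombination/LD logic, not genotype-calling noise.

## Sweep injection

`inject_sweep` drives the derived allele at the focal site to frequency
≥ 0.95 in the target population (each diploid escapes with probability
0.02) and homogenizes linked sites onto a single *template haplotype*: the
template sample's heterozygous sites are resolved to one allele each, once,
and at a site at distance *d* each swept sample independently keeps its own
genotype with escape probability 1 − exp(−d/strength), otherwise adopting
the template homozygote. Per-sample (rather than per-site) escape is what
produces hitchhiking's characteristic SFS: high-frequency-derived classes
plus rare escapee alleles. `strength` is the footprint length scale in bp;
strength → 0 alters only the focal site.

## Estimators

* π per site: 2·(k/n)(1 − k/n)·n/(n − 1); region π divides the sum over
  SNPs by a supplied callable length (monomorphic sites contribute through
  the denominator). SNPs inside excluded intervals (e.g. structural
  variants) are skipped.
* π_N/π_S: Nei–Gojobori site counting (each codon position contributes the
  fraction of its three changes that are synonymous), N + S equal to CDS
  length exactly; ratio undefined (NaN, not ∞) when π_S = 0.
* Tajima's D from the standard constants; reported missing (not 0) when
  S = 0 so window means are not biased.
* r² is the squared Pearson correlation of unphased dosage vectors over
  jointly-called samples (composite estimator; no phasing needed). LD decay
  bins pairs by physical distance to 100 kb; the decay distance applies an
  isotonic-decreasing fit to the bin means before linear interpolation at
  r² = 0.2, and reports "beyond max distance" (∞) when the curve never
  reaches the threshold.
* HWE uses the exact conditional test (heterozygote-count distribution given
  allele counts); LD pruning slides 50-SNP windows in steps of 5 and drops
  the later member of any pair with r² > 0.33.

## Sweep scans

The CLR scan follows the classical composite-likelihood construction: the
genome-wide SFS is the background; at escape probability p_e each of the n
lineages escapes independently, the k escapees plus the single swept
ancestral lineage form an effective sample of k + 1 drawn from the
background (hypergeometric projection), and the swept lineage's state is
replicated into the n − k non-escapees. Monomorphic outcome classes are
dropped and the spectrum renormalized before likelihood evaluation, since
only segregating sites enter the data (this shifts absolute CLR values, not
their ranking). p_e(d, α) = 1 − exp(−α·d) with α maximized over a grid that
includes the neutral limit, so CLR ≥ 0. Spectra are precomputed on a 48-point
p_e grid and looked up by nearest value. Defaults: grid every 10 kb, 50 kb
flanks, α ∈ geomspace(2·10⁻⁶, 2·10⁻³); positions with < 5 SNPs are skipped.

The μ statistic multiplies, over k = 50-SNP windows: window span / k over
the genome-average SNP spacing (diversity reduction), the observed fraction
of singleton and (n−1) classes over its neutral expectation
(1 + 1/(n−1))/Σ1/j (SFS skew), and within-half over cross-half mean r²
(LD partition, ε = 10⁻⁶).

## Branch scan

For a (outgroup, a, b) tree, the outgroup frequency is the ancestral proxy
(a documented simplification of the published three-population composite
method, which integrates over the latent ancestral frequency). Drift scales
ω are method-of-moments estimates with binomial sampling corrections,
floored at 0; under pure drift ω ≈ T/2N summed along the path between the
branch and the outgroup. Selection inflates the focal branch's drift
variance by 1 + A·exp(−d/r_scale) (grids A ∈ {0, 0.5, 1, 2, 5, 10},
r_scale ∈ {5, 20, 50} kb; A = 0 nests the neutral model). The scan slides
100-SNP windows with every 10th SNP focal. Branch scans are informative when
baseline drift is far from saturation — with a deeply diverged outgroup
(T ≳ 2N) frequencies pin at their variance bound and local inflation is
invisible; the validation experiments therefore use recent splits and large
sizes (ω ≈ 0.1).

## Methylome

Non-conversion e is the pooled methylated-read fraction on the chloroplast
control. Calling drops cytosines with coverage < 5, computes the binomial
tail P(X ≥ m | cov, e), adjusts by Benjamini–Hochberg at 0.05 (the test is
stated in the source methodology without a correction; raw-α mode is
available), and zeroes the methylated reads of non-significant sites while
preserving coverage so regional denominators are unchanged. Cytosines are
strand-resolved throughout (no CpG symmetrization). Metagene profiles use
20 scaled body bins and 10 fixed bins per 2 kb flank, reversing minus-strand
features. Clustering is average linkage on 1 − Pearson correlation of
regional wML profiles (scipy's deterministic merge order); concordance with
genetic distance is a one-sided Mantel test with add-one permutation p.

## Enrichment

The permutation null re-places each interval uniformly on its source
chromosome (length preserved, overlaps permitted; cross-chromosome placement
available). Empirical p = (1 + #{null ≥ obs})/(N + 1), BH across families.
Fisher's exact test, Pearson χ² (no continuity correction by default) and
the OLS Wald association stand behind thin wrappers.

## ABC

Rejection only (no regression adjustment). Summaries per population: π,
first five folded-SFS proportions, LD-decay distance censored at 50 kb,
median heterozygosity; per pair: Hudson F_ST (ratio of averages) and the
shared-polymorphism fraction (segregating in both / segregating in either).
The shared-polymorphism summaries carry most of the deep-structure signal
that separates the three scenarios; without them model choice is close to
chance. Summaries are standardized by the reference table's spread;
zero-spread summaries are dropped. Priors: split times log-uniform
10³–5·10⁶ generations (draws sorted to respect the topology), sizes
log-uniform 10³–10⁶, σ uniform 0.001–1. The mutation rate is fixed via
reference_size = 2.5·10⁵ and θ_ref = 0.0016 so diversity identifies size.

Validation runs ten independent recovery trials, each with its *own*
1000-simulation reference table (L = 60 kb, 4 diploids per population,
tolerance 0.05 for model choice, 0.10 for parameter posteriors). One shared
table would correlate all trials through table-level sampling noise and turn
the experiment into a lottery over tables. The recovery truth uses a small
ghost population (N = 1.5·10⁴) against large sampled populations — the
regime in which the ghost scenario is identifiable at desk scale.

## Problem sizes used in validation

Chosen as the smallest sizes at which each check is informative: simulator
calibration at n = 20 diploids, L = 500 kb, 50 replicates; LD ordering over
σ ∈ {0.01, 0.1, 1} at L = 100 kb with matched seeds, 20 replicates; sweep
power at n = 20 diploids, L = 300 kb, footprint 15 kb, 20 replicates; null
calibration on a 2 kb scan grid (a top-1% cutoff estimated from a coarse
30-position scan is order-statistics biased upward, so the dense grid is
required to measure the nominal rate); branch attribution at
3 × 8 diploids, L = 400 kb, footprint 25 kb, 20 replicates; clonal recovery
at L = 400 kb so that heterozygous-site denominators are large enough for
the 2% threshold to be meaningful at 0.5% planted LOH divergence.

## Known limitations

* SMC (not SMC'), so very long-range LD is slightly underestimated; immaterial
  at ≤ 100 kb scales with the rates used here.
* The branch scan's Gaussian likelihood treats SNPs as independent;
  genealogical correlation inflates window CLRs under low recombination, so
  empirical top-quantile calling (not absolute CLR) is the supported
  interpretation.
* Folded-spectrum projection operates on minor-allele counts directly, an
  approximation to folding after projection; exact for complete-call data.
* The effect classifier annotates against a single transcript per gene and
  labels sites 'other' when the VCF REF disagrees with the reference genome.
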