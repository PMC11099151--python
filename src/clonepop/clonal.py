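"""Clonal-family identification from pairwise genotype distances.

A facultatively asexual plant is resampled as near-identical clones: a pair
belongs to the same clonal family when it differs at no more than 0.01% of
jointly homozygous sites and no more than 2% of heterozygous-involving
sites.  Families are the connected components of that graph (transitive
closure), and each family is represented by its least-missing member.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .genotypes import MISSING, GenotypeMatrix

DEFAULT_HOM_THRESH = 1e-4   # 0.01% different homozygous sites
DEFAULT_HET_THRESH = 0.02   # 2% different heterozygous sites


@dataclass
class PairwiseDistances:
    sample_ids: list
    hom_frac: np.ndarray      # fraction of jointly-hom sites with different alleles
    het_frac: np.ndarray      # fraction of het-involving jointly-called sites that differ
    hom_n: np.ndarray         # denominators
    het_n: np.ndarray

    def defined(self) -> np.ndarray:
        return self.hom_n > 0


@dataclass
class ClonalPartition:
    families: list            # list of lists of sample ids
    representative: dict      # family index -> sample id
    pairwise: PairwiseDistances


def pairwise_genotype_distances(gm: GenotypeMatrix) -> PairwiseDistances:
    """Homozygous- and heterozygous-difference fractions for every pair.

    hom fraction: sites where both are called and homozygous, with different
    alleles (0 vs 2), over all jointly-called jointly-homozygous sites.
    het fraction: sites where both are called and at least one is
    heterozygous, with differing genotypes, over those sites.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    d = gm.dosage
    n = gm.n_samples
    called = d != MISSING
    hom = called & ((d == 0) | (d == 2))
    het = called & (d == 1)
    hom_frac = np.zeros((n, n))
    het_frac = np.zeros((n, n))
    hom_n = np.zeros((n, n), dtype=np.int64)
    het_n = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            both_hom = hom[i] & hom[j]
            nh = int(both_hom.sum())
            diff_h = int((d[i, both_hom] != d[j, both_hom]).sum())
            any_het = (het[i] | het[j]) & called[i] & called[j]
            ne = int(any_het.sum())
            diff_e = int((d[i, any_het] != d[j, any_het]).sum())
            hom_n[i, j] = hom_n[j, i] = nh
            het_n[i, j] = het_n[j, i] = ne
            hom_frac[i, j] = hom_frac[j, i] = diff_h / nh if nh else np.nan
            het_frac[i, j] = het_frac[j, i] = diff_e / ne if ne else 0.0
    return PairwiseDistances(list(gm.sample_ids), hom_frac, het_frac, hom_n, het_n)


def clonal_families(
    pairwise: PairwiseDistances,
    hom_thresh: float = DEFAULT_HOM_THRESH,
    het_thresh: float = DEFAULT_HET_THRESH,
) -> ClonalPartition:
    """Connected components of the clonal-pair graph.

    An edge joins a pair iff both fractions are defined and at or below
    their thresholds; undefined distances are conservative non-edges.
    """
    n = len(pairwise.sample_ids)
    with np.errstate(invalid="ignore"):
        adj = (
            (pairwise.hom_frac <= hom_thresh)
            & (pairwise.het_frac <= het_thresh)
            & pairwise.defined()
        )
    np.fill_diagonal(adj, False)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    families = [[] for _ in range(labels.max() + 1)]
    for sid, lab in zip(pairwise.sample_ids, labels):
        families[lab].append(sid)
    families = sorted((sorted(f) for f in families), key=lambda f: f[0])
    return ClonalPartition(families=families, representative={}, pairwise=pairwise)


def select_representatives(partition: ClonalPartition, gm: GenotypeMatrix) -> dict:
    """Least-missing member per family; ties broken by lexicographic id."""
    missing = dict(zip(gm.sample_ids, (gm.dosage == MISSING).mean(axis=1)))
    reps = {}
    for fi, fam in enumerate(partition.families):
        reps[fi] = min(fam, key=lambda s: (missing[s], s))
    partition.representative = reps
    return reps


def individual_heterozygosity(gm: GenotypeMatrix):
    """Per-sample heterozygosity rate and per-population medians.

    Rate = heterozygous calls / called sites; samples with zero calls get
    NaN.  Returns (per-sample dict, per-population median dict).
    """
    d = gm.dosage
    called = (d != MISSING).sum(axis=1)
    het = (d == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(called > 0, het / np.maximum(called, 1), np.nan)
    per_sample = dict(zip(gm.sample_ids, rate))
    pops: dict = {}
    for sid, r in per_sample.items():
        pops.setdefault(gm.populations.get(sid), []).append(r)
    medians = {p: float(np.nanmedian(v)) for p, v in pops.items() if p is not None}
    return per_sample, medians


# ---------------------------------------------------------------------------
# Structure-analysis input mask: exact HWE test + windowed LD pruning
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy–Weinberg test.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed the observed one
    (the standard exact SNP-HWE construction).
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    probs = _het_count_distribution(n, n_rare)
    obs = probs.get(n_het, 0.0)
    return min(1.0, sum(p for p in probs.values() if p <= obs + 1e-12))


def _het_count_distribution(n: int, n_rare: int) -> dict:
    """P(het count) given n diploids and n_rare copies of the rarer allele."""
    from math import comb

    n_common = 2 * n - n_rare
    total = 0.0
    probs = {}
    for h in range(n_rare % 2, n_rare + 1, 2):
        a = (n_rare - h) // 2          # rare homozygotes
        b = n - h - a                  # common homozygotes
        if b < 0:
            continue
        # multinomial weight * 2^h, normalized below
        w = comb(n, a) * comb(n - a, h) * (2 ** h)
        # probability proportional to multinomial over ordered allele draws
        probs[h] = w
        total += w
    return {h: w / total for h, w in probs.items()}


def structure_input_mask(
    gm: GenotypeMatrix,
    hwe_alpha: float = 0.01,
    r2_max: float = 0.33,
    window: int = 50,
    step: int = 5,
) -> np.ndarray:
    """Keep mask for structure analyses: HWE filter then windowed LD pruning.

    Sites failing the exact HWE test at `hwe_alpha` are removed first; then,
    inside sliding windows of `window` SNPs advanced by `step`, the later
    member of any pair with r^2 > `r2_max` is greedily pruned.
    """
    keep = np.ones(gm.n_sites, dtype=bool)
    d = gm.dosage
    for j in range(gm.n_sites):
        col = d[:, j]
        called = col != MISSING
        p = hwe_exact_pvalue(
            int((col[called] == 0).sum()),
            int((col[called] == 1).sum()),
            int((col[called] == 2).sum()),
        )
        if p < hwe_alpha:
            keep[j] = False

    from .diversity import genotype_r2

    for c in np.unique(gm.chrom):
        idx = np.flatnonzero((gm.chrom == c) & keep)
        start = 0
        while start < idx.size:
            win = idx[start : start + window]
            for a in range(win.size):
                if not keep[win[a]]:
                    continue
                for b in range(a + 1, win.size):
                    if not keep[win[b]]:
                        continue
                    r2 = genotype_r2(d[:, win[a]], d[:, win[b]])
                    if np.isfinite(r2) and r2 > r2_max:
                        keep[win[b]] = False
            if start + window >= idx.size:
                break
            start += step
    return keep
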