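"""Diversity and linkage-disequilibrium statistics.

pi here is the unbiased per-site pairwise heterozygosity summed over SNPs and
divided by a callable length, which is the genome-wide convention that yields
per-site values like 0.0016 for a low-diversity plant.  r^2 is the composite
(genotype-dosage correlation) estimator, which needs no phasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .effects import count_ns_sites  # re-exported: N/S site totals live with codon logic
from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "per_site_pi", "region_pi", "count_ns_sites", "pin_pis", "tajimas_d",
    "tajimas_d_from_matrix", "genotype_r2", "ld_decay", "LDCurve",
    "sliding_windows",
]


def per_site_pi(alt_count, called_alleles):
    """Unbiased pairwise heterozygosity 2*(k/n)*(1-k/n)*n/(n-1); vectorized."""
    k = np.asarray(alt_count, dtype=float)
    n = np.asarray(called_alleles, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 2.0 * (k / n) * (1.0 - k / n) * n / (n - 1.0)
    return np.where(n >= 2, out, np.nan)


def region_pi(
    gm: GenotypeMatrix,
    region=None,
    callable_length=None,
    exclude: pd.DataFrame | None = None,
    sample_idx=None,
) -> float:
    """pi over a region: sum of per-site pi over included SNPs / callable bp.

    region is (chrom, start, end) 0-based half-open or None for everything;
    exclude is an optional interval frame (chrom, start, end) whose SNPs are
    skipped (e.g. SNPs inside structural variants).
    """
    mask = np.ones(gm.n_sites, dtype=bool)
    if region is not None:
        chrom, start, end = region
        mask &= (gm.chrom == chrom) & (gm.pos - 1 >= start) & (gm.pos - 1 < end)
        if callable_length is None:
            callable_length = end - start
    if callable_length is None or callable_length <= 0:
        raise ValueError("callable_length must be positive")
    if exclude is not None and len(exclude):
        for _, row in exclude.iterrows():
            mask &= ~(
                (gm.chrom == row["chrom"])
                & (gm.pos - 1 >= row["start"])
                & (gm.pos - 1 < row["end"])
            )
    k = gm.alt_counts(sample_idx)[mask]
    n = gm.called_alleles(sample_idx)[mask]
    pi = per_site_pi(k, n)
    return float(np.nansum(pi) / callable_length)


def pin_pis(gm: GenotypeMatrix, effects, n_sites: float, s_sites: float, sample_idx=None):
    """(pi_N, pi_S, ratio) from per-SNP effect classes and Nei–Gojobori totals.

    ratio is NaN (undefined, not infinity) when pi_S is zero.
    """
    effects = np.asarray(effects)
    k = gm.alt_counts(sample_idx)
    n = gm.called_alleles(sample_idx)
    pi = per_site_pi(k, n)
    pi_n = float(np.nansum(pi[effects == "nonsynonymous"]) / n_sites) if n_sites else 0.0
    pi_s = float(np.nansum(pi[effects == "synonymous"]) / s_sites) if s_sites else 0.0
    ratio = pi_n / pi_s if pi_s > 0 else (0.0 if pi_n == 0.0 else np.nan)
    return pi_n, pi_s, ratio


def tajimas_d(S: int, n: int, pi_total: float) -> float:
    """Tajima's D from segregating sites, haploid sample size, and mean
    pairwise differences (summed over sites, not per bp).  NaN when S == 0
    or n < 4."""
    if n < 4 or S == 0:
        return np.nan
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1.0)
    return float((pi_total - S / a1) / math.sqrt(var))


def tajimas_d_from_matrix(gm: GenotypeMatrix, site_mask=None, sample_idx=None) -> float:
    """Tajima's D of a set of sites, using the modal called sample size."""
    k = gm.alt_counts(sample_idx)
    n = gm.called_alleles(sample_idx)
    if site_mask is not None:
        k, n = k[site_mask], n[site_mask]
    seg = (k > 0) & (k < n) & (n >= 2)
    if seg.sum() == 0:
        return np.nan
    n_common = int(pd.Series(n[seg]).mode().iloc[0])
    pi_total = float(np.nansum(per_site_pi(k[seg], n[seg])))
    return tajimas_d(int(seg.sum()), n_common, pi_total)


def genotype_r2(dosage_i, dosage_j) -> float:
    """Squared Pearson correlation of two dosage vectors over jointly-called
    samples; NaN when either is monomorphic in the joint subset."""
    di = np.asarray(dosage_i, dtype=float)
    dj = np.asarray(dosage_j, dtype=float)
    ok = (di != MISSING) & (dj != MISSING)
    if ok.sum() < 2:
        return np.nan
    x, y = di[ok], dj[ok]
    if x.std() == 0 or y.std() == 0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


@dataclass
class LDCurve:
    bin_edges: np.ndarray      # contiguous distance bin edges in bp
    mean_r2: np.ndarray        # mean r^2 per bin (NaN for empty bins)
    pair_counts: np.ndarray

    def decay_distance_at(self, threshold: float = 0.2) -> float:
        """Distance where the isotonic-smoothed curve falls to `threshold`.

        Linear interpolation between the two bin centres straddling the
        threshold; math.inf when the curve never reaches it ("> max dist").
        """
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        ok = np.isfinite(self.mean_r2)
        if ok.sum() == 0:
            return math.nan
        x, y = centers[ok], self.mean_r2[ok]
        if ok.sum() > 1:
            iso = IsotonicRegression(increasing=False)
            y = iso.fit_transform(x, y)
        if y.min() > threshold:
            return math.inf
        below = np.flatnonzero(y <= threshold)
        i = below[0]
        if i == 0:
            return float(x[0])
        x0, x1, y0, y1 = x[i - 1], x[i], y[i - 1], y[i]
        if y0 == y1:
            return float(x1)
        return float(x0 + (y0 - threshold) * (x1 - x0) / (y0 - y1))


def ld_decay(
    gm: GenotypeMatrix,
    max_dist: int = 100_000,
    bin_width: int = 2_000,
    maf_min: float = 0.05,
    miss_max: float = 0.20,
    sample_idx=None,
) -> LDCurve:
    """Binned mean r^2 against physical distance for intra-chromosome pairs.

    Sites with MAF < maf_min or missingness > miss_max are excluded before
    pairing, mirroring standard LD-decay tooling.
    """
    d = gm.dosage if sample_idx is None else gm.dosage[sample_idx]
    called = d != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(called.sum(axis=0) > 0,
                        np.where(d == MISSING, 0, d).sum(axis=0) / (2.0 * called.sum(axis=0)),
                        np.nan)
    maf = np.minimum(freq, 1 - freq)
    miss = 1.0 - called.mean(axis=0)
    use = np.flatnonzero((maf >= maf_min) & (miss <= miss_max))

    edges = np.arange(0, max_dist + bin_width, bin_width)
    nbins = edges.size - 1
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=np.int64)

    for c in np.unique(gm.chrom[use] if use.size else []):
        idx = use[gm.chrom[use] == c]
        pos = gm.pos[idx].astype(np.int64)
        sub = d[:, idx].astype(float)
        complete = not (sub == MISSING).any()
        if complete:
            z = sub - sub.mean(axis=0)
            norm = np.sqrt((z * z).sum(axis=0))
            norm[norm == 0] = np.nan
            z = z / norm
        for a in range(idx.size - 1):
            hi = np.searchsorted(pos, pos[a] + max_dist, side="right")
            if hi <= a + 1:
                continue
            dist = pos[a + 1 : hi] - pos[a]
            if complete:
                r2 = (z[:, a] @ z[:, a + 1 : hi]) ** 2
            else:
                r2 = np.array(
                    [genotype_r2(sub[:, a], sub[:, b]) for b in range(a + 1, hi)]
                )
            ok = np.isfinite(r2)
            bins = np.minimum((dist[ok] - 1) // bin_width, nbins - 1).astype(int)
            np.add.at(sums, bins, r2[ok])
            np.add.at(counts, bins, 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LDCurve(bin_edges=edges, mean_r2=mean_r2, pair_counts=counts)


def sliding_windows(
    gm: GenotypeMatrix,
    size: int = 50_000,
    step: int = 10_000,
    stat: str = "pi",
    sample_idx=None,
) -> pd.DataFrame:
    """Windowed statistic track (chrom, start, end 0-based half-open, value,
    n_sites) tiling each chromosome; genome-wide average in .attrs."""
    if step > size:
        raise ValueError("step must not exceed window size")
    k = gm.alt_counts(sample_idx)
    n = gm.called_alleles(sample_idx)
    pi_site = np.nan_to_num(per_site_pi(k, n))
    rows = []
    for c in pd.unique(gm.chrom):
        on = np.flatnonzero(gm.chrom == c)
        pos0 = gm.pos[on] - 1
        chrom_len = int(pos0.max()) + 1 if on.size else 0
        start = 0
        while start < chrom_len:
            end = start + size
            inw = on[(pos0 >= start) & (pos0 < end)]
            if stat == "pi":
                val = float(pi_site[inw].sum() / size)
            elif stat == "tajD":
                mask = np.zeros(gm.n_sites, dtype=bool)
                mask[inw] = True
                val = tajimas_d_from_matrix(gm, mask, sample_idx)
            elif stat == "het":
                d = gm.dosage if sample_idx is None else gm.dosage[sample_idx]
                sub = d[:, inw]
                called = (sub != MISSING).sum()
                val = float((sub == 1).sum() / called) if called else np.nan
            else:
                raise ValueError(f"unknown statistic {stat!r}")
            rows.append((c, start, end, val, int(inw.size)))
            start += step
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "value", "n_sites"])
    out.attrs["genome_average"] = float(np.nanmean(out["value"])) if len(out) else np.nan
    out.attrs["stat"] = stat
    return out
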