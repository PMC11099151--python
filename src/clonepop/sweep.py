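"""Species-level selective-sweep scans.

Two complementary scans over the same genotype matrix:

* a composite likelihood ratio (CLR) that contrasts the genome-wide
  ("background") SFS with a sweep-transformed SFS in which lineages escape a
  hard sweep independently with probability p_e(d, alpha) = 1 - exp(-alpha*d)
  at distance d from the focal position, and

* a mu-type statistic multiplying three window factors — diversity reduction
  (SNP sparsity), SFS skew toward singletons and near-fixed classes, and LD
  partitioning across the window midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .sfs import SFS, project_probs

_LOG_FLOOR = 1e-300


@dataclass
class SweepModel:
    alpha_grid: np.ndarray = field(
        default_factory=lambda: np.geomspace(2e-6, 2e-3, 12)
    )
    grid_spacing: int = 10_000
    flank: int = 50_000
    pe_grid_size: int = 48


@dataclass
class MuFactors:
    mu_var: float
    mu_sfs: float
    mu_ld: float
    window_span: float
    k: int
    flagged: bool = False

    @property
    def mu(self) -> float:
        return self.mu_var * self.mu_sfs * self.mu_ld


class SweepSpectrumTable:
    """Caches the background projections so spectra for many p_e values are
    cheap (the projections do not depend on p_e)."""

    def __init__(self, bg: SFS, n: int):
        bg_probs = bg.probabilities()
        if bg.n < n:
            raise ValueError("background spectrum smaller than requested sample size")
        self.n = n
        self.base = project_probs(bg_probs, bg.n, n) if bg.n > n else bg_probs
        self.proj = {s: project_probs(self.base, n, s) for s in range(1, n + 1)}

    def transform(self, p_e: float) -> np.ndarray:
        """Distribution of derived counts 0..n at a site linked to a hard
        sweep.

        Each of the n lineages escapes the sweep independently with
        probability p_e.  The k escapees plus the single swept ancestral
        lineage form an effective sample of k+1 drawn from the background
        spectrum (projected to size k+1); the swept lineage's state is
        copied into the n-k non-escapees.  p_e = 1 returns the background at
        size n; p_e = 0 puts all mass on counts {0, n}.
        """
        if not 0.0 <= p_e <= 1.0:
            raise ValueError("p_e must lie in [0, 1]")
        from scipy.stats import binom

        n = self.n
        out = np.zeros(n + 1)
        weights = binom.pmf(np.arange(n + 1), n, p_e)
        for k in range(n + 1):
            w = weights[k]
            if w == 0.0:
                continue
            if k == n:
                out += w * self.base
                continue
            s = k + 1
            q = self.proj[s]
            j = np.arange(s + 1)
            p_swept = j / s
            # swept ancestor derived: j-1 escaped copies + (n-k) replicated
            np.add.at(out, np.clip(j - 1 + (n - k), 0, n), w * q * p_swept)
            np.add.at(out, j, w * q * (1.0 - p_swept))
        return out


def sweep_sfs_transform(bg: SFS, n: int, p_e: float) -> np.ndarray:
    """One-shot convenience wrapper around SweepSpectrumTable.transform."""
    return SweepSpectrumTable(bg, n).transform(p_e)


def _segregating_loglik(dist: np.ndarray) -> np.ndarray:
    """Log-probabilities over segregating classes 1..n-1, renormalized after
    dropping the monomorphic classes (only segregating sites enter data)."""
    p = dist.copy()
    p[0] = 0.0
    p[-1] = 0.0
    tot = p.sum()
    if tot <= 0:
        return np.full(p.size, np.log(_LOG_FLOOR))
    return np.log(np.maximum(p / tot, _LOG_FLOOR))


def clr_scan(
    gm: GenotypeMatrix,
    model: SweepModel | None = None,
    grid_positions=None,
    folded: bool = False,
    background: SFS | None = None,
    min_snps: int = 5,
) -> pd.DataFrame:
    """CLR(x) = 2*[max_alpha sum_i ln P_sweep(b_i | p_e(d_i, alpha))
    - sum_i ln P_bg(b_i)] over SNPs within `flank` of each grid position.

    The alpha maximization includes the neutral limit (p_e = 1), so CLR >= 0
    by construction.  Sweep spectra are precomputed on a discrete p_e grid
    and looked up by nearest p_e.
    """
    from .sfs import background_sfs

    model = model or SweepModel()
    if background is None:
        background = background_sfs(gm, folded=folded)
    n = background.n

    if folded or gm.ancestral is None:
        k = np.minimum(gm.alt_counts(), gm.called_alleles() - gm.alt_counts())
        nn = gm.called_alleles()
        use = (k > 0) & (nn == n * 0 + int(np.median(nn)))
        counts = k
        fold = True
    else:
        counts, nn = gm.derived_counts()
        use = gm.polarized_mask() & (counts > 0) & (counts < nn)
        fold = False
    common_n = int(pd.Series(nn[use]).mode().iloc[0]) if use.any() else n
    use &= nn == common_n

    pe_grid = np.concatenate([np.geomspace(1e-4, 0.999, model.pe_grid_size - 1), [1.0]])
    spectra = SweepSpectrumTable(background, common_n)
    table = np.zeros((pe_grid.size, common_n + 1))
    for gi, pe in enumerate(pe_grid):
        dist = spectra.transform(pe)
        if fold:
            folded_d = np.zeros_like(dist)
            for j in range(dist.size):
                folded_d[min(j, common_n - j)] += dist[j]
            dist = folded_d
        table[gi] = _segregating_loglik(dist)
    bg_ll = table[-1]  # p_e = 1 row IS the background likelihood

    rows = []
    for c in pd.unique(gm.chrom):
        on = np.flatnonzero((gm.chrom == c) & use)
        if on.size == 0:
            continue
        pos = gm.pos[on].astype(np.int64)
        b = counts[on].astype(int)
        if grid_positions is None:
            grid = np.arange(pos.min(), pos.max() + 1, model.grid_spacing)
        else:
            grid = np.asarray(grid_positions)
        for x in grid:
            lo = np.searchsorted(pos, x - model.flank)
            hi = np.searchsorted(pos, x + model.flank, side="right")
            if hi - lo < min_snps:
                continue
            d = np.abs(pos[lo:hi] - x).astype(float)
            bw = b[lo:hi]
            ll_bg = bg_ll[bw].sum()
            best = ll_bg
            for alpha in model.alpha_grid:
                pe = 1.0 - np.exp(-alpha * d)
                gi = np.clip(np.searchsorted(pe_grid, pe), 0, pe_grid.size - 1)
                ll = table[gi, bw].sum()
                if ll > best:
                    best = ll
            rows.append((c, int(x - model.flank), int(x + model.flank),
                         float(2.0 * (best - ll_bg)), int(hi - lo), int(x)))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "value", "n_sites", "position"]
    )


# ---------------------------------------------------------------------------
# mu statistic
# ---------------------------------------------------------------------------

def mu_statistic(
    positions: np.ndarray,
    derived_counts: np.ndarray,
    dosage_window: np.ndarray,
    n_haploids: int,
    genome_length: float,
    genome_snps: int,
    eps: float = 1e-6,
) -> MuFactors:
    """The three mu factors for one window of k consecutive SNPs.

    mu_var: local SNP spacing over genome-average spacing (diversity
    reduction widens the window needed to collect k SNPs).
    mu_sfs: observed fraction of singleton + (n-1) classes over its neutral
    expectation (1 + 1/(n-1)) / sum_{j<n} 1/j.
    mu_ld: within-half mean r^2 over cross-half mean r^2 (sweep centres
    break LD across the midpoint while preserving it within flanks).
    """
    k = positions.size
    n = n_haploids
    span = float(positions[-1] - positions[0])
    mu_var = (span / k) / (genome_length / genome_snps)

    a_n = np.sum(1.0 / np.arange(1, n))
    frac = np.mean((derived_counts == 1) | (derived_counts == n - 1))
    mu_sfs = frac / ((1.0 + 1.0 / (n - 1.0)) / a_n)

    flagged = False
    half = k // 2
    r2m = _window_r2_matrix(dosage_window)
    left = r2m[:half, :half][np.triu_indices(half, 1)]
    right = r2m[half:, half:][np.triu_indices(k - half, 1)]
    cross = r2m[:half, half:].ravel()
    ml, mr, mx = (np.nanmean(v) if np.isfinite(v).any() else np.nan
                  for v in (left, right, cross))
    if not (np.isfinite(ml) and np.isfinite(mr) and np.isfinite(mx)):
        mu_ld, flagged = 1.0, True
    else:
        mu_ld = (ml + mr) / (2.0 * mx + eps)
    return MuFactors(mu_var=float(mu_var), mu_sfs=float(mu_sfs),
                     mu_ld=float(mu_ld), window_span=span, k=k, flagged=flagged)


def _window_r2_matrix(dosage_window: np.ndarray) -> np.ndarray:
    """Pairwise dosage r^2 inside a window (samples x k), NaN where undefined."""
    x = dosage_window.astype(float)
    x[x == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(x, axis=0)
        z = x - mean
        z[np.isnan(z)] = 0.0
        norm = np.sqrt((z ** 2).sum(axis=0))
        bad = norm == 0
        norm[bad] = 1.0
        zn = z / norm
        r2 = (zn.T @ zn) ** 2
        r2[bad, :] = np.nan
        r2[:, bad] = np.nan
    return r2


def mu_scan(
    gm: GenotypeMatrix,
    k: int = 50,
    step: int = 10,
) -> pd.DataFrame:
    """Slide a k-SNP window along each chromosome and record mu."""
    if gm.ancestral is not None:
        counts, nn = gm.derived_counts()
    else:
        counts = gm.alt_counts()
        nn = gm.called_alleles()
    seg = (counts > 0) & (counts < nn)
    n_hap = int(pd.Series(nn[seg]).mode().iloc[0])
    genome_len = 0.0
    for c in pd.unique(gm.chrom):
        p = gm.pos[gm.chrom == c]
        genome_len += float(p.max() - p.min() + 1)
    genome_snps = int(seg.sum())

    rows = []
    for c in pd.unique(gm.chrom):
        on = np.flatnonzero((gm.chrom == c) & seg & (nn == n_hap))
        pos = gm.pos[on].astype(np.int64)
        for s in range(0, on.size - k + 1, step):
            w = on[s : s + k]
            f = mu_statistic(
                pos[s : s + k], counts[w], gm.dosage[:, w], n_hap,
                genome_len, genome_snps,
            )
            centre = int(0.5 * (pos[s] + pos[s + k - 1]))
            rows.append((c, int(pos[s]), int(pos[s + k - 1] + 1), f.mu, k, centre,
                         f.mu_var, f.mu_sfs, f.mu_ld))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "value", "n_sites", "position",
                 "mu_var", "mu_sfs", "mu_ld"],
    )


# ---------------------------------------------------------------------------
# Top-quantile calling and gene overlap
# ---------------------------------------------------------------------------

def top_fraction(stats: pd.DataFrame, q: float = 0.01):
    """Windows in the top fraction q by value.

    Windows strictly above the (1-q) quantile are selected; ties exactly at
    the quantile are included (flagged when that inflates the count).
    """
    if len(stats) == 0:
        raise ValueError("empty statistics frame")
    vals = stats["value"].to_numpy(dtype=float)
    thr = float(np.nanquantile(vals, 1.0 - q))
    sel = vals > thr
    ties = vals == thr
    flagged = ties.sum() > 1 and not sel.any()
    sel |= ties
    out = stats.loc[sel].copy()
    out.attrs["threshold"] = thr
    out.attrs["tie_flagged"] = bool(flagged)
    return out


def overlap_genes(windows: pd.DataFrame, genes: list) -> pd.DataFrame:
    """Genes overlapping any selected window by >= 1 bp (half-open
    coordinates), with the overlapping window count as provenance."""
    rows = []
    for g in genes:
        w = windows[windows["chrom"] == g.chrom]
        n = int(((w["start"] < g.end) & (w["end"] > g.start)).sum())
        if n:
            rows.append((g.gene_id, g.chrom, g.start, g.end, n))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "n_windows"])


def intersect_gene_lists(lists: list) -> list:
    """Genes present in every method's list (order of the first)."""
    if not lists:
        return []
    common = set(lists[0])
    for other in lists[1:]:
        common &= set(other)
    return [g for g in lists[0] if g in common]
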