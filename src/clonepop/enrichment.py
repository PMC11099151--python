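"""Permutation nulls for genomic-interval enrichment, exact 2x2 tests, and
single-variant Wald association."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError


def permute_intervals(
    genome_sizes: dict,
    intervals: pd.DataFrame,
    n_perm: int,
    seed: int,
    same_chrom: bool = True,
) -> list:
    """Uniform length-preserving random re-placements of every interval.

    Returns a list of n_perm frames (chrom, start, end).  By default each
    interval stays on its source chromosome; with same_chrom=False the
    target chromosome is drawn proportionally to its length among those that
    can hold the interval.  Overlaps among placed intervals are permitted.
    """
    rng = np.random.default_rng(seed)
    lens = (intervals["end"] - intervals["start"]).to_numpy()
    chroms = intervals["chrom"].to_numpy()
    for ln, c in zip(lens, chroms):
        if same_chrom and ln > genome_sizes[c]:
            raise ConfigurationError(f"interval of {ln} bp exceeds chromosome {c}")
        if not same_chrom and ln > max(genome_sizes.values()):
            raise ConfigurationError(f"interval of {ln} bp exceeds every chromosome")
    out = []
    names = list(genome_sizes)
    sizes = np.array([genome_sizes[c] for c in names], dtype=float)
    for _ in range(n_perm):
        new_chrom = chroms.copy()
        if not same_chrom:
            for i, ln in enumerate(lens):
                w = np.where(sizes >= ln, sizes, 0.0)
                new_chrom[i] = names[rng.choice(len(names), p=w / w.sum())]
        starts = np.array(
            [
                rng.integers(0, genome_sizes[c] - ln + 1)
                for c, ln in zip(new_chrom, lens)
            ]
        )
        out.append(
            pd.DataFrame({"chrom": new_chrom, "start": starts, "end": starts + lens})
        )
    return out


def count_family_overlaps(intervals: pd.DataFrame, family_features: dict) -> dict:
    """Per family: number of intervals overlapping >= 1 member feature.

    family_features maps family -> frame (chrom, start, end), half-open.
    """
    out = {}
    for fam, feats in family_features.items():
        n = 0
        for _, iv in intervals.iterrows():
            f = feats[feats["chrom"] == iv["chrom"]]
            if ((f["start"] < iv["end"]) & (f["end"] > iv["start"])).any():
                n += 1
        out[fam] = n
    return out


def null_family_counts(
    genome_sizes: dict,
    intervals: pd.DataFrame,
    family_features: dict,
    n_perm: int,
    seed: int,
) -> pd.DataFrame:
    """Vectorized equivalent of permute_intervals + count_family_overlaps.

    Same null (uniform length-preserving same-chromosome re-placement, same
    seed convention) but returns the (n_perm x families) overlap-count frame
    directly without materializing the placements.
    """
    rng = np.random.default_rng(seed)
    lens = (intervals["end"] - intervals["start"]).to_numpy()
    chroms = intervals["chrom"].to_numpy()
    starts = np.empty((n_perm, lens.size), dtype=np.int64)
    for i, (c, ln) in enumerate(zip(chroms, lens)):
        if ln > genome_sizes[c]:
            raise ConfigurationError(f"interval of {ln} bp exceeds chromosome {c}")
        starts[:, i] = rng.integers(0, genome_sizes[c] - ln + 1, size=n_perm)
    ends = starts + lens
    out = {}
    for fam, feats in family_features.items():
        hit = np.zeros((n_perm, lens.size), dtype=bool)
        for _, f in feats.iterrows():
            same = chroms == f["chrom"]
            if not same.any():
                continue
            hit[:, same] |= (starts[:, same] < f["end"]) & (ends[:, same] > f["start"])
        out[fam] = hit.sum(axis=1)
    return pd.DataFrame(out)


def family_enrichment(
    observed: dict,
    null_counts: pd.DataFrame,
) -> pd.DataFrame:
    """Empirical enrichment p per family with BH adjustment across families.

    null_counts is (n_perm x families).  p = (1 + #{null >= obs}) / (N + 1).
    """
    n_perm = len(null_counts)
    if n_perm < 100:
        raise ConfigurationError("need at least 100 permutations")
    rows = []
    for fam, obs in observed.items():
        null = null_counts[fam].to_numpy()
        p = (1.0 + (null >= obs).sum()) / (n_perm + 1.0)
        rows.append((fam, obs, float(null.mean()), p))
    out = pd.DataFrame(rows, columns=["family", "observed", "null_mean", "p"])
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric probabilities not
    exceeding that of the observed table)."""
    t = np.asarray(table)
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def chisq_enrichment(table, correction: bool = False):
    """Pearson chi-square with 1 df on a 2x2 table (no continuity correction
    by default).  Returns (statistic, p); (nan, nan) with a hint logged when
    an expected cell is zero."""
    t = np.asarray(table, dtype=float)
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    tot = t.sum()
    if tot == 0:
        return np.nan, np.nan
    expected = row @ col / tot
    if (expected == 0).any():
        return np.nan, np.nan  # degenerate margins: use fisher_exact_2x2 instead
    diff = np.abs(t - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float((diff**2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def wald_association(y, g):
    """OLS of y on genotype dosage with intercept; Wald p against Normal.

    Returns (beta, se, p); raises on constant genotype or < 3 usable pairs.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    ok = np.isfinite(y) & np.isfinite(g) & (g >= 0)
    if ok.sum() < 3:
        raise ValueError("need >= 3 samples with called genotype and trait")
    y, g = y[ok], g[ok]
    if np.all(g == g[0]):
        raise ValueError("genotype is constant")
    n = y.size
    gc = g - g.mean()
    beta = float((gc @ y) / (gc @ gc))
    alpha = y.mean() - beta * g.mean()
    resid = y - alpha - beta * g
    sigma2 = float(resid @ resid) / max(n - 2, 1)
    se = float(np.sqrt(sigma2 / (gc @ gc)))
    if se == 0:
        return beta, 0.0, 0.0
    z = beta / se
    return beta, se, float(2.0 * stats.norm.sf(abs(z)))
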