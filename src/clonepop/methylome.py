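"""Population bisulfite-sequencing analysis.

Cytosine reports are strand-resolved tables (chrom, pos, strand, methylated
reads, unmethylated reads, context, trinucleotide).  The pipeline estimates
the bisulfite non-conversion background from an unmethylated control contig
(chloroplast), calls per-cytosine methylation with a one-sided binomial test
against that background (BH-corrected), zeroes the methylated reads of
non-significant sites while preserving coverage, and summarizes methylation
as the proportion of methylated cytosines (mC) and the weighted methylation
level (wML = sum m / sum (m+u)) by context and region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import cophenet, linkage, to_tree
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError

CONTEXTS = ("CpG", "CHG", "CHH")


@dataclass
class RegionMethylation:
    chrom: str | None
    start: int | None
    end: int | None
    label: str
    context: str | None
    wml: float
    covered_cytosines: int
    total_reads: int


def nonconversion_rate(records: pd.DataFrame, control_contig: str = "chrC") -> float:
    """Non-conversion rate e = sum(m) / sum(m + u) over control cytosines."""
    ctl = records[records["chrom"] == control_contig]
    cov = ctl["count_methylated"] + ctl["count_unmethylated"]
    ctl = ctl[cov > 0]
    if len(ctl) < 100:
        raise ConfigurationError(
            f"control contig {control_contig!r} has {len(ctl)} covered cytosines (< 100)"
        )
    m = ctl["count_methylated"].sum()
    tot = m + ctl["count_unmethylated"].sum()
    return float(m / tot)


def call_methylated(
    records: pd.DataFrame,
    e: float,
    alpha: float = 0.05,
    min_cov: int = 5,
    fdr: str = "bh",
) -> pd.DataFrame:
    """Binomial methylation calling against the non-conversion background.

    Sites with coverage < min_cov are dropped.  p = P(X >= m | n=cov, e) by
    the binomial tail; BH across sites (or raw alpha with fdr="none").
    Non-significant sites keep their coverage but have methylated reads
    excluded (m -> 0, u -> cov), so region denominators are unaffected.
    """
    if e >= 1.0:
        raise ConfigurationError("non-conversion rate must be < 1")
    out = records.copy()
    cov = out["count_methylated"] + out["count_unmethylated"]
    out = out.loc[cov >= min_cov].reset_index(drop=True)
    cov = (out["count_methylated"] + out["count_unmethylated"]).to_numpy()
    m = out["count_methylated"].to_numpy()
    p = stats.binom.sf(m - 1, cov, e)
    p[m == 0] = 1.0
    if fdr == "bh":
        significant = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    elif fdr == "none":
        significant = p < alpha
    else:
        raise ConfigurationError(f"unknown fdr mode {fdr!r}")
    out["p_value"] = p
    out["methylated"] = significant
    out.loc[~significant, "count_unmethylated"] = cov[~significant]
    out.loc[~significant, "count_methylated"] = 0
    return out


def mc_proportion(called: pd.DataFrame, context: str) -> float:
    """Fraction of covered cytosines of a context that are methylated."""
    sub = called[called["context"] == context]
    if len(sub) == 0:
        return np.nan
    return float((sub["count_methylated"] > 0).mean())


def weighted_ml(
    called: pd.DataFrame,
    region=None,
    context: str | None = None,
    label: str = "",
) -> RegionMethylation:
    """wML = sum(m) / sum(m + u) over covered context cytosines in a region
    ((chrom, start, end) 0-based half-open, or None for everything)."""
    sub = called
    chrom = start = end = None
    if context is not None:
        sub = sub[sub["context"] == context]
    if region is not None:
        chrom, start, end = region
        sub = sub[(sub["chrom"] == chrom) & (sub["pos"] - 1 >= start) & (sub["pos"] - 1 < end)]
    m = int(sub["count_methylated"].sum())
    tot = m + int(sub["count_unmethylated"].sum())
    wml = m / tot if tot > 0 else np.nan
    return RegionMethylation(
        chrom=chrom, start=start, end=end, label=label, context=context,
        wml=wml, covered_cytosines=len(sub), total_reads=tot,
    )


def metagene_profile(
    called: pd.DataFrame,
    features: pd.DataFrame,
    context: str | None = None,
    flank: int = 2_000,
    body_bins: int = 20,
    flank_bins: int = 10,
) -> pd.DataFrame:
    """Pooled wML across scaled feature bodies and fixed-width 2 kb flanks.

    features: chrom, start, end (0-based half-open) and optional strand;
    minus-strand features are reversed so bins run 5'->3'.  Returns a frame
    with bin index (0..flank_bins+body_bins+flank_bins-1), segment label,
    and pooled wML.
    """
    sub = called if context is None else called[called["context"] == context]
    nbins = 2 * flank_bins + body_bins
    m_sum = np.zeros(nbins)
    t_sum = np.zeros(nbins)
    for _, f in features.iterrows():
        strand = f.get("strand", "+") if hasattr(f, "get") else "+"
        if strand not in ("+", "-"):
            strand = "+"
        s, e = int(f["start"]), int(f["end"])
        c = sub[
            (sub["chrom"] == f["chrom"])
            & (sub["pos"] - 1 >= s - flank)
            & (sub["pos"] - 1 < e + flank)
        ]
        if len(c) == 0:
            continue
        pos0 = c["pos"].to_numpy() - 1
        rel = np.empty(len(c))
        up = pos0 < s
        dn = pos0 >= e
        body = ~(up | dn)
        rel[up] = (pos0[up] - (s - flank)) / flank * flank_bins
        rel[body] = flank_bins + (pos0[body] - s) / max(e - s, 1) * body_bins
        rel[dn] = flank_bins + body_bins + (pos0[dn] - e) / flank * flank_bins
        bins = np.clip(rel.astype(int), 0, nbins - 1)
        if strand == "-":
            bins = nbins - 1 - bins
        np.add.at(m_sum, bins, c["count_methylated"].to_numpy())
        np.add.at(t_sum, bins,
                  (c["count_methylated"] + c["count_unmethylated"]).to_numpy())
    seg = (["upstream"] * flank_bins + ["body"] * body_bins + ["downstream"] * flank_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        wml = np.where(t_sum > 0, m_sum / np.maximum(t_sum, 1), np.nan)
    return pd.DataFrame({"bin": np.arange(nbins), "segment": seg, "wml": wml,
                         "total_reads": t_sum.astype(int)})


def compare_population_wml(groups: dict, bonferroni: bool = True) -> pd.DataFrame:
    """Pairwise exact rank-sum tests on per-sample wML values by population.

    groups maps population -> list of per-sample wML.  Groups of one sample
    are skipped with a warning column; p-values are Bonferroni-adjusted over
    the tested pairs.  A compact letter display is attached in .attrs.
    """
    names = [g for g in groups if len(groups[g]) >= 2]
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            stat, p = stats.mannwhitneyu(
                groups[a], groups[b], alternative="two-sided", method="exact"
            )
            rows.append((a, b, float(stat), float(p)))
    out = pd.DataFrame(rows, columns=["group1", "group2", "statistic", "p"])
    n_tests = max(len(out), 1)
    out["p_adjusted"] = np.minimum(out["p"] * (n_tests if bonferroni else 1), 1.0)
    out.attrs["letters"] = _compact_letters(names, out)
    out.attrs["skipped"] = [g for g in groups if len(groups[g]) < 2]
    return out


def _compact_letters(names: list, tests: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Greedy compact letter display: groups not significantly different
    share a letter."""
    differ = {
        frozenset((r["group1"], r["group2"]))
        for _, r in tests.iterrows()
        if r["p_adjusted"] < alpha
    }
    letters: dict = {g: "" for g in names}
    sets: list = []
    for g in names:
        placed = False
        for s in sets:
            if all(frozenset((g, h)) not in differ for h in s):
                s.append(g)
                placed = True
        if not placed:
            sets.append([g])
    for li, s in enumerate(sets):
        ch = chr(ord("A") + li)
        for g in s:
            letters[g] += ch
    return letters


def methylome_clustering(wml_matrix: pd.DataFrame):
    """Average-linkage clustering of samples on 1 - Pearson correlation of
    regional wML profiles (regions with any missing sample are dropped).

    Returns (linkage matrix, cophenetic distance condensed vector, newick).
    """
    mat = wml_matrix.dropna(axis=1)
    if mat.shape[0] < 3:
        raise ConfigurationError("need >= 3 samples to cluster")
    x = mat.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        flat = list(mat.index[sd == 0])
        raise ConfigurationError(f"constant methylation profile for {flat}")
    corr = np.corrcoef(x)
    dist = 1.0 - corr
    iu = np.triu_indices(len(mat), 1)
    condensed = dist[iu]
    z = linkage(condensed, method="average")
    coph = cophenet(z)
    return z, coph, _to_newick(z, list(mat.index))


def _to_newick(z, labels: list) -> str:
    tree = to_tree(z)

    def rec(node):
        if node.is_leaf():
            return labels[node.id]
        return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

    return rec(tree) + ";"


def tree_concordance(d_genetic, d_methyl, n_perm: int = 999, seed: int = 0):
    """Mantel test between two distance matrices (one-sided, positive r).

    Rows/columns of the second matrix are co-permuted; p uses the add-one
    permutation convention.
    """
    a = np.asarray(d_genetic, dtype=float)
    b = np.asarray(d_methyl, dtype=float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ConfigurationError("distance matrices must be square and matching")
    n = a.shape[0]
    iu = np.triu_indices(n, 1)

    def mantel_r(bb):
        x, y = a[iu], bb[iu]
        if x.std() == 0 or y.std() == 0:
            return np.nan
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = mantel_r(b)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if mantel_r(b[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return r_obs, p
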