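import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from clonepop.sfs import SFS, background_sfs, project_probs
from clonepop.sweep import (
    SweepModel,
    SweepSpectrumTable,
    clr_scan,
    intersect_gene_lists,
    mu_scan,
    mu_statistic,
    overlap_genes,
    sweep_sfs_transform,
    top_fraction,
)


def _neutral_sfs(n):
    counts = np.zeros(n + 1)
    counts[1:n] = 1.0 / np.arange(1, n)
    return SFS(n=n, counts=counts)


# -- SFS and projection -----------------------------------------------------

def test_single_site_spectrum_point_mass():
    from clonepop.genotypes import GenotypeMatrix

    gm = GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(5)], populations={},
        chrom=np.array(["chr1"], dtype=object), pos=np.array([10]),
        ref=np.array(["A"], dtype=object), alt=np.array(["C"], dtype=object),
        dosage=np.array([[1], [1], [1], [0], [0]], dtype=np.int8),
        ancestral=np.array(["A"], dtype=object),
    )
    sfs = background_sfs(gm)
    assert sfs.n == 10
    assert sfs.counts[3] == 1 and sfs.counts.sum() == 1


def test_projection_matches_hypergeometric_enumeration():
    """A site with derived count 3 of n=10 projected to n=4."""
    point = np.zeros(11)
    point[3] = 1.0
    proj = project_probs(point, 10, 4)
    expect = [hypergeom.pmf(j, 10, 3, 4) for j in range(5)]
    assert np.allclose(proj, expect, atol=1e-12)


def test_neutral_simulation_sfs_shape():
    """xi_j ~ 1/j under neutrality; aggregate a few well-recombining
    replicates to tame the genealogical noise."""
    from clonepop.models import single_population_model
    from clonepop.simulate import simulate_population_set

    m = single_population_model(size=200_000, sigma=1.0, theta_site=0.001, rho_site=2e-9)
    agg = None
    for seed in range(5):
        gm, _ = simulate_population_set(m, {"asia": 8}, 100_000, seed=seed)
        sfs = background_sfs(gm)
        agg = sfs.counts if agg is None else agg + sfs.counts
    probs = agg / agg.sum()
    n = sfs.n
    assert probs[1] == probs[1:n].max()
    expected = (1 / np.arange(1, n)) / np.sum(1 / np.arange(1, n))
    assert 0.5 * np.abs(probs[1:n] - expected).sum() < 0.08  # total variation


# -- sweep-transformed spectrum ---------------------------------------------

def test_transform_identity_at_full_escape():
    bg = _neutral_sfs(8)
    out = sweep_sfs_transform(bg, 8, 1.0)
    assert np.allclose(out[1:8], bg.probabilities()[1:8], atol=1e-12)


def test_transform_total_hitchhiking_at_zero_escape():
    bg = _neutral_sfs(8)
    out = sweep_sfs_transform(bg, 8, 0.0)
    assert out[0] + out[8] == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("p_e", [0.0, 0.1, 0.5, 0.9, 1.0])
def test_transform_sums_to_one(p_e):
    bg = _neutral_sfs(10)
    assert sweep_sfs_transform(bg, 10, p_e).sum() == pytest.approx(1.0, abs=1e-12)


def test_transform_matches_brute_force_enumeration():
    """n=4, p_e=0.5, toy background: enumerate escape configurations and
    lineage states directly."""
    n = 4
    bg = np.array([0.0, 0.5, 0.3, 0.2, 0.0])  # probs over derived counts 0..4
    sfs = SFS(n=n, counts=bg.copy())
    p_e = 0.5

    # Oracle: P(site pattern) by total enumeration.  With k escapees the
    # effective draw is k+1 iid? No — draws are WITHOUT replacement from a
    # sample of size k+1 distributed as the projected background.  Enumerate
    # j (derived among k+1) and the identity of the swept lineage.
    oracle = np.zeros(n + 1)
    for k in range(n + 1):
        w = math.comb(n, k) * p_e**k * (1 - p_e) ** (n - k)
        if k == n:
            oracle += w * bg
            continue
        s = k + 1
        q = np.zeros(s + 1)
        for i, p in enumerate(bg):
            for j in range(s + 1):
                q[j] += p * hypergeom.pmf(j, n, i, s)
        for j in range(s + 1):
            if j >= 1:
                oracle[min(j - 1 + (n - k), n)] += w * q[j] * (j / s)
            oracle[j] += w * q[j] * (1 - j / s)
    got = sweep_sfs_transform(sfs, n, p_e)
    assert np.allclose(got, oracle, atol=1e-12)


# -- CLR scan ---------------------------------------------------------------

def test_clr_alpha_grid_refinement_never_decreases(small_single_pop):
    gm, _ = small_single_pop
    coarse = SweepModel(alpha_grid=np.geomspace(2e-6, 2e-3, 6))
    fine = SweepModel(alpha_grid=np.unique(np.concatenate(
        [coarse.alpha_grid, np.geomspace(2e-6, 2e-3, 11)])))
    s1 = clr_scan(gm, coarse)
    s2 = clr_scan(gm, fine)
    merged = s1.merge(s2, on="position", suffixes=("_c", "_f"))
    assert (merged["value_f"] >= merged["value_c"] - 1e-9).all()


def test_clr_nonnegative_and_near_zero_under_null(small_single_pop):
    gm, _ = small_single_pop
    scan = clr_scan(gm)
    assert (scan["value"] >= 0).all()
    assert np.quantile(scan["value"], 0.5) < 5.0


# -- mu statistic -----------------------------------------------------------

def test_mu_factors_normalize_to_one_at_genome_average(rng):
    n = 20
    k = 50
    positions = np.arange(k) * 100 + 1         # local spacing span/k = 98
    a_n = np.sum(1 / np.arange(1, n))
    expect_frac = (1 + 1 / (n - 1)) / a_n
    n_extreme = int(round(expect_frac * k))
    counts = np.array([1] * n_extreme + [n // 2] * (k - n_extreme))
    dosage = rng.integers(0, 3, size=(10, k)).astype(np.int8)
    span = positions[-1] - positions[0]
    f = mu_statistic(positions, counts, dosage, n,
                     genome_length=span / k * 1000, genome_snps=1000, eps=0.0)
    assert f.mu_var == pytest.approx(1.0)      # window at genome-average density
    assert f.mu_sfs == pytest.approx(n_extreme / k / expect_frac)


def test_mu_factors_hand_arithmetic():
    positions = np.array([100, 200, 300, 400])
    counts = np.array([1, 5, 5, 9])
    n = 10
    dosage = np.array(
        [[0, 0, 2, 2], [0, 0, 2, 2], [2, 2, 0, 0], [2, 2, 0, 0], [1, 1, 1, 1]],
        dtype=np.int8,
    )
    f = mu_statistic(positions, counts, dosage, n, genome_length=10_000, genome_snps=100)
    assert f.mu_var == pytest.approx((300 / 4) / (10_000 / 100))
    a_n = sum(1 / j for j in range(1, 10))
    assert f.mu_sfs == pytest.approx((2 / 4) / ((1 + 1 / 9) / a_n))
    # left pair and right pair perfectly correlated; cross pairs perfectly
    # anticorrelated -> r^2 = 1 everywhere -> mu_ld ~ 1
    assert f.mu_ld == pytest.approx(1.0, rel=1e-4)
    assert f.mu == pytest.approx(f.mu_var * f.mu_sfs * f.mu_ld)


def test_mu_scan_product_invariant(small_single_pop):
    gm, _ = small_single_pop
    scan = mu_scan(gm, k=30, step=15)
    assert len(scan) > 3
    prod = scan["mu_var"] * scan["mu_sfs"] * scan["mu_ld"]
    assert np.allclose(scan["value"], prod, rtol=1e-12)


# -- top fraction and gene overlap ------------------------------------------

def test_top_fraction_examples():
    df = pd.DataFrame({"value": np.arange(100, dtype=float)})
    sel = top_fraction(df, 0.01)
    assert len(sel) == 1 and sel["value"].iloc[0] == 99
    assert len(top_fraction(df, 0.05)) >= len(sel)
    tied = pd.DataFrame({"value": np.ones(10)})
    sel_t = top_fraction(tied, 0.01)
    assert len(sel_t) == 10 and sel_t.attrs["tie_flagged"]


def test_overlap_genes_half_open_and_brute_force(rng):
    from clonepop.annotation import Gene

    genes = [
        Gene(f"g{i}", "chr1", int(s), int(s) + 200, "+")
        for i, s in enumerate(rng.integers(0, 10_000, size=30))
    ]
    windows = pd.DataFrame(
        {
            "chrom": ["chr1"] * 10,
            "start": rng.integers(0, 10_000, size=10),
        }
    )
    windows["end"] = windows["start"] + 500
    hits = overlap_genes(windows, genes)
    expect = {
        g.gene_id
        for g in genes
        if any(
            (w_s < g.end) and (w_e > g.start)
            for w_s, w_e in zip(windows["start"], windows["end"])
        )
    }
    assert set(hits["gene_id"]) == expect
    # adjacency: window ending exactly at gene start does not overlap
    w = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [genes[0].start]})
    assert genes[0].gene_id not in set(overlap_genes(w, [genes[0]])["gene_id"])


def test_intersection_across_methods():
    assert intersect_gene_lists([["a", "b", "c"], ["c", "a"], ["a", "c", "d"]]) == ["a", "c"]
    assert intersect_gene_lists([]) == []
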