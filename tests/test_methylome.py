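import itertools
import math

import numpy as np
import pandas as pd
import pytest

from clonepop.errors import ConfigurationError
from clonepop.fixtures import generate_methylome_fixture
from clonepop.methylome import (
    call_methylated,
    compare_population_wml,
    mc_proportion,
    metagene_profile,
    methylome_clustering,
    nonconversion_rate,
    tree_concordance,
    weighted_ml,
)


def _records(rows):
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "count_methylated", "count_unmethylated",
                 "context", "trinucleotide"],
    )


@pytest.fixture(scope="module")
def fixture():
    return generate_methylome_fixture(n_samples=2, seed=3)


def test_nonconversion_rate_examples():
    rows = [("chrC", i + 1, "+", 0, 10, "CpG", "CGA") for i in range(150)]
    assert nonconversion_rate(_records(rows)) == 0.0
    rows = [("chrC", i + 1, "+", (1 if i < 5 else 0), (9 if i < 5 else 10), "CHH", "CTA")
            for i in range(100)]
    rec = _records(rows)
    assert nonconversion_rate(rec) == pytest.approx(5 / 1000)
    with pytest.raises(ConfigurationError):
        nonconversion_rate(_records(rows[:50]))


def test_nonconversion_recovered_within_3_se(fixture):
    rep = fixture.reports["meth_00"]
    e = nonconversion_rate(rep)
    ctl = rep[rep["chrom"] == "chrC"]
    n = int((ctl["count_methylated"] + ctl["count_unmethylated"]).sum())
    se = math.sqrt(fixture.nonconv * (1 - fixture.nonconv) / n)
    assert abs(e - fixture.nonconv) <= 3 * se


def test_binomial_tail_matches_direct_sum():
    """n=10, m=3, e=0.01: p = sum_{k>=3} C(10,k) e^k (1-e)^(10-k)."""
    rec = _records([("chr1", 1, "+", 3, 7, "CpG", "CGA")])
    called = call_methylated(rec, e=0.01, fdr="none")
    oracle = sum(
        math.comb(10, k) * 0.01**k * 0.99 ** (10 - k) for k in range(3, 11)
    )
    assert called["p_value"].iloc[0] == pytest.approx(oracle, abs=1e-12)
    assert oracle == pytest.approx(1.1e-4, rel=0.05)
    assert bool(called["methylated"].iloc[0])


def test_calling_preserves_coverage_and_zeroes_nonsignificant(fixture):
    rep = fixture.reports["meth_00"]
    e = nonconversion_rate(rep)
    called = call_methylated(rep, e)
    cov_in = (rep["count_methylated"] + rep["count_unmethylated"])
    kept = cov_in >= 5
    assert len(called) == int(kept.sum())
    assert (called["count_methylated"] + called["count_unmethylated"]).sum() == int(
        cov_in[kept].sum()
    )
    assert (called.loc[~called["methylated"], "count_methylated"] == 0).all()


def test_zero_methylation_fixture_fdr_controlled():
    fx = generate_methylome_fixture(
        n_samples=1, seed=5, mc_proportion={"CpG": 0, "CHG": 0, "CHH": 0}, nonconv=0.005
    )
    rep = fx.reports["meth_00"]
    called = call_methylated(rep, nonconversion_rate(rep), alpha=0.05)
    assert called["methylated"].mean() <= 0.05


def test_mc_proportion_and_wml_examples():
    rec = _records(
        [
            ("chr1", 1, "+", 3, 7, "CpG", "CGT"),
            ("chr1", 5, "+", 0, 8, "CpG", "CGT"),
        ]
    )
    assert weighted_ml(rec, context="CpG").wml == pytest.approx(3 / 18)
    assert mc_proportion(rec, "CpG") == pytest.approx(0.5)
    all_m = _records([("chr1", 1, "+", 9, 0, "CHG", "CAG")])
    assert weighted_ml(all_m, context="CHG").wml == 1.0


def test_region_wml_is_coverage_weighted_mean_of_site_levels(fixture):
    rep = fixture.reports["meth_00"]
    called = call_methylated(rep, nonconversion_rate(rep))
    sub = called[(called["chrom"] == "chr1") & (called["context"] == "CpG")]
    cov = sub["count_methylated"] + sub["count_unmethylated"]
    site_level = sub["count_methylated"] / cov
    expect = float((site_level * cov).sum() / cov.sum())
    got = weighted_ml(called, region=("chr1", 0, 10**9), context="CpG").wml
    assert got == pytest.approx(expect, abs=1e-12)


def test_metagene_flat_profile_and_strand_reversal():
    rows = []
    for pos in range(1, 5001, 25):
        rows.append(("chr1", pos, "+", 4, 6, "CpG", "CGA"))
    rec = _records(rows)
    feats = pd.DataFrame({"chrom": ["chr1"], "start": [2000], "end": [3000],
                          "strand": ["+"]})
    prof = metagene_profile(rec, feats)
    vals = prof["wml"].dropna()
    assert np.allclose(vals, 0.4)
    # gradient fixture flips exactly under strand reversal
    rows = [("chr1", pos, "+", (8 if pos < 2500 else 2), (2 if pos < 2500 else 8),
             "CpG", "CGA") for pos in range(1, 5001, 10)]
    rec = _records(rows)
    fwd = metagene_profile(rec, feats)
    feats_rev = feats.assign(strand="-")
    rev = metagene_profile(rec, feats_rev)
    assert np.allclose(fwd["wml"].to_numpy(), rev["wml"].to_numpy()[::-1], equal_nan=True)


def test_rank_sum_exact_p_matches_permutation_enumeration():
    a, b = [0.11, 0.25, 0.30], [0.12, 0.26, 0.31]
    out = compare_population_wml({"x": a, "y": b}, bonferroni=False)
    pooled = a + b
    from scipy.stats import rankdata

    obs = sum(sorted(pooled).index(v) + 1 for v in a)
    count = total = 0
    for comb in itertools.combinations(range(6), 3):
        ranks = sum(c + 1 for c in comb)
        total += 1
        if abs(ranks - 10.5) >= abs(obs - 10.5) - 1e-9:
            count += 1
    assert out["p"].iloc[0] == pytest.approx(count / total, abs=1e-12)


def test_identical_groups_all_adjusted_p_one():
    g = {"a": [0.1, 0.2, 0.3], "b": [0.1, 0.2, 0.3]}
    out = compare_population_wml(g)
    assert (out["p_adjusted"] == 1.0).all()


def test_group_shift_detected():
    hits = 0
    rng = np.random.default_rng(2)
    for _ in range(10):
        a = list(rng.normal(0.10, 0.02, 5))
        b = list(rng.normal(0.30, 0.02, 5))
        out = compare_population_wml({"a": a, "b": b})
        hits += (out["p_adjusted"] < 0.05).all()
    assert hits >= 9


def test_clustering_structure_and_region_order_invariance(rng):
    base = rng.uniform(0, 1, 30)
    mat = pd.DataFrame(
        {
            "s1": base + rng.normal(0, 0.01, 30),
            "s2": base + rng.normal(0, 0.01, 30),
            "s3": rng.uniform(0, 1, 30),
        }
    ).T
    z, coph, newick = methylome_clustering(mat)
    assert z[0, 0] == 0 and z[0, 1] == 1  # s1,s2 merge first
    perm = rng.permutation(mat.shape[1])
    z2, _, _ = methylome_clustering(mat.iloc[:, perm])
    assert np.allclose(z, z2)
    assert newick.count(",") == 2 and newick.endswith(";")


def test_duplicated_sample_merges_at_zero(rng):
    row = rng.uniform(0, 1, 20)
    mat = pd.DataFrame([row, row, rng.uniform(0, 1, 20)], index=["a", "b", "c"])
    z, _, _ = methylome_clustering(mat)
    assert z[0, 2] == pytest.approx(0.0, abs=1e-12)


def test_mantel_identity_and_exhaustive_enumeration(rng):
    d = np.array(
        [[0, 1, 2, 3], [1, 0, 1.5, 2.5], [2, 1.5, 0, 1.2], [3, 2.5, 1.2, 0]]
    )
    r, _ = tree_concordance(d, d, n_perm=99, seed=1)
    assert r == pytest.approx(1.0)
    # exhaustive oracle over all 4! label permutations
    e = np.abs(rng.normal(0, 1, (4, 4)))
    e = (e + e.T) / 2
    np.fill_diagonal(e, 0)
    iu = np.triu_indices(4, 1)
    r_obs = np.corrcoef(d[iu], e[iu])[0, 1]
    perms = list(itertools.permutations(range(4)))
    count = sum(
        np.corrcoef(d[iu], e[np.ix_(p, p)][iu])[0, 1] >= r_obs - 1e-12 for p in perms
    )
    exact = count / len(perms)
    _, p_hat = tree_concordance(d, e, n_perm=4999, seed=7)
    assert p_hat == pytest.approx(exact, abs=0.03)


def test_fixture_determinism():
    a = generate_methylome_fixture(n_samples=1, seed=9)
    b = generate_methylome_fixture(n_samples=1, seed=9)
    pd.testing.assert_frame_equal(a.reports["meth_00"], b.reports["meth_00"])


def test_degenerate_rates_give_all_zero_chh():
    fx = generate_methylome_fixture(
        n_samples=1, seed=1, nonconv=0.0,
        mc_proportion={"CpG": 0.05, "CHG": 0.02, "CHH": 0.0},
    )
    rep = fx.reports["meth_00"]
    chh = rep[rep["context"] == "CHH"]
    assert (chh["count_methylated"] == 0).all()
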