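import itertools
import math

import numpy as np
import pandas as pd
import pytest

from clonepop.diversity import (
    LDCurve,
    count_ns_sites,
    genotype_r2,
    ld_decay,
    per_site_pi,
    pin_pis,
    region_pi,
    sliding_windows,
    tajimas_d,
    tajimas_d_from_matrix,
)
from clonepop.genotypes import GenotypeMatrix


def _gm(dosage, pos=None, chrom=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)], populations={},
        chrom=np.array(chrom or ["chr1"] * m, dtype=object),
        pos=np.array(pos if pos is not None else np.arange(1, m + 1) * 10),
        ref=np.array(["A"] * m, dtype=object), alt=np.array(["C"] * m, dtype=object),
        dosage=dosage,
    )


# -- pi ---------------------------------------------------------------------

def test_per_site_pi_closed_forms():
    assert per_site_pi(0, 10) == 0
    assert per_site_pi(2, 4) == pytest.approx(2 * 0.25 * (4 / 3))
    assert math.isnan(per_site_pi(0, 1))


def test_per_site_pi_equals_pairwise_mismatch_enumeration(rng):
    """Oracle: mean mismatch indicator over all C(n,2) haplotype pairs."""
    for _ in range(100):
        n = int(rng.integers(2, 12))
        k = int(rng.integers(0, n + 1))
        haps = np.array([1] * k + [0] * (n - k))
        pairs = list(itertools.combinations(range(n), 2))
        oracle = np.mean([haps[i] != haps[j] for i, j in pairs])
        assert per_site_pi(k, n) == pytest.approx(oracle, abs=1e-12)


def test_region_pi_with_exclusion():
    gm = _gm([[1, 0], [1, 0]], pos=[5, 50])  # site0: k=2,n=4 -> pi=2/3
    assert region_pi(gm, callable_length=10) == pytest.approx(0.0667, abs=1e-4)
    excl = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]})
    assert region_pi(gm, callable_length=10, exclude=excl) == 0.0


def test_pi_invariant_under_relabeling_and_allele_swap(small_single_pop):
    gm, _ = small_single_pop
    pi1 = region_pi(gm, callable_length=100_000)
    flipped = gm.take_sites(np.arange(gm.n_sites))
    flipped.dosage = np.where(flipped.dosage >= 0, 2 - flipped.dosage, -1).astype(np.int8)
    assert region_pi(flipped, callable_length=100_000) == pytest.approx(pi1, abs=1e-15)
    shuffled = gm.take_samples(list(reversed(gm.sample_ids)))
    assert region_pi(shuffled, callable_length=100_000) == pytest.approx(pi1, abs=1e-15)


# -- Nei-Gojobori site counting ---------------------------------------------

def test_count_ns_sites_codon_examples():
    n, s = count_ns_sites("ATG")
    assert (n, s) == (3.0, 0.0)
    n, s = count_ns_sites("TTT")
    assert s == pytest.approx(1 / 3)
    assert n == pytest.approx(8 / 3)


def test_count_ns_sites_matches_exhaustive_enumeration(rng):
    """Oracle: translate all 9 point changes per codon directly."""
    from Bio.Seq import Seq

    codons = [c for c in map("".join, itertools.product("ACGT", repeat=3))]
    for _ in range(10):
        seq = "".join(rng.choice(codons, size=30))
        n_o = s_o = 0.0
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            aa = str(Seq(codon).translate())
            for p in range(3):
                for b in "ACGT":
                    if b == codon[p]:
                        continue
                    alt = codon[:p] + b + codon[p + 1 :]
                    if str(Seq(alt).translate()) == aa:
                        s_o += 1 / 3
                    else:
                        n_o += 1 / 3
        n, s = count_ns_sites(seq)
        assert n == pytest.approx(n_o, abs=1e-10)
        assert s == pytest.approx(s_o, abs=1e-10)
        assert n + s == pytest.approx(len(seq), abs=1e-9)


def test_pin_pis_trivial_and_planted():
    gm = _gm([[1, 1], [1, 1]])
    effects = np.array(["nonsynonymous", "synonymous"])
    pi_n, pi_s, ratio = pin_pis(gm, effects, n_sites=10.0, s_sites=10.0)
    assert ratio == pytest.approx(1.0)  # equal diversity at N and S sites
    pi_n, pi_s, ratio = pin_pis(gm, np.array(["synonymous", "synonymous"]), 10.0, 10.0)
    assert pi_n == 0 and ratio == 0.0


# -- Tajima's D -------------------------------------------------------------

def _tajima_oracle(S, n, pi):
    """Textbook formula, re-derived independently for the test."""
    a1 = np.sum(1 / np.arange(1, n))
    a2 = np.sum(1 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1, c2 = b1 - 1 / a1, b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1 * a1 + a2)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def test_tajimas_d_matches_independent_formula(rng):
    for _ in range(100):
        n = int(rng.integers(4, 40))
        S = int(rng.integers(1, 60))
        pi = float(rng.uniform(0, 2 * S))
        assert tajimas_d(S, n, pi) == pytest.approx(_tajima_oracle(S, n, pi), abs=1e-12)


def test_tajimas_d_undefined_cases():
    assert math.isnan(tajimas_d(0, 10, 0.0))
    assert math.isnan(tajimas_d(5, 3, 1.0))


def test_neutral_simulation_tajima_near_zero(small_single_pop):
    gm, _ = small_single_pop
    win = sliding_windows(gm, size=10_000, step=10_000, stat="tajD")
    vals = win["value"].dropna()
    assert len(vals) > 5
    assert abs(vals.mean()) < 0.6  # single replicate; acceptance covers 200 windows


# -- r^2 and LD decay -------------------------------------------------------

def test_genotype_r2_examples(rng):
    assert genotype_r2([0, 1, 2, 1], [0, 1, 2, 1]) == pytest.approx(1.0)
    assert genotype_r2([0, 0, 2, 2], [0, 2, 0, 2]) == pytest.approx(0.0, abs=1e-12)
    assert math.isnan(genotype_r2([1, 1, 1], [0, 1, 2]))
    for _ in range(100):
        x = rng.integers(0, 3, size=12).astype(float)
        y = rng.integers(0, 3, size=12).astype(float)
        if x.std() == 0 or y.std() == 0:
            continue
        oracle = (np.mean(x * y) - x.mean() * y.mean()) ** 2 / (x.var() * y.var())
        assert genotype_r2(x, y) == pytest.approx(oracle, abs=1e-10)


def test_decay_distance_linear_interpolation():
    curve = LDCurve(
        bin_edges=np.array([0, 10_000, 20_000]),
        mean_r2=np.array([0.3, 0.1]),
        pair_counts=np.array([10, 10]),
    )
    assert curve.decay_distance_at(0.2) == pytest.approx(10_000)


def test_decay_distance_never_reached_reports_beyond_max():
    curve = LDCurve(
        bin_edges=np.array([0, 50_000, 100_000]),
        mean_r2=np.array([0.4, 0.25]),
        pair_counts=np.array([10, 10]),
    )
    assert math.isinf(curve.decay_distance_at(0.2))


def test_ld_decay_bin_means_and_pair_conservation(small_single_pop):
    gm, _ = small_single_pop
    curve = ld_decay(gm, max_dist=50_000, bin_width=5_000)
    ok = np.isfinite(curve.mean_r2)
    assert ((curve.mean_r2[ok] >= 0) & (curve.mean_r2[ok] <= 1)).all()
    # pair conservation against a direct count of qualifying pairs
    maf = gm.maf()
    miss = gm.site_info["missingness"].to_numpy()
    use = np.flatnonzero((maf >= 0.05) & (miss <= 0.20))
    pos = gm.pos[use]
    total = sum(
        int(np.searchsorted(pos, pos[a] + 50_000, side="right") - a - 1)
        for a in range(len(pos))
    )
    # undefined-r2 pairs are excluded from bins, so counts cannot exceed total
    assert curve.pair_counts.sum() <= total
    assert curve.pair_counts.sum() > 0.9 * total


# -- sliding windows --------------------------------------------------------

def test_windows_constant_fixture_flat():
    dosage = np.tile(np.array([[1], [1]], dtype=np.int8), (1, 20))
    gm = _gm(dosage, pos=np.arange(1, 21) * 500)
    win = sliding_windows(gm, size=2_000, step=2_000, stat="pi")
    vals = win["value"].to_numpy()
    assert np.allclose(vals, vals[0])


def test_windows_zero_snps_pi_zero_tajd_missing():
    gm = _gm([[1], [1]], pos=[100])
    win_pi = sliding_windows(gm, size=50, step=50, stat="pi")
    assert 0.0 in win_pi["value"].to_numpy()
    win_d = sliding_windows(gm, size=50, step=50, stat="tajD")
    assert win_d["value"].isna().any()


def test_windows_concatenation_invariance():
    from clonepop.models import DemographicModel
    from clonepop.simulate import simulate_population_set

    gm2, _ = simulate_population_set(DemographicModel(), 6, 60_000, seed=21, n_chroms=2)
    both = sliding_windows(gm2, size=20_000, step=20_000, stat="pi")
    for c in ("chr1", "chr2"):
        solo = sliding_windows(gm2.take_sites(gm2.chrom == c), 20_000, 20_000, "pi")
        sub = both[both["chrom"] == c].reset_index(drop=True)
        pd.testing.assert_frame_equal(sub, solo.reset_index(drop=True))
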