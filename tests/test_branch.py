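import numpy as np
import pandas as pd
import pytest

from clonepop.branch import (
    BranchDriftParams,
    branch_clr_window,
    estimate_drift_params,
    threepop_scan,
    validate_candidates,
)
from clonepop.errors import ConfigurationError
from clonepop.models import DemographicModel
from clonepop.simulate import simulate_population_set


def test_zero_drift_when_branch_equals_outgroup(rng):
    p = rng.uniform(0.05, 0.95, size=5000)
    params = estimate_drift_params(p, p, p, 10_000, 10_000, 10_000)
    assert params.omega_a == pytest.approx(0.0, abs=1e-3)
    assert params.omega_b == pytest.approx(0.0, abs=1e-3)


def test_swapping_branches_swaps_omegas(rng):
    p = rng.uniform(0.05, 0.95, size=3000)
    pa = np.clip(p + rng.normal(0, 0.1, p.size), 0, 1)
    pb = np.clip(p + rng.normal(0, 0.2, p.size), 0, 1)
    one = estimate_drift_params(pa, pb, p, 20, 20, 20)
    two = estimate_drift_params(pb, pa, p, 20, 20, 20)
    assert one.omega_a == pytest.approx(two.omega_b)
    assert one.omega_b == pytest.approx(two.omega_a)


def test_drift_floor_never_negative(rng):
    p = rng.uniform(0.4, 0.6, size=1500)
    params = estimate_drift_params(p, p, p, 5, 5, 5)  # sampling noise dominates
    assert params.omega_a >= 0 and params.omega_b >= 0


def test_too_few_snps_rejected(rng):
    p = rng.uniform(0.1, 0.9, size=50)
    with pytest.raises(ConfigurationError, match="polymorphic"):
        estimate_drift_params(p, p, p, 10, 10, 10)


def test_drift_recovery_matches_simulated_divergence():
    """Pure-drift two-population split: omega should track T/2N (the branch
    length in drift time) within the spec'd 15% across replicates."""
    T, N = 40_000.0, 200_000.0
    model = DemographicModel(
        pop_sizes={"asia": N, "europe": N, "america": N, "ancestral": N},
        sexuality={p: 0.5 for p in ("asia", "europe", "america", "ancestral")},
        split_times={"europe": T, "india": 60_000, "america": 100_000},
    )
    omegas = []
    for seed in range(12):
        gm, _ = simulate_population_set(
            model, {"asia": 10, "europe": 10, "america": 10}, 150_000, seed=seed
        )
        idx = {p: gm.sample_index(gm.samples_in(p)) for p in ("asia", "europe", "america")}
        f = {p: gm.alt_freq(idx[p]) for p in idx}
        ok = np.isfinite(f["asia"]) & np.isfinite(f["europe"])
        params = estimate_drift_params(
            f["europe"][ok], f["america"][ok], f["asia"][ok], 10, 10, 10,
            min_snps=200,
        )
        omegas.append(params.omega_a)
    # europe vs outgroup asia: total drift ~ T_eu/2N_eu + T_eu/2N_asia
    expect = T / (2 * N) * 2
    assert np.mean(omegas) == pytest.approx(expect, rel=0.15)


def test_clr_zero_when_grid_has_no_selection(rng):
    snps = pd.DataFrame(
        {
            "p_a": rng.uniform(0.1, 0.9, 50),
            "p_b": rng.uniform(0.1, 0.9, 50),
            "p_out": rng.uniform(0.1, 0.9, 50),
            "pos": np.arange(50) * 1000.0,
        }
    )
    params = BranchDriftParams(0.05, 0.05, 10, 10, 10)
    assert branch_clr_window(snps, params, "b", 25_000.0, A_grid=(0.0,)) == 0.0


def test_toy_window_matches_hand_normal_likelihood():
    snps = pd.DataFrame(
        {
            "p_a": [0.2, 0.5, 0.9], "p_b": [0.3, 0.4, 0.8],
            "p_out": [0.25, 0.45, 0.85], "pos": [0.0, 1000.0, 2000.0],
        }
    )
    params = BranchDriftParams(omega_a=0.1, omega_b=0.2, n_a=10, n_b=12, n_out=14)
    A, rs, x = 2.0, 5000.0, 1000.0

    def hand_ll(inflate):
        tot = 0.0
        for _, r in snps.iterrows():
            var_anc = r["p_out"] * (1 - r["p_out"])
            drift = 0.2 * (1 + A * np.exp(-abs(r["pos"] - x) / rs) if inflate else 1)
            var = (var_anc * drift + r["p_b"] * (1 - r["p_b"]) / 24 + var_anc / 28)
            tot += -0.5 * (np.log(2 * np.pi * var) + (r["p_b"] - r["p_out"]) ** 2 / var)
        return tot

    got = branch_clr_window(snps, params, "b", x, A_grid=(0.0, A), rscale_grid=(rs,), min_snps=3)
    expect = 2 * max(0.0, hand_ll(True) - hand_ll(False))
    assert got == pytest.approx(expect, abs=1e-9)


@pytest.fixture(scope="module")
def symmetric_scan():
    model = DemographicModel(
        pop_sizes={p: 300_000 for p in ("asia", "europe", "america", "ancestral")},
        sexuality={p: 0.3 for p in ("asia", "europe", "america", "ancestral")},
        split_times={"europe": 20_000, "india": 30_000, "america": 60_000},
    )
    gm, _ = simulate_population_set(model, {"america": 8, "asia": 8, "europe": 8},
                                    250_000, seed=3)
    return threepop_scan(gm, ("america", "asia", "europe")), gm


def test_scan_output_invariant_to_snp_order(symmetric_scan):
    res, gm = symmetric_scan
    perm = np.random.default_rng(1).permutation(gm.n_sites)
    gm2 = gm.take_sites(perm)  # constructor re-sorts by (chrom, pos)
    res2 = threepop_scan(gm2, ("america", "asia", "europe"))
    pd.testing.assert_frame_equal(res["b"], res2["b"])


def test_branch_clr_nonnegative(symmetric_scan):
    res, _ = symmetric_scan
    for br in ("a", "b"):
        vals = res[br]["value"].dropna()
        assert (vals >= -1e-9).all()


def test_missing_population_rejected(four_pop_matrix):
    gm, _ = four_pop_matrix
    with pytest.raises(ConfigurationError):
        threepop_scan(gm, ("america", "asia", "atlantis"))


def test_validate_candidates_reports_flags(four_pop_matrix):
    gm, _ = four_pop_matrix
    windows = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [0, 10_000_000], "end": [40_000, 10_040_000]}
    )
    rep = validate_candidates(windows, gm, ["asia", "europe"])
    real = rep[rep["start"] == 0]
    assert real["pi"].notna().all()
    empty = rep[rep["start"] == 10_000_000]
    assert empty["pi"].isna().all()
    assert empty["low_pi"].isna().all() or empty["low_pi"].isnull().all()
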