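"""Rejection-ABC over three demographic scenarios of a four-population
facultatively asexual species.

The three candidate histories share the ingroup structure (europe from asia
most recently, india from asia next) and differ in the deepest event: the
asia lineage ancestral, the america lineage ancestral, or both derived from
an unsampled ("ghost") ancestral population.  Simulations run at desk scale
(small L, few diploids per population) with a FIXED mutation rate, so that
population sizes are identified through diversity levels; summaries are
standardized by the reference table's spread and compared by Euclidean
distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clonal import individual_heterozygosity
from .diversity import ld_decay, per_site_pi
from .errors import ConfigurationError
from .genotypes import GenotypeMatrix
from .models import ANCESTRAL_POP, CONTEMPORARY_POPS, SCENARIOS, DemographicModel
from .sfs import background_sfs
from .simulate import simulate_population_set

# Fixed calibration of the simulator's mutation rate: theta_site / (4 * REF_SIZE).
REF_SIZE = 250_000.0
THETA_REF = 0.0016


def hudson_fst(p1, n1, p2, n2) -> float:
    """Hudson's F_ST as a ratio of averages over sites.

    p1/p2 are per-site allele frequencies, n1/n2 HAPLOID sample sizes.
    Per-site numerator (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1) and
    denominator p1(1-p2) + p2(1-p1); the genome value divides the summed
    numerators by the summed denominators.
    """
    p1 = np.atleast_1d(np.asarray(p1, dtype=float))
    p2 = np.atleast_1d(np.asarray(p2, dtype=float))
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = np.isfinite(num) & np.isfinite(den)
    dsum = float(den[ok].sum())
    if dsum == 0:
        return np.nan
    return float(num[ok].sum() / dsum)


@dataclass
class SummaryConfig:
    ld_max_dist: int = 50_000
    ld_bin_width: int = 5_000
    ld_max_sites: int = 400
    sfs_bins: int = 5


def summarize(gm: GenotypeMatrix, L: float, config: SummaryConfig | None = None) -> pd.Series:
    """Deterministic summary-statistic vector for ABC.

    Per population: pi, folded-SFS proportions (first bins), LD-decay
    distance at r^2 = 0.2 (censored at ld_max_dist), median heterozygosity;
    per population pair: Hudson F_ST and the shared-polymorphism fraction
    (sites segregating in both populations over sites segregating in
    either), which carries the deep-structure signal that separates the
    ancestral-population scenarios.  NaNs are replaced by neutral fillers so
    the vector length is fixed.
    """
    config = config or SummaryConfig()
    pops = [p for p in CONTEMPORARY_POPS if gm.samples_in(p)]
    for p in pops:
        if len(gm.samples_in(p)) < 4:
            raise ConfigurationError(f"population {p} has < 4 samples")
    out = {}
    _, med_h = individual_heterozygosity(gm)
    freqs = {}
    for p in pops:
        idx = gm.sample_index(gm.samples_in(p))
        k = gm.alt_counts(idx)
        n = gm.called_alleles(idx)
        freqs[p] = (k, n)
        out[f"pi_{p}"] = float(np.nansum(per_site_pi(k, n)) / L)
        sub = gm.take_samples(gm.samples_in(p))
        try:
            sfs = background_sfs(sub, folded=True)
            probs = sfs.counts / sfs.counts.sum()
            for j in range(1, config.sfs_bins + 1):
                out[f"sfs{j}_{p}"] = float(probs[j]) if j < probs.size else 0.0
        except ValueError:
            for j in range(1, config.sfs_bins + 1):
                out[f"sfs{j}_{p}"] = 0.0
        poly = np.flatnonzero((k > 0) & (k < n))
        if poly.size > config.ld_max_sites:
            poly = poly[np.linspace(0, poly.size - 1, config.ld_max_sites).astype(int)]
        curve = ld_decay(
            sub.take_sites(poly), max_dist=config.ld_max_dist,
            bin_width=config.ld_bin_width, maf_min=0.05,
        )
        dd = curve.decay_distance_at(0.2)
        if not math.isfinite(dd):
            dd = float(config.ld_max_dist)
        out[f"ld_{p}"] = min(dd, float(config.ld_max_dist))
        out[f"het_{p}"] = med_h.get(p, 0.0)
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            ka, na = freqs[a]
            kb, nb = freqs[b]
            ok = (na > 0) & (nb > 0)
            pa, pb = ka[ok] / na[ok], kb[ok] / nb[ok]
            seg = ((pa > 0) | (pb > 0)) & ((pa < 1) | (pb < 1))
            fst = hudson_fst(pa[seg], int(np.median(na[ok])), pb[seg], int(np.median(nb[ok])))
            out[f"fst_{a}_{b}"] = 0.0 if not np.isfinite(fst) else fst
            seg_a = (pa > 0) & (pa < 1)
            seg_b = (pb > 0) & (pb < 1)
            either = (seg_a | seg_b).sum()
            out[f"shared_{a}_{b}"] = (
                float((seg_a & seg_b).sum() / either) if either else 0.0
            )
    return pd.Series(out)


@dataclass
class PriorSpec:
    """Independent priors; split-time draws are sorted to satisfy the
    topology constraint T_europe < T_india < T_america."""

    split_log10_bounds: tuple = (3.0, math.log10(5e6))
    size_log10_bounds: tuple = (3.0, 6.0)
    sigma_bounds: tuple = (0.001, 1.0)

    def __post_init__(self):
        for lo, hi in (self.split_log10_bounds, self.size_log10_bounds, self.sigma_bounds):
            if not lo < hi:
                raise ConfigurationError("prior bounds must be ordered")
        if self.sigma_bounds[0] < 0 or self.sigma_bounds[1] > 1:
            raise ConfigurationError("sigma prior must stay inside [0, 1]")

    def draw(self, rng: np.random.Generator) -> dict:
        splits = np.sort(10 ** rng.uniform(*self.split_log10_bounds, size=3))
        params = {
            "T_europe": float(splits[0]),
            "T_india": float(splits[1]),
            "T_america": float(splits[2]),
        }
        for p in CONTEMPORARY_POPS + (ANCESTRAL_POP,):
            params[f"N_{p}"] = float(10 ** rng.uniform(*self.size_log10_bounds))
            params[f"sigma_{p}"] = float(rng.uniform(*self.sigma_bounds))
        return params


def model_from_params(scenario: str, params: dict) -> DemographicModel:
    return DemographicModel(
        scenario_id=scenario,
        split_times={
            "europe": params["T_europe"],
            "india": params["T_india"],
            "america": params["T_america"],
        },
        pop_sizes={p: params[f"N_{p}"] for p in CONTEMPORARY_POPS + (ANCESTRAL_POP,)},
        sexuality={p: params[f"sigma_{p}"] for p in CONTEMPORARY_POPS + (ANCESTRAL_POP,)},
        theta_site=THETA_REF,
        rho_site=1.5e-9,
        reference_size=REF_SIZE,
    )


@dataclass
class ABCResult:
    table: pd.DataFrame           # all draws: scenario, params, summaries, distance, accepted
    model_posterior: dict
    winning_scenario: str
    accepted: pd.DataFrame
    tolerance: float
    summary_names: list = field(default_factory=list)


def build_reference_table(
    scenarios,
    priors: PriorSpec,
    n_sims: int,
    seed: int,
    n_per_pop: int = 4,
    L: int = 100_000,
) -> pd.DataFrame:
    """Simulate the ABC reference table (scenarios cycled round-robin)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_sims):
        scenario = scenarios[i % len(scenarios)]
        params = priors.draw(rng)
        model = model_from_params(scenario, params)
        sim_seed = int(rng.integers(2**31 - 1))
        gm, _ = simulate_population_set(model, n_per_pop, L, seed=sim_seed)
        summ = summarize(gm, L)
        rows.append({"scenario": scenario, **params, **summ.to_dict()})
    return pd.DataFrame(rows)


def abc_reject(
    observed: pd.Series,
    reference: pd.DataFrame,
    tolerance: float,
) -> ABCResult:
    """Rejection step: accept the tolerance fraction of draws closest to the
    observed summaries under standardized Euclidean distance.

    Summaries with zero spread in the reference table are dropped with a
    warning column rather than poisoning the distance.
    """
    if not 0 < tolerance <= 1.0:
        raise ConfigurationError("tolerance must lie in (0, 1]")
    names = [c for c in observed.index if c in reference.columns]
    ref = reference[names].to_numpy(dtype=float)
    obs = observed[names].to_numpy(dtype=float)
    sd = np.nanstd(ref, axis=0)
    usable = np.isfinite(sd) & (sd > 0) & np.isfinite(obs)
    used = [n for n, u in zip(names, usable) if u]
    z = (ref[:, usable] - obs[usable]) / sd[usable]
    z = np.nan_to_num(z, nan=0.0)
    dist = np.sqrt((z**2).sum(axis=1))
    table = reference.copy()
    table["distance"] = dist
    n_accept = max(1, int(round(tolerance * len(table))))
    cutoff = np.sort(dist)[n_accept - 1]
    table["accepted"] = dist <= cutoff
    accepted = table[table["accepted"]].copy()
    shares = accepted["scenario"].value_counts(normalize=True).to_dict()
    posterior = {s: float(shares.get(s, 0.0)) for s in SCENARIOS}
    winning = max(posterior, key=posterior.get)
    return ABCResult(
        table=table,
        model_posterior=posterior,
        winning_scenario=winning,
        accepted=accepted,
        tolerance=tolerance,
        summary_names=used,
    )


def posterior_summary(result: ABCResult, truth: dict | None = None) -> pd.DataFrame:
    """Median and central 95% interval per parameter of the winning
    scenario's accepted draws; optional recovery check against truth."""
    acc = result.accepted[result.accepted["scenario"] == result.winning_scenario]
    if len(acc) < 20:
        raise ConfigurationError(f"only {len(acc)} accepted draws for the winning scenario")
    params = [c for c in acc.columns if c.startswith(("T_", "N_", "sigma_"))]
    rows = []
    for p in params:
        v = acc[p].to_numpy(dtype=float)
        lo, med, hi = np.quantile(v, [0.025, 0.5, 0.975])
        row = {"parameter": p, "q2.5": lo, "median": med, "q97.5": hi}
        if truth is not None and p in truth:
            row["truth"] = truth[p]
            row["covered"] = bool(lo <= truth[p] <= hi)
        rows.append(row)
    return pd.DataFrame(rows)
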