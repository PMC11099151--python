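"""Demographic models for a facultatively asexual plant sampled from four populations.

The species is clonal by default and only occasionally reproduces sexually.
The fraction of sexual generations in population ``p`` is ``sigma[p]``; because
recombination (and segregation) only happens in sexual generations, the
effective per-generation recombination rate of that population is
``rho_site * sigma[p]``.  Everything else is a standard pure-split coalescent
demography: four contemporary populations (america, asia, india, europe) whose
topology follows the species history — europe derives from asia most recently,
india next, and the america/asia split is the deepest event.  Three scenarios
differ in which population is ancestral at the deepest split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .errors import ConfigurationError

CONTEMPORARY_POPS = ("america", "asia", "india", "europe")
ANCESTRAL_POP = "ancestral"
SCENARIOS = ("asia_ancestral", "america_ancestral", "ghost_ancestral")


@dataclass(frozen=True)
class PopEpoch:
    """One population's existence interval on the species tree (generations ago)."""

    name: str
    size: float           # diploid effective size
    sigma: float          # fraction of sexual generations, in [0, 1]
    start: float          # time the population comes into existence (backwards)
    end: float            # time it merges into `parent` (math.inf for the root)
    parent: str | None


@dataclass(frozen=True)
class DemographicModel:
    """Scenario topology plus parameters.

    split_times maps a derived population to the number of generations before
    present at which it merges into its parent lineage.  Keys: "europe",
    "india", "america"; under the ghost scenario "america" is the time at
    which both america and asia merge into the unobserved ancestral
    population.
    """

    scenario_id: str = "ghost_ancestral"
    split_times: dict = field(
        default_factory=lambda: {"europe": 12_000.0, "india": 51_000.0, "america": 1_000_000.0}
    )
    pop_sizes: dict = field(
        default_factory=lambda: {
            "america": 200_000.0,
            "asia": 600_000.0,
            "india": 300_000.0,
            "europe": 100_000.0,
            ANCESTRAL_POP: 400_000.0,
        }
    )
    sexuality: dict = field(
        default_factory=lambda: {
            "america": 0.01,
            "asia": 0.1,
            "india": 0.03,
            "europe": 0.003,
            ANCESTRAL_POP: 0.1,
        }
    )
    theta_site: float = 0.0016
    rho_site: float = 1.5e-9
    reference_size: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities -------------------------------------------------

    @property
    def mu_site(self) -> float:
        """Per-site per-generation mutation rate implied by theta_site.

        theta_site is interpreted as the expected pairwise diversity
        4*Nref*mu at the reference size (mean of contemporary sizes unless
        given explicitly), so single-population models calibrate exactly.
        """
        nref = self.reference_size
        if nref is None:
            sizes = [self.pop_sizes[p] for p in self.populations()]
            nref = sum(sizes) / len(sizes)
        return self.theta_site / (4.0 * nref)

    def populations(self) -> tuple:
        """Contemporary (sampleable) populations present in this model."""
        return tuple(p for p in CONTEMPORARY_POPS if p in self.pop_sizes)

    def validate(self) -> None:
        if self.scenario_id not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {self.scenario_id!r}")
        if not self.theta_site > 0:
            raise ConfigurationError("theta_site must be > 0")
        if self.rho_site < 0:
            raise ConfigurationError("rho_site must be >= 0")
        for p, s in self.sexuality.items():
            if not 0.0 <= s <= 1.0:
                raise ConfigurationError(f"sexuality fraction for {p} outside [0, 1]")
        for p, n in self.pop_sizes.items():
            if not n > 0:
                raise ConfigurationError(f"population size for {p} must be > 0")
        present = self.populations()
        if "asia" not in present:
            raise ConfigurationError("the asia (stem) population must be present")
        t = self.split_times
        for k in ("europe", "india", "america"):
            if k in present and k not in t:
                raise ConfigurationError(f"missing split time for {k}")
        order = [t[k] for k in ("europe", "india", "america") if k in present]
        if any(b <= a for a, b in zip(order, order[1:])):
            raise ConfigurationError(
                "split order violates scenario topology: require "
                "T_europe < T_india < T_america"
            )

    # -- epochs -------------------------------------------------------------

    def epochs(self) -> dict:
        """Resolve the scenario into PopEpoch records keyed by population name."""
        t = self.split_times
        sz = self.pop_sizes
        sx = self.sexuality

        present = self.populations()

        def ep(name, start, end, parent):
            return PopEpoch(name, sz[name], sx[name], start, end, parent)

        out = {}
        if "europe" in present:
            out["europe"] = ep("europe", 0.0, t["europe"], "asia")
        if "india" in present:
            out["india"] = ep("india", 0.0, t["india"], "asia")
        if "america" not in present:
            out["asia"] = ep("asia", 0.0, math.inf, None)
        elif self.scenario_id == "asia_ancestral":
            out["america"] = ep("america", 0.0, t["america"], "asia")
            out["asia"] = ep("asia", 0.0, math.inf, None)
        elif self.scenario_id == "america_ancestral":
            out["asia"] = ep("asia", 0.0, t["america"], "america")
            out["america"] = ep("america", 0.0, math.inf, None)
        else:  # ghost_ancestral
            out["asia"] = ep("asia", 0.0, t["america"], ANCESTRAL_POP)
            out["america"] = ep("america", 0.0, t["america"], ANCESTRAL_POP)
            out[ANCESTRAL_POP] = ep(ANCESTRAL_POP, t["america"], math.inf, None)
        return out

    def with_params(self, **kwargs) -> "DemographicModel":
        return replace(self, **kwargs)


def single_population_model(
    *, size: float = 250_000.0, sigma: float = 1.0, theta_site: float = 0.001,
    rho_site: float = 0.0,
) -> DemographicModel:
    """A one-population model (asia only), handy for calibration experiments."""
    return DemographicModel(
        scenario_id="asia_ancestral",
        split_times={"europe": 1.0, "india": 2.0, "america": 3.0},
        pop_sizes={"asia": size},
        sexuality={"asia": sigma},
        theta_site=theta_site,
        rho_site=rho_site,
        reference_size=size,
    )


@dataclass
class SimTruth:
    """Ground-truth record emitted next to every simulated dataset."""

    model: DemographicModel
    seed: int
    sweep_sites: list = field(default_factory=list)  # (pop, chrom, pos, strength)
    planted_filter_counts: dict = field(default_factory=dict)
    true_clonal_partition: list = field(default_factory=list)  # list of sample-id lists

    def validate(self, chrom_lengths: dict | None = None) -> None:
        for _, chrom, pos, _ in self.sweep_sites:
            if chrom_lengths is not None:
                if chrom not in chrom_lengths or not (1 <= pos <= chrom_lengths[chrom]):
                    raise ConfigurationError(f"sweep site {chrom}:{pos} outside simulated range")
        for k, v in self.planted_filter_counts.items():
            if v < 0:
                raise ConfigurationError(f"negative planted count for {k}")
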