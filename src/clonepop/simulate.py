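"""Simulation front-end: genotype matrices from the coalescent engine,
post-hoc hard-sweep injection, and planted clonal families.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import numpy as np

from .coalescent import simulate_haplotypes
from .errors import BoundsError, ConfigurationError
from .genotypes import MISSING, GenotypeMatrix, clean_site_info
from .models import DemographicModel, SimTruth

_NUCS = np.array(list("ACGT"))


def simulate_population_set(
    model: DemographicModel,
    n_per_pop,
    L: int,
    seed: int,
    n_chroms: int = 1,
) -> tuple:
    """Simulate diploid genotypes for all populations of `model`.

    n_per_pop is an int (same for every population) or a dict
    population -> diploid count.  Returns (GenotypeMatrix, SimTruth) with
    REF fixed to the ancestral allele, so polarization truth is exact.
    """
    if L < 10_000:
        raise ConfigurationError("L must be at least 10 kb")
    pops = model.populations()
    if isinstance(n_per_pop, int):
        n_per_pop = {p: n_per_pop for p in pops}
    for p, n in n_per_pop.items():
        if n < 4:
            raise ConfigurationError(f"need at least 4 diploids per population (got {n} for {p})")

    rng = np.random.default_rng(seed)
    sample_ids = []
    populations = {}
    for pop in sorted(n_per_pop):
        for i in range(n_per_pop[pop]):
            sid = f"{pop}_{i:03d}"
            sample_ids.append(sid)
            populations[sid] = pop

    chroms, poss, refs, alts, dosages = [], [], [], [], []
    sim_stats = []
    for c in range(n_chroms):
        sim = simulate_haplotypes(model, n_per_pop, L, rng)
        sim_stats.append(sim)
        hap = sim.haplotypes
        dos = (hap[0::2, :] + hap[1::2, :]).astype(np.int8)
        s = sim.positions.size
        chroms.append(np.full(s, f"chr{c + 1}", dtype=object))
        poss.append(sim.positions + 1)  # 1-based
        ref = rng.choice(_NUCS, size=s)
        shift = rng.integers(1, 4, size=s)
        alt = _NUCS[(np.searchsorted(_NUCS, ref) + shift) % 4]
        refs.append(ref.astype(object))
        alts.append(alt.astype(object))
        dosages.append(dos)

    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        populations=populations,
        chrom=np.concatenate(chroms) if chroms else np.zeros(0, dtype=object),
        pos=np.concatenate(poss),
        ref=np.concatenate(refs),
        alt=np.concatenate(alts),
        dosage=np.concatenate(dosages, axis=1),
        ancestral=np.concatenate(refs).copy() if refs else None,
    )
    truth = SimTruth(model=model, seed=seed)
    truth.sim_stats = sim_stats  # per-chromosome tree/breakpoint bookkeeping
    return gm, truth


def inject_sweep(
    gm: GenotypeMatrix,
    pop: str,
    chrom: str,
    pos: int,
    strength: float,
    seed: int,
) -> GenotypeMatrix:
    """Overlay a hard selective sweep on one population after the fact.

    The derived (ALT, since REF is ancestral in simulated matrices) allele at
    the site nearest `pos` is driven to frequency >= 0.95 in `pop`.  At a
    linked site at distance d, each swept sample keeps its pre-sweep genotype
    with escape probability 1 - exp(-d / strength) and is otherwise
    homogenized to the sweeping template genotype — per-sample escape, the
    granularity at which recombination rescues hitchhiking lineages, which
    leaves the characteristic high-frequency-derived / rare-escapee SFS
    skew.  Samples outside `pop` are untouched.
    """
    on_chrom = np.flatnonzero(gm.chrom == chrom)
    if on_chrom.size == 0:
        raise BoundsError(f"no sites on chromosome {chrom!r}")
    lo, hi = int(gm.pos[on_chrom].min()), int(gm.pos[on_chrom].max())
    if not (lo <= pos <= hi):
        raise BoundsError(f"position {pos} outside simulated range [{lo}, {hi}] on {chrom}")
    members = gm.samples_in(pop)
    if not members:
        raise ConfigurationError(f"population {pop!r} not present")

    rng = np.random.default_rng(seed)
    out = gm.take_sites(np.arange(gm.n_sites))
    ridx = out.sample_index(members)
    focal = on_chrom[np.argmin(np.abs(gm.pos[on_chrom] - pos))]

    # Sweep the focal site: nearly all members become homozygous derived.
    escape_focal = rng.random(len(ridx)) < 0.02
    out.dosage[ridx[~escape_focal], focal] = 2
    swept = ridx[~escape_focal]
    template = swept[0] if swept.size else ridx[0]

    # The sweeping template is a HAPLOTYPE: resolve the template sample's
    # heterozygous sites to one allele each, once.
    tdos = out.dosage[template, on_chrom]
    template_allele = np.where(tdos == 2, 1, 0).astype(np.int8)
    het = tdos == 1
    template_allele[het] = rng.integers(0, 2, size=int(het.sum()))
    valid = tdos != MISSING

    d = np.abs(gm.pos[on_chrom].astype(float) - float(gm.pos[focal]))
    with np.errstate(over="ignore"):
        escape_p = 1.0 - np.exp(-d / strength) if strength > 0 else np.ones_like(d)
    hitch = rng.random((swept.size, d.size)) >= escape_p[None, :]
    for col, site in enumerate(on_chrom):
        if site == focal or not valid[col] or not hitch[:, col].any():
            continue
        riders = swept[hitch[:, col]]
        out.dosage[riders, site] = 2 * template_allele[col]
    out.refresh_missingness()
    return out


def add_clonal_copies(
    gm: GenotypeMatrix,
    copies: dict,
    hom_divergence: float = 2e-5,
    het_divergence: float = 0.005,
    seed: int = 0,
) -> tuple:
    """Append near-identical clonal copies of selected samples.

    copies maps sample id -> number of clonal copies to add.  Each copy
    differs from its founder at a fraction `hom_divergence` of the founder's
    homozygous sites (0 <-> 2 flips: somatic mutations fixed within the
    clone) and at a fraction `het_divergence` of heterozygous sites (1 -> 0
    or 2: loss of heterozygosity).  Returns (expanded matrix, true clonal
    partition as a list of sample-id lists, founders included).
    """
    rng = np.random.default_rng(seed)
    new_rows = []
    new_ids = []
    new_pops = {}
    partition = {s: [s] for s in gm.sample_ids}
    for sid, k in copies.items():
        base = gm.dosage[gm.sample_index([sid])[0]].copy()
        for c in range(k):
            row = base.copy()
            hom = np.flatnonzero((row == 0) | (row == 2))
            het = np.flatnonzero(row == 1)
            n_hom = rng.binomial(hom.size, hom_divergence)
            n_het = rng.binomial(het.size, het_divergence)
            if n_hom:
                flip = rng.choice(hom, size=n_hom, replace=False)
                row[flip] = 2 - row[flip]
            if n_het:
                flip = rng.choice(het, size=n_het, replace=False)
                row[flip] = rng.choice([0, 2], size=n_het)
            cid = f"{sid}_c{c + 1}"
            new_rows.append(row)
            new_ids.append(cid)
            new_pops[cid] = gm.populations.get(sid)
            partition[sid].append(cid)

    out = GenotypeMatrix(
        sample_ids=list(gm.sample_ids) + new_ids,
        populations={**gm.populations, **new_pops},
        chrom=gm.chrom.copy(),
        pos=gm.pos.copy(),
        ref=gm.ref.copy(),
        alt=gm.alt.copy(),
        dosage=np.vstack([gm.dosage] + new_rows) if new_rows else gm.dosage.copy(),
        ancestral=None if gm.ancestral is None else gm.ancestral.copy(),
    )
    out.refresh_missingness()
    return out, sorted(partition.values())
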