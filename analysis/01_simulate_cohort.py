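#!/usr/bin/env python
"""Simulate the study cohort: four populations (america, asia, india,
europe) under the ghost-ancestral demography with population-specific
sexuality fractions, and write the VCF plus per-population summaries.

The asia population is the most sexual (sigma = 0.1) and europe the least
(sigma = 0.003), so asia should carry the most diversity and the fastest
LD decay."""

import argparse
import os

import numpy as np
import pandas as pd

from clonepop.diversity import per_site_pi
from clonepop.models import DemographicModel
from clonepop.simulate import simulate_population_set
from clonepop.vcfio import write_vcf


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", default="results")
    ap.add_argument("--n-per-pop", type=int, default=8)
    ap.add_argument("--length", type=int, default=300_000)
    args = ap.parse_args()
    os.makedirs(args.out_dir, exist_ok=True)

    model = DemographicModel()
    gm, truth = simulate_population_set(model, args.n_per_pop, args.length, args.seed)
    write_vcf(gm, os.path.join(args.out_dir, "cohort.vcf"))
    pd.DataFrame(
        [(s, p) for s, p in gm.populations.items()], columns=["sample", "population"]
    ).to_csv(os.path.join(args.out_dir, "populations.tsv"), sep="\t", index=False)

    rows = []
    for pop in model.populations():
        idx = gm.sample_index(gm.samples_in(pop))
        pi = float(np.nansum(per_site_pi(gm.alt_counts(idx), gm.called_alleles(idx)))
                   / args.length)
        rows.append((pop, model.sexuality[pop], model.pop_sizes[pop], pi))
    tab = pd.DataFrame(rows, columns=["population", "sigma", "Ne", "pi"])
    tab.to_csv(os.path.join(args.out_dir, "cohort_summary.tsv"), sep="\t", index=False)
    print(f"simulated {gm.n_samples} diploids, {gm.n_sites} SNPs over {args.length} bp")
    print(tab.to_string(index=False))
    print("asia most diverse:", tab.loc[tab["pi"].idxmax(), "population"] == "asia")


if __name__ == "__main__":
    main()
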