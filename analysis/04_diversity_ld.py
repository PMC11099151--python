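#!/usr/bin/env python
"""Diversity and LD portrait of the cohort: per-population pi, pi_N/pi_S
over an annotated genome, LD-decay distance at r^2 = 0.2, and sliding
pi / Tajima's D tracks.

pi_N/pi_S uses Nei-Gojobori site counting over all annotated CDS; the LD
decay distance is expected to shorten with the population's sexuality
fraction."""

import argparse
import math
import os

import numpy as np
import pandas as pd

from clonepop.diversity import ld_decay, pin_pis, region_pi, sliding_windows
from clonepop.effects import classify_coding_effect, count_ns_sites
from clonepop.annotation import cds_spliced_sequence
from clonepop.fixtures import generate_annotation_fixture
from clonepop.models import DemographicModel
from clonepop.simulate import simulate_population_set


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", default="results")
    ap.add_argument("--length", type=int, default=120_000)
    args = ap.parse_args()
    os.makedirs(args.out_dir, exist_ok=True)

    model = DemographicModel()
    gm, _ = simulate_population_set(model, 8, args.length, args.seed)
    ann = generate_annotation_fixture(args.length, 40, 5, seed=args.seed)
    # anchor simulated SNPs onto the annotated genome so effects are callable
    seq = ann.sequence["chr1"]
    comp = {"A": "C", "C": "G", "G": "T", "T": "A"}
    gm.ref = np.array([seq[p - 1] for p in gm.pos], dtype=object)
    gm.alt = np.array([comp[r] for r in gm.ref], dtype=object)
    effects = classify_coding_effect(gm, ann.genes, ann.sequence)
    n_sites = s_sites = 0.0
    for g in ann.genes:
        n, s = count_ns_sites(cds_spliced_sequence(g, ann.sequence))
        n_sites += n
        s_sites += s

    rows = []
    for pop in model.populations():
        idx = gm.sample_index(gm.samples_in(pop))
        pi = region_pi(gm, callable_length=args.length, sample_idx=idx)
        pi_n, pi_s, ratio = pin_pis(gm, effects, n_sites, s_sites, sample_idx=idx)
        dd = ld_decay(gm, max_dist=100_000, bin_width=2_000,
                      sample_idx=idx).decay_distance_at(0.2)
        rows.append((pop, model.sexuality[pop], pi, pi_n, pi_s, ratio,
                     dd if math.isfinite(dd) else float("nan")))
    tab = pd.DataFrame(rows, columns=["population", "sigma", "pi", "pi_N", "pi_S",
                                      "pi_N/pi_S", "ld_decay_bp"])
    tab.to_csv(os.path.join(args.out_dir, "diversity_ld.tsv"), sep="\t", index=False)

    for stat in ("pi", "tajD"):
        track = sliding_windows(gm, size=20_000, step=5_000, stat=stat)
        track.to_csv(os.path.join(args.out_dir, f"track_{stat}.tsv"), sep="\t",
                     index=False)
    counts = pd.Series(effects).value_counts()
    print("effect classes:", counts.to_dict())
    print(tab.round(5).to_string(index=False))
    print("(NaN LD decay = curve stays above r^2 = 0.2 within 100 kb; the")
    print(" coalescent is neutral, so pi_N/pi_S fluctuates around 1 here —")
    print(" values well below 1 in real data reflect purifying selection)")


if __name__ == "__main__":
    main()
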