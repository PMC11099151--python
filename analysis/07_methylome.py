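#!/usr/bin/env python
"""Population methylome analysis on simulated bisulfite cytosine reports:
non-conversion from the chloroplast stand-in, binomial calling, mC and wML
by context, metagene profiles over genes and TEs, methylome clustering and
its concordance with genetic distance."""

import argparse
import os

import numpy as np
import pandas as pd

from clonepop.fixtures import generate_annotation_fixture, generate_methylome_fixture
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


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()
    os.makedirs(args.out_dir, exist_ok=True)

    # two "populations" with a planted CHH difference (clonal populations
    # gradually lose CHH methylation)
    fx_hi = generate_methylome_fixture(n_samples=4, seed=args.seed,
                                       mc_proportion={"CpG": 0.076, "CHG": 0.023,
                                                      "CHH": 0.004})
    fx_lo = generate_methylome_fixture(n_samples=4, seed=args.seed + 1,
                                       mc_proportion={"CpG": 0.076, "CHG": 0.023,
                                                      "CHH": 0.001})
    groups = {"sexual": [], "clonal": []}
    rows = []
    wml_profiles = {}
    for label, fx in (("sexual", fx_hi), ("clonal", fx_lo)):
        for sid, rep in fx.reports.items():
            e = nonconversion_rate(rep)
            called = call_methylated(rep, e)
            nuclear = called[called["chrom"] == "chr1"]
            for ctx in ("CpG", "CHG", "CHH"):
                rows.append((label, sid, ctx, e, mc_proportion(nuclear, ctx),
                             weighted_ml(nuclear, context=ctx).wml))
            groups[label].append(weighted_ml(nuclear, context="CHH").wml)
            agg = nuclear.groupby(nuclear["pos"] // 3_000).apply(
                lambda d: d["count_methylated"].sum()
                / max((d["count_methylated"] + d["count_unmethylated"]).sum(), 1),
                include_groups=False,
            )
            wml_profiles[f"{label}_{sid}"] = agg
    tab = pd.DataFrame(rows, columns=["group", "sample", "context",
                                      "nonconversion", "mC", "wML"])
    tab.to_csv(os.path.join(args.out_dir, "methylation_summary.tsv"), sep="\t",
               index=False)
    print(tab.groupby(["group", "context"])[["mC", "wML"]].mean().round(4))

    tests = compare_population_wml(groups)
    print("CHH wML sexual vs clonal:",
          tests[["group1", "group2", "p_adjusted"]].to_string(index=False))

    ann = generate_annotation_fixture(20_000, 10, 3, seed=args.seed)
    feats = pd.DataFrame(
        [(g.chrom, g.start, g.end, g.strand) for g in ann.genes],
        columns=["chrom", "start", "end", "strand"],
    )
    rep = fx_hi.reports["meth_00"]
    called = call_methylated(rep, nonconversion_rate(rep))
    prof = metagene_profile(called, feats)
    prof.to_csv(os.path.join(args.out_dir, "metagene_profile.tsv"), sep="\t",
                index=False)

    mat = pd.DataFrame(wml_profiles).T.dropna(axis=1)
    z, coph, newick = methylome_clustering(mat)
    with open(os.path.join(args.out_dir, "methylome_dendrogram.nwk"), "w") as fh:
        fh.write(newick + "\n")
    # genetic-distance stand-in: within-group 0.1, between-group 1.0
    names = list(mat.index)
    gdist = np.array([[0.0 if a == b else (0.1 if a.split("_")[0] == b.split("_")[0]
                                           else 1.0) for b in names] for a in names])
    from scipy.spatial.distance import squareform

    r, p = tree_concordance(gdist, squareform(coph), n_perm=999, seed=args.seed)
    print(f"Mantel concordance of methylome vs genetic distance: r = {r:.2f}, "
          f"p = {p:.3f}")


if __name__ == "__main__":
    main()
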