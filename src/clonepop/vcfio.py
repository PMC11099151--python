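"""VCF reading/writing for the GenotypeMatrix model (cyvcf2-backed)."""

from __future__ import annotations

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import ParseError
from .genotypes import MISSING, GenotypeMatrix

_INFO_TAGS = ("QD", "SOR", "FS", "MQ", "MQRankSum", "ReadPosRankSum")


def read_vcf(path, populations: dict | None = None) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix.

    Dosages encode ALT-allele counts (any non-reference allele for
    multi-allelic records, which are flagged non-biallelic and removed later
    in the cascade).  Half-calls such as 0/. are treated as missing.
    """
    try:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
        chroms, poss, refs, alts, quals = [], [], [], [], []
        dosages = []
        infos = {t: [] for t in _INFO_TAGS}
        depths = []
        biallelic = []
        for ln, var in enumerate(vcf):
            chroms.append(var.CHROM)
            poss.append(var.POS)
            refs.append(var.REF)
            alts.append(",".join(var.ALT) if var.ALT else ".")
            quals.append(var.QUAL if var.QUAL is not None else np.nan)
            biallelic.append(len(var.ALT) == 1)
            row = np.empty(len(samples), dtype=np.int8)
            for i, g in enumerate(var.genotypes):
                alleles = g[:-1]
                if len(alleles) != 2 or any(a < 0 for a in alleles):
                    row[i] = MISSING
                else:
                    row[i] = int(alleles[0] > 0) + int(alleles[1] > 0)
            dosages.append(row)
            for t in _INFO_TAGS:
                v = var.INFO.get(t)
                infos[t].append(np.nan if v is None else float(v))
            dp = var.format("DP")
            if dp is not None:
                dp = dp.astype(float).ravel()
                dp[dp < 0] = np.nan
                depths.append(np.nanmean(dp) if np.isfinite(dp).any() else np.nan)
            else:
                v = var.INFO.get("DP")
                depths.append(float(v) / len(samples) if v is not None else np.nan)
    except ParseError:
        raise
    except Exception as exc:  # cyvcf2 raises plain Exceptions on malformed input
        raise ParseError(f"malformed VCF near record {len(poss) + 1} in {path}: {exc}") from exc

    n_sites = len(poss)
    dosage = (
        np.stack(dosages, axis=1) if n_sites else np.zeros((len(samples), 0), dtype=np.int8)
    )
    site_info = pd.DataFrame(
        {
            "QD": infos["QD"],
            "QUAL": quals,
            "SOR": infos["SOR"],
            "FS": infos["FS"],
            "MQ": infos["MQ"],
            "MQRankSum": infos["MQRankSum"],
            "ReadPosRankSum": infos["ReadPosRankSum"],
            "mean_depth": depths,
            "missingness": (dosage == MISSING).mean(axis=0) if n_sites else [],
            "is_organelle": np.zeros(n_sites, dtype=bool),
            "biallelic": biallelic,
        }
    )
    return GenotypeMatrix(
        sample_ids=samples,
        populations=dict(populations or {}),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        dosage=dosage,
        site_info=site_info,
    )


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a biallelic GenotypeMatrix back to VCF v4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(gm.chrom):
            ln = int(gm.pos[gm.chrom == c].max()) + 1000
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        for t in _INFO_TAGS:
            fh.write(f'##INFO=<ID={t},Number=1,Type=Float,Description="{t}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        si = gm.site_info
        for j in range(gm.n_sites):
            info = ";".join(
                f"{t}={si[t].iloc[j]:g}" for t in _INFO_TAGS if np.isfinite(si[t].iloc[j])
            )
            qual = si["QUAL"].iloc[j]
            qual_s = f"{qual:g}" if np.isfinite(qual) else "."
            gts = "\t".join(_GT[int(d)] for d in gm.dosage[:, j])
            fh.write(
                f"{gm.chrom[j]}\t{gm.pos[j]}\t.\t{gm.ref[j]}\t{gm.alt[j]}\t{qual_s}\t"
                f"PASS\t{info or '.'}\tGT\t{gts}\n"
            )
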