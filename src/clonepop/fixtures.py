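"""Self-describing test fixtures: VCFs with planted filter violations,
bisulfite cytosine reports with known methylation truth, and small annotated
genomes (FASTA + GFF3 + TE BED + gene families).

Every generator is a pure function of (parameters, seed) and returns the
ground truth alongside the files, so downstream filters and estimators can be
checked against exact planted counts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import Gene, revcomp, write_bed, write_fasta, write_gff3
from .errors import ConfigurationError, PlacementError
from .models import SimTruth

ORGANELLE_CONTIG = "chrM"
CONTROL_CONTIG = "chrC"

VCF_VIOLATION_CLASSES = (
    "QD", "QUAL", "SOR", "FS", "MQ", "MQRankSum", "ReadPosRankSum",
    "organelle", "missingness", "depth", "non_biallelic", "maf", "cluster",
    "clean",
)

_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


# ---------------------------------------------------------------------------
# VCF fixture with planted filter violations
# ---------------------------------------------------------------------------

def generate_vcf_fixture(
    path,
    counts: dict,
    seed: int = 0,
    n_samples: int = 60,
) -> SimTruth:
    """Write a VCF whose sites violate exactly the requested filter rules.

    counts maps a violation class (see VCF_VIOLATION_CLASSES; "clean" means
    no violation) to the number of sites to plant.  Each planted site
    violates its own rule and passes every other rule, so an ordered filter
    cascade must attribute exactly these counts.  n_samples >= 51 is required
    so that a singleton heterozygote sits below the 1% MAF threshold.
    """
    unknown = set(counts) - set(VCF_VIOLATION_CLASSES)
    if unknown:
        raise ConfigurationError(f"unknown violation classes: {sorted(unknown)}")
    if any(v < 0 for v in counts.values()):
        raise ConfigurationError("planted counts must be non-negative")
    if counts.get("cluster", 0) in (1, 2):
        raise ConfigurationError("cluster violations need at least 3 SNPs")
    if n_samples < 51:
        raise ConfigurationError("need >= 51 samples for sub-1% MAF singletons")

    rng = np.random.default_rng(seed)
    sample_names = [f"S{i:03d}" for i in range(n_samples)]
    nucs = "ACGT"

    def base_info():
        return {
            "QD": 25.0, "SOR": 1.0, "FS": 2.0, "MQ": 60.0,
            "MQRankSum": 0.0, "ReadPosRankSum": 0.0,
        }

    records = []   # (chrom, pos, ref, alts, qual, info dict, genotypes, dp per sample)

    def default_gts(n_alt_carriers=6):
        gts = ["0/0"] * n_samples
        carriers = rng.choice(n_samples, size=n_alt_carriers, replace=False)
        for c in carriers:
            gts[c] = "0/1"
        return gts

    pos_nuclear = 1000
    pos_organelle = 500

    def next_nuclear(step=50):
        nonlocal pos_nuclear
        pos_nuclear += step
        return pos_nuclear

    for cls in VCF_VIOLATION_CLASSES:
        k = counts.get(cls, 0)
        if cls == "cluster":
            remaining = k
            while remaining >= 3:
                group = remaining if remaining <= 5 else 3
                start = next_nuclear(200)
                for j in range(group):
                    records.append(_record(rng, "chr1", start + 2 * j, base_info(),
                                           default_gts(), 900.0, nucs))
                pos_nuclear = start + 2 * group
                remaining -= group
            continue
        for _ in range(k):
            info = base_info()
            qual = 900.0
            chrom = "chr1"
            gts = default_gts()
            dp = np.full(n_samples, 25)
            alts = None
            if cls == "QD":
                info["QD"] = 1.0
            elif cls == "QUAL":
                qual = 20.0
            elif cls == "SOR":
                info["SOR"] = 4.0
            elif cls == "FS":
                info["FS"] = 70.0
            elif cls == "MQ":
                info["MQ"] = 30.0
            elif cls == "MQRankSum":
                info["MQRankSum"] = -13.0
            elif cls == "ReadPosRankSum":
                info["ReadPosRankSum"] = -9.0
            elif cls == "organelle":
                chrom = ORGANELLE_CONTIG
            elif cls == "missingness":
                miss = rng.choice(n_samples, size=int(0.3 * n_samples), replace=False)
                for mi in miss:
                    gts[mi] = "./."
                # keep at least 2 alt carriers among called samples (MAF safe)
                called = [i for i in range(n_samples) if gts[i] != "./."]
                for c in called[:2]:
                    gts[c] = "0/1"
            elif cls == "depth":
                dp = np.full(n_samples, 5 if rng.random() < 0.5 else 45)
            elif cls == "non_biallelic":
                alts = True
            elif cls == "maf":
                gts = default_gts(n_alt_carriers=1)
            pos = pos_organelle if chrom == ORGANELLE_CONTIG else next_nuclear()
            if chrom == ORGANELLE_CONTIG:
                pos_organelle += 100
            records.append(_record(rng, chrom, pos, info, gts, qual, nucs,
                                   dp=dp, multi=alts))

    records.sort(key=lambda r: (r[0], r[1]))
    max_pos = max((r[1] for r in records), default=1000) + 1000
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=chr1,length={max_pos}>\n")
        fh.write(f"##contig=<ID={ORGANELLE_CONTIG},length={max_pos}>\n")
        for tag in ("QD", "SOR", "FS", "MQ", "MQRankSum", "ReadPosRankSum"):
            fh.write(f'##INFO=<ID={tag},Number=1,Type=Float,Description="{tag}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names) + "\n")
        for chrom, pos, ref, alt, qual, info, gts, dp in records:
            info_s = ";".join(f"{k}={v:g}" for k, v in info.items())
            cols = [f"{g}:{d}" for g, d in zip(gts, dp)]
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual:g}\tPASS\t{info_s}\tGT:DP\t"
                     + "\t".join(cols) + "\n")

    truth = SimTruth(model=None, seed=seed, planted_filter_counts=dict(counts))
    return truth


def _record(rng, chrom, pos, info, gts, qual, nucs, dp=None, multi=None):
    ref = nucs[rng.integers(4)]
    others = [b for b in nucs if b != ref]
    if multi:
        a1, a2 = rng.choice(others, size=2, replace=False)
        alt = f"{a1},{a2}"
        gts = list(gts)
        carriers = rng.choice(len(gts), size=6, replace=False)
        for i, c in enumerate(carriers):
            gts[c] = "0/1" if i < 3 else "0/2"
    else:
        alt = others[rng.integers(3)]
    if dp is None:
        dp = np.full(len(gts), 25)
    return (chrom, pos, ref, alt, qual, info, gts, dp)


# ---------------------------------------------------------------------------
# Bisulfite cytosine-report fixture
# ---------------------------------------------------------------------------

CONTEXTS = ("CpG", "CHG", "CHH")


@dataclass
class MethylomeFixture:
    reports: dict                    # sample id -> cytosine-report DataFrame
    site_truth: pd.DataFrame         # chrom, pos, strand, context, methylated
    nonconv: float
    target_wml: dict
    mc_proportion: dict
    paths: dict = field(default_factory=dict)


def _cytosines_of(seq: str, chrom: str) -> pd.DataFrame:
    rows = []
    n = len(seq)
    for i in range(n - 2):
        if seq[i] == "C":
            tri = seq[i : i + 3]
            ctx = "CpG" if tri[1] == "G" else ("CHG" if tri[2] == "G" else "CHH")
            rows.append((chrom, i + 1, "+", ctx, tri))
        if seq[i + 2] == "G" and i + 2 >= 2:
            j = i + 2
            tri = revcomp(seq[j - 2 : j + 1])
            ctx = "CpG" if tri[1] == "G" else ("CHG" if tri[2] == "G" else "CHH")
            rows.append((chrom, j + 1, "-", ctx, tri))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "trinucleotide"])


def generate_methylome_fixture(
    n_samples: int = 4,
    target_wml: dict | None = None,
    nonconv: float = 0.005,
    seed: int = 0,
    mc_proportion: dict | None = None,
    L_nuclear: int = 30_000,
    L_control: int = 8_000,
    mean_coverage: float = 20.0,
    outdir=None,
) -> MethylomeFixture:
    """Per-sample cytosine reports with known methylation truth.

    A random genome is generated; each cytosine (strand-resolved) is truly
    methylated with probability mc_proportion[context].  Methylated-read
    counts are Binomial(coverage, target_wml[context]) at methylated sites
    and Binomial(coverage, nonconv) at unmethylated sites (bisulfite
    non-conversion noise).  The control contig (chloroplast stand-in) carries
    zero true methylation.
    """
    if not (0.0 <= nonconv < 0.1):
        raise ConfigurationError("nonconv must lie in [0, 0.1)")
    target_wml = dict(target_wml or {"CpG": 0.8, "CHG": 0.7, "CHH": 0.4})
    mc_proportion = dict(mc_proportion or {"CpG": 0.076, "CHG": 0.023, "CHH": 0.001})
    for ctx, v in target_wml.items():
        if not 0.0 <= v <= 1.0:
            raise ConfigurationError(f"target wML for {ctx} outside [0, 1]")

    rng = np.random.default_rng(seed)
    seq_nuc = "".join(rng.choice(list("ACGT"), size=L_nuclear))
    seq_ctl = "".join(rng.choice(list("ACGT"), size=L_control))
    cyt = pd.concat(
        [_cytosines_of(seq_nuc, "chr1"), _cytosines_of(seq_ctl, CONTROL_CONTIG)],
        ignore_index=True,
    )
    p_meth = cyt["context"].map(mc_proportion).to_numpy()
    p_meth[cyt["chrom"].to_numpy() == CONTROL_CONTIG] = 0.0
    methylated = rng.random(len(cyt)) < p_meth
    cyt["methylated"] = methylated

    rate = np.where(methylated, cyt["context"].map(target_wml).to_numpy(), nonconv)
    reports = {}
    paths = {}
    for s in range(n_samples):
        cov = rng.poisson(mean_coverage, size=len(cyt))
        m = rng.binomial(cov, rate)
        rep = cyt[["chrom", "pos", "strand"]].copy()
        rep["count_methylated"] = m
        rep["count_unmethylated"] = cov - m
        rep["context"] = cyt["context"]
        rep["trinucleotide"] = cyt["trinucleotide"]
        sid = f"meth_{s:02d}"
        reports[sid] = rep
        if outdir is not None:
            p = os.path.join(str(outdir), f"{sid}.CX_report.txt")
            rep.to_csv(p, sep="\t", header=False, index=False)
            paths[sid] = p
    return MethylomeFixture(
        reports=reports,
        site_truth=cyt,
        nonconv=nonconv,
        target_wml=target_wml,
        mc_proportion=mc_proportion,
        paths=paths,
    )


def read_cytosine_report(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "pos", "strand", "count_methylated", "count_unmethylated",
               "context", "trinucleotide"],
    )
    return df


# ---------------------------------------------------------------------------
# Annotated-genome fixture
# ---------------------------------------------------------------------------

@dataclass
class AnnotationFixture:
    sequence: dict                  # chrom -> str
    genes: list                     # Gene records
    te_intervals: pd.DataFrame      # chrom, start, end, name (0-based half-open)
    families: pd.DataFrame          # gene_id, family
    paths: dict = field(default_factory=dict)


def generate_annotation_fixture(
    L: int,
    n_genes: int,
    n_families: int,
    seed: int = 0,
    chrom: str = "chr1",
    outdir=None,
    two_exon_fraction: float = 0.5,
) -> AnnotationFixture:
    """Random genome with non-overlapping protein-coding genes, TEs disjoint
    from CDS, and a one-family-per-gene table."""
    if n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list("ACGT"), size=L))

    genes = []
    cursor = 100
    for gi in range(n_genes):
        n_codons = int(rng.integers(30, 80))
        cds_seq = "ATG" + "".join(rng.choice(_CODONS, size=n_codons - 2)) + "TAA"
        two_exon = rng.random() < two_exon_fraction and n_codons > 10
        strand = "+" if rng.random() < 0.5 else "-"
        intron = int(rng.integers(60, 150)) if two_exon else 0
        glen = len(cds_seq) + intron
        gap = int(rng.integers(150, 400))
        start = cursor + gap
        if start + glen + 100 > L:
            raise PlacementError(
                f"cannot place gene {gi + 1}/{n_genes} without overlap in {L} bp"
            )
        cursor = start + glen
        if two_exon:
            l1 = 3 * int(rng.integers(3, n_codons - 3)) + int(rng.integers(0, 3))
            segs = [(start, start + l1), (start + l1 + intron, start + glen)]
        else:
            segs = [(start, start + glen)]
        placed = cds_seq if strand == "+" else revcomp(cds_seq)
        # genomic order of coding pieces follows strand orientation
        lens = [e - s for s, e in segs]
        if strand == "+":
            pieces, off = [], 0
            for ln in lens:
                pieces.append(placed[off : off + ln])
                off += ln
        else:
            pieces, off = [], 0
            for ln in lens:
                pieces.append(placed[off : off + ln])
                off += ln
        for (s, e), piece in zip(segs, pieces):
            seq[s:e] = list(piece)
        # GFF phase: bases to trim from segment start to hit a codon boundary
        cds = []
        consumed = 0
        order = segs if strand == "+" else list(reversed(segs))
        phases = {}
        for s, e in order:
            phases[(s, e)] = (3 - consumed % 3) % 3 if consumed % 3 else 0
            consumed += e - s
        for s, e in segs:
            cds.append((s, e, phases[(s, e)]))
        genes.append(
            Gene(
                gene_id=f"gene{gi + 1:04d}", chrom=chrom,
                start=segs[0][0], end=segs[-1][1], strand=strand, cds=cds,
            )
        )

    # TEs in the gaps between genes, disjoint from CDS
    te_rows = []
    blocked = sorted((g.start, g.end) for g in genes)
    prev = 0
    ti = 0
    for s, e in blocked + [(L, L)]:
        gap_lo, gap_hi = prev + 10, s - 10
        if gap_hi - gap_lo > 120:
            te_len = int(rng.integers(50, min(400, gap_hi - gap_lo - 10)))
            te_start = int(rng.integers(gap_lo, gap_hi - te_len))
            te_rows.append((chrom, te_start, te_start + te_len, f"TE{ti + 1:04d}"))
            ti += 1
        prev = e
    te = pd.DataFrame(te_rows, columns=["chrom", "start", "end", "name"])

    fam = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "family": [f"fam{int(rng.integers(n_families)) + 1:03d}" for _ in genes],
        }
    )

    sequences = {chrom: "".join(seq)}
    paths = {}
    if outdir is not None:
        outdir = str(outdir)
        paths = {
            "fasta": os.path.join(outdir, "genome.fa"),
            "gff": os.path.join(outdir, "genes.gff3"),
            "te_bed": os.path.join(outdir, "te.bed"),
            "families": os.path.join(outdir, "families.tsv"),
        }
        write_fasta(paths["fasta"], sequences)
        write_gff3(paths["gff"], genes)
        write_bed(paths["te_bed"], te)
        fam.to_csv(paths["families"], sep="\t", index=False)
    return AnnotationFixture(
        sequence=sequences, genes=genes, te_intervals=te, families=fam, paths=paths
    )
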