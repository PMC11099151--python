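"""Gene-annotation I/O: GFF3 genes with CDS, FASTA access, BED intervals.

Coordinates: GFF3 and FASTA positions are 1-based inclusive on disk; BED is
0-based half-open; the in-memory Gene/Interval model is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
from pyfaidx import Fasta


@dataclass
class Gene:
    gene_id: str
    chrom: str
    start: int          # 0-based half-open
    end: int
    strand: str
    cds: list = field(default_factory=list)   # sorted (start, end, phase), 0-based half-open

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e, _ in self.cds)


def read_gff3(path) -> list:
    """Parse GFF3 into Gene records (gene + child CDS features)."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        cds = []
        for c in db.children(g, featuretype="CDS"):
            phase = int(c.frame) if c.frame not in (None, ".") else 0
            cds.append((c.start - 1, c.end, phase))
        cds.sort()
        genes.append(
            Gene(
                gene_id=g.id,
                chrom=g.seqid,
                start=g.start - 1,
                end=g.end,
                strand=g.strand,
                cds=cds,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_gff3(path, genes: list) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\tclonepop\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tclonepop\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for i, (s, e, phase) in enumerate(g.cds):
                fh.write(
                    f"{g.chrom}\tclonepop\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t{phase}\t"
                    f"ID={mrna}.cds{i};Parent={mrna}\n"
                )


def write_fasta(path, sequences: dict, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def open_fasta(path) -> Fasta:
    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


def read_bed(path) -> pd.DataFrame:
    """BED into a frame with columns chrom, start, end[, name] (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_bed(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def cds_spliced_sequence(gene: Gene, fasta) -> str:
    """Spliced CDS in coding (5'->3') orientation."""
    parts = [str(fasta[gene.chrom][s:e]) for s, e, _ in gene.cds]
    seq = "".join(parts)
    if gene.strand == "-":
        seq = revcomp(seq)
    return seq


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def genome_position_to_cds_index(gene: Gene, pos0: int):
    """Map a 0-based genomic position to its index in the spliced CDS, or None."""
    off = 0
    segs = gene.cds if gene.strand == "+" else list(reversed(gene.cds))
    for s, e, _ in segs:
        if s <= pos0 < e:
            within = (pos0 - s) if gene.strand == "+" else (e - 1 - pos0)
            return off + within
        off += e - s
    return None
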