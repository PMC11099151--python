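"""Coding-effect classification of SNPs and Nei–Gojobori site counting.

Effects are assigned per biallelic SNP against an annotated genome: a SNP in
an annotated CDS is synonymous iff substituting the ALT base leaves the
translated amino acid unchanged (standard genetic code, strand-aware).
"""

from __future__ import annotations

import warnings

import numpy as np
from Bio.Seq import Seq

from .annotation import Gene, cds_spliced_sequence, genome_position_to_cds_index, revcomp
from .genotypes import GenotypeMatrix

EFFECT_CLASSES = ("synonymous", "nonsynonymous", "intergenic", "intronic", "other")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def classify_coding_effect(gm: GenotypeMatrix, genes: list, fasta) -> np.ndarray:
    """Effect class per site ('fasta' is any mapping chrom -> sequence-like).

    Genes whose spliced CDS length is not a multiple of 3 are skipped with a
    warning; their sites fall back to 'other'.
    """
    effects = np.full(gm.n_sites, "intergenic", dtype=object)
    by_chrom: dict = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    cds_cache = {}
    for j in range(gm.n_sites):
        chrom, p0 = gm.chrom[j], int(gm.pos[j]) - 1
        hits = [g for g in by_chrom.get(chrom, []) if g.start <= p0 < g.end]
        if not hits:
            continue
        label = "intronic"
        for g in hits:
            ci = genome_position_to_cds_index(g, p0)
            if ci is None:
                continue
            if g.gene_id not in cds_cache:
                seq = cds_spliced_sequence(g, fasta)
                if len(seq) % 3 != 0:
                    warnings.warn(f"CDS length of {g.gene_id} not divisible by 3; skipped")
                    cds_cache[g.gene_id] = None
                else:
                    cds_cache[g.gene_id] = seq
            seq = cds_cache[g.gene_id]
            if seq is None:
                label = "other"
                continue
            codon_i, within = divmod(ci, 3)
            codon = seq[3 * codon_i : 3 * codon_i + 3]
            ref_b, alt_b = gm.ref[j], gm.alt[j]
            if g.strand == "-":
                ref_b = _COMP.get(ref_b, "N")
                alt_b = _COMP.get(alt_b, "N")
            if "N" in codon or codon[within] != ref_b or len(alt_b) != 1 or alt_b == "N":
                label = "other"
                continue
            alt_codon = codon[:within] + alt_b + codon[within + 1 :]
            label = (
                "synonymous" if _translate(codon) == _translate(alt_codon)
                else "nonsynonymous"
            )
            break
        effects[j] = label
    return effects


def count_ns_sites(cds_sequence: str):
    """Nei–Gojobori counts of nonsynonymous and synonymous sites.

    Each codon position contributes the fraction of its 3 possible point
    changes that are synonymous to S and the complement to N, so
    N + S equals the sequence length exactly.  Codons containing ambiguous
    bases are skipped with a warning.
    """
    seq = cds_sequence.upper()
    if len(seq) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    n_sites = 0.0
    s_sites = 0.0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if any(b not in "ACGT" for b in codon):
            warnings.warn(f"ambiguous codon {codon!r} at {i}; skipped")
            continue
        aa = _translate(codon)
        for pos in range(3):
            syn = 0
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1 :]
                if _translate(alt) == aa:
                    syn += 1
            s_sites += syn / 3.0
            n_sites += (3 - syn) / 3.0
    return n_sites, s_sites
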