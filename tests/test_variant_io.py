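"""VCF round trip, the hard-filter clauses, the ordered cascade, SNP-cluster
windows, and coding-effect classification."""

import numpy as np
import pandas as pd
import pytest

from clonepop.annotation import Gene, read_gff3, revcomp
from clonepop.effects import classify_coding_effect, count_ns_sites
from clonepop.filters import (
    CascadeConfig,
    filter_cascade,
    hard_filter_sites,
    snp_cluster_filter,
)
from clonepop.fixtures import generate_annotation_fixture, generate_vcf_fixture
from clonepop.genotypes import MISSING, GenotypeMatrix, clean_site_info
from clonepop.vcfio import read_vcf

PLANTED = {
    "QD": 5, "QUAL": 3, "SOR": 2, "FS": 2, "MQ": 2, "MQRankSum": 2,
    "ReadPosRankSum": 2, "organelle": 4, "missingness": 3, "depth": 6,
    "non_biallelic": 3, "maf": 4, "cluster": 7, "clean": 30,
}


@pytest.fixture(scope="module")
def fixture_vcf(tmp_path_factory):
    path = tmp_path_factory.mktemp("vcf") / "planted.vcf"
    truth = generate_vcf_fixture(path, PLANTED, seed=7)
    return path, truth


def test_read_vcf_encodings_and_round_trip(fixture_vcf):
    path, _ = fixture_vcf
    gm = read_vcf(path)
    assert gm.n_sites == sum(PLANTED.values())
    assert set(np.unique(gm.dosage)) <= {-1, 0, 1, 2}
    # het carriers on clean sites are dosage 1; missing preserved
    miss_sites = gm.site_info["missingness"] > 0.2
    assert miss_sites.sum() == PLANTED["missingness"]


def test_hard_filter_counts_match_planted(fixture_vcf):
    path, truth = fixture_vcf
    gm = read_vcf(path)
    kept, counts = hard_filter_sites(gm)
    for clause in ("QD", "QUAL", "SOR", "FS", "MQ", "MQRankSum", "ReadPosRankSum"):
        assert counts[clause] == truth.planted_filter_counts[clause]
    assert kept.n_sites == gm.n_sites - sum(counts.values())


def test_hard_filter_boundary_values_retained():
    si = clean_site_info(1)
    si.loc[0, ["QD", "QUAL", "SOR", "FS", "MQ", "MQRankSum", "ReadPosRankSum"]] = [
        2.0, 30.0, 3.0, 60.0, 40.0, -12.5, -8.0,
    ]
    gm = GenotypeMatrix(
        sample_ids=["a", "b"], populations={},
        chrom=np.array(["chr1"], dtype=object), pos=np.array([5]),
        ref=np.array(["A"], dtype=object), alt=np.array(["C"], dtype=object),
        dosage=np.array([[1], [0]], dtype=np.int8), site_info=si,
    )
    kept, counts = hard_filter_sites(gm)
    assert kept.n_sites == 1 and sum(counts.values()) == 0


def test_cascade_counts_match_planted_and_idempotent(fixture_vcf):
    path, truth = fixture_vcf
    gm, _ = hard_filter_sites(read_vcf(path))
    cfg = CascadeConfig(organelle_contigs=("chrM",))
    kept, report = filter_cascade(gm, cfg)
    got = dict(zip(report["rule"], report["removed"]))
    assert got["organelle"] == truth.planted_filter_counts["organelle"]
    assert got["missingness"] == truth.planted_filter_counts["missingness"]
    assert got["depth"] == truth.planted_filter_counts["depth"]
    assert got["non_biallelic"] == truth.planted_filter_counts["non_biallelic"]
    assert got["maf"] == truth.planted_filter_counts["maf"]
    assert got["cluster"] == truth.planted_filter_counts["cluster"]
    assert got["surviving"] == truth.planted_filter_counts["clean"]
    # attribution partition: per-rule counts sum to removed total
    removed = sum(v for k, v in got.items() if k != "surviving")
    assert removed == gm.n_sites - kept.n_sites
    # idempotence
    again, report2 = filter_cascade(kept, cfg)
    assert again.n_sites == kept.n_sites
    assert (report2["removed"][:-1] == 0).all()


def test_cascade_order_attributes_first_rule():
    """A site on an organelle contig that also fails MAF goes to the
    organelle rule."""
    si = clean_site_info(2)
    gm = GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(60)], populations={},
        chrom=np.array(["chrM", "chr1"], dtype=object), pos=np.array([100, 200]),
        ref=np.array(["A", "A"], dtype=object), alt=np.array(["C", "C"], dtype=object),
        dosage=np.vstack(
            [np.array([1, 1], dtype=np.int8)] + [np.zeros(2, dtype=np.int8)] * 59
        ),
        site_info=si,
    )
    _, report = filter_cascade(gm, CascadeConfig(organelle_contigs=("chrM",)))
    got = dict(zip(report["rule"], report["removed"]))
    assert got["organelle"] == 1 and got["maf"] == 1


def test_cascade_maf_boundary_exact_one_percent_retained():
    gm = GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(50)], populations={},
        chrom=np.array(["chr1"], dtype=object), pos=np.array([100]),
        ref=np.array(["A"], dtype=object), alt=np.array(["C"], dtype=object),
        dosage=np.array([[1]] + [[0]] * 49, dtype=np.int8),  # 1/100 alleles = 1%
        site_info=clean_site_info(1),
    )
    kept, _ = filter_cascade(gm)
    assert kept.n_sites == 1


def test_unknown_cascade_rule_rejected():
    from clonepop.errors import ConfigurationError

    with pytest.raises(ConfigurationError, match="unknown cascade rule"):
        CascadeConfig.from_dict({"bogus_rule": 1})


@pytest.mark.parametrize(
    "positions,k,w,removed",
    [
        ([100, 105, 109], 3, 10, [100, 105, 109]),
        ([100, 105, 120], 3, 10, []),
        ([100, 105, 110], 3, 10, []),  # inclusive span 11 > 10
    ],
)
def test_snp_cluster_examples(positions, k, w, removed):
    keep = snp_cluster_filter(positions, k, w)
    assert [p for p, kp in zip(positions, keep) if not kp] == removed


def test_snp_cluster_relaxed_rule_200_per_kb(rng):
    pos = np.sort(rng.choice(np.arange(5000, 5999), size=200, replace=False))
    assert not snp_cluster_filter(pos, 200, 1000).any()
    assert snp_cluster_filter(pos[:199], 200, 1000).all()


def test_snp_cluster_matches_window_enumeration(rng):
    """Quadratic oracle: a SNP is removed iff some w-bp window holds >= k."""
    for _ in range(25):
        pos = np.sort(rng.choice(2000, size=rng.integers(5, 60), replace=False))
        k, w = int(rng.integers(2, 5)), int(rng.integers(5, 40))
        keep = snp_cluster_filter(pos, k, w)
        condemned = np.zeros(pos.size, dtype=bool)
        for i in range(pos.size):
            for j in range(i + k - 1, pos.size):
                if pos[j] - pos[i] + 1 <= w and j - i + 1 >= k:
                    condemned[(pos >= pos[i]) & (pos <= pos[j])] = True
        assert np.array_equal(~keep, condemned)


# ---------------------------------------------------------------------------
# Coding-effect classification
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def annotated(tmp_path_factory):
    td = tmp_path_factory.mktemp("ann")
    return generate_annotation_fixture(40_000, 15, 4, seed=13, outdir=td)


def _snp_matrix(chrom, positions, refs, alts):
    n = len(positions)
    return GenotypeMatrix(
        sample_ids=["a", "b"], populations={},
        chrom=np.array([chrom] * n, dtype=object), pos=np.array(positions),
        ref=np.array(refs, dtype=object), alt=np.array(alts, dtype=object),
        dosage=np.ones((2, n), dtype=np.int8),
    )


def test_effect_classification_genetic_code_examples():
    gene = Gene("g1", "chr1", 0, 6, "+", cds=[(0, 6, 0)])
    fasta = {"chr1": "ATGTTT"}
    gm = _snp_matrix("chr1", [3, 6], ["G", "T"], ["A", "C"])
    eff = classify_coding_effect(gm, [gene], fasta)
    assert list(eff) == ["nonsynonymous", "synonymous"]  # ATG->ATA (M->I), TTT->TTC (F->F)


def test_effect_classification_matches_translation_oracle(annotated):
    """Every CDS position of a random fixture gene, all 3 alternates,
    checked against direct codon translation."""
    from Bio.Seq import Seq

    fx = annotated
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    checked = 0
    for gene in fx.genes[:6]:
        spliced = []
        for s, e, _ in gene.cds:
            spliced.append((s, e))
        cds_seq = "".join(fx.sequence[gene.chrom][s:e] for s, e in spliced)
        if gene.strand == "-":
            cds_seq = revcomp(cds_seq)
        genome_positions = [
            p for s, e in spliced for p in range(s, e)
        ]
        if gene.strand == "-":
            genome_positions = genome_positions[::-1]
        for ci in range(0, len(cds_seq), 7):  # sample positions for speed
            p0 = genome_positions[ci]
            ref_g = fx.sequence[gene.chrom][p0]
            alt_g = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref_g]
            gm = _snp_matrix(gene.chrom, [p0 + 1], [ref_g], [alt_g])
            eff = classify_coding_effect(gm, [gene], fx.sequence)[0]
            codon_i, within = divmod(ci, 3)
            codon = cds_seq[3 * codon_i : 3 * codon_i + 3]
            alt_b = alt_g if gene.strand == "+" else comp[alt_g]
            alt_codon = codon[:within] + alt_b + codon[within + 1 :]
            expect = (
                "synonymous"
                if str(Seq(codon).translate()) == str(Seq(alt_codon).translate())
                else "nonsynonymous"
            )
            assert eff == expect
            checked += 1
    assert checked > 50


def test_effect_classes_outside_cds(annotated):
    fx = annotated
    g = next(g for g in fx.genes if len(g.cds) == 2)
    intron_pos = g.cds[0][1] + 1  # inside the intron, 0-based
    gm = _snp_matrix(
        g.chrom, [5, intron_pos + 1],
        ["A", fx.sequence[g.chrom][intron_pos]], ["C", "C"],
    )
    eff = classify_coding_effect(gm, fx.genes, fx.sequence)
    assert eff[0] == "intergenic"
    assert eff[1] == "intronic"


def test_gff_round_trip_preserves_intervals(annotated, tmp_path):
    fx = annotated
    genes = read_gff3(fx.paths["gff"])
    mine = sorted(fx.genes, key=lambda g: (g.chrom, g.start))
    assert len(genes) == len(mine)
    for a, b in zip(mine, genes):
        assert (a.gene_id, a.chrom, a.start, a.end, a.strand) == (
            b.gene_id, b.chrom, b.start, b.end, b.strand,
        )
        assert [(s, e) for s, e, _ in a.cds] == [(s, e) for s, e, _ in b.cds]


def test_count_ns_sites_reexported_from_diversity():
    from clonepop.diversity import count_ns_sites as cns

    assert cns is count_ns_sites
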