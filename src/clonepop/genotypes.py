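"""The GenotypeMatrix container: samples × biallelic sites with dosages.

Dosages count ALT alleles per diploid genotype: 0, 1, 2, or -1 for missing.
Sites are kept sorted by (chrom, pos) with pos 1-based as read from VCF;
internal interval arithmetic elsewhere is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

ANNOTATION_COLUMNS = [
    "QD", "QUAL", "SOR", "FS", "MQ", "MQRankSum", "ReadPosRankSum",
    "mean_depth", "missingness", "is_organelle", "biallelic",
]


def clean_site_info(n: int) -> pd.DataFrame:
    """Annotation frame for n sites that passes every hard filter."""
    return pd.DataFrame(
        {
            "QD": np.full(n, 25.0),
            "QUAL": np.full(n, 900.0),
            "SOR": np.full(n, 1.0),
            "FS": np.full(n, 2.0),
            "MQ": np.full(n, 60.0),
            "MQRankSum": np.zeros(n),
            "ReadPosRankSum": np.zeros(n),
            "mean_depth": np.full(n, 25.0),
            "missingness": np.zeros(n),
            "is_organelle": np.zeros(n, dtype=bool),
            "biallelic": np.ones(n, dtype=bool),
        }
    )


@dataclass
class GenotypeMatrix:
    sample_ids: list
    populations: dict                 # sample id -> population label
    chrom: np.ndarray                 # per-site chromosome name
    pos: np.ndarray                   # per-site 1-based position
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray                # (n_samples, n_sites) int8, -1 missing
    site_info: pd.DataFrame = None
    ancestral: np.ndarray = None      # per-site ancestral allele or "" if unpolarized

    def __post_init__(self):
        if self.site_info is None:
            self.site_info = clean_site_info(self.n_sites)
        if self.dosage.shape != (self.n_samples, self.n_sites):
            raise ValueError("dosage dimensions must be n_samples x n_sites")
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(self.n_sites)):
            self._reorder(order)

    def _reorder(self, order):
        self.chrom = self.chrom[order]
        self.pos = self.pos[order]
        self.ref = self.ref[order]
        self.alt = self.alt[order]
        self.dosage = self.dosage[:, order]
        self.site_info = self.site_info.iloc[order].reset_index(drop=True)
        if self.ancestral is not None:
            self.ancestral = self.ancestral[order]

    # -- basic shape --------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def samples_in(self, pop: str) -> list:
        return [s for s in self.sample_ids if self.populations.get(s) == pop]

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([lookup[s] for s in ids], dtype=int)

    # -- subsetting ---------------------------------------------------------

    def take_sites(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            populations=dict(self.populations),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            dosage=self.dosage[:, idx],
            site_info=self.site_info.iloc[idx].reset_index(drop=True),
            ancestral=None if self.ancestral is None else self.ancestral[idx],
        )

    def take_samples(self, ids) -> "GenotypeMatrix":
        idx = self.sample_index(ids)
        gm = GenotypeMatrix(
            sample_ids=list(ids),
            populations={s: self.populations.get(s) for s in ids},
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            dosage=self.dosage[idx, :].copy(),
            site_info=self.site_info.copy().reset_index(drop=True),
            ancestral=None if self.ancestral is None else self.ancestral.copy(),
        )
        gm.refresh_missingness()
        return gm

    # -- per-site summaries --------------------------------------------------

    def called(self) -> np.ndarray:
        return self.dosage != MISSING

    def alt_counts(self, sample_idx=None) -> np.ndarray:
        d = self.dosage if sample_idx is None else self.dosage[sample_idx]
        return np.where(d == MISSING, 0, d).sum(axis=0)

    def called_alleles(self, sample_idx=None) -> np.ndarray:
        d = self.dosage if sample_idx is None else self.dosage[sample_idx]
        return 2 * (d != MISSING).sum(axis=0)

    def alt_freq(self, sample_idx=None) -> np.ndarray:
        n = self.called_alleles(sample_idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, self.alt_counts(sample_idx) / n, np.nan)

    def maf(self) -> np.ndarray:
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)

    def refresh_missingness(self) -> None:
        self.site_info["missingness"] = 1.0 - self.called().mean(axis=0)

    # -- polarization --------------------------------------------------------

    def derived_counts(self) -> tuple:
        """(derived allele count, called alleles) per site; needs ancestral."""
        if self.ancestral is None:
            raise ValueError("matrix is not polarized")
        anc_is_ref = self.ancestral == self.ref
        k = self.alt_counts()
        n = self.called_alleles()
        return np.where(anc_is_ref, k, n - k), n

    def polarized_mask(self) -> np.ndarray:
        if self.ancestral is None:
            return np.zeros(self.n_sites, dtype=bool)
        return self.ancestral != ""


def allele_freq_by_group(gm: GenotypeMatrix, site: int, grouping: dict) -> dict:
    """ALT-allele frequency per group at one site (index into gm's sites).

    grouping maps group label -> list of sample ids.  Groups with no called
    genotypes get None (undefined), mirroring how a monomorphic-for-missing
    group cannot contribute a frequency.
    """
    out = {}
    for group, ids in grouping.items():
        idx = gm.sample_index(ids)   # raises KeyError for unknown samples
        d = gm.dosage[idx, site]
        called = d != MISSING
        if called.sum() == 0:
            out[group] = None
        else:
            out[group] = float(d[called].sum() / (2.0 * called.sum()))
    return out


def polarize_alleles(gm: GenotypeMatrix, outgroup_alleles: dict) -> GenotypeMatrix:
    """Set ancestral states from outgroup alleles keyed by (chrom, pos).

    The outgroup allele becomes the ancestral state when it matches either
    REF or ALT; otherwise (or when absent) the site is flagged unpolarized
    (ancestral "") and remains usable only by folded statistics.
    """
    anc = np.full(gm.n_sites, "", dtype=object)
    for i in range(gm.n_sites):
        og = outgroup_alleles.get((gm.chrom[i], int(gm.pos[i])))
        if og is not None and og in (gm.ref[i], gm.alt[i]):
            anc[i] = og
    out = gm.take_sites(np.arange(gm.n_sites))
    out.ancestral = anc
    return out
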