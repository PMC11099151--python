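"""Site-filter cascade for population VCFs.

Two stages mirror common GATK practice for non-model plants: per-site hard
filters on variant-call annotations, then an ordered cascade of population
filters.  The cascade applies its rules in a fixed order and attributes each
removed site to the FIRST rule that fires, so per-rule counts partition the
removed sites exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .genotypes import GenotypeMatrix

# clause name -> (annotation column, direction, threshold); strict inequalities
HARD_FILTER_CLAUSES = {
    "QD": ("QD", "lt", 2.0),
    "QUAL": ("QUAL", "lt", 30.0),
    "SOR": ("SOR", "gt", 3.0),
    "FS": ("FS", "gt", 60.0),
    "MQ": ("MQ", "lt", 40.0),
    "MQRankSum": ("MQRankSum", "lt", -12.5),
    "ReadPosRankSum": ("ReadPosRankSum", "lt", -8.0),
}


def hard_filter_sites(gm: GenotypeMatrix, thresholds: dict | None = None):
    """Remove sites failing ANY hard-filter clause; report per-clause counts.

    A missing (NaN) annotation never triggers its clause.  A site failing
    several clauses is counted once per clause, so counts can exceed the
    number of removed sites.
    """
    clauses = dict(HARD_FILTER_CLAUSES)
    if thresholds:
        for name, thr in thresholds.items():
            if name not in clauses:
                raise ConfigurationError(f"unknown hard-filter clause {name!r}")
            col, op, _ = clauses[name]
            clauses[name] = (col, op, thr)
    remove = np.zeros(gm.n_sites, dtype=bool)
    counts = {}
    for name, (col, op, thr) in clauses.items():
        x = gm.site_info[col].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            fired = (x < thr) if op == "lt" else (x > thr)
        fired &= np.isfinite(x)
        counts[name] = int(fired.sum())
        remove |= fired
    return gm.take_sites(~remove), counts


@dataclass
class CascadeConfig:
    organelle_contigs: tuple = ("chrM", "chrC")
    max_missing: float = 0.20          # strict: remove if missingness > 20%
    depth_range: tuple = (8.0, 41.0)   # strict: remove if mean depth < 8 or > 41
    maf_min: float = 0.01              # strict: remove if MAF < 1%
    cluster_k: int = 3
    cluster_w: int = 10                # relaxed alternative: k=200, w=1000

    @classmethod
    def from_dict(cls, d: dict) -> "CascadeConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown cascade rule(s): {sorted(unknown)}")
        return cls(**d)


CASCADE_RULES = ("organelle", "missingness", "depth", "non_biallelic", "maf", "cluster")


def filter_cascade(gm: GenotypeMatrix, config: CascadeConfig | dict | None = None):
    """Apply the six population filters in order; first-rule attribution.

    Order: (1) organelle contigs, (2) missingness > 20%, (3) mean depth
    outside [8, 41], (4) non-biallelic, (5) MAF < 1% (called-allele
    denominator), (6) SNP clusters (>= k SNPs whose inclusive span fits in a
    w-bp window).  Returns (filtered matrix, report frame with per-rule
    removal counts and the surviving count).
    """
    if config is None:
        config = CascadeConfig()
    elif isinstance(config, dict):
        config = CascadeConfig.from_dict(config)

    alive = np.ones(gm.n_sites, dtype=bool)
    counts = {}

    is_org = np.isin(gm.chrom, config.organelle_contigs) | gm.site_info[
        "is_organelle"
    ].to_numpy(dtype=bool)
    counts["organelle"] = _apply(alive, is_org)

    miss = gm.site_info["missingness"].to_numpy(dtype=float)
    counts["missingness"] = _apply(alive, miss > config.max_missing)

    dep = gm.site_info["mean_depth"].to_numpy(dtype=float)
    lo, hi = config.depth_range
    with np.errstate(invalid="ignore"):
        bad_depth = ((dep < lo) | (dep > hi)) & np.isfinite(dep)
    counts["depth"] = _apply(alive, bad_depth)

    counts["non_biallelic"] = _apply(
        alive, ~gm.site_info["biallelic"].to_numpy(dtype=bool)
    )

    maf = gm.maf()
    with np.errstate(invalid="ignore"):
        low_maf = np.where(np.isfinite(maf), maf < config.maf_min, True)
    counts["maf"] = _apply(alive, low_maf)

    clustered = np.zeros(gm.n_sites, dtype=bool)
    for c in pd.unique(gm.chrom):
        idx = np.flatnonzero((gm.chrom == c) & alive)
        keep = snp_cluster_filter(gm.pos[idx], config.cluster_k, config.cluster_w)
        clustered[idx[~keep]] = True
    counts["cluster"] = _apply(alive, clustered)

    report = pd.DataFrame(
        {"rule": list(CASCADE_RULES), "removed": [counts[r] for r in CASCADE_RULES]}
    )
    report.loc[len(report)] = ["surviving", int(alive.sum())]
    return gm.take_sites(alive), report


def _apply(alive: np.ndarray, fired: np.ndarray) -> int:
    hit = alive & fired
    alive &= ~fired
    return int(hit.sum())


def snp_cluster_filter(positions, k: int = 3, w: int = 10) -> np.ndarray:
    """Keep mask: False for every SNP inside a condemned cluster window.

    Any run of k consecutive SNPs whose inclusive span (last - first + 1)
    fits within w bp condemns every SNP inside that span.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted")
    m = pos.size
    keep = np.ones(m, dtype=bool)
    if m < k:
        return keep
    span = pos[k - 1 :] - pos[: m - k + 1]
    for i in np.flatnonzero(span + 1 <= w):
        lo, hi = pos[i], pos[i + k - 1]
        keep[(pos >= lo) & (pos <= hi)] = False
    return keep
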