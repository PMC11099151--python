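"""Site-frequency spectra with hypergeometric projection."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .genotypes import GenotypeMatrix


@dataclass
class SFS:
    """Frequency spectrum over derived (unfolded) or minor (folded) counts.

    counts has length n+1 indexed by allele count 0..n; classes 0 and n are
    zero for spectra built from segregating sites.
    """

    n: int
    counts: np.ndarray
    folded: bool = False

    def probabilities(self) -> np.ndarray:
        """Normalized spectrum over the segregating classes."""
        p = self.counts.astype(float).copy()
        p[0] = 0.0
        if not self.folded:
            p[self.n] = 0.0
        tot = p.sum()
        if tot == 0:
            raise ValueError("no segregating sites in spectrum")
        return p / tot


def project_probs(probs: np.ndarray, m: int, s: int) -> np.ndarray:
    """Project a probability vector over counts 0..m down to sample size s.

    Hypergeometric downsampling: drawing s of m lineages without
    replacement.  Returns a vector over 0..s.
    """
    if s > m:
        raise ValueError("cannot project to a larger sample size")
    out = np.zeros(s + 1)
    for i, p in enumerate(probs):
        if p == 0:
            continue
        j = np.arange(max(0, s - (m - i)), min(i, s) + 1)
        out[j] += p * hypergeom.pmf(j, m, i, s)
    return out


def background_sfs(
    gm: GenotypeMatrix,
    folded: bool = False,
    project_to: int | None = None,
) -> SFS:
    """Genome-wide spectrum over segregating sites.

    Unfolded spectra use polarized sites only (ancestral known).  When call
    numbers vary across sites, every site is projected down to a common
    sample size (`project_to`, default the minimum observed) via the
    hypergeometric expectation.
    """
    if folded or gm.ancestral is None:
        k = np.minimum(gm.alt_counts(), gm.called_alleles() - gm.alt_counts())
        n = gm.called_alleles()
        folded = True
    else:
        polar = gm.polarized_mask()
        k, n = gm.derived_counts()
        k, n = k[polar], n[polar]
    seg = (k > 0) & (n >= 2) & (folded | (k < n))
    if folded:
        seg &= k > 0
    k, n = k[seg], n[seg]
    if k.size == 0:
        raise ValueError("no segregating sites")
    target = int(project_to or n.min())
    counts = np.zeros(target + 1)
    for ki, ni in zip(k, n):
        if ni == target:
            counts[ki] += 1.0
        else:
            point = np.zeros(ni + 1)
            point[ki] = 1.0
            counts += project_probs(point, ni, target)
    if folded:
        half = target // 2
        fold = np.zeros(target + 1)
        for j in range(target + 1):
            fold[min(j, target - j)] += counts[j]
        fold[half + 1 :] = 0.0
        counts = fold
        counts[0] = 0.0
    return SFS(n=target, counts=counts, folded=folded)
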