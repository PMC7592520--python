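"""Pairwise linkage-disequilibrium r^2 and greedy selection primitives.

Shared by the discovery clumping step and the PRS pruning step; both express
their own priority/threshold conventions on top of these.
"""

from __future__ import annotations

import numpy as np

from .containers import GenotypeMatrix


def pairwise_r2(genotypes: GenotypeMatrix, variant_ids=None) -> np.ndarray:
    """Squared Pearson correlation between dosage columns.

    Missing dosages are mean-imputed; monomorphic variants get r^2 = 0
    against everything (and 1 with themselves).
    """
    geno = genotypes if variant_ids is None else genotypes.take_variants(variant_ids)
    g = geno.dosages.copy()
    mean = np.nanmean(g, axis=0)
    miss = np.isnan(g)
    if miss.any():
        g[miss] = np.take(mean, np.nonzero(miss)[1])
    sd = g.std(axis=0)
    ok = sd > 0
    z = np.zeros_like(g)
    z[:, ok] = (g[:, ok] - g[:, ok].mean(axis=0)) / sd[ok]
    corr = (z.T @ z) / len(z)
    r2 = corr * corr
    np.fill_diagonal(r2, 1.0)
    return r2


def greedy_select(
    order: np.ndarray, r2: np.ndarray, cutoff: float, strict: bool
) -> list[int]:
    """Visit indices in ``order``; keep one unless it is in LD (r^2 >= cutoff,
    or > cutoff when ``strict``) with an already-kept index."""
    kept: list[int] = []
    for i in order:
        in_ld = False
        for j in kept:
            r = r2[i, j]
            if (r > cutoff) if strict else (r >= cutoff):
                in_ld = True
                break
        if not in_ld:
            kept.append(int(i))
    return kept
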