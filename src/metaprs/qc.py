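"""Variant- and sample-level quality control and principal components.

Filters follow the conventional pre-GWAS thresholds: variants with call rate
< 95%, minor allele frequency < 1% or Hardy-Weinberg exact-test p < 1e-5 are
excluded (boundary values kept); samples with call rate < 90%, a
genotype-inferred vs reported sex mismatch, or one member of any pair with
pi-hat > 0.9 are excluded. Filters are applied in a fixed order and each
removal is attributed to the first failing filter, so report counts
reconcile exactly.

HWE and identity-by-state are computed on hard-called genotypes (dosages
rounded when within 0.1 of an integer, missing otherwise); HWE is tested
within each ancestry stratum to avoid Wahlund artifacts from pooling.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import GenotypeMatrix

log = logging.getLogger(__name__)

VARIANT_FILTER_ORDER = ("call_rate", "maf", "hwe")
SAMPLE_FILTER_ORDER = ("call_rate", "sex_mismatch", "relatedness")


@dataclass
class QcReport:
    """Accounting of one QC pass; ``n_in - total removed == n_out``."""

    axis: str  # "variants" | "samples"
    n_in: int
    n_out: int
    removed: dict = field(default_factory=dict)  # filter -> count
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_in - sum(self.removed.values()) != self.n_out:
            raise ValueError("QcReport counts do not reconcile")


class AllRemovedError(RuntimeError):
    def __init__(self, report: QcReport):
        super().__init__(f"QC removed every {report.axis}: {report.removed}")
        self.report = report


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact conditional Hardy-Weinberg test on the heterozygote count.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one (two-sided
    by probability ordering). Monomorphic configurations carry no
    information and return 1.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("total genotype count must be positive")
    n_a = 2 * n_hom1 + n_het  # copies of allele 1
    n_b = 2 * n_hom2 + n_het
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(h hets | n, n_a) up to the common normalising constant
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln((n_a - hets) / 2 + 1)
        - gammaln((n_b - hets) / 2 + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[np.searchsorted(hets, n_het)]
    return float(min(1.0, prob[prob <= obs * (1 + 1e-12)].sum()))


def _hwe_pvalues_by_stratum(geno: GenotypeMatrix) -> np.ndarray:
    """Min across strata of per-stratum HWE exact p per variant."""
    calls = geno.hard_calls()
    pmin = np.ones(geno.n_variants)
    for s in geno.strata.unique():
        sub = calls[(geno.strata == s).to_numpy()]
        if sub.shape[0] == 0:
            continue
        n0 = np.nansum(sub == 0, axis=0)
        n1 = np.nansum(sub == 1, axis=0)
        n2 = np.nansum(sub == 2, axis=0)
        for j in range(geno.n_variants):
            tot = n0[j] + n1[j] + n2[j]
            if tot == 0:
                continue
            pmin[j] = min(pmin[j], hwe_exact_test(int(n0[j]), int(n1[j]), int(n2[j])))
    return pmin


# ---------------------------------------------------------------------------
# variant filter
# ---------------------------------------------------------------------------

def filter_variants(
    genotypes: GenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-5,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply call-rate, MAF and HWE filters in fixed order.

    A variant failing HWE in any ancestry stratum in which it is observed is
    removed. Boundary values (call rate exactly 0.95, MAF exactly 0.01, HWE
    p exactly 1e-5) are kept, matching the strict inequalities of the rule.
    """
    cr = genotypes.call_rate_variants()
    f = genotypes.allele_freq()
    with np.errstate(invalid="ignore"):
        maf = np.fmin(f, 1.0 - f)
    fail_cr = cr < call_rate_min
    fail_maf = ~fail_cr & (np.isnan(maf) | (maf < maf_min))
    hwe_p = _hwe_pvalues_by_stratum(genotypes)
    fail_hwe = ~fail_cr & ~fail_maf & (hwe_p < hwe_p_min)
    keep = ~(fail_cr | fail_maf | fail_hwe)
    report = QcReport(
        axis="variants",
        n_in=genotypes.n_variants,
        n_out=int(keep.sum()),
        removed={
            "call_rate": int(fail_cr.sum()),
            "maf": int(fail_maf.sum()),
            "hwe": int(fail_hwe.sum()),
        },
        thresholds={
            "call_rate_min": call_rate_min,
            "maf_min": maf_min,
            "hwe_p_min": hwe_p_min,
        },
    )
    if report.n_out == 0:
        raise AllRemovedError(report)
    return genotypes.take_variants(keep), report


# ---------------------------------------------------------------------------
# relatedness
# ---------------------------------------------------------------------------

def estimate_relatedness(
    genotypes: GenotypeMatrix, min_variants: int = 50
) -> pd.DataFrame:
    """Method-of-moments IBD estimates for all sample pairs.

    Works on hard calls at variants with complete calls in every sample;
    identity-by-state counts are converted to P(IBD=0/1/2) using expectations
    under the sample allele frequencies, and
    ``pihat = P(IBD=1)/2 + P(IBD=2)``, clipped to [0, 1].

    Returns a long frame (sample_i, sample_j, pihat, low_confidence).
    """
    if genotypes.n_samples < 2:
        raise ValueError("relatedness needs at least two samples")
    calls = genotypes.hard_calls()
    complete = ~np.isnan(calls).any(axis=0)
    f = calls[:, complete].mean(axis=0) / 2.0
    poly = (f > 0) & (f < 1)
    g = calls[:, complete][:, poly]
    p = f[poly]
    m = g.shape[1]
    low_conf = m < min_variants
    if low_conf:
        log.warning("relatedness estimated from only %d usable variants", m)
    if m == 0:
        raise ValueError("no usable variants for relatedness estimation")
    q = 1.0 - p
    # expected per-SNP IBS-class probabilities given IBD state, summed
    e0_ibd0 = float(np.sum(2 * p**2 * q**2))
    e1_ibd0 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e2_ibd0 = float(np.sum(p**4 + q**4 + 4 * p**2 * q**2))
    e1_ibd1 = float(np.sum(2 * p**2 * q + 2 * p * q**2))
    e2_ibd1 = float(np.sum(p**2 + q**2))
    ind = [(g == a).astype(np.float64) for a in (0.0, 1.0, 2.0)]
    ibs2 = sum(a @ a.T for a in ind)
    ibs0 = ind[0] @ ind[2].T + ind[2] @ ind[0].T
    ibs1 = m - ibs0 - ibs2

    p0 = ibs0 / e0_ibd0 if e0_ibd0 > 0 else np.zeros_like(ibs0)
    p1 = (ibs1 - p0 * e1_ibd0) / e1_ibd1 if e1_ibd1 > 0 else np.zeros_like(ibs0)
    p0c = np.clip(p0, 0.0, 1.0)
    p1c = np.clip(p1, 0.0, 1.0 - p0c)
    p2 = (ibs2 - p0c * e2_ibd0 - p1c * e2_ibd1) / m
    p2c = np.clip(p2, 0.0, 1.0 - p0c - p1c)
    pihat = np.clip(p1c / 2.0 + p2c, 0.0, 1.0)

    ids = list(genotypes.samples)
    rows = [
        {"sample_i": ids[i], "sample_j": ids[j],
         "pihat": float(pihat[i, j]), "low_confidence": low_conf}
        for i, j in itertools.combinations(range(len(ids)), 2)
    ]
    return pd.DataFrame(rows)


def infer_sex_from_het(
    genotypes: GenotypeMatrix, sex_check_variants, het_max_male: float = 0.2
) -> pd.Series:
    """X-heterozygosity proxy: heterozygosity rate on designated variants;
    below ``het_max_male`` the sample is called male."""
    sub = genotypes.take_variants(sex_check_variants)
    calls = sub.hard_calls()
    with np.errstate(invalid="ignore"):
        het = np.nanmean(calls == 1, axis=1)
    return pd.Series(
        np.where(het < het_max_male, "M", "F"), index=genotypes.samples, name="sex"
    )


def filter_samples(
    genotypes: GenotypeMatrix,
    reported_sex: pd.Series | None = None,
    call_rate_min: float = 0.90,
    pihat_max: float = 0.9,
    sex_check_variants=None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Sample QC: call rate, sex concordance, relatedness — in that order.

    The sex check runs only when ``sex_check_variants`` (X-like markers) are
    supplied. Of each pair with pi-hat above the cutoff, the member with the
    lower call rate is dropped (ties: the lexicographically larger ID).
    """
    cr = pd.Series(genotypes.call_rate_samples(), index=genotypes.samples)
    fail_cr = cr < call_rate_min
    reason = pd.Series("", index=genotypes.samples, dtype=object)
    reason[fail_cr] = "call_rate"

    if sex_check_variants is not None and reported_sex is not None:
        inferred = infer_sex_from_het(genotypes, sex_check_variants)
        rep = reported_sex.reindex(genotypes.samples)
        mism = (inferred != rep) & rep.notna() & (reason == "")
        reason[mism] = "sex_mismatch"

    survivors = genotypes.take_samples((reason == "").to_numpy())
    if survivors.n_samples >= 2:
        rel = estimate_relatedness(survivors)
        close = rel[rel["pihat"] > pihat_max]
        pairs = sorted(
            close.itertuples(index=False),
            key=lambda r: -r.pihat,
        )
        dropped: set = set()
        for r in pairs:
            a, b = r.sample_i, r.sample_j
            if a in dropped or b in dropped:
                continue
            ca, cb = cr[a], cr[b]
            if ca < cb:
                victim = a
            elif cb < ca:
                victim = b
            else:
                victim = max(a, b)
            dropped.add(victim)
        for v in dropped:
            reason[v] = "relatedness"

    keep = reason == ""
    report = QcReport(
        axis="samples",
        n_in=genotypes.n_samples,
        n_out=int(keep.sum()),
        removed={k: int((reason == k).sum()) for k in SAMPLE_FILTER_ORDER},
        thresholds={"call_rate_min": call_rate_min, "pihat_max": pihat_max},
    )
    if report.n_out == 0:
        raise AllRemovedError(report)
    return genotypes.take_samples(keep.to_numpy()), report


# ---------------------------------------------------------------------------
# principal components
# ---------------------------------------------------------------------------

def compute_pcs(
    genotypes: GenotypeMatrix,
    n_pcs: int = 10,
    exclude_region: tuple | None = None,
) -> pd.DataFrame:
    """Sample principal components of the standardized genotype matrix.

    Intended to run within one ancestry stratum. Each variant is centered at
    2f and scaled by sqrt(2 f (1-f)); missing dosages contribute zero after
    centering; monomorphic variants are dropped. ``exclude_region`` is a
    (chrom, start, end) interval (e.g. an MHC analogue) removed before the
    decomposition. Sign convention: the loading of largest magnitude on each
    component is positive.
    """
    geno = genotypes
    if exclude_region is not None:
        chrom, start, end = exclude_region
        v = geno.variants
        inside = (
            (v["chrom"].astype(str) == str(chrom))
            & (v["pos"] >= start)
            & (v["pos"] <= end)
        )
        geno = geno.take_variants((~inside).to_numpy())
    f = geno.allele_freq()
    poly = np.isfinite(f) & (f > 0) & (f < 1)
    x = geno.dosages[:, poly]
    f = f[poly]
    z = (x - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))
    z = np.nan_to_num(z, nan=0.0)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    rank = int((s > s[0] * 1e-9).sum()) if len(s) else 0
    if n_pcs > rank:
        raise ValueError(f"requested {n_pcs} PCs but rank is {rank}")
    flip = np.sign(vt[np.arange(n_pcs), np.abs(vt[:n_pcs]).argmax(axis=1)])
    flip[flip == 0] = 1.0
    coords = u[:, :n_pcs] * s[:n_pcs] * flip
    return pd.DataFrame(
        coords,
        index=geno.samples,
        columns=[f"PC{i + 1}" for i in range(n_pcs)],
    )
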