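"""Synthetic two-ancestry cohort generator.

Emulates the statistical structure the downstream analysis assumes: two
ancestry strata ("EA"/"AA") with Balding-Nichols-diverged allele frequencies,
block-structured linkage disequilibrium, polygenic quantitative traits with
covariate effects, liability-threshold binary diseases, well-powered external
reference summary statistics, eSNP annotations enriched near chosen loci, and
longitudinal clinical records (lipid panels, HbA1c, medications).

LD model: within each block of variants, haplotypes are generated from a
latent Gaussian with exchangeable correlation, thresholded at the quantile of
each variant's stratum frequency; the latent correlation is calibrated so the
mean pairwise genotype r^2 inside a block matches the requested target.
Across blocks variants are independent.

All randomness flows through one :class:`numpy.random.Generator` derived from
an explicit integer seed; identical seeds reproduce cohorts bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import GenotypeMatrix

STRATA = ("EA", "AA")

#: Male fraction per stratum (matches the cohort composition the analysis
#: is designed for: a predominantly male HIV clinical cohort).
MALE_FRACTION = {"EA": 0.893, "AA": 0.690}
ART_FRACTION = {"EA": 0.918, "AA": 0.885}
SITES = ("site_A", "site_B", "site_C", "site_D")


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """Genotype-architecture parameters for the two-stratum simulator."""

    n_variants: int
    n_blocks: int
    block_size: int
    allele_freq_ranges: dict = field(
        default_factory=lambda: {"EA": (0.05, 0.95), "AA": (0.05, 0.95)}
    )
    within_block_r2: float = 0.3
    fst_divergence: float = 0.05

    def __post_init__(self) -> None:
        if self.block_size <= 0 or self.n_blocks <= 0:
            raise ValueError("block_size and n_blocks must be positive")
        if self.block_size * self.n_blocks != self.n_variants:
            raise ValueError("block_size * n_blocks must equal n_variants")
        if not (0.0 <= self.within_block_r2 < 1.0):
            raise ValueError("within_block_r2 must lie in [0, 1)")
        if self.fst_divergence < 0:
            raise ValueError("fst_divergence must be >= 0")
        for s in STRATA:
            lo, hi = self.allele_freq_ranges[s]
            if not (0.0 < lo <= hi < 1.0):
                raise ValueError(f"allele_freq_range for {s} outside (0, 1)")


@dataclass
class TraitSpec:
    """Architecture of one simulated trait.

    ``h2`` is narrow-sense heritability on the trait (quantitative) or
    liability (binary) scale; the genetic and residual components sum to unit
    variance, covariate effects add on top. ``ancestry_effect_corr`` is the
    correlation of causal effect sizes between the two strata (1 = shared
    architecture, 0 = independent).
    """

    name: str
    kind: str = "quantitative"  # or "binary"
    n_causal: int = 100
    h2: float = 0.3
    prevalence: float | None = None
    covariate_effects: dict = field(default_factory=dict)
    ancestry_effect_corr: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("quantitative", "binary"):
            raise ValueError("kind must be 'quantitative' or 'binary'")
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError("h2 must lie in [0, 1]")
        if self.kind == "binary":
            if self.prevalence is None or not (0.0 < self.prevalence < 1.0):
                raise ValueError("binary traits require prevalence in (0, 1)")
        elif self.prevalence is not None:
            raise ValueError("prevalence is only meaningful for binary traits")
        if not (-1.0 <= self.ancestry_effect_corr <= 1.0):
            raise ValueError("ancestry_effect_corr must lie in [-1, 1]")


@dataclass
class SyntheticCohort:
    """A fully generated cohort: genotypes, phenotype table and ground truth."""

    genotypes: GenotypeMatrix
    cohort: pd.DataFrame
    truth: pd.DataFrame  # columns: trait, variant_id, beta_EA, beta_AA
    seed: int


# ---------------------------------------------------------------------------
# LD calibration
# ---------------------------------------------------------------------------

def _pair_indicator_corr(rho: float, f: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Correlation of Bernoulli allele indicators for the given frequency
    pairs under a latent bivariate normal with correlation ``rho``.

    ``pairs`` is an (n_pairs, 2) index array into ``f``.
    """
    t = stats.norm.ppf(f)
    fi, fj = f[pairs[:, 0]], f[pairs[:, 1]]
    if rho <= 0.0:
        joint = fi * fj
    else:
        mvn = stats.multivariate_normal(
            mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        )
        joint = np.atleast_1d(mvn.cdf(np.column_stack([t[pairs[:, 0]],
                                                       t[pairs[:, 1]]])))
    return (joint - fi * fj) / np.sqrt(
        fi * (1.0 - fi) * fj * (1.0 - fj)
    )


def _block_rho(freqs: np.ndarray, target_r2: float) -> float:
    """Latent correlation for one LD block.

    Solves for the exchangeable latent-Gaussian correlation at which the
    mean pairwise squared indicator correlation across the block's actual
    frequencies equals ``target_r2``. Heterogeneous frequencies cap the
    achievable r^2; the solution saturates at the cap.
    """
    k = len(freqs)
    if target_r2 <= 0.0 or k < 2:
        return 0.0
    idx = np.array([(i, j) for i in range(k) for j in range(i + 1, k)])

    def mean_r2(rho: float) -> float:
        c = _pair_indicator_corr(rho, freqs, idx)
        return float(np.mean(c * c))

    hi = 0.999999
    if mean_r2(hi) <= target_r2:
        return hi
    return float(
        optimize.brentq(lambda r: mean_r2(r) - target_r2, 0.0, hi, xtol=1e-6)
    )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    spec: PopulationSpec,
    n_per_stratum: dict | tuple,
    seed: int,
) -> GenotypeMatrix:
    """Generate a two-stratum dosage matrix under the block-LD model.

    Parameters
    ----------
    spec
        Population architecture.
    n_per_stratum
        ``{"EA": n, "AA": n}`` (or a 2-tuple in that order); either count may
        be zero, in which case variant metadata is still produced.
    seed
        Integer seed; all draws derive from it.
    """
    if not isinstance(n_per_stratum, dict):
        n_per_stratum = dict(zip(STRATA, n_per_stratum))
    for s in STRATA:
        if n_per_stratum.get(s, 0) < 0:
            raise ValueError("stratum sizes must be >= 0")

    rng = np.random.default_rng(seed)
    m = spec.n_variants

    # ancestral frequency drawn uniformly over the mean of the two intervals,
    # then Balding-Nichols perturbation per stratum, clipped into the
    # stratum's own interval
    lo = np.mean([spec.allele_freq_ranges[s][0] for s in STRATA])
    hi = np.mean([spec.allele_freq_ranges[s][1] for s in STRATA])
    p_anc = rng.uniform(lo, hi, size=m)
    freqs = {}
    for s in STRATA:
        F = spec.fst_divergence
        if F > 0:
            a = p_anc * (1.0 - F) / F
            b = (1.0 - p_anc) * (1.0 - F) / F
            f = rng.beta(a, b)
        else:
            f = p_anc.copy()
        slo, shi = spec.allele_freq_ranges[s]
        freqs[s] = np.clip(f, max(slo, 1e-3), min(shi, 1 - 1e-3))

    block_of = np.repeat(np.arange(spec.n_blocks), spec.block_size)

    # per-block, per-stratum latent correlation calibrated against the mean
    # pairwise genotype r^2 at the block's actual frequencies; rho is stored
    # so the reference-sumstats generator can compute exact model-marginal
    # effects
    rho = {s: np.zeros(spec.n_blocks) for s in STRATA}
    for s in STRATA:
        for b in range(spec.n_blocks):
            rho[s][b] = _block_rho(
                freqs[s][block_of == b], spec.within_block_r2
            )

    variants = pd.DataFrame(
        {
            "variant_id": [f"var{j + 1:05d}" for j in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 1000,
            "ref": "A",
            "alt": "G",
            "block": block_of,
        }
    )
    for s in STRATA:
        variants[f"freq_{s}"] = freqs[s]
        variants[f"ld_rho_{s}"] = rho[s][block_of]

    dosage_parts, sample_parts, strata_parts = [], [], []
    for s in STRATA:
        n = n_per_stratum.get(s, 0)
        if n == 0:
            continue
        thresh = stats.norm.ppf(freqs[s])  # per-variant
        dos = np.zeros((n, m))
        for b in range(spec.n_blocks):
            cols = np.flatnonzero(block_of == b)
            r = rho[s][b]
            # two gametes per individual, one shared factor per gamete
            shared = rng.standard_normal((n, 2, 1))
            eps = rng.standard_normal((n, 2, len(cols)))
            z = np.sqrt(r) * shared + np.sqrt(1.0 - r) * eps
            alleles = z < thresh[cols][None, None, :]
            dos[:, cols] = alleles.sum(axis=1)
        dosage_parts.append(dos)
        sample_parts.extend(f"{s}{i + 1:05d}" for i in range(n))
        strata_parts.extend([s] * n)

    if dosage_parts:
        dosages = np.vstack(dosage_parts)
    else:
        dosages = np.zeros((0, m))
    return GenotypeMatrix(
        dosages, variants, pd.Index(sample_parts), pd.Series(strata_parts)
    )


# ---------------------------------------------------------------------------
# covariates and phenotypes
# ---------------------------------------------------------------------------

def simulate_covariates(n_per_stratum: dict | tuple, seed: int) -> pd.DataFrame:
    """Demographic/design covariates: sex, age, site, ART exposure."""
    if not isinstance(n_per_stratum, dict):
        n_per_stratum = dict(zip(STRATA, n_per_stratum))
    rng = np.random.default_rng(seed)
    rows = []
    for s in STRATA:
        n = n_per_stratum.get(s, 0)
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{s}{i + 1:05d}",
                    "stratum": s,
                    "sex": "M" if rng.random() < MALE_FRACTION[s] else "F",
                    "age": float(np.clip(rng.normal(53.3, 10.2), 18, 90)),
                    "site": SITES[rng.integers(len(SITES))],
                    "art": int(rng.random() < ART_FRACTION[s]),
                }
            )
    return pd.DataFrame(rows)


def _covariate_design(cohort: pd.DataFrame, effects: dict) -> np.ndarray:
    """Numeric covariate contribution Sum_k c_k * x_k (x standardized)."""
    out = np.zeros(len(cohort))
    for name, c in effects.items():
        if name == "sex":
            x = (cohort["sex"] == "F").to_numpy(float)
        elif name == "art":
            x = cohort["art"].to_numpy(float)
        elif name in cohort.columns:
            x = pd.to_numeric(cohort[name]).to_numpy(float)
        else:
            raise KeyError(f"unknown covariate '{name}' in covariate_effects")
        sd = x.std()
        if sd > 0:
            x = (x - x.mean()) / sd
        out = out + c * x
    return out


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    traits: list[TraitSpec],
    covariates: pd.DataFrame,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach simulated trait columns to the covariate table.

    The genetic value is standardized within each stratum, so ``h2`` is the
    variance share of genetics in every stratum; causal effect sizes are
    drawn jointly for the two strata with correlation
    ``spec.ancestry_effect_corr``. Binary traits arise from a liability
    threshold at the empirical quantile implied by the prevalence.

    Returns the augmented cohort table and a truth table
    (trait, variant_id, beta_EA, beta_AA).
    """
    cohort = covariates.reset_index(drop=True).copy()
    order = genotypes.samples.get_indexer(cohort["sample_id"])
    if (order < 0).any():
        raise ValueError("covariate table contains samples absent from genotypes")
    rng = np.random.default_rng(seed)
    truth_rows = []
    for spec in traits:
        if spec.n_causal > genotypes.n_variants:
            raise ValueError(
                f"trait {spec.name}: n_causal exceeds available variants"
            )
        causal = np.sort(
            rng.choice(genotypes.n_variants, size=spec.n_causal, replace=False)
        )
        b_ea = rng.standard_normal(spec.n_causal)
        r = spec.ancestry_effect_corr
        b_aa = r * b_ea + np.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(
            spec.n_causal
        )
        betas = {"EA": b_ea, "AA": b_aa}

        g = np.zeros(len(cohort))
        strata = genotypes.strata.iloc[order].to_numpy()
        dos = genotypes.dosages[order][:, causal]
        for s in STRATA:
            in_s = strata == s
            if not in_s.any() or spec.n_causal == 0:
                continue
            raw = dos[in_s] @ betas[s]
            sd = raw.std()
            g[in_s] = (raw - raw.mean()) / sd if sd > 0 else 0.0

        cov_part = _covariate_design(cohort, spec.covariate_effects)
        noise = rng.standard_normal(len(cohort))
        liability = (
            np.sqrt(spec.h2) * g + cov_part + np.sqrt(1.0 - spec.h2) * noise
        )
        if spec.kind == "quantitative":
            cohort[spec.name] = liability
        else:
            mu, sd = liability.mean(), liability.std()
            thr = mu + sd * stats.norm.ppf(1.0 - spec.prevalence)
            cohort[spec.name] = (liability > thr).astype(int)
        cohort[f"_gv_{spec.name}"] = g  # true genetic value, for diagnostics

        ids = genotypes.variants["variant_id"].iloc[causal].to_numpy()
        for vid, be, ba in zip(ids, b_ea, b_aa):
            truth_rows.append(
                {"trait": spec.name, "variant_id": vid, "beta_EA": be, "beta_AA": ba}
            )
    truth = pd.DataFrame(
        truth_rows, columns=["trait", "variant_id", "beta_EA", "beta_AA"]
    )
    return cohort, truth


def simulate_cohort(
    pop_spec: PopulationSpec,
    traits: list[TraitSpec],
    n_per_stratum: dict | tuple,
    seed: int,
) -> SyntheticCohort:
    """Convenience wrapper: genotypes + covariates + phenotypes + truth."""
    seeds = np.random.SeedSequence(seed).spawn(3)
    geno = simulate_genotypes(pop_spec, n_per_stratum, _child_seed(seeds[0]))
    cov = simulate_covariates(n_per_stratum, _child_seed(seeds[1]))
    cohort, truth = simulate_phenotypes(geno, traits, cov, _child_seed(seeds[2]))
    return SyntheticCohort(geno, cohort, truth, seed)


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0])


# ---------------------------------------------------------------------------
# reference summary statistics
# ---------------------------------------------------------------------------

def simulate_reference_sumstats(
    genotypes: GenotypeMatrix,
    effects: pd.DataFrame,
    h2: float,
    n_reference: int,
    seed: int,
    stratum: str = "EA",
) -> pd.DataFrame:
    """Well-powered external GWAS for a trait with the given causal effects.

    ``effects`` holds (variant_id, beta) raw causal effects on the given
    stratum's scale (the truth table's ``beta_<stratum>`` column). The true
    per-dosage marginal effect of each variant on the unit-variance trait is
    computed in closed form from the block-LD model (within-block
    exchangeable indicator correlation, zero across blocks), then an
    estimate is drawn with standard error ``1 / sqrt(2 f (1-f) n_reference)``
    and a two-sided Wald p-value is attached.

    Monomorphic variants yield rows with missing statistics.
    """
    if n_reference <= 0:
        raise ValueError("n_reference must be positive")
    rng = np.random.default_rng(seed)
    v = genotypes.variants
    f = v[f"freq_{stratum}"].to_numpy(float)
    sd = np.sqrt(2.0 * f * (1.0 - f))
    block = v["block"].to_numpy()
    rho = v[f"ld_rho_{stratum}"].to_numpy(float)

    b = np.zeros(len(v))
    idx = pd.Index(v["variant_id"]).get_indexer(effects["variant_id"])
    if (idx < 0).any():
        raise KeyError("effects reference unknown variant ids")
    b[idx] = effects["beta"].to_numpy(float)

    # model-exact marginal covariances on the standardized-genotype scale:
    # within causal blocks the indicator correlation matrix follows from the
    # latent rho and the variant frequencies; across blocks it is zero
    bsd = b * sd
    cov_ug = bsd.copy()
    tot = 0.0
    for blk in np.unique(block[b != 0]):
        cols = np.flatnonzero(block == blk)
        k = len(cols)
        corr = np.eye(k)
        if k > 1 and rho[cols[0]] > 0:
            pairs = np.array(
                [(i, j) for i in range(k) for j in range(i + 1, k)]
            )
            c = _pair_indicator_corr(rho[cols[0]], f[cols], pairs)
            corr[pairs[:, 0], pairs[:, 1]] = c
            corr[pairs[:, 1], pairs[:, 0]] = c
        w = bsd[cols]
        cov_ug[cols] = corr @ w
        tot += float(w @ corr @ w)
    theta = np.zeros(len(v)) if tot == 0 else np.sqrt(h2) * cov_ug / np.sqrt(tot)

    poly = (f > 0) & (f < 1)
    se = np.full(len(v), np.nan)
    se[poly] = 1.0 / np.sqrt(2.0 * f[poly] * (1.0 - f[poly]) * n_reference)
    true_dosage_beta = np.where(poly, theta / np.where(poly, sd, 1.0), np.nan)
    beta_hat = true_dosage_beta + rng.standard_normal(len(v)) * se
    z = beta_hat / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    return pd.DataFrame(
        {
            "variant_id": v["variant_id"],
            "chrom": v["chrom"],
            "pos": v["pos"],
            "effect_allele": v["alt"],
            "other_allele": v["ref"],
            "eaf": f,
            "beta": beta_hat,
            "se": se,
            "p": p,
            "n": n_reference,
            "stratum": f"REF_{stratum}",
        }
    )


# ---------------------------------------------------------------------------
# eQTL annotations
# ---------------------------------------------------------------------------

def simulate_eqtl_annotations(
    genotypes: GenotypeMatrix,
    enriched_set,
    conditions,
    base_rate: float,
    enriched_rate: float,
    seed: int,
) -> pd.DataFrame:
    """Per-condition eSNP flags: Bernoulli(base_rate), or Bernoulli(enriched_rate)
    for variants in ``enriched_set`` (long format: variant_id, condition, esnp)."""
    if not (0.0 <= base_rate <= enriched_rate <= 1.0):
        raise ValueError("need 0 <= base_rate <= enriched_rate <= 1")
    ids = pd.Index(genotypes.variants["variant_id"])
    enriched = pd.Index(enriched_set)
    unknown = enriched.difference(ids)
    if len(unknown):
        raise KeyError(f"enriched_set contains unknown variants: {list(unknown)[:5]}")
    rate = np.where(ids.isin(enriched), enriched_rate, base_rate)
    rng = np.random.default_rng(seed)
    frames = []
    for cond in conditions:
        flags = rng.random(len(ids)) < rate
        frames.append(
            pd.DataFrame(
                {"variant_id": ids, "condition": cond, "esnp": flags}
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# clinical records
# ---------------------------------------------------------------------------

def simulate_clinical_records(
    cohort: pd.DataFrame,
    seed: int,
    n_draws: int = 3,
    statin_fraction: float = 0.10,
    lipid_scale: dict | None = None,
) -> dict:
    """Longitudinal records consistent with the phenotype-derivation rules.

    ``cohort`` must carry per-sample target values ``hdl``, ``ldl``, ``tg``
    (standardized trait scale, mapped to mg/dL via ``lipid_scale``:
    mean/sd per lipid) and a binary ``t2d`` column. Returns a dict of frames:
    ``labs`` (repeated lipid panels), ``hba1c``, ``meds``, ``diagnoses``,
    ``anthro``.

    T2D-positive samples are made to satisfy at least one adjudication
    criterion (HbA1c >= 6.5, a diabetes-specific medication, or a
    diabetes-related medication plus diagnosis flag); negatives satisfy none.
    Samples drawn as statin users get a baseline (day 0) lipid-lowering
    medication record, so they are removed by the statin-exclusion rule.
    """
    if lipid_scale is None:
        lipid_scale = {
            "hdl": (44.9, 14.8),
            "ldl": (103.7, 32.3),
            "tg": (180.7, 143.2),
        }
    rng = np.random.default_rng(seed)
    labs, hba1c, meds, dx, anthro = [], [], [], [], []
    for _, row in cohort.iterrows():
        sid = row["sample_id"]
        targets = {}
        for lip in ("hdl", "ldl", "tg"):
            mu, sdev = lipid_scale[lip]
            targets[lip] = max(1.0, mu + sdev * float(row[lip]))
        for d in range(n_draws):
            hdl_d = max(1.0, rng.normal(targets["hdl"], 4.0))
            tg_d = max(1.0, rng.normal(targets["tg"], 15.0))
            eps = rng.normal(0.0, 3.0)
            tc_d = targets["ldl"] + eps + hdl_d + tg_d / 5.0
            rec = {
                "sample_id": sid,
                "day": d * 180,
                "total_cholesterol": tc_d,
                "hdl": hdl_d,
                "triglycerides": tg_d,
                "ldl_direct": (
                    max(0.0, rng.normal(targets["ldl"], 4.0))
                    if rng.random() < 0.3
                    else np.nan
                ),
            }
            labs.append(rec)
        if rng.random() < statin_fraction:
            meds.append(
                {"sample_id": sid, "day": 0, "code": "atorvastatin",
                 "med_class": "lipid_lowering"}
            )
        if int(row["t2d"]):
            mech = rng.integers(3)
            if mech == 0:
                hba1c.append(
                    {"sample_id": sid, "day": 90, "hba1c": rng.uniform(6.5, 9.5)}
                )
            elif mech == 1:
                hba1c.append(
                    {"sample_id": sid, "day": 90, "hba1c": rng.uniform(5.0, 6.4)}
                )
                meds.append(
                    {"sample_id": sid, "day": 90, "code": "insulin",
                     "med_class": "diabetes_specific"}
                )
            else:
                hba1c.append(
                    {"sample_id": sid, "day": 90, "hba1c": rng.uniform(5.0, 6.4)}
                )
                meds.append(
                    {"sample_id": sid, "day": 90, "code": "metformin",
                     "med_class": "diabetes_related"}
                )
                dx.append({"sample_id": sid, "t2d_dx": True})
        else:
            hba1c.append(
                {"sample_id": sid, "day": 90, "hba1c": rng.uniform(4.8, 6.2)}
            )
        height = rng.normal(1.78 if row["sex"] == "M" else 1.65, 0.07)
        bmi_t = rng.normal(27.0, 4.0)
        anthro.append(
            {"sample_id": sid, "height_m": height,
             "weight_kg": bmi_t * height * height}
        )
    return {
        "labs": pd.DataFrame(labs),
        "hba1c": pd.DataFrame(hba1c),
        "meds": pd.DataFrame(
            meds, columns=["sample_id", "day", "code", "med_class"]
        ),
        "diagnoses": pd.DataFrame(dx, columns=["sample_id", "t2d_dx"]),
        "anthro": pd.DataFrame(anthro),
    }
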