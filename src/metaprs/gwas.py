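"""Stratified single-variant association and cross-stratum meta-analysis.

Association is the standard single-variant dosage model: for each variant,
trait ~ dosage + covariates, linear for quantitative traits and logistic
(IRLS, max 50 iterations, tolerance 1e-8) for binary traits, with Wald
beta/SE/p for the dosage term using the normal reference. The linear path is
vectorised across variants via Frisch-Waugh-Lovell residualisation, which is
what keeps genome-wide nulls and cross-validated re-GWAS cheap.

Strata are pooled with DerSimonian-Laird random-effects meta-analysis
(fixed-effects pooling is also provided); whenever the heterogeneity
statistic Q <= k-1 the moment estimate of tau^2 is zero and the two
coincide.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SUMSTATS_COLUMNS, GenotypeMatrix

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


# ---------------------------------------------------------------------------
# design-matrix helpers
# ---------------------------------------------------------------------------

def encode_covariates(
    cohort: pd.DataFrame,
    names=("sex", "age", "site", "art"),
    pcs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Numeric covariate matrix (no intercept), indexed by sample_id.

    ``site`` (and any other non-numeric column) becomes drop-first indicator
    columns; ``sex`` becomes an is-female indicator; ``age2`` may be named to
    add squared (standardized) age. PC coordinates are joined if given.
    """
    df = cohort.set_index("sample_id") if "sample_id" in cohort.columns else cohort
    cols = {}
    for name in names:
        if name == "sex":
            cols["sex_F"] = (df["sex"] == "F").astype(float)
        elif name == "age2":
            a = pd.to_numeric(df["age"])
            a = (a - a.mean()) / (a.std() if a.std() > 0 else 1.0)
            cols["age2"] = a * a
        elif name in df.columns and not pd.api.types.is_numeric_dtype(df[name]):
            dummies = pd.get_dummies(df[name], prefix=name, drop_first=True)
            for c in dummies.columns:
                cols[c] = dummies[c].astype(float)
        else:
            cols[name] = pd.to_numeric(df[name]).astype(float)
    out = pd.DataFrame(cols, index=df.index)
    if pcs is not None:
        out = out.join(pcs)
    return out


def _design(covariates: pd.DataFrame | None, index: pd.Index) -> np.ndarray:
    n = len(index)
    if covariates is None:
        return np.ones((n, 1))
    cov = covariates.reindex(index)
    if cov.isna().any().any():
        raise ValueError("covariates incomplete for analyzed samples")
    return np.column_stack([np.ones(n), cov.to_numpy(float)])


# ---------------------------------------------------------------------------
# single-variant association
# ---------------------------------------------------------------------------

def single_variant_assoc(
    genotypes: GenotypeMatrix,
    trait: pd.Series,
    covariates: pd.DataFrame | None = None,
    model: str = "linear",
    stratum_label: str = "ALL",
) -> pd.DataFrame:
    """Per-variant Wald association of a trait with allele dosage.

    ``trait`` is indexed by sample_id; samples with a missing trait value are
    dropped; missing dosages are mean-imputed per variant. Monomorphic
    variants (and non-converged logistic fits) yield rows with missing
    statistics.
    """
    if model not in ("linear", "logistic"):
        raise ValueError("model must be 'linear' or 'logistic'")
    trait = trait.reindex(genotypes.samples)
    use = trait.notna().to_numpy()
    geno = genotypes.take_samples(use)
    y = trait[use].to_numpy(float)
    x_cov = _design(covariates, geno.samples)
    n, p_cov = x_cov.shape

    g = geno.dosages.copy()
    col_mean = np.nanmean(g, axis=0) if n else np.zeros(g.shape[1])
    miss = np.isnan(g)
    if miss.any():
        g[miss] = np.take(col_mean, np.nonzero(miss)[1])
    sd = g.std(axis=0)
    mono = ~(sd > 0)

    m = geno.n_variants
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    if model == "linear":
        q, _ = np.linalg.qr(x_cov)
        y_res = y - q @ (q.T @ y)
        g_res = g - q @ (q.T @ g)
        sxx = np.einsum("ij,ij->j", g_res, g_res)
        sxy = g_res.T @ y_res
        ssy = float(y_res @ y_res)
        dof = n - p_cov - 1
        if dof <= 0:
            raise ValueError("not enough samples for the covariate model")
        with np.errstate(divide="ignore", invalid="ignore"):
            b = sxy / sxx
            sigma2 = np.maximum(ssy - b * sxy, 0.0) / dof
            s = np.sqrt(sigma2 / sxx)
        beta[~mono] = b[~mono]
        se[~mono] = s[~mono]
    else:
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("logistic model requires a 0/1 trait")
        for j in range(m):
            if mono[j]:
                continue
            fit = _logistic_irls(np.column_stack([x_cov, g[:, j]]), y)
            if fit is not None:
                beta[j], se[j] = fit

    with np.errstate(invalid="ignore", divide="ignore"):
        p = 2.0 * stats.norm.sf(np.abs(beta / se))
    eaf = col_mean / 2.0
    v = geno.variants
    out = pd.DataFrame(
        {
            "variant_id": v["variant_id"],
            "chrom": v["chrom"],
            "pos": v["pos"],
            "effect_allele": v["alt"],
            "other_allele": v["ref"],
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "p": p,
            "n": n,
            "stratum": stratum_label,
        }
    )
    return out[SUMSTATS_COLUMNS]


def _logistic_irls(
    x: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-8
):
    """Newton/IRLS logistic fit; returns (beta, se) for the last column or
    None on non-convergence / separation."""
    k = x.shape[1]
    coef = np.zeros(k)
    for _ in range(max_iter):
        eta = np.clip(x @ coef, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        if w.max() < 1e-10:
            return None
        xtw = x.T * w
        try:
            step = np.linalg.solve(xtw @ x, x.T @ (y - mu))
        except np.linalg.LinAlgError:
            return None
        coef = coef + step
        if np.max(np.abs(step)) < tol:
            eta = np.clip(x @ coef, -30, 30)
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
            try:
                cov = np.linalg.inv((x.T * w) @ x)
            except np.linalg.LinAlgError:
                return None
            if cov[-1, -1] <= 0 or not np.isfinite(coef[-1]):
                return None
            return float(coef[-1]), float(np.sqrt(cov[-1, -1]))
    return None


# ---------------------------------------------------------------------------
# meta-analysis
# ---------------------------------------------------------------------------

def _meta_core(frames: list[pd.DataFrame], random_effects: bool) -> pd.DataFrame:
    merged = pd.concat(frames, ignore_index=True)
    merged = merged[merged["beta"].notna() & merged["se"].notna()]
    rows = []
    for vid, grp in merged.groupby("variant_id", sort=False):
        b = grp["beta"].to_numpy(float)
        s = grp["se"].to_numpy(float)
        k = len(b)
        w = 1.0 / (s * s)
        b_fe = float(np.sum(w * b) / np.sum(w))
        q = float(np.sum(w * (b - b_fe) ** 2))
        if random_effects and k > 1:
            denom = np.sum(w) - np.sum(w * w) / np.sum(w)
            tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
        else:
            tau2 = 0.0
        ws = 1.0 / (s * s + tau2)
        pooled_b = float(np.sum(ws * b) / np.sum(ws))
        pooled_se = float(1.0 / np.sqrt(np.sum(ws)))
        z = pooled_b / pooled_se
        rows.append(
            {
                "variant_id": vid,
                "beta": pooled_b,
                "se": pooled_se,
                "p": 2.0 * stats.norm.sf(abs(z)),
                "q_stat": q,
                "tau2": tau2,
                "k": k,
            }
        )
    out = pd.DataFrame(
        rows, columns=["variant_id", "beta", "se", "p", "q_stat", "tau2", "k"]
    )
    # carry positional metadata from the first source that has each variant
    meta_cols = merged.drop_duplicates("variant_id")[
        ["variant_id", "chrom", "pos", "effect_allele", "other_allele"]
    ]
    return out.merge(meta_cols, on="variant_id", how="left")


def random_effects_meta(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """DerSimonian-Laird random-effects pooling across strata.

    Weights are inverse-variance; tau^2 is the DL moment estimate
    ``max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))``; the pooled effect
    uses weights ``1 / (se^2 + tau^2)``. With a single stratum the input is
    returned with tau^2 = 0.
    """
    if not frames:
        raise ValueError("no strata to pool")
    return _meta_core(frames, random_effects=True)


def fixed_effects_meta(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Inverse-variance fixed-effects pooling (tau^2 fixed at zero)."""
    if not frames:
        raise ValueError("no strata to pool")
    return _meta_core(frames, random_effects=False)


# ---------------------------------------------------------------------------
# allele harmonization
# ---------------------------------------------------------------------------

def harmonize_alleles(
    stats_df: pd.DataFrame, reference: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Align effect/other alleles of ``stats_df`` to ``reference``.

    Variants are matched on chrom:pos. Swapped alleles flip the sign of beta
    and complement ``eaf``; strand flips are resolved via base complement;
    palindromic A/T and C/G variants with eaf in (0.4, 0.6) are ambiguous and
    dropped (outside that band the frequencies decide); anything else is
    irreconcilable and dropped. Returns the aligned frame and an audit count
    dict. The operation is idempotent.
    """
    ref = reference.set_index(
        reference["chrom"].astype(str) + ":" + reference["pos"].astype(str)
    )
    key = stats_df["chrom"].astype(str) + ":" + stats_df["pos"].astype(str)
    counts = {"kept": 0, "flipped": 0, "strand_fixed": 0,
              "ambiguous_dropped": 0, "irreconcilable": 0, "unmatched": 0}
    rows = []
    for (_, row), k in zip(stats_df.iterrows(), key):
        if k not in ref.index:
            counts["unmatched"] += 1
            continue
        r = ref.loc[k]
        ea, oa = row["effect_allele"], row["other_allele"]
        rea, roa = r["effect_allele"], r["other_allele"]
        pal = oa == _COMPLEMENT.get(ea)
        if pal:
            if 0.4 < row["eaf"] < 0.6:
                counts["ambiguous_dropped"] += 1
                continue
            if {ea, oa} != {rea, roa}:
                counts["irreconcilable"] += 1
                continue
            # frequency-based orientation: align minor/major status
            same_orientation = (row["eaf"] < 0.5) == (
                (r["eaf"] < 0.5) if (ea == rea) else (r["eaf"] > 0.5)
            )
            if ea == rea and same_orientation:
                counts["kept"] += 1
                rows.append(row)
            else:
                counts["flipped"] += 1
                rows.append(_flip(row, rea, roa))
            continue
        if (ea, oa) == (rea, roa):
            counts["kept"] += 1
            rows.append(row)
        elif (oa, ea) == (rea, roa):
            counts["flipped"] += 1
            rows.append(_flip(row, rea, roa))
        elif (_COMPLEMENT.get(ea), _COMPLEMENT.get(oa)) == (rea, roa):
            counts["strand_fixed"] += 1
            fixed = row.copy()
            fixed["effect_allele"], fixed["other_allele"] = rea, roa
            rows.append(fixed)
        elif (_COMPLEMENT.get(oa), _COMPLEMENT.get(ea)) == (rea, roa):
            counts["strand_fixed"] += 1
            rows.append(_flip(row, rea, roa))
        else:
            counts["irreconcilable"] += 1
    out = pd.DataFrame(rows).reset_index(drop=True) if rows else \
        stats_df.iloc[0:0].copy()
    return out, counts


def _flip(row: pd.Series, new_ea, new_oa) -> pd.Series:
    out = row.copy()
    out["effect_allele"], out["other_allele"] = new_ea, new_oa
    out["beta"] = -row["beta"]
    out["eaf"] = 1.0 - row["eaf"]
    return out


# ---------------------------------------------------------------------------
# stratified driver
# ---------------------------------------------------------------------------

def stratified_gwas(
    genotypes: GenotypeMatrix,
    cohort: pd.DataFrame,
    trait: str,
    model: str = "linear",
    strata_col: str = "stratum",
    covariate_names=("sex", "age", "site", "art"),
    n_pcs: int = 0,
) -> dict:
    """Per-stratum association plus random-effects pooling.

    Runs :func:`single_variant_assoc` within every non-empty stratum defined
    by ``cohort[strata_col]`` (PCs, when requested, are computed within the
    stratum) and pools the layers with DerSimonian-Laird. Returns
    ``{"per_stratum": {label: frame}, "meta": frame}``.
    """
    from .qc import compute_pcs

    per = {}
    for label, sub in cohort.groupby(strata_col):
        if len(sub) == 0:
            continue
        geno_s = genotypes.take_samples(list(sub["sample_id"]))
        covs = [c for c in covariate_names if c != strata_col and
                (c in sub.columns or c in ("sex_F", "age2"))]
        pcs = compute_pcs(geno_s, n_pcs=n_pcs) if n_pcs > 0 else None
        cov = encode_covariates(sub, covs, pcs=pcs) if (covs or pcs is not None) \
            else None
        if cov is not None:  # drop constant columns (single-site strata etc.)
            cov = cov.loc[:, cov.std() > 0]
            if cov.shape[1] == 0:
                cov = None
        per[label] = single_variant_assoc(
            geno_s, sub.set_index("sample_id")[trait], cov, model, str(label)
        )
    if not per:
        raise ValueError("no non-empty strata")
    meta = random_effects_meta(list(per.values()))
    return {"per_stratum": per, "meta": meta}


def genomic_inflation(p_values) -> float:
    """Genomic-control lambda: median association chi^2 over its null median."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))


def manhattan_table(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready (chrom, pos, -log10 p) table."""
    out = stats_df[["variant_id", "chrom", "pos"]].copy()
    with np.errstate(divide="ignore"):
        out["neglog10_p"] = -np.log10(stats_df["p"])
    return out
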