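"""Thresholding-pruning polygenic risk scores, multiethnic mixing, and
top-percentile risk stratification.

A PRS is the weighted sum of allele dosages over variants that survive a
GWAS p-value threshold (the conventional grid 1e-1 ... 1e-8) followed by
greedy LD pruning that removes redundant variants with r^2 >= 0.5 in a
reference genotype panel. The multiethnic score is the linear combination

    PRS_combined = alpha1 * PRS_EA + alpha2 * PRS_AA

whose mixing weights are the two score coefficients of a covariate-adjusted
linear regression fitted on validation data; performance is the incremental
adjusted R^2 of the two scores over the covariate-only model, averaged over
(case/control-stratified) ten-fold cross-validation in which the
target-ancestry GWAS is re-estimated on each 90% training split.

Top-percentile risk: samples at or above the (1-q) empirical score quantile
form the top group; disease odds ratios come from the resulting 2x2 table
with a Wald CI on the log odds (Haldane-Anscombe 0.5 correction when a cell
is empty) and BH-FDR across all (score, fraction) tests per disease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix
from .discover import bh_fdr
from .gwas import _logistic_irls, encode_covariates, single_variant_assoc
from .ld import greedy_select, pairwise_r2

log = logging.getLogger(__name__)

#: The conventional p-value threshold grid for PRS derivation.
PRS_THRESHOLDS = (1e-1, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6, 1e-7, 1e-8)

#: Default top-percentile fractions for risk stratification.
TOP_FRACTIONS = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)


@dataclass
class PrsModel:
    """A derived PRS: (variant, effect allele, weight) triples + provenance."""

    trait: str
    source: str
    threshold: float
    weights: pd.DataFrame  # variant_id, effect_allele, weight, source_p, eaf
    pruning: tuple = (0.5, "panel")  # (r2 cutoff, panel label)

    @property
    def n_variants(self) -> int:
        return len(self.weights)

    def to_tsv(self, path) -> None:
        self.weights.to_csv(path, sep="\t", index=False)


@dataclass
class MultiethnicPrs:
    """Cross-validated multiethnic PRS: components, mixing weights, CV record."""

    component_ea: PrsModel
    component_aa: PrsModel | None
    alpha1: float
    alpha2: float
    cv: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def mean_adjusted_r2(self) -> float:
        return float(self.cv["r2_multi"].mean()) if len(self.cv) else np.nan


# ---------------------------------------------------------------------------
# pruning and derivation
# ---------------------------------------------------------------------------

def ld_prune(
    sumstats: pd.DataFrame,
    panel: GenotypeMatrix,
    r2_cutoff: float = 0.5,
    strict: bool = False,
) -> tuple[list, dict]:
    """Greedy LD pruning by ascending p (ties: position, then id).

    A variant is dropped when its r^2 with an already-retained variant
    reaches the cutoff (``>=`` by default; ``>`` when ``strict``, the
    convention of the eQTL path). Variants absent from the panel carry no LD
    evidence and are retained with a warning. Returns (retained ids, audit).
    """
    work = sumstats.sort_values(
        ["p", "pos", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)
    panel_ids = pd.Index(panel.variants["variant_id"])
    in_panel = work["variant_id"].isin(panel_ids).to_numpy()
    n_missing = int((~in_panel).sum())
    if n_missing:
        log.warning("%d variants absent from the LD panel; retained", n_missing)
    sub = work[in_panel]
    retained = list(work.loc[~in_panel, "variant_id"])
    if len(sub):
        r2 = pairwise_r2(panel, list(sub["variant_id"]))
        kept = greedy_select(np.arange(len(sub)), r2, r2_cutoff, strict)
        retained.extend(sub["variant_id"].iloc[sorted(kept)])
    order = {v: i for i, v in enumerate(work["variant_id"])}
    retained.sort(key=order.get)
    return retained, {"n_in": len(work), "n_out": len(retained),
                      "n_no_panel": n_missing}


def derive_prs_weights(
    sumstats: pd.DataFrame,
    threshold: float,
    panel: GenotypeMatrix,
    trait: str = "trait",
    source: str = "sumstats",
    r2_cutoff: float = 0.5,
) -> PrsModel:
    """Thresholding-pruning weight derivation.

    Keeps variants with p < ``threshold``, LD-prunes the survivors (removal
    at r^2 >= ``r2_cutoff``), and takes the harmonized betas as weights. An
    empty model is returned (and logged) when nothing survives.
    """
    sel = sumstats[(sumstats["p"] < threshold) & sumstats["beta"].notna()]
    if len(sel) == 0:
        log.warning("PRS %s@%g: no variants survive the threshold", trait, threshold)
        weights = pd.DataFrame(
            columns=["variant_id", "effect_allele", "weight", "source_p", "eaf"]
        )
        return PrsModel(trait, source, threshold, weights, (r2_cutoff, "panel"))
    kept, _ = ld_prune(sel, panel, r2_cutoff=r2_cutoff, strict=False)
    sub = sel.set_index("variant_id").loc[kept]
    weights = pd.DataFrame(
        {
            "variant_id": kept,
            "effect_allele": sub["effect_allele"].to_numpy(),
            "weight": sub["beta"].to_numpy(),
            "source_p": sub["p"].to_numpy(),
            "eaf": sub["eaf"].to_numpy(),
        }
    )
    return PrsModel(trait, source, threshold, weights, (r2_cutoff, "panel"))


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score(model: PrsModel, genotypes: GenotypeMatrix,
          max_unmappable: float = 0.2) -> pd.Series:
    """Per-sample PRS: sum over model variants of dosage x weight.

    The model's effect allele is matched against the genotype ALT allele;
    swapped variants have their dosage reflected (2 - dosage). Missing
    dosages are mean-imputed as 2 x eaf from the model record. More than
    ``max_unmappable`` of model variants unmappable is an error.
    """
    if model.n_variants == 0:
        return pd.Series(0.0, index=genotypes.samples, name="prs")
    v = genotypes.variants.set_index("variant_id")
    total = np.zeros(genotypes.n_samples)
    n_unmappable = 0
    n_imputed = 0
    pos_of = pd.Index(genotypes.variants["variant_id"])
    for _, w in model.weights.iterrows():
        vid = w["variant_id"]
        if vid not in v.index:
            n_unmappable += 1
            continue
        j = pos_of.get_loc(vid)
        alt, ref = v.loc[vid, "alt"], v.loc[vid, "ref"]
        if w["effect_allele"] == alt:
            d = genotypes.dosages[:, j]
        elif w["effect_allele"] == ref:
            d = 2.0 - genotypes.dosages[:, j]
        else:
            n_unmappable += 1
            continue
        miss = np.isnan(d)
        if miss.any():
            n_imputed += int(miss.sum())
            d = np.where(miss, 2.0 * w["eaf"], d)
        total += d * w["weight"]
    if n_unmappable / model.n_variants > max_unmappable:
        raise ValueError(
            f"{n_unmappable}/{model.n_variants} model variants unmappable"
        )
    if n_imputed:
        log.info("mean-imputed %d missing dosages while scoring", n_imputed)
    return pd.Series(total, index=genotypes.samples, name="prs")


# ---------------------------------------------------------------------------
# mixing weights
# ---------------------------------------------------------------------------

def _ols_r2(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
    return coef, r2


def multiethnic_combine(
    prs_ea: pd.Series,
    prs_aa: pd.Series,
    phenotype: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """Fit mixing weights alpha1/alpha2 and the incremental adjusted R^2.

    The phenotype is regressed on both scores plus covariates; alpha1 and
    alpha2 are the two score coefficients. The reported R^2 is the
    incremental R^2 of the scores over the covariate-only model, adjusted as
    ``1 - (1 - R^2)(n - 1)/(n - k - 1)`` with k the number of full-model
    predictors. Collinear scores (|r| > 0.999) fall back to the EA-only
    model with alpha2 undefined, flagged.
    """
    idx = phenotype.dropna().index
    s1 = prs_ea.reindex(idx).to_numpy(float)
    s2 = prs_aa.reindex(idx).to_numpy(float)
    y = phenotype.reindex(idx).to_numpy(float)
    n = len(idx)
    cov = (
        covariates.reindex(idx).to_numpy(float)
        if covariates is not None
        else np.empty((n, 0))
    )
    base = np.column_stack([np.ones(n), cov])
    collinear = (
        s1.std() > 0 and s2.std() > 0
        and abs(np.corrcoef(s1, s2)[0, 1]) > 0.999
    ) or s2.std() == 0
    if collinear:
        x = np.column_stack([base, s1])
        coef, r2_full = _ols_r2(x, y)
        alpha1, alpha2 = float(coef[-1]), np.nan
    else:
        x = np.column_stack([base, s1, s2])
        coef, r2_full = _ols_r2(x, y)
        alpha1, alpha2 = float(coef[-2]), float(coef[-1])
    _, r2_cov = _ols_r2(base, y)
    r2_inc = max(0.0, r2_full - r2_cov)
    # penalise for the score degrees of freedom only: the covariates are
    # present in both the full and the baseline model and cancel out
    k = x.shape[1] - base.shape[1]
    r2_adj = 1.0 - (1.0 - r2_inc) * (n - 1) / (n - k - 1) if n - k - 1 > 0 \
        else np.nan
    return {
        "alpha1": alpha1,
        "alpha2": alpha2,
        "r2_incremental": r2_inc,
        "adjusted_r2": float(r2_adj),
        "collinear_fallback": bool(collinear),
        "n": n,
    }


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def stratified_folds(
    labels: pd.Series, k: int, seed: int, stratify: bool
) -> pd.Series:
    """Fold assignment (0..k-1) per sample; with ``stratify`` each fold
    preserves the case:control ratio to within one case."""
    rng = np.random.default_rng(seed)
    fold = pd.Series(-1, index=labels.index, dtype=int)
    groups = [labels.index] if not stratify else [
        labels.index[labels == v] for v in sorted(labels.unique())
    ]
    for idx in groups:
        perm = rng.permutation(len(idx))
        fold.loc[idx[perm]] = np.arange(len(idx)) % k
    return fold


def crossval_multiethnic(
    genotypes: GenotypeMatrix,
    cohort: pd.DataFrame,
    reference_sumstats: pd.DataFrame,
    trait: str,
    threshold: float = 1e-2,
    k: int = 10,
    seed: int = 0,
    target_stratum: str = "AA",
    binary: bool = False,
    covariate_names=("sex", "age", "age2", "art", "site"),
    n_pcs: int = 10,
    r2_cutoff: float = 0.5,
) -> MultiethnicPrs:
    """Ten-fold cross-validated multiethnic PRS in the target stratum.

    Per fold: a GWAS of the trait is re-estimated on the 90% training split
    of the target-ancestry sub-cohort (PCs computed on that stratum only),
    target-ancestry PRS weights are derived by thresholding-pruning, the
    reference-based PRS uses the external summary statistics, and the mixing
    weights plus incremental adjusted R^2 are evaluated on the held-out 10%.
    Binary traits use case/control-stratified folds. The reference-only
    adjusted R^2 is recorded per fold for comparison.
    """
    sub = cohort[cohort["stratum"] == target_stratum].reset_index(drop=True)
    geno_t = genotypes.take_samples(list(sub["sample_id"]))
    y = sub.set_index("sample_id")[trait]

    from .qc import compute_pcs

    n_pcs_eff = min(n_pcs, max(0, geno_t.n_samples - 2))
    pcs = compute_pcs(geno_t, n_pcs=n_pcs_eff) if n_pcs_eff > 0 else None
    cov = encode_covariates(sub, covariate_names, pcs=pcs)
    cov = cov.loc[:, cov.std() > 0]

    model_ea = derive_prs_weights(
        reference_sumstats, threshold, geno_t,
        trait=trait, source="reference", r2_cutoff=r2_cutoff,
    )
    s_ea_all = score(model_ea, geno_t)

    folds = stratified_folds(y, k, seed, stratify=binary)
    if binary:
        for f in range(k):
            if (y[folds == f] == 1).sum() == 0:
                raise ValueError(f"fold {f} has zero cases for trait {trait}")
    records = []
    model_aa = None
    for f in range(k):
        test_ids = folds.index[folds == f]
        train_ids = folds.index[folds != f]
        geno_tr = geno_t.take_samples(list(train_ids))
        fold_stats = single_variant_assoc(
            geno_tr,
            y.loc[train_ids],
            cov.reindex(train_ids),
            model="logistic" if binary else "linear",
            stratum_label=target_stratum,
        )
        model_aa = derive_prs_weights(
            fold_stats, threshold, geno_tr,
            trait=trait, source=f"{target_stratum}_fold{f}", r2_cutoff=r2_cutoff,
        )
        geno_te = geno_t.take_samples(list(test_ids))
        s_aa = score(model_aa, geno_te)
        s_ea = s_ea_all.reindex(test_ids)
        fit = multiethnic_combine(s_ea, s_aa, y.loc[test_ids], cov.reindex(test_ids))
        ea_only = multiethnic_combine(
            s_ea, pd.Series(0.0, index=test_ids), y.loc[test_ids],
            cov.reindex(test_ids),
        )
        records.append(
            {"fold": f, "alpha1": fit["alpha1"], "alpha2": fit["alpha2"],
             "r2_multi": fit["adjusted_r2"], "r2_ea_only": ea_only["adjusted_r2"],
             "n_test": len(test_ids), "n_variants_aa": model_aa.n_variants}
        )
    cv = pd.DataFrame(records)
    return MultiethnicPrs(
        component_ea=model_ea,
        component_aa=model_aa,
        alpha1=float(cv["alpha1"].mean()),
        alpha2=float(cv["alpha2"].mean()),
        cv=cv,
    )


# ---------------------------------------------------------------------------
# PRS-phenotype association matrix
# ---------------------------------------------------------------------------

def prs_phenotype_matrix(
    models: dict,
    genotypes: GenotypeMatrix,
    cohort: pd.DataFrame,
    phenotypes: list,
    covariates: pd.DataFrame | None = None,
    fdr: float = 0.10,
) -> pd.DataFrame:
    """Signed association z-matrix of every PRS model against every phenotype.

    ``models`` maps (trait, threshold) -> PrsModel. Each standardized score
    is tested against each phenotype with a covariate-adjusted linear
    (quantitative) or logistic (binary 0/1) model; BH flags at the given FDR
    are computed across all cells. Long-format output, one row per cell.
    """
    coh = cohort.set_index("sample_id")
    rows = []
    for (trait, threshold), model in models.items():
        s = score(model, genotypes)
        sd = s.std()
        s = (s - s.mean()) / sd if sd > 0 else s * 0.0
        for pheno in phenotypes:
            y = coh[pheno].dropna()
            if len(y) == 0:
                continue
            binary = set(pd.unique(y)) <= {0, 1}
            x_base = (
                covariates.reindex(y.index).to_numpy(float)
                if covariates is not None
                else np.empty((len(y), 0))
            )
            x = np.column_stack([np.ones(len(y)), x_base,
                                 s.reindex(y.index).to_numpy(float)])
            if binary:
                fit = _logistic_irls(x, y.to_numpy(float))
                if fit is None:
                    z = np.nan
                else:
                    z = fit[0] / fit[1]
            else:
                yv = y.to_numpy(float)
                coef, _ = _ols_r2(x, yv)
                resid = yv - x @ coef
                dof = len(y) - x.shape[1]
                sigma2 = float(resid @ resid) / dof
                xtx_inv = np.linalg.inv(x.T @ x)
                se = np.sqrt(sigma2 * xtx_inv[-1, -1])
                z = coef[-1] / se
            p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            rows.append(
                {"prs_trait": trait, "threshold": threshold,
                 "phenotype": pheno, "z": z, "p": p}
            )
    out = pd.DataFrame(rows)
    out["fdr_significant"] = False
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "fdr_significant"] = bh_fdr(out.loc[ok, "p"].to_numpy()) < fdr
    return out


# ---------------------------------------------------------------------------
# risk stratification
# ---------------------------------------------------------------------------

def risk_stratification(
    scores: pd.DataFrame | pd.Series,
    disease: pd.Series,
    top_fractions=TOP_FRACTIONS,
) -> pd.DataFrame:
    """Disease odds ratios for top-percentile score groups.

    ``scores`` is one column per score (a Series is treated as one column);
    for each (score, fraction), samples at or above the (1 - q) empirical
    quantile form the top group (ties included) and the odds ratio
    ``(a*d)/(b*c)`` is computed from the 2x2 of disease by group with a Wald
    95% CI on the log odds. When any cell is zero, the Haldane-Anscombe 0.5
    correction is applied and the row is flagged ``corrected``; rows with no
    cases at all are flagged non-estimable. BH-FDR runs across all rows.
    """
    if isinstance(scores, pd.Series):
        scores = scores.to_frame(scores.name or "score")
    disease = disease.reindex(scores.index)
    ok = disease.notna()
    d = disease[ok].astype(int)
    if d.sum() == 0 or (1 - d).sum() == 0:
        raise ValueError("need at least one case and one control")
    rows = []
    for name in scores.columns:
        s = scores.loc[ok.to_numpy(), name].astype(float)
        for q in top_fractions:
            thr = float(np.quantile(s, 1.0 - q))
            top = (s >= thr).to_numpy()
            a = int((d[top] == 1).sum())
            b = int((d[top] == 0).sum())
            c = int((d[~top] == 1).sum())
            dd = int((d[~top] == 0).sum())
            corrected = min(a, b, c, dd) == 0
            estimable = (a + c) > 0 and (b + dd) > 0
            aa, bb, cc, ddd = (
                (a + 0.5, b + 0.5, c + 0.5, dd + 0.5) if corrected
                else (a, b, c, dd)
            )
            or_ = (aa * ddd) / (bb * cc)
            se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / ddd)
            lo = np.exp(np.log(or_) - 1.959964 * se)
            hi = np.exp(np.log(or_) + 1.959964 * se)
            p = 2.0 * stats.norm.sf(abs(np.log(or_)) / se)
            rows.append(
                {"score": name, "top_fraction": q, "n_top": a + b,
                 "cases_top": a, "controls_top": b,
                 "cases_rest": c, "controls_rest": dd,
                 "odds_ratio": or_, "ci_lo": lo, "ci_hi": hi, "p": p,
                 "prevalence_top": a / (a + b) if (a + b) else np.nan,
                 "corrected": corrected, "estimable": estimable}
            )
    out = pd.DataFrame(rows)
    okp = out["p"].notna() & out["estimable"]
    out["fdr_adjusted_p"] = np.nan
    if okp.any():
        out.loc[okp, "fdr_adjusted_p"] = bh_fdr(out.loc[okp, "p"].to_numpy())
    return out


def meta_prs_r2(marginal: pd.DataFrame) -> dict:
    """Pooled PRS-trait R^2 from per-stratum standardized marginal effects.

    ``marginal`` has one row per stratum with columns ``beta`` (standardized
    coefficient) and ``se``. Inverse-variance (fixed-effects) pooling gives
    the pooled coefficient b; the pooled variance explained is b^2.
    """
    b = marginal["beta"].to_numpy(float)
    se = marginal["se"].to_numpy(float)
    if len(b) == 0:
        raise ValueError("no strata")
    if len(b) == 1:
        pooled = float(b[0])
    else:
        w = 1.0 / (se * se)
        pooled = float(np.sum(w * b) / np.sum(w))
    return {"pooled_beta": pooled, "r2": pooled * pooled}
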