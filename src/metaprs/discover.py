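"""Cohort-specific variant discovery and enrichment analyses.

A variant is called cohort-specific when it meets all three of: association
p < 0.01 in the target cohort, p >= 0.05 in the well-powered reference GWAS,
and non-overlapping 99% confidence intervals for the two beta coefficients
(intervals sharing even an endpoint count as overlapping — the conservative
reading). Both sources must be allele-harmonized and on comparable
standardized effect scales before the interval comparison.

Enrichment is tested two ways: a one-sided Fisher overrepresentation test of
hit genes against user-supplied GMT gene-set libraries, and a chi-squared
comparison of eSNP proportions between cohort-specific and remaining
variants after excluding variants associated in the reference GWAS
(p < 1e-6) and LD-pruning at r^2 > 0.2. Both apply Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix
from .ld import greedy_select, pairwise_r2

#: z quantile for a two-sided 99% confidence interval.
Z_995 = 2.5758293


# ---------------------------------------------------------------------------
# BH-FDR
# ---------------------------------------------------------------------------

def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``adj[(i)] = min_{j >= i} min(1, m * p[(j)] / j)`` over the sorted
    p-values; invariant under permutation of the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# specificity filter
# ---------------------------------------------------------------------------

def specific_variant_filter(
    cohort: pd.DataFrame,
    reference: pd.DataFrame,
    p_cohort: float = 0.01,
    p_reference: float = 0.05,
    ci_level: float = 0.99,
) -> pd.DataFrame:
    """Call cohort-specific variants by the dual p-threshold + CI rule.

    Returns one row per cohort variant with both sources' statistics, the
    two CIs, the boolean ``specific`` call and a ``reasons`` audit string.
    Variants absent from the reference are not callable.
    """
    z = float(stats.norm.ppf(0.5 + ci_level / 2.0)) if ci_level != 0.99 else Z_995
    ref = reference.set_index(
        reference["chrom"].astype(str) + ":" + reference["pos"].astype(str)
    )
    rows = []
    for _, row in cohort.iterrows():
        key = f"{row['chrom']}:{row['pos']}"
        rec = {
            "variant_id": row["variant_id"],
            "chrom": row["chrom"],
            "pos": row["pos"],
            "beta_cohort": row["beta"],
            "se_cohort": row["se"],
            "p_cohort": row["p"],
        }
        reasons = []
        if key not in ref.index:
            rec.update(
                beta_ref=np.nan, se_ref=np.nan, p_ref=np.nan,
                ci_cohort_lo=np.nan, ci_cohort_hi=np.nan,
                ci_ref_lo=np.nan, ci_ref_hi=np.nan,
                specific=False, reasons="absent_from_reference",
            )
            rows.append(rec)
            continue
        r = ref.loc[key]
        lo_c, hi_c = row["beta"] - z * row["se"], row["beta"] + z * row["se"]
        lo_r, hi_r = r["beta"] - z * r["se"], r["beta"] + z * r["se"]
        ok_cohort = bool(row["p"] < p_cohort)
        ok_ref = bool(r["p"] >= p_reference)
        disjoint = bool(hi_c < lo_r or hi_r < lo_c)  # touching = overlap
        if not ok_cohort:
            reasons.append("cohort_p_above_threshold")
        if not ok_ref:
            reasons.append("reference_p_significant")
        if not disjoint:
            reasons.append("ci_overlap")
        rec.update(
            beta_ref=r["beta"], se_ref=r["se"], p_ref=r["p"],
            ci_cohort_lo=lo_c, ci_cohort_hi=hi_c,
            ci_ref_lo=lo_r, ci_ref_hi=hi_r,
            specific=ok_cohort and ok_ref and disjoint,
            reasons=";".join(reasons) if reasons else "passed_all",
        )
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# clumping into independent loci
# ---------------------------------------------------------------------------

def independent_loci(
    calls: pd.DataFrame,
    genotypes: GenotypeMatrix,
    r2_max: float = 0.5,
    window_kb: float = 500.0,
) -> pd.DataFrame:
    """Greedy clumping of calls into LD-independent loci.

    Calls are visited by ascending cohort p (ties: position, then variant
    id); a call joins an existing locus when it lies within ``window_kb`` of
    the locus index variant and has r^2 > ``r2_max`` with it, otherwise it
    founds a new locus. Returns (locus, index_variant, variant_id) rows.
    """
    if len(calls) == 0:
        return pd.DataFrame(columns=["locus", "index_variant", "variant_id"])
    work = calls.sort_values(
        ["p_cohort", "pos", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)
    r2 = pairwise_r2(genotypes, list(work["variant_id"]))
    loci: list[dict] = []
    assignment = []
    for i, row in work.iterrows():
        placed = None
        for locus in loci:
            j = locus["order_idx"]
            same_chrom = str(row["chrom"]) == str(locus["chrom"])
            close = abs(row["pos"] - locus["pos"]) <= window_kb * 1000.0
            if same_chrom and close and r2[i, j] > r2_max:
                placed = locus
                break
        if placed is None:
            placed = {
                "locus": len(loci) + 1,
                "index_variant": row["variant_id"],
                "chrom": row["chrom"],
                "pos": row["pos"],
                "order_idx": i,
            }
            loci.append(placed)
        assignment.append(
            {
                "locus": placed["locus"],
                "index_variant": placed["index_variant"],
                "variant_id": row["variant_id"],
            }
        )
    return pd.DataFrame(assignment)


# ---------------------------------------------------------------------------
# gene-set overrepresentation
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict:
    """Parse a GMT gene-set library: one set per line, tab-separated
    (name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def gene_set_enrichment(
    hit_genes: set, library: dict, universe: set
) -> pd.DataFrame:
    """One-sided Fisher overrepresentation of ``hit_genes`` in each set.

    Each library set is intersected with the universe; the 2x2 table is
    (hit / non-hit) x (in-set / out-of-set) and the alternative is
    enrichment (depletion is not flagged). BH adjustment across sets;
    sorted by adjusted p.
    """
    if not universe:
        raise ValueError("empty gene universe")
    hits = set(hit_genes)
    if not hits <= set(universe):
        raise ValueError("hit_genes must be a subset of the universe")
    rows = []
    for name, genes in library.items():
        gs = set(genes) & set(universe)
        a = len(hits & gs)
        b = len(hits) - a
        c = len(gs) - a
        d = len(universe) - len(hits) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {"set": name, "n_hit_in_set": a, "n_hit_out": b,
             "n_other_in_set": c, "n_other_out": d,
             "odds_ratio": odds, "p": p}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr_adjusted_p"] = bh_fdr(out["p"].to_numpy())
        out = out.sort_values(
            ["fdr_adjusted_p", "p", "set"], kind="mergesort"
        ).reset_index(drop=True)
    return out


def variants_to_genes(
    variants: pd.DataFrame, gene_map: pd.DataFrame, max_distance: float = 100_000
) -> pd.Series:
    """Nearest gene within ``max_distance`` bp for each variant.

    ``gene_map`` is a BED-like frame (chrom, start, end, gene). Variants with
    no gene in range map to NaN.
    """
    out = []
    for _, row in variants.iterrows():
        sub = gene_map[gene_map["chrom"].astype(str) == str(row["chrom"])]
        if len(sub) == 0:
            out.append(np.nan)
            continue
        dist = np.maximum(
            sub["start"].to_numpy() - row["pos"],
            row["pos"] - sub["end"].to_numpy(),
        )
        dist = np.maximum(dist, 0)
        k = int(np.argmin(dist))
        out.append(sub["gene"].iloc[k] if dist[k] <= max_distance else np.nan)
    return pd.Series(out, index=variants["variant_id"].to_numpy(), name="gene")


# ---------------------------------------------------------------------------
# eQTL (eSNP) enrichment
# ---------------------------------------------------------------------------

def eqtl_enrichment(
    specific_ids,
    all_stats: pd.DataFrame,
    esnp_table: pd.DataFrame,
    reference: pd.DataFrame,
    panel: GenotypeMatrix,
    exclude_ref_p: float = 1e-6,
    prune_r2: float = 0.2,
) -> pd.DataFrame:
    """Per-condition chi-squared comparison of eSNP proportions.

    Pipeline per condition: (1) exclude variants with reference GWAS
    p < ``exclude_ref_p``; (2) LD-prune the survivors at r^2 > ``prune_r2``
    (greedy, ascending cohort p); (3) test the 2x2 of eSNP proportion among
    cohort-specific vs remaining variants with a 1-df chi-squared without
    continuity correction, falling back to Fisher's exact test (flagged) when
    any expected cell is below 5. BH adjustment across conditions.
    """
    ref_p = reference.set_index("variant_id")["p"]
    work = all_stats[["variant_id", "p"]].copy()
    work["ref_p"] = ref_p.reindex(work["variant_id"]).to_numpy()
    work = work[~(work["ref_p"] < exclude_ref_p)]

    order = np.argsort(
        work["p"].fillna(1.0).to_numpy(), kind="mergesort"
    )
    r2 = pairwise_r2(panel, list(work["variant_id"]))
    kept_idx = greedy_select(order, r2, prune_r2, strict=True)
    kept = work.iloc[sorted(kept_idx)]
    specific = set(specific_ids)
    is_spec = kept["variant_id"].isin(specific).to_numpy()

    flags = esnp_table.pivot_table(
        index="variant_id", columns="condition", values="esnp", aggfunc="first"
    )
    rows = []
    for cond in flags.columns:
        es = flags[cond].reindex(kept["variant_id"]).fillna(False).to_numpy(bool)
        a = int(np.sum(is_spec & es))
        b = int(np.sum(is_spec & ~es))
        c = int(np.sum(~is_spec & es))
        d = int(np.sum(~is_spec & ~es))
        table = np.array([[a, b], [c, d]], dtype=float)
        test = "chi2"
        if table.sum() == 0:
            stat, p = np.nan, np.nan
        else:
            expected = (
                table.sum(axis=1, keepdims=True)
                * table.sum(axis=0, keepdims=True)
                / table.sum()
            )
            if (expected < 5).any():
                test = "fisher_exact"
                odds_, p = stats.fisher_exact([[a, b], [c, d]])
                stat = np.nan
            else:
                stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        n_spec, n_rest = a + b, c + d
        odds = (a * d) / (b * c) if b * c > 0 else np.nan
        rows.append(
            {"condition": cond, "n_specific": n_spec, "n_rest": n_rest,
             "esnp_specific": a, "esnp_rest": c, "odds_ratio": odds,
             "statistic": stat, "p": p, "test": test}
        )
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["fdr_adjusted_p"] = np.nan
    if ok.any():
        out.loc[ok, "fdr_adjusted_p"] = bh_fdr(out.loc[ok, "p"].to_numpy())
    return out
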