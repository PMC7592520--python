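"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Dosages are expected alternate-allele counts in ``[0, 2]``; ``NaN`` marks a
  missing call.
* Variant coordinates are 1-based, as in VCF; the effect allele of any summary
  statistic produced here is the ALT allele.
* Summary statistics and cohort tables are plain :class:`pandas.DataFrame`
  objects with documented column sets (see :data:`SUMSTATS_COLUMNS` and
  :data:`COHORT_KEY_COLUMNS`); no wrapper class is imposed on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Column set of a summary-statistics frame (one row per variant).
SUMSTATS_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "p",
    "n",
    "stratum",
]

#: Identity / design columns every cohort table carries.
COHORT_KEY_COLUMNS = ["sample_id", "stratum", "sex", "age", "site", "art"]

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Per-sample, per-variant dosage matrix with variant metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_variants)`` float array of alternate-allele dosages in
        ``[0, 2]``; ``NaN`` marks missing calls.
    variants
        One row per variant with at least :data:`VARIANT_COLUMNS`; the
        synthetic generator adds per-stratum frequencies (``freq_<stratum>``),
        ``block`` ids and the per-stratum latent LD parameter
        (``ld_rho_<stratum>``).
    samples
        Sample identifiers, aligned with the rows of ``dosages``.
    strata
        Per-sample ancestry-stratum labels aligned with ``samples``.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.Index
    strata: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (samples x variants) array")
        self.samples = pd.Index(self.samples, name="sample_id")
        self.variants = self.variants.reset_index(drop=True)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if self.strata is None:
            self.strata = pd.Series("ALL", index=self.samples)
        else:
            self.strata = pd.Series(
                np.asarray(self.strata), index=self.samples
            )
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosages < 0) | (self.dosages > 2))
        if bad:
            raise ValueError("dosages outside [0, 2] detected")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> pd.Index:
        return pd.Index(self.variants["variant_id"])

    def take_variants(self, mask_or_ids) -> "GenotypeMatrix":
        """Subset by boolean mask over variants or an iterable of variant ids."""
        if isinstance(mask_or_ids, (pd.Series, np.ndarray, list)) and (
            len(mask_or_ids) == self.n_variants
            and np.asarray(mask_or_ids).dtype == bool
        ):
            idx = np.flatnonzero(np.asarray(mask_or_ids))
        else:
            pos = pd.Index(self.variants["variant_id"]).get_indexer(list(mask_or_ids))
            if (pos < 0).any():
                missing = [v for v, i in zip(mask_or_ids, pos) if i < 0]
                raise KeyError(f"unknown variant ids: {missing[:5]}")
            idx = pos
        return GenotypeMatrix(
            self.dosages[:, idx],
            self.variants.iloc[idx].reset_index(drop=True),
            self.samples,
            self.strata,
        )

    def take_samples(self, mask_or_ids) -> "GenotypeMatrix":
        """Subset by boolean mask over samples or an iterable of sample ids."""
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool and len(arr) == self.n_samples:
            idx = np.flatnonzero(arr)
        else:
            pos = self.samples.get_indexer(list(mask_or_ids))
            if (pos < 0).any():
                raise KeyError("unknown sample ids in subset request")
            idx = pos
        samples = self.samples[idx]
        return GenotypeMatrix(
            self.dosages[idx, :],
            self.variants,
            samples,
            self.strata.iloc[idx],
        )

    def stratum_samples(self, stratum: str) -> "GenotypeMatrix":
        return self.take_samples((self.strata == stratum).to_numpy())

    # -- statistics ------------------------------------------------------
    def allele_freq(self) -> np.ndarray:
        """Empirical ALT-allele frequency per variant (missing-aware)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def call_rate_variants(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def call_rate_samples(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def hard_calls(self, band: float = 0.1) -> np.ndarray:
        """Round dosages to genotypes {0,1,2}; calls farther than ``band``
        from an integer (or missing) become ``NaN``.

        HWE and identity-by-state are defined on genotypes, not expectations,
        so downstream QC works on these hard calls.
        """
        rounded = np.round(self.dosages)
        off = np.abs(self.dosages - rounded)
        calls = np.where(off <= band, rounded, np.nan)
        calls[np.isnan(self.dosages)] = np.nan
        return calls

    # -- text I/O ---------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write variants-in-rows dosage TSV (columns: metadata, then samples)."""
        body = pd.DataFrame(
            self.dosages.T, columns=self.samples, index=self.variants.index
        )
        out = pd.concat([self.variants, body], axis=1)
        out.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path, strata: pd.Series | None = None) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t")
        meta_cols = [c for c in df.columns if c in VARIANT_COLUMNS or
                     c.startswith(("freq_", "ld_")) or c == "block"]
        sample_cols = [c for c in df.columns if c not in meta_cols]
        return cls(
            df[sample_cols].to_numpy(dtype=float).T,
            df[meta_cols],
            pd.Index(sample_cols),
            strata,
        )


def validate_sumstats(stats: pd.DataFrame) -> pd.DataFrame:
    """Check the summary-statistics contract; returns the frame unchanged.

    Enforces column presence, ``eaf`` in (0,1) and Wald-consistency of ``p``
    with ``beta/se`` (1e-6 relative tolerance) on non-missing rows.
    """
    from scipy import stats as sps

    missing = [c for c in SUMSTATS_COLUMNS if c not in stats.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    ok = stats[["beta", "se", "p"]].notna().all(axis=1)
    sub = stats.loc[ok]
    if len(sub):
        if ((sub["eaf"] <= 0) | (sub["eaf"] >= 1)).any():
            raise ValueError("eaf outside (0,1) on rows with statistics")
        z = (sub["beta"] / sub["se"]).to_numpy()
        expected = 2.0 * sps.norm.sf(np.abs(z))
        got = sub["p"].to_numpy()
        denom = np.maximum(expected, 1e-300)
        if np.any(np.abs(got - expected) / denom > 1e-6):
            raise ValueError("p inconsistent with beta/se under the Wald rule")
    return stats
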