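"""Variant- and sample-level genotype quality control.

Filters applied (in this fixed order):

1. drop samples whose missing-call fraction is ``>= max_sample_missing``;
2. recompute per-variant statistics on the remaining samples;
3. drop variants with missing fraction ``> max_variant_missing``, minor
   allele frequency ``< min_maf``, or Hardy-Weinberg exact-test p-value
   ``< hwe_alpha``.

Boundary conventions mirror the strict/inclusive wording of the filters:
variant missingness and MAF are strict, sample missingness is inclusive.

The Hardy-Weinberg test is the two-sided exact test over heterozygote
counts conditional on the allele counts (Wigginton, Cutler & Abecasis
2005): ``p = sum of P(n'_AB) over all n'_AB with P(n'_AB) <= P(observed)``.
It is evaluated with a log-space recurrence and is stable for sample
totals well beyond 10^4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, TransformerMixin

from .datamodel import MISSING, validate_genotypes


@dataclass
class FilterParams:
    """Thresholds for :func:`apply_filters`; all fractions in [0, 1]."""

    max_variant_missing: float = 0.10
    min_maf: float = 0.05
    hwe_alpha: float = 0.01
    max_sample_missing: float = 0.15

    def validate(self) -> None:
        for name in ("max_variant_missing", "min_maf", "hwe_alpha", "max_sample_missing"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")


def variant_missingness(genotypes: np.ndarray) -> np.ndarray:
    """Fraction of MISSING calls per variant, in [0, 1]."""
    g = validate_genotypes(genotypes)
    if g.shape[0] < 1:
        raise ValueError("need at least one sample")
    return (g == MISSING).mean(axis=0)


def sample_missingness(genotypes: np.ndarray) -> np.ndarray:
    """Fraction of MISSING calls per sample, in [0, 1]."""
    g = validate_genotypes(genotypes)
    if g.shape[1] < 1:
        raise ValueError("need at least one variant")
    return (g == MISSING).mean(axis=1)


def alt_allele_freq(genotypes: np.ndarray) -> np.ndarray:
    """Per-variant alternate allele frequency among non-missing calls.

    Variants with no non-missing calls get NaN.
    """
    g = validate_genotypes(genotypes)
    obs = g != MISSING
    n_obs = obs.sum(axis=0)
    alt = np.where(obs, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)


def minor_allele_freq(genotypes: np.ndarray) -> np.ndarray:
    """Per-variant minor allele frequency min(p, 1-p) in [0, 0.5]; NaN when
    every call at the variant is missing."""
    p = alt_allele_freq(genotypes)
    return np.minimum(p, 1.0 - p)


def hwe_exact_test(n_AA: int, n_AB: int, n_BB: int) -> float:
    """Two-sided Hardy-Weinberg exact p-value for one genotype table.

    Conditional on the observed allele counts, heterozygote counts of the
    same parity are enumerated via a log-space recurrence; the p-value sums
    the probabilities of all outcomes no more likely than the observed one.
    A monomorphic table has a single possible outcome, hence p = 1.
    """
    if min(n_AA, n_AB, n_BB) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_AB + n_BB
    if n < 1:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_AA + n_AB
    n_rare = min(n_a, 2 * n - n_a)
    if n_rare == 0:
        return 1.0
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # log P(h+2) - log P(h) = log(4 * hom_rare(h) * hom_common(h)) - log((h+1)(h+2))
    h = hets[:-1].astype(np.float64)
    hom_rare = (n_rare - h) / 2.0
    hom_common = n - (n_rare + h) / 2.0
    log_ratio = np.log(4.0 * hom_rare * hom_common) - np.log((h + 1.0) * (h + 2.0))
    logw = np.concatenate(([0.0], np.cumsum(log_ratio)))
    logw -= logsumexp(logw)
    probs = np.exp(logw)
    obs_idx = (n_AB - hets[0]) // 2
    p = probs[probs <= probs[obs_idx] * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_pvalues(genotypes: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg exact p-value per variant (missing calls excluded).

    All-missing variants get p = NaN.
    """
    g = validate_genotypes(genotypes)
    out = np.empty(g.shape[1])
    for j in range(g.shape[1]):
        col = g[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            out[j] = np.nan
            continue
        out[j] = hwe_exact_test(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
    return out


class VariantQC(BaseEstimator, TransformerMixin):
    """Genotype QC as a (samples x variants) -> (samples' x variants') filter.

    Parameters mirror :class:`FilterParams`.  Fitted attributes:

    - ``sample_keep_``, ``variant_keep_`` — boolean masks;
    - ``sample_report_``, ``variant_report_`` — per-unit DataFrames with the
      computed statistics, pass flags and failure reasons.
    """

    def __init__(
        self,
        max_variant_missing: float = 0.10,
        min_maf: float = 0.05,
        hwe_alpha: float = 0.01,
        max_sample_missing: float = 0.15,
    ):
        self.max_variant_missing = max_variant_missing
        self.min_maf = min_maf
        self.hwe_alpha = hwe_alpha
        self.max_sample_missing = max_sample_missing

    def _params(self) -> FilterParams:
        p = FilterParams(
            self.max_variant_missing, self.min_maf, self.hwe_alpha, self.max_sample_missing
        )
        p.validate()
        return p

    def fit(self, X, y=None):
        params = self._params()
        g = validate_genotypes(X)
        n_samples, n_variants = g.shape

        smiss = sample_missingness(g)
        sample_keep = smiss < params.max_sample_missing  # >= threshold excluded
        self.sample_report_ = pd.DataFrame(
            {
                "sample_index": np.arange(n_samples),
                "missing_fraction": smiss,
                "pass": sample_keep,
                "reason": np.where(sample_keep, "", "sample_missingness"),
            }
        )
        if not sample_keep.any():
            raise ValueError(
                f"all {n_samples} samples removed by sample-missingness filter"
            )

        gk = g[sample_keep]
        vmiss = variant_missingness(gk)
        maf = minor_allele_freq(gk)
        hwe_p = hwe_pvalues(gk)

        reasons = []
        keep = np.ones(n_variants, dtype=bool)
        for j in range(n_variants):
            r = []
            if vmiss[j] > params.max_variant_missing:
                r.append("missingness")
            if np.isnan(maf[j]) or maf[j] < params.min_maf:
                r.append("maf")
            if not np.isnan(hwe_p[j]) and hwe_p[j] < params.hwe_alpha:
                r.append("hwe")
            if r:
                keep[j] = False
            reasons.append(",".join(r))
        self.variant_report_ = pd.DataFrame(
            {
                "variant_index": np.arange(n_variants),
                "missing_fraction": vmiss,
                "maf": maf,
                "hwe_p": hwe_p,
                "pass": keep,
                "reason": reasons,
            }
        )
        if not keep.any():
            raise ValueError(
                f"all {n_variants} variants removed "
                f"(missingness {int((vmiss > params.max_variant_missing).sum())}, "
                f"maf {int((np.nan_to_num(maf) < params.min_maf).sum())})"
            )
        self.sample_keep_ = sample_keep
        self.variant_keep_ = keep
        return self

    def transform(self, X):
        g = validate_genotypes(X)
        return g[self.sample_keep_][:, self.variant_keep_]


def apply_filters(genotypes: np.ndarray, params: FilterParams | None = None):
    """Run the full QC filter; returns (filtered matrix, fitted VariantQC)."""
    params = params or FilterParams()
    qc = VariantQC(
        params.max_variant_missing, params.min_maf, params.hwe_alpha, params.max_sample_missing
    ).fit(genotypes)
    return qc.transform(genotypes), qc
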