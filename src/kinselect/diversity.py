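"""Per-individual heterozygosity and method-of-moments genomic inbreeding.

The inbreeding coefficient is the classic excess-homozygosity moments
estimator:

    F̂_i = (O_hom,i − E_hom,i) / (L_i − E_hom,i)

where, over individual i's non-missing variants, the expected homozygote
count under Hardy-Weinberg is

    E_hom,i = Σ_l [ 1 − 2 p_l (1 − p_l) · 2n_l / (2n_l − 1) ]

with p_l the cohort alternate-allele frequency and n_l the number of
non-missing samples at variant l.  The 2n/(2n−1) factor corrects the
downward bias of plug-in expected heterozygosity at small sample size.
Negative values indicate heterozygosity excess and are reported as-is.

Allele frequencies come from the full post-QC cohort, not per subpopulation.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import MISSING, validate_genotypes
from .qc import alt_allele_freq

logger = logging.getLogger(__name__)


def het_rate(genotypes: np.ndarray) -> np.ndarray:
    """Heterozygous fraction per sample: (#g==1) / (#non-missing).

    A sample with no non-missing genotype is an error.
    """
    g = validate_genotypes(genotypes)
    obs = g != MISSING
    n_used = obs.sum(axis=1)
    if (n_used == 0).any():
        bad = int(np.flatnonzero(n_used == 0)[0])
        raise ValueError(f"sample index {bad} has no non-missing genotypes")
    return (g == 1).sum(axis=1) / n_used


def inbreeding_f(genotypes: np.ndarray) -> np.ndarray:
    """Method-of-moments genomic inbreeding coefficient F̂ per sample.

    Degenerate samples (denominator L − E_hom ≈ 0, e.g. all variants
    monomorphic) are reported as NaN.
    """
    g = validate_genotypes(genotypes)
    p = alt_allele_freq(g)
    obs = g != MISSING
    n_l = obs.sum(axis=0).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        e_l = 1.0 - 2.0 * p * (1.0 - p) * (2.0 * n_l / (2.0 * n_l - 1.0))
    e_l = np.nan_to_num(e_l, nan=0.0)  # all-missing variant contributes nothing
    hom = (g == 0) | (g == 2)
    o_hom = (hom & obs).sum(axis=1).astype(np.float64)
    e_hom = obs @ e_l
    l_used = obs.sum(axis=1).astype(np.float64)
    denom = l_used - e_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (o_hom - e_hom) / denom
    f[np.abs(denom) < 1e-9] = np.nan
    return f


def diversity_records(genotypes: np.ndarray, sample_ids=None) -> pd.DataFrame:
    """Per-sample table of heterozygosity and inbreeding statistics."""
    g = validate_genotypes(genotypes)
    obs = g != MISSING
    p = alt_allele_freq(g)
    n_l = obs.sum(axis=0).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        e_l = 1.0 - 2.0 * p * (1.0 - p) * (2.0 * n_l / (2.0 * n_l - 1.0))
    e_l = np.nan_to_num(e_l, nan=0.0)
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(g.shape[0])]
    return pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "n_used": obs.sum(axis=1),
            "het_rate": het_rate(g),
            "o_hom": ((g == 0) | (g == 2)).sum(axis=1),
            "e_hom": obs @ e_l,
            "f_hat": inbreeding_f(g),
        }
    )


def subpop_summary(
    values: np.ndarray, groups, value_name: str = "value"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subpopulation mean ± SD (n−1 denominator), min, max, and pairwise
    between-group tests.

    Both a Welch two-sided t-test (headline) and a two-sided Mann-Whitney U
    are reported for every group pair; pairs involving a group of size < 2
    are skipped with a warning.
    """
    values = np.asarray(values, dtype=np.float64)
    groups = pd.Series(list(groups))
    if groups.nunique() < 2:
        raise ValueError("need at least two subpopulations")
    rows = []
    for name, idx in groups.groupby(groups).groups.items():
        v = values[np.asarray(idx)]
        rows.append(
            {
                "subpopulation": name,
                "n": len(v),
                f"{value_name}_mean": v.mean(),
                f"{value_name}_sd": v.std(ddof=1) if len(v) > 1 else np.nan,
                f"{value_name}_min": v.min(),
                f"{value_name}_max": v.max(),
            }
        )
    summary = pd.DataFrame(rows).sort_values("subpopulation").reset_index(drop=True)

    pair_rows = []
    names = sorted(groups.unique())
    for a, b in combinations(names, 2):
        va = values[groups.to_numpy() == a]
        vb = values[groups.to_numpy() == b]
        if len(va) < 2 or len(vb) < 2:
            logger.warning("subpop_summary: group pair (%s, %s) too small, tests skipped", a, b)
            continue
        welch = stats.ttest_ind(va, vb, equal_var=False)
        mwu = stats.mannwhitneyu(va, vb, alternative="two-sided")
        pair_rows.append(
            {
                "group1": a,
                "group2": b,
                "welch_t": welch.statistic,
                "welch_p": welch.pvalue,
                "mannwhitney_u": mwu.statistic,
                "mannwhitney_p": mwu.pvalue,
            }
        )
    pairwise = pd.DataFrame(
        pair_rows,
        columns=["group1", "group2", "welch_t", "welch_p", "mannwhitney_u", "mannwhitney_p"],
    )
    return summary, pairwise
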