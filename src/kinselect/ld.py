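"""Windowed pairwise-r² linkage-disequilibrium pruning.

r² is the squared Pearson correlation of genotype counts (composite LD —
genotypes are unphased), computed with pairwise deletion of missing calls.
Pruning slides a window of ``window_size`` SNPs along each chromosome in
steps of ``step`` SNPs; within each window, while any kept pair exceeds the
r² threshold, the member of the first offending pair with the higher index
(later position) is removed.  The procedure is greedy and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datamodel import MISSING, validate_genotypes


@dataclass
class PruneParams:
    window_size: int = 50
    step: int = 5
    r2_threshold: float = 0.5

    def validate(self) -> None:
        if not (self.window_size > self.step >= 1):
            raise ValueError("require window_size > step >= 1")
        if not (0.0 < self.r2_threshold <= 1.0):
            raise ValueError("r2_threshold must be in (0, 1]")


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two genotype vectors.

    Loci where either value is MISSING are dropped.  Returns NaN when fewer
    than two complete pairs remain or either vector has zero variance
    (undefined; pruning treats NaN as 0).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("vectors must have the same length")
    ok = (x != MISSING) & (y != MISSING)
    x, y = x[ok], y[ok]
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _window_r2(g: np.ndarray) -> np.ndarray:
    """Pairwise r² matrix for all columns of g with pairwise missing deletion.

    Undefined entries (zero variance / <2 complete pairs) are 0.
    """
    m = (g != MISSING).astype(np.float64)
    x = np.where(g == MISSING, 0, g).astype(np.float64)
    n = m.T @ m
    sx = x.T @ m  # sx[i,j] = sum of x_i over loci complete for (i,j)
    sxx = (x * x).T @ m
    sxy = x.T @ x
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        varx = sxx - sx * sx / n
        r2 = cov * cov / (varx * varx.T)
    r2[~np.isfinite(r2)] = 0.0
    bad = n < 2
    r2[bad] = 0.0
    return r2


class LDPruner(BaseEstimator, TransformerMixin):
    """LD pruning as a variant-selection transformer.

    ``fit`` expects the genotype matrix and (optionally) the variant table,
    which supplies the per-chromosome grouping; without it all variants are
    treated as one chromosome.  Fitted attributes: ``support_`` (boolean
    mask over variants) and ``keep_`` (kept variant indices, ascending).
    """

    def __init__(self, window_size: int = 50, step: int = 5, r2_threshold: float = 0.5):
        self.window_size = window_size
        self.step = step
        self.r2_threshold = r2_threshold

    def fit(self, X, y=None, variants: pd.DataFrame | None = None):
        PruneParams(self.window_size, self.step, self.r2_threshold).validate()
        g = validate_genotypes(X)
        n_variants = g.shape[1]
        if variants is None:
            chrom = np.zeros(n_variants, dtype=int)
        else:
            if len(variants) != n_variants:
                raise ValueError("variant table length does not match genotype columns")
            chrom = pd.factorize(variants["chrom"])[0]
        keep = np.ones(n_variants, dtype=bool)
        for c in np.unique(chrom):
            idx = np.flatnonzero(chrom == c)
            self._prune_chromosome(g[:, idx], keep, idx)
        self.support_ = keep
        self.keep_ = np.flatnonzero(keep)
        return self

    def _prune_chromosome(self, g: np.ndarray, keep: np.ndarray, idx: np.ndarray) -> None:
        L = g.shape[1]
        w, step, thr = self.window_size, self.step, self.r2_threshold
        starts = range(0, L, step) if L <= w else range(0, L - w + step, step)
        for s in starts:
            e = min(s + w, L)
            local = np.arange(s, e)
            r2 = _window_r2(g[:, local])
            alive = keep[idx[local]].copy()
            changed = True
            while changed:
                changed = False
                live = np.flatnonzero(alive)
                for a in range(len(live)):
                    i = live[a]
                    js = live[a + 1 :]
                    over = js[r2[i, js] > thr]
                    if over.size:
                        alive[over[0]] = False  # drop later variant of first offending pair
                        changed = True
                        break
            keep[idx[local]] = alive

    def transform(self, X):
        g = validate_genotypes(X)
        return g[:, self.support_]


def prune(
    genotypes: np.ndarray,
    variants: pd.DataFrame | None = None,
    params: PruneParams | None = None,
) -> np.ndarray:
    """Return the kept-variant index list for the given pruning parameters."""
    params = params or PruneParams()
    pruner = LDPruner(params.window_size, params.step, params.r2_threshold)
    pruner.fit(genotypes, variants=variants)
    return pruner.keep_
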