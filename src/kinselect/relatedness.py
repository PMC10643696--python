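"""Pairwise IBS counts, method-of-moments IBD (Z0/Z1/Z2, Pi-Hat),
relationship classification, and classical MDS of the IBS distance matrix.

For a pair of individuals at a biallelic locus with alternate-allele
frequency p (q = 1 − p), the probabilities of the identity-by-state
configurations conditional on the identity-by-descent state are

    P(IBS0|Z0) = 2p²q²        P(IBS1|Z0) = 4p³q + 4pq³
    P(IBS2|Z0) = p⁴ + q⁴ + 4p²q²
    P(IBS0|Z1) = 0            P(IBS1|Z1) = 2pq
    P(IBS2|Z1) = p² + q²      P(IBS2|Z2) = 1

Accumulating these over the loci complete for the pair gives expected IBS
counts per IBD state, and the moments estimator solves for z0, z1, z2 in
sequence; the triple is clamped to [0,1] and renormalized to the simplex.
Pi-Hat = z2 + z1/2.  Plug-in cohort allele frequencies are used (no
finite-sample correction) — accuracy is validated by pedigree recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datamodel import MISSING, validate_genotypes
from .qc import alt_allele_freq

REL_CLASSES = ("duplicate_or_twin", "first_degree", "second_degree", "third_degree", "unrelated")


@dataclass
class RelationshipThresholds:
    """Pi-Hat cut points: duplicate is strict (>), the rest inclusive (>=)."""

    duplicate: float = 0.95
    first: float = 0.40
    second: float = 0.20
    third: float = 0.10

    def validate(self) -> None:
        seq = (self.duplicate, self.first, self.second, self.third)
        if not all(a > b for a, b in zip(seq, seq[1:])):
            raise ValueError("thresholds must be strictly decreasing")


def ibs_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int]:
    """IBS state counts for one pair; loci with either call MISSING excluded.

    IBS2 = equal genotypes, IBS0 = opposite homozygotes {0 vs 2}, IBS1
    otherwise.  Counts sum to the number of complete loci; zero complete
    loci is fatal.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    ok = (x != MISSING) & (y != MISSING)
    x, y = x[ok], y[ok]
    if x.size == 0:
        raise ValueError("no loci complete for the pair")
    ibs2 = int((x == y).sum())
    ibs0 = int((np.abs(x - y) == 2).sum())
    return ibs0, x.size - ibs2 - ibs0, ibs2


def ibd_moments(
    counts: tuple[int, int, int], freqs: np.ndarray
) -> tuple[float, float, float, float]:
    """Solve the moments equations for one pair.

    ``freqs`` are the cohort alternate-allele frequencies of exactly the
    loci complete for the pair (the loci the counts were taken over).
    Returns (z0, z1, z2, pi_hat).
    """
    p = np.asarray(freqs, dtype=np.float64)
    q = 1.0 - p
    e00 = float(np.sum(2 * p**2 * q**2))
    e10 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e20 = float(np.sum(p**4 + q**4 + 4 * p**2 * q**2))
    e11 = float(np.sum(2 * p * q))
    e21 = float(np.sum(p**2 + q**2))
    n_loci = float(p.size)
    if min(e00, e11) <= 0:
        raise ValueError("IBD expectations are non-positive (all loci monomorphic?)")
    n0, n1, n2 = counts
    z0 = n0 / e00
    z1 = (n1 - z0 * e10) / e11
    z2 = (n2 - z0 * e20 - z1 * e21) / n_loci
    z = np.clip([z0, z1, z2], 0.0, 1.0)
    z = z / z.sum()
    return float(z[0]), float(z[1]), float(z[2]), float(z[2] + 0.5 * z[1])


def classify_relationship(
    pi_hat: float, thresholds: RelationshipThresholds | None = None
) -> str:
    """Map Pi-Hat to the five-class relationship scale.

    > 0.95 duplicate/twin; >= 0.40 first degree; >= 0.20 second degree;
    >= 0.10 third degree; below that, unrelated.
    """
    t = thresholds or RelationshipThresholds()
    t.validate()
    if not (0.0 <= pi_hat <= 1.0):
        raise ValueError(f"pi_hat must be in [0,1], got {pi_hat}")
    if pi_hat > t.duplicate:
        return "duplicate_or_twin"
    if pi_hat >= t.first:
        return "first_degree"
    if pi_hat >= t.second:
        return "second_degree"
    if pi_hat >= t.third:
        return "third_degree"
    return "unrelated"


class IBDRelatedness(BaseEstimator):
    """All-pairs IBS/IBD relatedness over a genotype matrix.

    Fit computes, for every unordered sample pair, the IBS counts, the
    moments IBD triple, Pi-Hat and the relationship class, plus the IBS
    distance matrix D_ij = 1 − (IBS2 + 0.5·IBS1)/N_ij used for MDS.

    Fitted attributes: ``pairs_`` (DataFrame), ``distance_`` (n×n array),
    ``freqs_`` (allele frequencies used).
    """

    def __init__(self, thresholds: RelationshipThresholds | None = None):
        self.thresholds = thresholds

    def fit(self, X, y=None, sample_ids=None, allele_freqs=None):
        g = validate_genotypes(X)
        n = g.shape[0]
        if sample_ids is None:
            sample_ids = [f"S{i}" for i in range(n)]
        sample_ids = list(sample_ids)
        p = alt_allele_freq(g) if allele_freqs is None else np.asarray(allele_freqs, float)
        q = 1.0 - p

        ind = [(g == k).astype(np.float64) for k in (0, 1, 2)]
        m = ind[0] + ind[1] + ind[2]
        n_pair = m @ m.T
        ibs2 = ind[0] @ ind[0].T + ind[1] @ ind[1].T + ind[2] @ ind[2].T
        ibs0 = ind[0] @ ind[2].T + ind[2] @ ind[0].T
        ibs1 = n_pair - ibs2 - ibs0

        coeffs = {
            "e00": 2 * p**2 * q**2,
            "e10": 4 * p**3 * q + 4 * p * q**3,
            "e20": p**4 + q**4 + 4 * p**2 * q**2,
            "e11": 2 * p * q,
            "e21": p**2 + q**2,
        }
        exp = {k: (m * c) @ m.T for k, c in coeffs.items()}

        with np.errstate(invalid="ignore", divide="ignore"):
            z0 = ibs0 / exp["e00"]
            z1 = (ibs1 - z0 * exp["e10"]) / exp["e11"]
            z2 = (ibs2 - z0 * exp["e20"] - z1 * exp["e21"]) / n_pair
        iu = np.triu_indices(n, k=1)
        if np.any(n_pair[iu] == 0):
            i, j = iu[0][n_pair[iu] == 0][0], iu[1][n_pair[iu] == 0][0]
            raise ValueError(f"no complete loci for pair ({sample_ids[i]}, {sample_ids[j]})")
        if np.any(exp["e00"][iu] <= 0):
            raise ValueError("IBD expectations non-positive for some pair (monomorphic loci?)")
        z = np.stack([z0, z1, z2])
        z = np.clip(z, 0.0, 1.0)
        z = z / z.sum(axis=0)
        pi_hat = z[2] + 0.5 * z[1]

        thr = self.thresholds or RelationshipThresholds()
        rows = []
        for i, j in zip(*iu):
            rows.append(
                {
                    "id1": sample_ids[i],
                    "id2": sample_ids[j],
                    "n_ibs0": int(ibs0[i, j]),
                    "n_ibs1": int(ibs1[i, j]),
                    "n_ibs2": int(ibs2[i, j]),
                    "z0": z[0, i, j],
                    "z1": z[1, i, j],
                    "z2": z[2, i, j],
                    "pi_hat": pi_hat[i, j],
                    "rel_class": classify_relationship(float(pi_hat[i, j]), thr),
                }
            )
        self.pairs_ = pd.DataFrame(rows)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = 1.0 - (ibs2 + 0.5 * ibs1) / n_pair
        np.fill_diagonal(dist, 0.0)
        self.distance_ = dist
        self.freqs_ = p
        self.sample_ids_ = sample_ids
        return self


def pairwise_relatedness(
    genotypes: np.ndarray,
    sample_ids=None,
    thresholds: RelationshipThresholds | None = None,
    allele_freqs=None,
):
    """Convenience wrapper: returns (pairs DataFrame, IBS distance matrix)."""
    est = IBDRelatedness(thresholds).fit(
        genotypes, sample_ids=sample_ids, allele_freqs=allele_freqs
    )
    return est.pairs_, est.distance_


def mds_embed(dist: np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centers −½·D², eigendecomposes, and returns the top-``dims``
    coordinates scaled by the square roots of the (non-negative)
    eigenvalues.  Sign convention: the first nonzero loading of each
    dimension is positive, making the embedding deterministic.
    """
    d = np.asarray(dist, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(lam)
    for k in range(coords.shape[1]):
        col = coords[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, k] = -col
    return coords


class ClassicalMDS(BaseEstimator):
    """Torgerson MDS as an estimator over a precomputed distance matrix."""

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        self.embedding_ = mds_embed(X, self.n_components)
        return self

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self.embedding_


def pair_matrix(
    pairs: pd.DataFrame,
    row_ids,
    col_ids,
    value: str = "pi_hat",
    percent: bool = True,
) -> pd.DataFrame:
    """Rectangular export of a pair statistic (e.g. males × females Pi-Hat
    heatmap, as percentages); rows/columns in the given deterministic order."""
    lut = {}
    for _, r in pairs.iterrows():
        lut[(r["id1"], r["id2"])] = r[value]
        lut[(r["id2"], r["id1"])] = r[value]
    scale = 100.0 if percent else 1.0
    data = [[lut.get((a, b), np.nan) * scale for b in col_ids] for a in row_ids]
    return pd.DataFrame(data, index=list(row_ids), columns=list(col_ids))
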