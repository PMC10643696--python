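"""Sliding-window detection of runs of homozygosity (ROH).

The detector follows the classic SNP-window scheme: a fixed-size window of
consecutive SNPs slides one SNP at a time along each chromosome; a window
is called homozygous when it contains at most ``max_opp_window``
heterozygous calls and at most ``max_miss_window`` missing calls.  Each SNP
is then scored by the proportion of overlapping windows called homozygous,
and SNPs whose proportion exceeds ``threshold`` form candidate runs.  Runs
are split at inter-SNP gaps larger than ``max_gap`` and kept only when they
satisfy the minimum SNP count, minimum physical length and minimum SNP
density.  Only full windows of ``window_size`` SNPs are formed (no
truncated windows at chromosome edges).

Default parameters: windowSize 15, threshold 0.05, minSNP 20,
maxOppWindow 1, maxMissWindow 1, maxGap 1 Mb, minLengthBps 250 kb,
minDensity 1 SNP per Mb (1/1000 per kb); opposite/missing calls inside a
run are unbounded.

Downstream statistics: F_ROH (ROH-covered fraction of the SNP map extent),
five length-class bins (0-6, 6-12, 12-24, 24-48, > 48 Mb), and the
generations-to-common-ancestor dating g = 100/(2 r L) with the deer
recombination rate r = 1.04 cM/Mb and L the tract length in Mb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datamodel import MISSING, validate_genotypes

logger = logging.getLogger(__name__)

LENGTH_CLASS_EDGES_MB = (0.0, 6.0, 12.0, 24.0, 48.0, np.inf)
LENGTH_CLASS_LABELS = ("0-6Mb", "6-12Mb", "12-24Mb", "24-48Mb", ">48Mb")


@dataclass
class ROHParams:
    window_size: int = 15
    threshold: float = 0.05
    min_snp: int = 20
    max_opp_window: int = 1
    max_miss_window: int = 1
    max_gap: int = 1_000_000
    min_length_bps: int = 250_000
    min_density: float = 1.0 / 1000.0  # SNPs per kb of run length

    def validate(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        for name in (
            "threshold",
            "min_snp",
            "max_opp_window",
            "max_miss_window",
            "max_gap",
            "min_length_bps",
            "min_density",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class GenerationModel:
    """g = 100 / (2 r L): generations to the common ancestor that produced a
    ROH of length L Mb at recombination rate r cM/Mb."""

    r: float = 1.04

    def validate(self) -> None:
        if self.r <= 0:
            raise ValueError("recombination rate must be positive")


def generations_to_ancestor(length_mb: float, model: GenerationModel | None = None) -> float:
    """Expected generations back to the ancestor implied by a ROH tract."""
    model = model or GenerationModel()
    model.validate()
    if length_mb <= 0:
        raise ValueError("tract length must be positive (Mb)")
    return 100.0 / (2.0 * model.r * length_mb)


def _runs_one_chromosome(
    g: np.ndarray, pos: np.ndarray, params: ROHParams
) -> list[tuple[int, int, int]]:
    """Candidate+filtered runs for one sample on one chromosome.

    Returns (start_idx, end_idx, n_snps) over local SNP indices.
    """
    L = g.size
    w = params.window_size
    if L < w:
        logger.warning("chromosome with %d SNPs < window size %d: no runs", L, w)
        return []
    het = (g == 1).astype(np.int32)
    mis = (g == MISSING).astype(np.int32)
    ch = np.concatenate(([0], np.cumsum(het)))
    cm = np.concatenate(([0], np.cumsum(mis)))
    starts = np.arange(0, L - w + 1)
    homo = (ch[starts + w] - ch[starts] <= params.max_opp_window) & (
        cm[starts + w] - cm[starts] <= params.max_miss_window
    )
    homo_c = np.concatenate(([0], np.cumsum(homo.astype(np.int64))))
    j = np.arange(L)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, L - w)
    n_cover = hi - lo + 1
    n_homo = homo_c[hi + 1] - homo_c[lo]
    in_run = n_homo / n_cover > params.threshold

    runs: list[tuple[int, int, int]] = []
    i = 0
    while i < L:
        if not in_run[i]:
            i += 1
            continue
        start = i
        while i + 1 < L and in_run[i + 1] and (pos[i + 1] - pos[i]) <= params.max_gap:
            i += 1
        runs.append((start, i, i - start + 1))
        i += 1
    kept = []
    for s, e, n in runs:
        length = int(pos[e] - pos[s])
        if n < params.min_snp or length < params.min_length_bps:
            continue
        if n / (length / 1000.0) < params.min_density:
            continue
        kept.append((s, e, n))
    return kept


def detect_roh(
    genotypes: np.ndarray,
    variants: pd.DataFrame,
    params: ROHParams | None = None,
    sample_ids=None,
) -> pd.DataFrame:
    """Detect ROH for every sample.

    Returns a DataFrame with columns sample_id, chrom, start_pos, end_pos,
    n_snps, length_bp, length_class, g_estimate.  Positions are the 1-based
    coordinates of the terminal SNPs; length_bp = end_pos − start_pos.
    """
    params = params or ROHParams()
    params.validate()
    g = validate_genotypes(genotypes)
    if len(variants) != g.shape[1]:
        raise ValueError("variant table does not match genotype columns")
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(g.shape[0])]
    rows = []
    for chrom, grp in variants.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        for si, sid in enumerate(sample_ids):
            for s, e, n in _runs_one_chromosome(g[si, idx], pos, params):
                length = int(pos[e] - pos[s])
                rows.append(
                    {
                        "sample_id": sid,
                        "chrom": chrom,
                        "start_pos": int(pos[s]),
                        "end_pos": int(pos[e]),
                        "n_snps": n,
                        "length_bp": length,
                        "length_class": bin_length_class(length / 1e6),
                        "g_estimate": generations_to_ancestor(length / 1e6),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "chrom",
            "start_pos",
            "end_pos",
            "n_snps",
            "length_bp",
            "length_class",
            "g_estimate",
        ],
    )


class ROHDetector(BaseEstimator):
    """Estimator wrapper: fit stores ``segments_`` and per-sample ``froh_``."""

    def __init__(self, params: ROHParams | None = None):
        self.params = params

    def fit(self, X, y=None, variants: pd.DataFrame | None = None, sample_ids=None):
        if variants is None:
            raise ValueError("ROH detection requires the variant table (positions)")
        if sample_ids is None:
            sample_ids = [f"S{i}" for i in range(np.asarray(X).shape[0])]
        self.segments_ = detect_roh(X, variants, self.params, sample_ids)
        self.froh_ = pd.Series(
            {sid: f_roh(self.segments_[self.segments_["sample_id"] == sid], variants)
             for sid in sample_ids},
            name="froh",
        )
        return self


def map_extent(variants: pd.DataFrame) -> int:
    """Total SNP-covered map length: Σ per chromosome (max pos − min pos)."""
    if len(variants) == 0:
        raise ValueError("empty SNP map")
    ext = variants.groupby("chrom")["pos"].agg(lambda p: p.max() - p.min()).sum()
    return int(ext)


def f_roh(segments: pd.DataFrame, variants: pd.DataFrame, genome_length: int | None = None) -> float:
    """F_ROH = total ROH length / genome length.

    The denominator defaults to the SNP-covered map extent; pass
    ``genome_length`` to use an assembly size instead.
    """
    denom = genome_length if genome_length is not None else map_extent(variants)
    if denom <= 0:
        raise ValueError("genome length must be positive")
    total = int(segments["length_bp"].sum()) if len(segments) else 0
    return total / denom


def bin_length_class(length_mb: float) -> str:
    """Assign one of the five half-open length classes [0,6), [6,12),
    [12,24), [24,48), [48,inf) Mb."""
    if length_mb <= 0:
        raise ValueError("length must be positive")
    for lo, hi, lab in zip(LENGTH_CLASS_EDGES_MB[:-1], LENGTH_CLASS_EDGES_MB[1:], LENGTH_CLASS_LABELS):
        if lo <= length_mb < hi:
            return lab
    raise AssertionError("unreachable")


def bin_length_classes(segments: pd.DataFrame) -> pd.Series:
    """Count segments per length class (all five classes always present)."""
    counts = pd.Series(0, index=list(LENGTH_CLASS_LABELS), dtype=int)
    if len(segments):
        vc = segments["length_class"].value_counts()
        counts.update(vc)
    return counts
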