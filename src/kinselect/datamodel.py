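"""Shared data model: genotype matrix, variant map and sample metadata.

The currency of every analysis stage is a trio of objects:

* ``GenotypeMatrix`` — a 2-D ``int8`` array of shape (samples, variants)
  holding alternate-allele counts {0, 1, 2} with :data:`MISSING` (= -1) as a
  distinct sentinel for no-calls.  ``MISSING`` is never conflated with the
  homozygous-reference genotype 0.
* ``VariantTable`` — a :class:`pandas.DataFrame` with columns
  ``chrom, pos, ref, alt, vid``; positions are 1-based and strictly
  increasing within each chromosome after loading.
* ``SampleTable`` — a :class:`pandas.DataFrame` with columns
  ``sample_id, sex, subpopulation, organization``.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call.  Kept negative so it can never be
#: mistaken for an allele count.
MISSING: int = -1

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "vid"]
SAMPLE_COLUMNS = ["sample_id", "sex", "subpopulation", "organization"]

_SEX_MAP = {"m": "male", "male": "male", "f": "female", "female": "female"}


def normalize_sex(value: object) -> str:
    """Map free-text sex labels to {male, female, unknown}.

    Accepts ``m/male/f/female`` case-insensitively; anything else (including
    empty or NaN) becomes ``unknown``.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "unknown"
    return _SEX_MAP.get(str(value).strip().lower(), "unknown")


def natural_chrom_key(label: str) -> tuple:
    """Sort key giving natural order of chromosome labels (chr2 < chr10)."""
    parts = re.split(r"(\d+)", str(label))
    return tuple(int(p) if p.isdigit() else p for p in parts)


def make_variant_table(
    chrom: Sequence[str],
    pos: Sequence[int],
    ref: Sequence[str] | None = None,
    alt: Sequence[str] | None = None,
    vid: Sequence[str] | None = None,
) -> pd.DataFrame:
    n = len(pos)
    if ref is None:
        ref = ["A"] * n
    if alt is None:
        alt = ["G"] * n
    if vid is None:
        vid = [f"{c}:{p}" for c, p in zip(chrom, pos)]
    df = pd.DataFrame(
        {
            "chrom": np.asarray(chrom, dtype=object),
            "pos": np.asarray(pos, dtype=np.int64),
            "ref": np.asarray(ref, dtype=object),
            "alt": np.asarray(alt, dtype=object),
            "vid": np.asarray(vid, dtype=object),
        }
    )
    return df


def sort_variants(
    variants: pd.DataFrame, genotypes: np.ndarray | None = None
) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Stable sort by (natural chromosome order, position).

    Returns the sorted variant table (index reset) and the genotype matrix
    with columns reordered to match.
    """
    keys = [natural_chrom_key(c) for c in variants["chrom"]]
    order = pd.Series(range(len(variants))).iloc[
        np.lexsort((variants["pos"].to_numpy(), pd.Series(keys).rank(method="dense").to_numpy()))
    ]
    # np.lexsort is stable; dense rank preserves the natural key order.
    idx = order.to_numpy()
    out_v = variants.iloc[idx].reset_index(drop=True)
    out_g = genotypes[:, idx] if genotypes is not None else None
    return out_v, out_g


def validate_variant_table(variants: pd.DataFrame) -> None:
    missing_cols = set(VARIANT_COLUMNS) - set(variants.columns)
    if missing_cols:
        raise ValueError(f"variant table missing columns: {sorted(missing_cols)}")
    for _, grp in variants.groupby("chrom", sort=False):
        p = grp["pos"].to_numpy()
        if np.any(np.diff(p) <= 0):
            raise ValueError("positions not strictly increasing within a chromosome")
    for col in ("ref", "alt"):
        bad = variants[~variants[col].astype(str).str.fullmatch("[ACGTacgt]")]
        if len(bad):
            raise ValueError(f"non-SNP allele in column {col!r}: {bad[col].iloc[0]!r}")


def validate_genotypes(genotypes: np.ndarray) -> np.ndarray:
    g = np.asarray(genotypes)
    if g.ndim != 2:
        raise ValueError("genotype matrix must be 2-D (samples x variants)")
    ok = np.isin(g, (0, 1, 2, MISSING))
    if not ok.all():
        bad = g[~ok].ravel()[0]
        raise ValueError(f"genotype value out of domain {{0,1,2,{MISSING}}}: {bad}")
    return g.astype(np.int8, copy=False)


def make_sample_table(
    sample_ids: Iterable[str],
    sex: Iterable[str] | None = None,
    subpopulation: Iterable[str] | None = None,
    organization: Iterable[str] | None = None,
) -> pd.DataFrame:
    ids = list(sample_ids)
    n = len(ids)
    df = pd.DataFrame(
        {
            "sample_id": ids,
            "sex": [normalize_sex(s) for s in (sex if sex is not None else ["unknown"] * n)],
            "subpopulation": list(subpopulation) if subpopulation is not None else ["NA"] * n,
            "organization": list(organization) if organization is not None else ["NA"] * n,
        }
    )
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id: {dup!r}")
    return df


def check_dimensions(
    variants: pd.DataFrame, samples: pd.DataFrame, genotypes: np.ndarray
) -> None:
    if genotypes.shape != (len(samples), len(variants)):
        raise ValueError(
            f"genotype matrix shape {genotypes.shape} does not match "
            f"{len(samples)} samples x {len(variants)} variants"
        )
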