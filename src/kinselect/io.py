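"""Reading and writing genotype data.

VCF input goes through :mod:`cyvcf2`; only biallelic SNP records with a GT
field are retained.  Output is plain-text VCF 4.2 with unphased genotypes.
Sample metadata is a tab-separated table with a header row.

Coordinates are 1-based and inclusive throughout, as in VCF.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datamodel import (
    MISSING,
    check_dimensions,
    make_sample_table,
    normalize_sex,
    sort_variants,
    validate_genotypes,
)

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


def read_vcf(path: str, region_filter: set[str] | None = None):
    """Load a multi-sample VCF into the shared data model.

    Multiallelic and non-SNP records are skipped (count logged).  ``./.``,
    ``.`` and half-calls such as ``0/.`` all become :data:`MISSING`; phased
    and unphased genotypes are treated identically.

    Returns
    -------
    (variants, samples, genotypes)
        Variant table sorted by (chromosome, position), a stub sample table
        (sex/subpopulation unknown until metadata is attached), and the
        samples x variants genotype matrix.
    """
    if not os.path.exists(path):
        raise IOError(f"cannot read VCF: {path!r} does not exist")
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # cyvcf2 raises bare Exception on parse failure
        raise ValueError(f"cannot parse VCF {path!r}: {exc}") from exc
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise ValueError(f"VCF {path!r} contains no samples")

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    vids: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for v in vcf:
        if region_filter is not None and v.CHROM not in region_filter:
            n_skipped += 1
            continue
        if (
            len(v.ALT) != 1
            or len(v.REF) != 1
            or len(v.ALT[0]) != 1
            or v.REF.upper() not in _BASES
            or v.ALT[0].upper() not in _BASES
        ):
            n_skipped += 1
            continue
        gt = np.asarray(v.genotype.array())  # (n_samples, ploidy+1); last col = phased flag
        alleles = gt[:, :2]
        g = alleles.sum(axis=1).astype(np.int8)
        g[(alleles < 0).any(axis=1)] = MISSING  # no-calls and half-calls
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        vids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        rows.append(g)
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP/filtered records", n_skipped)

    variants = pd.DataFrame(
        {"chrom": chroms, "pos": np.asarray(poss, dtype=np.int64), "ref": refs, "alt": alts, "vid": vids}
    )
    genotypes = (
        np.vstack(rows).T.astype(np.int8) if rows else np.empty((len(sample_ids), 0), np.int8)
    )
    variants, genotypes = sort_variants(variants, genotypes)
    samples = make_sample_table(sample_ids)
    return variants, samples, validate_genotypes(genotypes)


def read_metadata(path: str) -> pd.DataFrame:
    """Read the sample metadata table (TSV with header).

    Required columns: ``sample_id, sex, subpopulation``; ``organization`` is
    optional.  Duplicate sample ids are fatal.  Sex labels are normalized to
    {male, female, unknown}; unrecognized values are flagged with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"sample_id", "sex", "subpopulation"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing required columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id in metadata: {dup!r}")
    raw_sex = df["sex"].copy()
    df["sex"] = [normalize_sex(s) for s in df["sex"]]
    unknown = df["sex"] == "unknown"
    if unknown.any():
        logger.warning(
            "read_metadata: %d sample(s) with unknown sex (e.g. %r)",
            int(unknown.sum()),
            raw_sex[unknown].iloc[0],
        )
    if "organization" not in df.columns:
        df["organization"] = "NA"
    return df[["sample_id", "sex", "subpopulation", "organization"]]


def attach_metadata(vcf_samples: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Join metadata onto VCF sample order; a VCF sample absent from the
    metadata is fatal (named in the error)."""
    meta = metadata.set_index("sample_id")
    out = []
    for sid in vcf_samples["sample_id"]:
        if sid not in meta.index:
            raise ValueError(f"sample {sid!r} present in VCF but absent from metadata")
        rec = meta.loc[sid]
        out.append((sid, rec["sex"], rec["subpopulation"], rec["organization"]))
    return pd.DataFrame(out, columns=["sample_id", "sex", "subpopulation", "organization"])


def write_vcf(path: str, variants: pd.DataFrame, samples: pd.DataFrame, genotypes: np.ndarray) -> None:
    """Write VCF 4.2 with unphased GT; MISSING is written as ``./.``.

    Records are emitted in deterministic (chromosome, position) order.
    """
    genotypes = validate_genotypes(genotypes)
    check_dimensions(variants, samples, genotypes)
    variants, genotypes = sort_variants(variants, genotypes)
    gt_str = np.array(["0/0", "0/1", "1/1"], dtype=object)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=kinselect\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, grp in variants.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(grp['pos'].max()) + 1}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples["sample_id"])
            + "\n"
        )
        for j in range(len(variants)):
            v = variants.iloc[j]
            col = genotypes[:, j]
            fields = np.where(col == MISSING, "./.", gt_str[np.clip(col, 0, 2)])
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['vid']}\t{v['ref']}\t{v['alt']}\t.\t.\t.\tGT\t"
                + "\t".join(fields)
                + "\n"
            )


def write_tsv(path: str, df: pd.DataFrame, comment_lines: Iterable[str] = ()) -> None:
    """Write a report table as TSV with optional '#'-prefixed comment lines."""
    with open(path, "w") as fh:
        for line in comment_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
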