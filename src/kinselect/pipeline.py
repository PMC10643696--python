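"""End-to-end orchestration: QC -> LD pruning -> diversity -> relatedness ->
ROH -> admixture -> purity -> breeder recommendation.

Every artifact is a TSV written into a stage subfolder of the run
directory, recorded in an append-only manifest (file, rows, sha256).  All
randomness flows through one master seed recorded in the manifest, so a
rerun with identical config reproduces identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as kio
from .ancestry import AdmixtureEM, align_clusters, choose_k, purity_calls
from .breeder import PoolSpec, breeder_report
from .datamodel import MISSING
from .diversity import diversity_records, subpop_summary
from .ld import LDPruner, PruneParams
from .qc import FilterParams, VariantQC
from .relatedness import IBDRelatedness, RelationshipThresholds, mds_embed, pair_matrix
from .roh import ROHParams, bin_length_classes, detect_roh, f_roh

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    vcf: str
    metadata: str
    outdir: str
    filter_params: FilterParams = field(default_factory=FilterParams)
    prune_params: PruneParams = field(default_factory=PruneParams)
    roh_params: ROHParams = field(default_factory=ROHParams)
    thresholds: RelationshipThresholds = field(default_factory=RelationshipThresholds)
    k_values: tuple[int, ...] = (1, 2, 3)
    cv_folds: int = 3
    n_restarts: int = 3
    purity_tol: float = 0.001
    admix_flag: float = 0.40
    tier_cutoff: int = 10
    seed: int = 0

    def validate(self) -> None:
        self.filter_params.validate()
        self.prune_params.validate()
        self.roh_params.validate()
        self.thresholds.validate()
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if min(self.k_values) < 1:
            raise ValueError("K values must be >= 1")


class Manifest:
    def __init__(self, outdir: str):
        self.outdir = outdir
        self.records: list[dict] = []

    def add(self, path: str, n_rows: int) -> None:
        with open(path, "rb") as fh:
            digest = hashlib.sha256(fh.read()).hexdigest()
        self.records.append(
            {"file": os.path.relpath(path, self.outdir), "rows": n_rows, "sha256": digest}
        )

    def write(self, extra: dict | None = None) -> None:
        doc = {"artifacts": self.records}
        if extra:
            doc.update(extra)
        with open(os.path.join(self.outdir, "manifest.json"), "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)


def _write(manifest: Manifest, path: str, df: pd.DataFrame) -> None:
    os.makedirs(os.path.dirname(path), exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    manifest.add(path, len(df))


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns a dict of the in-memory results."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    manifest = Manifest(config.outdir)

    variants, samples_stub, genotypes = kio.read_vcf(config.vcf)
    metadata = kio.read_metadata(config.metadata)
    samples = kio.attach_metadata(samples_stub, metadata)

    # --- QC -----------------------------------------------------------
    fp = config.filter_params
    qc = VariantQC(fp.max_variant_missing, fp.min_maf, fp.hwe_alpha, fp.max_sample_missing)
    qc.fit(genotypes)
    g_qc = qc.transform(genotypes)
    samples_qc = samples[qc.sample_keep_].reset_index(drop=True)
    variants_qc = variants[qc.variant_keep_].reset_index(drop=True)
    vrep = qc.variant_report_.copy()
    vrep.insert(0, "vid", variants["vid"])
    srep = qc.sample_report_.copy()
    srep.insert(0, "sample_id", samples["sample_id"])
    _write(manifest, os.path.join(config.outdir, "qc", "variants.qc.tsv"), vrep)
    _write(manifest, os.path.join(config.outdir, "qc", "samples.qc.tsv"), srep)
    logger.info(
        "QC: %d/%d samples, %d/%d variants retained",
        len(samples_qc), len(samples), len(variants_qc), len(variants),
    )

    # --- LD pruning ---------------------------------------------------
    pp = config.prune_params
    pruner = LDPruner(pp.window_size, pp.step, pp.r2_threshold)
    pruner.fit(g_qc, variants=variants_qc)
    g_pruned = pruner.transform(g_qc)
    variants_pruned = variants_qc[pruner.support_].reset_index(drop=True)
    _write(
        manifest,
        os.path.join(config.outdir, "prune", "kept_variants.tsv"),
        variants_pruned[["vid"]],
    )
    kio.write_vcf(
        os.path.join(config.outdir, "prune", "pruned.vcf"),
        variants_pruned,
        samples_qc,
        g_pruned,
    )
    manifest.add(os.path.join(config.outdir, "prune", "pruned.vcf"), len(variants_pruned))

    # --- diversity ----------------------------------------------------
    div = diversity_records(g_pruned, samples_qc["sample_id"])
    _write(manifest, os.path.join(config.outdir, "diversity", "diversity.tsv"), div)
    if samples_qc["subpopulation"].nunique() >= 2:
        het_sum, het_pairs = subpop_summary(
            div["het_rate"].to_numpy(), samples_qc["subpopulation"], "het_rate"
        )
        f_sum, f_pairs = subpop_summary(
            div["f_hat"].to_numpy(), samples_qc["subpopulation"], "f_hat"
        )
        summary = het_sum.merge(f_sum.drop(columns=["n"]), on="subpopulation")
        _write(manifest, os.path.join(config.outdir, "diversity", "diversity_summary.tsv"), summary)
        tests = het_pairs.merge(f_pairs, on=["group1", "group2"], suffixes=("_het", "_fhat"))
        _write(manifest, os.path.join(config.outdir, "diversity", "diversity_tests.tsv"), tests)

    # --- relatedness + MDS -------------------------------------------
    rel = IBDRelatedness(config.thresholds).fit(
        g_pruned, sample_ids=list(samples_qc["sample_id"])
    )
    _write(manifest, os.path.join(config.outdir, "ibd", "ibd_pairs.tsv"), rel.pairs_)
    coords = mds_embed(rel.distance_, dims=2)
    mds_df = pd.DataFrame(
        {"sample_id": samples_qc["sample_id"], "dim1": coords[:, 0], "dim2": coords[:, 1]}
    )
    _write(manifest, os.path.join(config.outdir, "ibd", "mds.tsv"), mds_df)

    # --- ROH ----------------------------------------------------------
    segments = detect_roh(
        g_pruned, variants_pruned, config.roh_params, list(samples_qc["sample_id"])
    )
    _write(manifest, os.path.join(config.outdir, "roh", "roh_segments.tsv"), segments)
    froh = pd.DataFrame(
        {
            "sample_id": samples_qc["sample_id"],
            "froh": [
                f_roh(segments[segments["sample_id"] == sid], variants_pruned)
                for sid in samples_qc["sample_id"]
            ],
        }
    )
    _write(manifest, os.path.join(config.outdir, "roh", "froh.tsv"), froh)
    class_rows = []
    for sub, grp in samples_qc.groupby("subpopulation"):
        seg_sub = segments[segments["sample_id"].isin(grp["sample_id"])]
        counts = bin_length_classes(seg_sub)
        class_rows.append({"subpopulation": sub, **counts.to_dict()})
    _write(
        manifest,
        os.path.join(config.outdir, "roh", "class_counts.tsv"),
        pd.DataFrame(class_rows),
    )

    # --- admixture ----------------------------------------------------
    cv = choose_k(
        g_pruned, config.k_values, folds=config.cv_folds, seed=config.seed,
        n_restarts=max(1, config.n_restarts - 1),
    )
    _write(manifest, os.path.join(config.outdir, "admix", "cv_errors.tsv"), cv)
    best_k = int(cv.loc[cv["cv_error"].idxmin(), "K"])
    fit = AdmixtureEM(
        best_k, n_restarts=config.n_restarts, random_state=config.seed
    ).fit(g_pruned)
    np.savetxt(os.path.join(config.outdir, "admix", f"K{best_k}.Q"), fit.Q_, fmt="%.6f")
    manifest.add(os.path.join(config.outdir, "admix", f"K{best_k}.Q"), fit.Q_.shape[0])
    np.savetxt(os.path.join(config.outdir, "admix", f"K{best_k}.P"), fit.F_.T, fmt="%.6f")
    manifest.add(os.path.join(config.outdir, "admix", f"K{best_k}.P"), fit.F_.shape[1])
    mapping = align_clusters(fit.Q_, samples_qc["subpopulation"])
    purity = purity_calls(
        fit.Q_, samples_qc["sample_id"], mapping, config.purity_tol, config.admix_flag
    )
    _write(manifest, os.path.join(config.outdir, "admix", "purity.tsv"), purity)

    # --- breeder selection --------------------------------------------
    reports = {}
    for cand_sex, mate_sex, name in (("male", "female", "males"), ("female", "male", "females")):
        spec = PoolSpec(cand_sex, mate_sex, gate_candidates=True, gate_mates=True)
        rep = breeder_report(samples_qc, purity, rel.pairs_, spec, config.tier_cutoff)
        _write(manifest, os.path.join(config.outdir, "select", f"breeders_{name}.tsv"), rep)
        reports[name] = rep
    males = samples_qc.loc[samples_qc["sex"] == "male", "sample_id"].tolist()
    females = samples_qc.loc[samples_qc["sex"] == "female", "sample_id"].tolist()
    if males and females:
        heat = pair_matrix(rel.pairs_, sorted(males), sorted(females), "pi_hat", percent=True)
        heat_path = os.path.join(config.outdir, "select", "pihat_heatmap.tsv")
        heat.to_csv(heat_path, sep="\t")
        manifest.add(heat_path, len(heat))

    manifest.write(extra={"seed": config.seed, "best_k": best_k})
    return {
        "samples": samples_qc,
        "variants": variants_pruned,
        "genotypes": g_pruned,
        "qc": qc,
        "diversity": div,
        "pairs": rel.pairs_,
        "mds": mds_df,
        "roh": segments,
        "froh": froh,
        "cv": cv,
        "best_k": best_k,
        "Q": fit.Q_,
        "purity": purity,
        "breeders": reports,
    }
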