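"""Synthetic genotype data with ground truth for every pipeline stage.

The generator emulates the study design this toolkit targets: two
subpopulations diverged under a Balding-Nichols model, multi-generation
pedigrees simulated by gene dropping with Poisson recombination (no
interference), admixed individuals with known ancestry fractions, injected
autozygous segments, and missing-call / genotyping-error processes.

Founder-allele origin is tracked per locus, so the exported truth contains
*realized* quantities — pairwise IBD-state fractions and Pi-Hat, per-sample
autozygous segments, ancestry fractions — not just pedigree expectations.
All randomness flows through one seed; identical seeds give identical
output.

Coordinates are 1-based inclusive internally; the truth BED export is
0-based half-open per BED convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .datamodel import MISSING, make_sample_table, make_variant_table


@dataclass
class PedigreeEntry:
    """One individual: founders carry ``pop`` ('A' or 'B'); non-founders
    carry parent ids (which must appear earlier in the pedigree)."""

    id: str
    sex: str = "unknown"
    pop: str | None = None
    father: str | None = None
    mother: str | None = None
    subpopulation: str | None = None

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass
class SimConfig:
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 60_000_000, "chr2": 50_000_000, "chr3": 40_000_000}
    )
    n_variants: int = 10_000
    spacing: str = "uniform"  # or "poisson"
    fst: float = 0.2
    anc_freq_range: tuple[float, float] = (0.05, 0.95)
    pedigree: list[PedigreeEntry] = field(default_factory=list)
    recomb_rate: float = 1.04  # cM/Mb
    missing_rate: float = 0.0
    genotype_error_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.fst < 1.0):
            raise ValueError("fst must be in (0,1)")
        for name in ("missing_rate", "genotype_error_rate"):
            if not (0.0 <= getattr(self, name) < 1.0):
                raise ValueError(f"{name} must be in [0,1)")
        if self.spacing not in ("uniform", "poisson"):
            raise ValueError("spacing must be 'uniform' or 'poisson'")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class TruthSet:
    q: pd.DataFrame  # sample_id, q_A, q_B (realized allele-copy fractions)
    pairs: pd.DataFrame  # id1, id2, z0, z1, z2, pi_hat, expected_kinship
    autozygous: pd.DataFrame  # sample_id, chrom, start_pos, end_pos (1-based incl.)
    autozygous_fraction: pd.Series  # per sample, fraction of loci autozygous


def build_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Variant map: n_variants allocated across chromosomes by length."""
    total = sum(config.chrom_lengths.values())
    chroms, poss = [], []
    remaining = config.n_variants
    items = list(config.chrom_lengths.items())
    for i, (name, length) in enumerate(items):
        n_c = remaining if i == len(items) - 1 else int(round(config.n_variants * length / total))
        n_c = min(n_c, remaining)
        remaining -= n_c
        if n_c == 0:
            continue
        if config.spacing == "uniform":
            pos = np.linspace(1, length, n_c + 2)[1:-1].round().astype(np.int64)
        else:
            pos = np.sort(rng.choice(np.arange(1, length + 1), size=n_c, replace=False))
        pos = np.maximum.accumulate(pos)  # guard rounding collisions
        while len(np.unique(pos)) < len(pos):
            dup = np.flatnonzero(np.diff(pos) == 0)
            pos[dup + 1] += 1
        chroms.extend([name] * n_c)
        poss.extend(pos.tolist())
    return make_variant_table(chroms, poss)


def draw_subpop_frequencies(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Balding-Nichols frequencies for two diverged subpopulations.

    Ancestral frequencies are uniform on ``anc_freq_range``; each
    subpopulation's frequency is Beta(p(1-fst)/fst, (1-p)(1-fst)/fst).
    Returns (ancestral (L,), subpop (2, L)).
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.anc_freq_range
    p = rng.uniform(lo, hi, size=config.n_variants)
    scale = (1.0 - config.fst) / config.fst
    freqs = np.vstack(
        [rng.beta(p * scale, (1.0 - p) * scale) for _ in range(2)]
    )
    return p, np.clip(freqs, 1e-6, 1 - 1e-6)


def _meiosis(
    h: tuple[np.ndarray, np.ndarray],
    lab: tuple[np.ndarray, np.ndarray],
    variants: pd.DataFrame,
    recomb_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete from a parent: Poisson crossovers at recomb_rate cM/Mb."""
    gam = np.empty_like(h[0])
    gl = np.empty_like(lab[0])
    for chrom, grp in variants.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        length = pos[-1]
        expected_co = recomb_rate * (length / 1e6) / 100.0
        n_co = rng.poisson(expected_co)
        breaks = np.sort(rng.integers(1, length + 1, size=n_co))
        phase = (np.searchsorted(breaks, pos, side="right") + rng.integers(0, 2)) % 2
        gam[idx] = np.where(phase == 0, h[0][idx], h[1][idx])
        gl[idx] = np.where(phase == 0, lab[0][idx], lab[1][idx])
    return gam, gl


def _shared_ibd(a1, a2, b1, b2) -> np.ndarray:
    """Per-locus count of alleles shared IBD between two individuals
    (multiset intersection of founder-allele labels, 0..2)."""
    eq_a = a1 == a2
    cnt1 = (b1 == a1).astype(np.int8) + (b2 == a1).astype(np.int8)
    cnt2 = (b1 == a2).astype(np.int8) + (b2 == a2).astype(np.int8)
    same = np.minimum(cnt1, 2)
    diff = np.minimum(cnt1, 1) + np.minimum(cnt2, 1)
    return np.where(eq_a, same, diff)


def expected_kinship(pedigree: list[PedigreeEntry]) -> pd.DataFrame:
    """Pedigree kinship matrix by the recursive (tabular) method."""
    ids = [e.id for e in pedigree]
    index = {e.id: i for i, e in enumerate(pedigree)}
    n = len(ids)
    phi = np.zeros((n, n))
    for i, e in enumerate(pedigree):
        if e.is_founder:
            phi[i, i] = 0.5
        else:
            f, m = index[e.father], index[e.mother]
            phi[i, i] = 0.5 * (1.0 + phi[f, m])
        for j in range(i):
            if e.is_founder:
                phi[i, j] = phi[j, i] = 0.0
            else:
                f, m = index[e.father], index[e.mother]
                phi[i, j] = phi[j, i] = 0.5 * (phi[f, j] + phi[m, j])
    return pd.DataFrame(phi, index=ids, columns=ids)


def gene_drop(config: SimConfig, freqs: np.ndarray | None = None):
    """Drop founder alleles down the pedigree with recombination.

    Returns (genotypes, variants, samples, truth).  Missingness and
    genotyping error are applied after truth extraction, so the truth
    reflects the error-free transmitted alleles.
    """
    config.validate()
    if not config.pedigree:
        raise ValueError("gene_drop requires a pedigree")
    rng = np.random.default_rng(config.seed)
    variants = build_map(config, rng)
    if freqs is None:
        _, freqs = draw_subpop_frequencies(config, rng)
    L = len(variants)
    pop_index = {"A": 0, "B": 1}

    haps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    labs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    founder_pop: dict[int, str] = {}
    n_founders = 0
    for e in config.pedigree:
        if e.is_founder:
            if e.pop not in pop_index:
                raise ValueError(f"founder {e.id!r} must name pop 'A' or 'B'")
            p = freqs[pop_index[e.pop]]
            h = tuple(rng.binomial(1, p).astype(np.int8) for _ in range(2))
            lab = (
                np.full(L, 2 * n_founders, dtype=np.int32),
                np.full(L, 2 * n_founders + 1, dtype=np.int32),
            )
            founder_pop[2 * n_founders] = e.pop
            founder_pop[2 * n_founders + 1] = e.pop
            n_founders += 1
        else:
            for parent in (e.father, e.mother):
                if parent not in haps:
                    raise ValueError(f"{e.id!r} references unknown parent {parent!r}")
            g1, l1 = _meiosis(haps[e.father], labs[e.father], variants, config.recomb_rate, rng)
            g2, l2 = _meiosis(haps[e.mother], labs[e.mother], variants, config.recomb_rate, rng)
            h, lab = (g1, g2), (l1, l2)
        haps[e.id] = h
        labs[e.id] = lab

    ids = [e.id for e in config.pedigree]
    genotypes = np.vstack([haps[i][0] + haps[i][1] for i in ids]).astype(np.int8)

    # realized ancestry fractions (allele copies from pop A vs B)
    pop_of = np.vectorize(lambda x: 0 if founder_pop[x] == "A" else 1)
    q_rows = []
    for i in ids:
        l1, l2 = labs[i]
        frac_b = 0.5 * (pop_of(l1).mean() + pop_of(l2).mean())
        q_rows.append({"sample_id": i, "q_A": 1.0 - frac_b, "q_B": frac_b})
    q_df = pd.DataFrame(q_rows)

    phi = expected_kinship(config.pedigree)
    pair_rows = []
    for ai in range(len(ids)):
        for bi in range(ai + 1, len(ids)):
            a, b = ids[ai], ids[bi]
            shared = _shared_ibd(labs[a][0], labs[a][1], labs[b][0], labs[b][1])
            z = np.array([(shared == k).mean() for k in (0, 1, 2)])
            pair_rows.append(
                {
                    "id1": a,
                    "id2": b,
                    "z0": z[0],
                    "z1": z[1],
                    "z2": z[2],
                    "pi_hat": z[2] + 0.5 * z[1],
                    "expected_kinship": phi.loc[a, b],
                }
            )
    pairs_df = pd.DataFrame(
        pair_rows, columns=["id1", "id2", "z0", "z1", "z2", "pi_hat", "expected_kinship"]
    )

    auto_rows = []
    auto_frac = {}
    for i in ids:
        l1, l2 = labs[i]
        auto = l1 == l2
        auto_frac[i] = float(auto.mean())
        for chrom, grp in variants.groupby("chrom", sort=False):
            idx = grp.index.to_numpy()
            pos = grp["pos"].to_numpy()
            a = auto[idx]
            start = None
            for j in range(len(a) + 1):
                if j < len(a) and a[j]:
                    if start is None:
                        start = j
                elif start is not None:
                    auto_rows.append(
                        {
                            "sample_id": i,
                            "chrom": chrom,
                            "start_pos": int(pos[start]),
                            "end_pos": int(pos[j - 1]),
                        }
                    )
                    start = None
    auto_df = pd.DataFrame(auto_rows, columns=["sample_id", "chrom", "start_pos", "end_pos"])

    genotypes = apply_noise(
        genotypes, config.missing_rate, config.genotype_error_rate, rng
    )
    samples = make_sample_table(
        ids,
        sex=[e.sex for e in config.pedigree],
        subpopulation=[
            e.subpopulation if e.subpopulation else (e.pop or "PED") for e in config.pedigree
        ],
    )
    truth = TruthSet(q_df, pairs_df, auto_df, pd.Series(auto_frac, name="autozygous_fraction"))
    return genotypes, variants, samples, truth


def apply_noise(
    genotypes: np.ndarray,
    missing_rate: float,
    error_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Genotyping error (call replaced by one of the other two genotypes)
    then missingness, each i.i.d. per call."""
    g = genotypes.copy()
    if error_rate > 0:
        err = (rng.random(g.shape) < error_rate) & (g != MISSING)
        shift = rng.integers(1, 3, size=g.shape).astype(np.int8)
        g[err] = (g[err] + shift[err]) % 3
    if missing_rate > 0:
        g[rng.random(g.shape) < missing_rate] = MISSING
    return g


def population_sample(
    freqs: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n unrelated Hardy-Weinberg individuals at the given allele
    frequencies (no linkage)."""
    return rng.binomial(2, freqs, size=(n, freqs.size)).astype(np.int8)


def make_admixed(
    config: SimConfig,
    freqs: np.ndarray,
    q_target: np.ndarray,
    rng: np.random.Generator | None = None,
):
    """Admixed individuals with known ancestry.

    Each haplotype is a mosaic of ancestry segments (Poisson breakpoints at
    the recombination rate); each segment's source population is drawn
    Bernoulli(q_target) so the realized fraction matches the target in
    expectation.  Returns (genotypes, variants, true_Q) with true_Q the
    realized per-sample ancestry fractions.
    """
    config.validate()
    q_target = np.atleast_2d(np.asarray(q_target, dtype=np.float64))
    if q_target.shape[1] != 2 or np.any(q_target < 0) or not np.allclose(q_target.sum(1), 1.0):
        raise ValueError("q_target rows must be length-2 simplex vectors")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    variants = build_map(config, rng)
    L = len(variants)
    n = q_target.shape[0]
    genotypes = np.empty((n, L), dtype=np.int8)
    true_q = np.empty((n, 2))
    for i in range(n):
        anc_copies = np.zeros(L)
        g = np.zeros(L, dtype=np.int8)
        for _ in range(2):
            anc = np.empty(L, dtype=np.int8)
            for chrom, grp in variants.groupby("chrom", sort=False):
                idx = grp.index.to_numpy()
                pos = grp["pos"].to_numpy()
                length = pos[-1]
                n_co = rng.poisson(config.recomb_rate * (length / 1e6) / 100.0)
                breaks = np.sort(rng.integers(1, length + 1, size=n_co))
                seg_id = np.searchsorted(breaks, pos, side="right")
                seg_anc = rng.random(n_co + 1) >= q_target[i, 0]  # True -> pop B
                anc[idx] = seg_anc[seg_id].astype(np.int8)
            allele = rng.binomial(1, np.where(anc == 0, freqs[0], freqs[1])).astype(np.int8)
            g += allele
            anc_copies += anc
        genotypes[i] = g
        frac_b = anc_copies.mean() / 2.0
        true_q[i] = (1.0 - frac_b, frac_b)
    return genotypes, variants, true_q


def inject_autozygosity(
    variants: pd.DataFrame,
    freqs: np.ndarray,
    segments: list[tuple[str, int, int]],
    rng: np.random.Generator,
    error_rate: float = 0.0,
) -> np.ndarray:
    """One individual homozygous-by-descent inside the given segments.

    Haplotype 1 is drawn from the allele frequencies; haplotype 2 copies
    haplotype 1 inside each (chrom, start, end) segment (1-based inclusive)
    and is independent elsewhere.  Optional genotyping error afterwards.
    """
    L = len(variants)
    h1 = rng.binomial(1, freqs).astype(np.int8)
    h2 = rng.binomial(1, freqs).astype(np.int8)
    inside = np.zeros(L, dtype=bool)
    chrom_arr = variants["chrom"].to_numpy()
    pos_arr = variants["pos"].to_numpy()
    for chrom, start, end in segments:
        inside |= (chrom_arr == chrom) & (pos_arr >= start) & (pos_arr <= end)
    h2[inside] = h1[inside]
    g = (h1 + h2).astype(np.int8)
    if error_rate > 0:
        g = apply_noise(g[None, :], 0.0, error_rate, rng)[0]
    return g


def export_truth(truth: TruthSet, outdir: str) -> None:
    """Write truth_q.tsv, truth_pairs.tsv and truth_autozygous.bed.

    The BED file is 0-based half-open (start = start_pos − 1, end =
    end_pos), converted from the internal 1-based inclusive coordinates.
    """
    os.makedirs(outdir, exist_ok=True)
    truth.q.to_csv(os.path.join(outdir, "truth_q.tsv"), sep="\t", index=False)
    truth.pairs.to_csv(os.path.join(outdir, "truth_pairs.tsv"), sep="\t", index=False)
    bed = truth.autozygous.copy()
    with open(os.path.join(outdir, "truth_autozygous.bed"), "w") as fh:
        for _, r in bed.iterrows():
            fh.write(f"{r['chrom']}\t{r['start_pos'] - 1}\t{r['end_pos']}\t{r['sample_id']}\n")


def read_truth_bed(path: str) -> pd.DataFrame:
    """Read a truth BED back into 1-based inclusive segments."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, sid = line.rstrip("\n").split("\t")
            rows.append(
                {"sample_id": sid, "chrom": chrom, "start_pos": int(start) + 1, "end_pos": int(end)}
            )
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "start_pos", "end_pos"])


# ---------------------------------------------------------------------------
# pedigree builders and the demo scenario


def ped_founders(n: int, pop: str, prefix: str, sexes=None) -> list[PedigreeEntry]:
    sexes = sexes or ["male" if i % 2 == 0 else "female" for i in range(n)]
    return [PedigreeEntry(f"{prefix}{i}", sexes[i], pop=pop) for i in range(n)]


def ped_parent_offspring(tag: str, pop: str = "A") -> list[PedigreeEntry]:
    return [
        PedigreeEntry(f"{tag}_f", "male", pop=pop),
        PedigreeEntry(f"{tag}_m", "female", pop=pop),
        PedigreeEntry(f"{tag}_c", "male", father=f"{tag}_f", mother=f"{tag}_m"),
    ]


def ped_full_sibs(tag: str, pop: str = "A") -> list[PedigreeEntry]:
    return [
        PedigreeEntry(f"{tag}_f", "male", pop=pop),
        PedigreeEntry(f"{tag}_m", "female", pop=pop),
        PedigreeEntry(f"{tag}_s1", "male", father=f"{tag}_f", mother=f"{tag}_m"),
        PedigreeEntry(f"{tag}_s2", "female", father=f"{tag}_f", mother=f"{tag}_m"),
    ]


def ped_half_sibs(tag: str, pop: str = "A") -> list[PedigreeEntry]:
    return [
        PedigreeEntry(f"{tag}_f", "male", pop=pop),
        PedigreeEntry(f"{tag}_m1", "female", pop=pop),
        PedigreeEntry(f"{tag}_m2", "female", pop=pop),
        PedigreeEntry(f"{tag}_h1", "male", father=f"{tag}_f", mother=f"{tag}_m1"),
        PedigreeEntry(f"{tag}_h2", "female", father=f"{tag}_f", mother=f"{tag}_m2"),
    ]


def ped_first_cousin_offspring(tag: str, pop: str = "A") -> list[PedigreeEntry]:
    """Grandparental couple, two full-sib parents married to unrelated
    spouses, and a child of the two first cousins (expected F = 1/16)."""
    return [
        PedigreeEntry(f"{tag}_gf", "male", pop=pop),
        PedigreeEntry(f"{tag}_gm", "female", pop=pop),
        PedigreeEntry(f"{tag}_u1", "female", pop=pop),
        PedigreeEntry(f"{tag}_u2", "male", pop=pop),
        PedigreeEntry(f"{tag}_p1", "male", father=f"{tag}_gf", mother=f"{tag}_gm"),
        PedigreeEntry(f"{tag}_p2", "female", father=f"{tag}_gf", mother=f"{tag}_gm"),
        PedigreeEntry(f"{tag}_c1", "male", father=f"{tag}_p1", mother=f"{tag}_u1"),
        PedigreeEntry(f"{tag}_c2", "female", father=f"{tag}_u2", mother=f"{tag}_p2"),
        PedigreeEntry(f"{tag}_x", "male", father=f"{tag}_c1", mother=f"{tag}_c2"),
    ]


def demo_config(seed: int = 17) -> SimConfig:
    """Scenario mimicking the target study: a bottlenecked herd descended
    from 3 founders with sib matings, an outbred herd from 12 founders, and
    a few F1/backcross hybrids."""
    ped: list[PedigreeEntry] = []
    # bottlenecked herd (subpopulation HERD-IN): 3 founders, sib matings
    ped += [
        PedigreeEntry("IN_f0", "male", pop="A", subpopulation="HERD-IN"),
        PedigreeEntry("IN_f1", "female", pop="A", subpopulation="HERD-IN"),
        PedigreeEntry("IN_f2", "male", pop="A", subpopulation="HERD-IN"),
    ]
    ped += [
        PedigreeEntry("IN_g1a", "male", father="IN_f0", mother="IN_f1", subpopulation="HERD-IN"),
        PedigreeEntry("IN_g1b", "female", father="IN_f0", mother="IN_f1", subpopulation="HERD-IN"),
        PedigreeEntry("IN_g1c", "female", father="IN_f2", mother="IN_f1", subpopulation="HERD-IN"),
    ]
    ped += [
        PedigreeEntry("IN_g2a", "male", father="IN_g1a", mother="IN_g1b", subpopulation="HERD-IN"),
        PedigreeEntry("IN_g2b", "female", father="IN_g1a", mother="IN_g1b", subpopulation="HERD-IN"),
        PedigreeEntry("IN_g2c", "male", father="IN_g1a", mother="IN_g1c", subpopulation="HERD-IN"),
        PedigreeEntry("IN_g2d", "female", father="IN_g1a", mother="IN_g1c", subpopulation="HERD-IN"),
    ]
    # outbred herd (HERD-OUT): 12 founders, unrelated matings
    ped += ped_founders(12, "B", "OUT_f")
    for e in ped[-12:]:
        e.subpopulation = "HERD-OUT"
    for i in range(0, 12, 2):
        ped.append(
            PedigreeEntry(
                f"OUT_g{i // 2}",
                "male" if i % 4 == 0 else "female",
                father=f"OUT_f{i}",
                mother=f"OUT_f{i + 1}",
                subpopulation="HERD-OUT",
            )
        )
    # hybrids: F1 (A founder x B founder) and a backcross to B
    ped += [
        PedigreeEntry("HYB_a", "male", pop="A", subpopulation="HYB"),
        PedigreeEntry("HYB_b", "female", pop="B", subpopulation="HYB"),
        PedigreeEntry("HYB_f1", "female", father="HYB_a", mother="HYB_b", subpopulation="HYB"),
        PedigreeEntry("HYB_bc", "male", father="OUT_f0", mother="HYB_f1", subpopulation="HYB"),
    ]
    return SimConfig(
        chrom_lengths={"chr1": 60_000_000, "chr2": 50_000_000, "chr3": 40_000_000},
        n_variants=6000,
        fst=0.2,
        pedigree=ped,
        missing_rate=0.02,
        genotype_error_rate=0.001,
        seed=seed,
    )


def load_scenario(path: str) -> SimConfig:
    """Load a SimConfig from a YAML scenario file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    ped = [PedigreeEntry(**e) for e in doc.pop("pedigree", [])]
    if "chrom_lengths" in doc:
        doc["chrom_lengths"] = {str(k): int(v) for k, v in doc["chrom_lengths"].items()}
    if "anc_freq_range" in doc:
        doc["anc_freq_range"] = tuple(doc["anc_freq_range"])
    cfg = SimConfig(pedigree=ped, **doc)
    cfg.validate()
    return cfg


def save_scenario(config: SimConfig, path: str) -> None:
    doc = {
        "chrom_lengths": dict(config.chrom_lengths),
        "n_variants": config.n_variants,
        "spacing": config.spacing,
        "fst": config.fst,
        "anc_freq_range": list(config.anc_freq_range),
        "recomb_rate": config.recomb_rate,
        "missing_rate": config.missing_rate,
        "genotype_error_rate": config.genotype_error_rate,
        "seed": config.seed,
        "pedigree": [
            {
                k: v
                for k, v in {
                    "id": e.id,
                    "sex": e.sex,
                    "pop": e.pop,
                    "father": e.father,
                    "mother": e.mother,
                    "subpopulation": e.subpopulation,
                }.items()
                if v is not None
            }
            for e in config.pedigree
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
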