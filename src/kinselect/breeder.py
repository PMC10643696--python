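"""Breeder-pair recommendation from purity calls, sexes and relatedness.

A candidate (e.g. each male) is scored by how many members of the
opposite-sex mate pool it is genetically unrelated to, where "unrelated"
is strictly the relationship class from the Pi-Hat classifier
(Pi-Hat < 0.10).  Candidates unrelated to the entire pool form the top
tier; candidates unrelated to more than ``tier_cutoff`` (default 10) pool
members form the next tier.  Purity gating optionally restricts either
side of the pool to purebred individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

TIERS = ("unrelated_to_all", "unrelated_to_more_than_10", "other")


@dataclass
class PoolSpec:
    candidate_sex: str = "male"
    mate_sex: str = "female"
    gate_candidates: bool = True
    gate_mates: bool = True


def build_mate_pool(
    samples: pd.DataFrame,
    purity: pd.DataFrame | None,
    spec: PoolSpec | None = None,
) -> tuple[list[str], list[str]]:
    """Select candidate and mate id lists.

    Pools are disjoint by sex; unknown-sex individuals are excluded from
    both with a warning.  When gating is on for a side, only individuals
    whose purity_class is ``purebred`` enter that side.
    """
    spec = spec or PoolSpec()
    unknown = samples[samples["sex"] == "unknown"]
    if len(unknown):
        logger.warning(
            "build_mate_pool: %d unknown-sex individual(s) excluded (e.g. %s)",
            len(unknown),
            unknown["sample_id"].iloc[0],
        )
    pure: set[str] = set()
    if purity is not None:
        pure = set(purity.loc[purity["purity_class"] == "purebred", "sample_id"])

    def side(sex: str, gated: bool) -> list[str]:
        ids = samples.loc[samples["sex"] == sex, "sample_id"].tolist()
        if gated:
            if purity is None:
                raise ValueError("purity gating requested but no purity calls given")
            ids = [i for i in ids if i in pure]
        return ids

    candidates = side(spec.candidate_sex, spec.gate_candidates)
    mates = side(spec.mate_sex, spec.gate_mates)
    if not candidates or not mates:
        logger.warning("build_mate_pool: empty pool after gating")
    return candidates, mates


def recommend(
    pairs: pd.DataFrame,
    candidates: list[str],
    mates: list[str],
    tier_cutoff: int = 10,
) -> pd.DataFrame:
    """Per-candidate breeder report.

    ``pairs`` must contain a relationship record for every candidate x mate
    pair (columns id1, id2, pi_hat, rel_class); a missing pair is fatal.
    The report is sorted by unrelated-mate count descending, then sample id.
    """
    lut: dict[tuple[str, str], str] = {}
    for _, r in pairs.iterrows():
        lut[(r["id1"], r["id2"])] = r["rel_class"]
        lut[(r["id2"], r["id1"])] = r["rel_class"]
    rows = []
    pool_size = len(mates)
    for cand in candidates:
        unrelated = []
        for m in mates:
            if (cand, m) not in lut:
                raise ValueError(f"missing relationship record for pair ({cand}, {m})")
            if lut[(cand, m)] == "unrelated":
                unrelated.append(m)
        n = len(unrelated)
        if n == pool_size and pool_size > 0:
            tier = "unrelated_to_all"
        elif n > tier_cutoff:
            tier = "unrelated_to_more_than_10"
        else:
            tier = "other"
        rows.append(
            {
                "sample_id": cand,
                "n_unrelated_mates": n,
                "pool_size": pool_size,
                "tier": tier,
                "unrelated_mate_ids": ",".join(unrelated),
            }
        )
    rep = pd.DataFrame(
        rows, columns=["sample_id", "n_unrelated_mates", "pool_size", "tier", "unrelated_mate_ids"]
    )
    return rep.sort_values(
        ["n_unrelated_mates", "sample_id"], ascending=[False, True]
    ).reset_index(drop=True)


def breeder_report(
    samples: pd.DataFrame,
    purity: pd.DataFrame | None,
    pairs: pd.DataFrame,
    spec: PoolSpec | None = None,
    tier_cutoff: int = 10,
) -> pd.DataFrame:
    """Candidate report with sex and purity columns attached."""
    spec = spec or PoolSpec()
    candidates, mates = build_mate_pool(samples, purity, spec)
    rep = recommend(pairs, candidates, mates, tier_cutoff)
    meta = samples.set_index("sample_id")
    rep.insert(1, "sex", [meta.loc[s, "sex"] for s in rep["sample_id"]])
    if purity is not None:
        pmeta = purity.set_index("sample_id")
        rep.insert(
            2,
            "purity_class",
            [
                pmeta.loc[s, "purity_class"] if s in pmeta.index else "NA"
                for s in rep["sample_id"]
            ],
        )
    return rep
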