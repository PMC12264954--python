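"""Mining activity-cliff (AC) compound pairs from interaction tables.

For every target, all compounds measured against it are paired; pairs whose
maximal similarity under any of the three criteria reaches the similarity
threshold (default 0.9) are kept, and a kept pair is labeled an activity
cliff when the absolute affinity difference on the log10 scale reaches the
affinity threshold (default 1.0, i.e. a 10-fold change in activity).
Pairs below the similarity threshold are neither AC nor non-AC; they are
discarded.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .chemio import Molecule, SimilarityTriple, similarity_triple

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ["compound_a", "compound_b", "target_id", "sim_substructure",
                "sim_scaffold", "sim_smiles", "delta_affinity", "label"]


@dataclass(frozen=True)
class InteractionRecord:
    """One (compound, target, affinity) measurement on a log10 scale."""

    compound_id: str
    target_id: str
    affinity: float


@dataclass(frozen=True)
class CompoundPair:
    """An oriented compound pair on one target with its similarity and label.

    Orientation is canonical: ``compound_a < compound_b`` lexicographically,
    so re-mining the same data yields an identical pair set.
    """

    compound_a: str
    compound_b: str
    target_id: str
    similarity: SimilarityTriple
    delta_affinity: float
    label: int


@dataclass(frozen=True)
class MiningConfig:
    """Thresholds of the AC definition.

    similarity_threshold: minimal similarity under the best of the three
        criteria for a pair to count as structurally similar (inclusive).
    affinity_threshold: minimal |delta affinity| in log10 units for a
        similar pair to be labeled a cliff (inclusive); 1.0 means 10-fold.
        For integrated scores such as KIBA the threshold applies to the
        score directly and must be chosen by the user.
    """

    similarity_threshold: float = 0.9
    affinity_threshold: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.similarity_threshold <= 1.0):
            raise ValueError("similarity_threshold must be in (0, 1]")
        if self.affinity_threshold <= 0:
            raise ValueError("affinity_threshold must be > 0")


def aggregate_records(raw: list[InteractionRecord]) -> list[InteractionRecord]:
    """Collapse replicate (compound, target) measurements to their mean.

    Records with non-finite affinity are rejected with a warning. Output
    order is deterministic (sorted by compound then target).
    """
    groups: dict[tuple[str, str], list[float]] = {}
    n_rejected = 0
    for rec in raw:
        if not math.isfinite(rec.affinity):
            warnings.warn(
                f"dropping record ({rec.compound_id}, {rec.target_id}): "
                f"non-finite affinity {rec.affinity}")
            n_rejected += 1
            continue
        groups.setdefault((rec.compound_id, rec.target_id), []).append(rec.affinity)
    n_collapsed = sum(len(v) - 1 for v in groups.values())
    if n_collapsed:
        logger.info("aggregated %d replicate measurements", n_collapsed)
    return [InteractionRecord(c, t, sum(v) / len(v))
            for (c, t), v in sorted(groups.items())]


def enumerate_candidate_pairs(records: list[InteractionRecord],
                              target_id: str) -> list[tuple[str, str]]:
    """All unordered pairs of distinct compounds measured against one target."""
    compounds = sorted({r.compound_id for r in records if r.target_id == target_id})
    return list(itertools.combinations(compounds, 2))


def select_similar(pairs: list[tuple[str, str]],
                   triples: dict[tuple[str, str], SimilarityTriple],
                   cfg: MiningConfig) -> list[tuple[str, str]]:
    """Keep pairs whose best criterion reaches the similarity threshold."""
    return [p for p in pairs if triples[p].max() >= cfg.similarity_threshold]


def label_pair(compound_a: str, compound_b: str, target_id: str,
               triple: SimilarityTriple, affinity_a: float, affinity_b: float,
               cfg: MiningConfig) -> CompoundPair:
    """Label a similar pair: AC (1) iff |delta affinity| >= threshold."""
    a, b = sorted((compound_a, compound_b))
    delta = abs(affinity_a - affinity_b)
    return CompoundPair(compound_a=a, compound_b=b, target_id=target_id,
                        similarity=triple, delta_affinity=delta,
                        label=int(delta >= cfg.affinity_threshold))


def mine_ac_dataset(records: list[InteractionRecord],
                    molecules: dict[str, Molecule],
                    cfg: MiningConfig = MiningConfig()) -> list[CompoundPair]:
    """Mine labeled similar pairs per target and combine across targets.

    ``records`` must be aggregated (one affinity per compound-target);
    ``molecules`` maps compound_id to its featurized Molecule. Similarity
    triples are computed once per unordered compound pair and reused across
    targets. Compounds whose canonical SMILES coincide are never paired
    with themselves.
    """
    if not records:
        warnings.warn("mine_ac_dataset: empty input, empty output")
        return []
    affinity = {(r.compound_id, r.target_id): r.affinity for r in records}
    if len(affinity) != len(records):
        raise ValueError("records are not aggregated: duplicate (compound, target)")
    targets = sorted({r.target_id for r in records})

    triple_cache: dict[tuple[str, str], SimilarityTriple] = {}

    def triple_for(a: str, b: str) -> SimilarityTriple:
        key = (a, b)
        if key not in triple_cache:
            triple_cache[key] = similarity_triple(molecules[a], molecules[b])
        return triple_cache[key]

    out: list[CompoundPair] = []
    per_target: dict[str, tuple[int, int]] = {}
    for t in targets:
        n_ac = n_non = 0
        for a, b in enumerate_candidate_pairs(records, t):
            if molecules[a].smiles == molecules[b].smiles:
                continue  # identical structures are not a pair
            triple = triple_for(a, b)
            if triple.max() < cfg.similarity_threshold:
                continue
            pair = label_pair(a, b, t, triple,
                              affinity[(a, t)], affinity[(b, t)], cfg)
            out.append(pair)
            if pair.label:
                n_ac += 1
            else:
                n_non += 1
        per_target[t] = (n_ac, n_non)
    total_ac = sum(v[0] for v in per_target.values())
    logger.info("mined %d pairs (%d AC, %d non-AC) across %d targets",
                len(out), total_ac, len(out) - total_ac, len(targets))
    return out


def pairs_to_frame(pairs: list[CompoundPair]) -> pd.DataFrame:
    """Tidy pair table with one row per labeled pair."""
    return pd.DataFrame(
        [(p.compound_a, p.compound_b, p.target_id,
          p.similarity.substructure_sim, p.similarity.scaffold_sim,
          p.similarity.smiles_sim, p.delta_affinity, p.label) for p in pairs],
        columns=PAIR_COLUMNS)


def frame_to_pairs(df: pd.DataFrame) -> list[CompoundPair]:
    return [CompoundPair(
        compound_a=row.compound_a, compound_b=row.compound_b,
        target_id=row.target_id,
        similarity=SimilarityTriple(row.sim_substructure, row.sim_scaffold,
                                    row.sim_smiles),
        delta_affinity=row.delta_affinity, label=int(row.label))
        for row in df.itertuples(index=False)]
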