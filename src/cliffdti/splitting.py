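"""Compound-based and random splits shared between the DTI and AC tasks.

The compound-based split assigns every *compound* to exactly one partition.
Interactions follow their compound; a compound pair goes to a partition only
if both members sit there, and cross-partition pairs are dropped (and
counted). Because both tasks are driven by the same assignment, the
train/test compound sets of the AC and DTI tasks coincide and no compound
can leak information from training to test through either task.

The random pair split is the over-optimistic baseline mode: pairs are
shuffled irrespective of shared compounds, so one compound may appear on
both sides of the split via different pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ac_mining import CompoundPair, InteractionRecord

PARTITIONS = ("train", "validation", "test")


@dataclass
class SplitAssignment:
    """Compound -> partition map with the settings that produced it."""

    partition_of: dict[str, str]
    mode: str
    seed: int
    fractions: tuple[float, float, float]

    def compounds_in(self, partition: str) -> set[str]:
        return {c for c, p in self.partition_of.items() if p == partition}


def _check_fractions(fractions) -> tuple[float, float, float]:
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be three non-negative numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    return fractions


def split_compounds(compound_ids, fractions=(0.72, 0.08, 0.2),
                    seed: int = 0) -> SplitAssignment:
    """Uniformly random compound partition at the stated fractions.

    Deterministic given the seed. Counts are the rounded fraction targets;
    train absorbs the rounding remainder.
    """
    fractions = _check_fractions(fractions)
    ids = sorted(set(compound_ids))
    if len(ids) < 3:
        raise ValueError("need at least 3 distinct compounds to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n = len(ids)
    n_val = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))
    n_train = n - n_val - n_test
    if n_train <= 0 and fractions[0] > 0:
        raise ValueError("train partition rounded to empty")
    partition_of: dict[str, str] = {}
    for rank, idx in enumerate(order):
        if rank < n_train:
            part = "train"
        elif rank < n_train + n_val:
            part = "validation"
        else:
            part = "test"
        partition_of[ids[idx]] = part
    return SplitAssignment(partition_of=partition_of, mode="compound_based",
                           seed=seed, fractions=fractions)


def split_dti(records: list[InteractionRecord], assignment: SplitAssignment):
    """Route every interaction to the partition of its compound.

    No interaction is ever dropped; an unknown compound is an error.
    """
    out = {p: [] for p in PARTITIONS}
    for rec in records:
        part = assignment.partition_of.get(rec.compound_id)
        if part is None:
            raise KeyError(f"compound {rec.compound_id!r} missing from assignment")
        out[part].append(rec)
    return out["train"], out["validation"], out["test"]


def split_pairs(pairs: list[CompoundPair], assignment: SplitAssignment):
    """Compound-exclusive pair split: both members must share the partition.

    Returns (train, validation, test, n_dropped); the dropped pairs are
    exactly the cross-partition ones, so no compound contributes pairs to
    two partitions.
    """
    if assignment.mode != "compound_based":
        raise ValueError("split_pairs requires a compound_based assignment")
    out = {p: [] for p in PARTITIONS}
    dropped = 0
    for pair in pairs:
        pa = assignment.partition_of.get(pair.compound_a)
        pb = assignment.partition_of.get(pair.compound_b)
        if pa is None or pb is None:
            raise KeyError(f"pair ({pair.compound_a}, {pair.compound_b}) has a "
                           "compound missing from the assignment")
        if pa == pb:
            out[pa].append(pair)
        else:
            dropped += 1
    return out["train"], out["validation"], out["test"], dropped


def split_pairs_random(pairs: list[CompoundPair], fractions=(0.72, 0.08, 0.2),
                       seed: int = 0):
    """Shuffle pairs and cut at the fractions, ignoring shared compounds."""
    fractions = _check_fractions(fractions)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    n = len(pairs)
    n_val = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))
    n_train = n - n_val - n_test
    shuffled = [pairs[i] for i in order]
    return (shuffled[:n_train],
            shuffled[n_train:n_train + n_val],
            shuffled[n_train + n_val:])


def assert_no_compound_leakage(assignment: SplitAssignment,
                               dti_splits=None, pair_splits=None) -> None:
    """Raise if any compound occurs in two partitions of either task."""
    seen: dict[str, str] = {}

    def note(compound: str, part: str):
        prev = seen.setdefault(compound, part)
        if prev != part:
            raise AssertionError(
                f"compound {compound!r} leaks between {prev} and {part}")

    if dti_splits is not None:
        for part, records in zip(PARTITIONS, dti_splits):
            for rec in records:
                note(rec.compound_id, part)
    if pair_splits is not None:
        for part, pairs in zip(PARTITIONS, pair_splits):
            for pair in pairs:
                note(pair.compound_a, part)
                note(pair.compound_b, part)
    for compound, part in seen.items():
        if assignment.partition_of.get(compound) != part:
            raise AssertionError(
                f"compound {compound!r} observed in {part} but assigned to "
                f"{assignment.partition_of.get(compound)}")
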