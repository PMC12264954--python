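"""Desk-scale synthetic chemogenomic datasets with planted activity cliffs.

The generator enumerates a scaffold x R-group combinatorial library: each
scaffold template is a small drug-like core (a distinct ring system, so
Bemis-Murcko scaffolds separate the series) with one attachment point that
takes a substituent fragment. Within a series, compounds share the scaffold
(scaffold similarity 1) and differ by one small R-group, which is exactly
the dense near-neighbor structure the >= 0.9 similarity filter needs;
across series, all three similarity criteria are low.

Affinities are additive on the log10 scale:

    latent(c, t) = base(scaffold(c), t) + effect(R(c), t) + cliff(scaffold(c), t, R(c))
    observed(c, t) = latent(c, t) + Normal(0, noise_sd)

with base ~ Uniform(4, 9) per (scaffold, target), small R-group effects
~ Normal(0, substituent_effect_sd), and a cliff term planted per
(scaffold, target, R-group) slot with probability ``cliff_rate`` and
magnitude ~ Uniform(cliff_magnitude_range). A same-series pair with exactly
one cliff member thus jumps by >= the cliff magnitude — a planted activity
cliff the miner should recover.

Cliff presence and sign are decided at the (target, R-group) level and
shared across scaffold series (the magnitude is redrawn per series). This
mimics a pharmacophore-bearing R-group that flips activity on a target
wherever it appears, and it is what makes the AC task *learnable* under a
compound-exclusive split: a model that never saw a test compound can still
have seen the same R-group trigger cliffs on the same target in another
series. Were the indicators independent per (scaffold, target, R-group)
triple, test-set cliffs would be irreducible noise and no classifier could
beat chance on them. The noise-free latents and the planted per-triple
cliff table are returned as ground truth for recovery tests.

The whole dataset is a pure function of :class:`SyntheticConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ac_mining import InteractionRecord
from .chemio import Molecule, canonicalize_smiles, featurize

# Cores with one {R} attachment point. Distinct ring systems keep
# cross-series scaffold similarity low, and the varied acyclic decorations
# keep cross-series SMILES similarity below the 0.9 mining threshold.
SCAFFOLD_TEMPLATES = (
    "O=C(N)c1ccc({R})cc1",            # benzamide (benzene core)
    "O=S(=O)(NC)c1ccc({R})cn1",       # pyridine sulfonamide
    "N#Cc1cc({R})oc1",                # furan nitrile
    "O=C(NCC)c1ccc2ccc({R})cc2c1",    # naphthamide
    "OCCn1cc({R})cn1",                # imidazole ethanol
    "O=C(O)Cc1csc({R})n1",            # thiazole acetic acid
    "NC(=O)Cc1ncc({R})cn1",           # pyrimidine acetamide
    "O=C(NC(C)C)C1CCC({R})CC1",       # cyclohexane carboxamide
)

# R-groups carry at least one full radius-2 environment of their own, so
# their fingerprint signature identifies them across scaffold series (the
# attachment-adjacent environments are scaffold-specific and do not).
SUBSTITUENTS = (
    "CC(C)C", "CC(C)(C)C", "OC(F)(F)F", "CCN(C)C", "CC(N)=O", "CC(=O)OC",
    "CS(C)(=O)=O", "OCC(F)(F)F", "CN(C)C=O", "CCC#N", "COC(C)C", "CNC(C)=O",
    "CCSC", "OCCOC", "CC(O)CO", "CCC(F)(F)F", "CN(C)S(C)(=O)=O", "CCOC(C)=O",
    "CC(C)NC=O", "OCC(C)(C)O",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the synthetic chemogenomic matrix.

    Defaults give a multi-target matrix with dense within-series similar
    pairs and an AC fraction in the imbalanced 10-30% regime typical of
    curated bioactivity extracts: cliff_rate 0.15 makes 15% of
    (target, R-group) combinations cliff-prone, so about
    2 x 0.15 x 0.85 = 26% of same-series pairs straddle exactly one cliff. Cliff magnitudes start at
    1.5 log10 units, safely above the 1.0 (10-fold) labeling threshold;
    R-group effects (sd 0.2) and measurement noise (sd 0.1) stay well below
    it, so mined labels recover the planted ones.
    """

    n_scaffolds: int = 6
    substituents_per_scaffold: int = 12
    n_targets: int = 8
    cliff_rate: float = 0.15
    cliff_magnitude_range: tuple[float, float] = (1.5, 3.0)
    substituent_effect_sd: float = 0.2
    noise_sd: float = 0.1
    seed: int = 0
    radius: int = 2
    n_bits: int = 1024

    def __post_init__(self):
        if not (0.0 <= self.cliff_rate <= 1.0):
            raise ValueError("cliff_rate must be in [0, 1]")
        lo, hi = self.cliff_magnitude_range
        if not (0 < lo <= hi):
            raise ValueError("cliff_magnitude_range must be 0 < low <= high")
        if self.n_scaffolds > len(SCAFFOLD_TEMPLATES):
            raise ValueError(
                f"at most {len(SCAFFOLD_TEMPLATES)} scaffolds available")
        if self.substituents_per_scaffold > len(SUBSTITUENTS):
            raise ValueError(
                f"at most {len(SUBSTITUENTS)} substituents available")


@dataclass
class GroundTruth:
    """Noise-free latents and the planted cliff table for recovery tests."""

    latent: dict[tuple[str, str], float]          # (compound, target) -> affinity
    cliff: dict[tuple[int, str, int], float]      # (scaffold, target, sub) -> signed magnitude
    scaffold_of_compound: dict[str, int] = field(default_factory=dict)
    substituent_of_compound: dict[str, int] = field(default_factory=dict)


def _compound_id(scaffold_idx: int, sub_idx: int) -> str:
    return f"S{scaffold_idx}_R{sub_idx}"


def generate_library(cfg: SyntheticConfig) -> dict[str, Molecule]:
    """Enumerate and featurize the scaffold x substituent library.

    Every emitted SMILES round-trips through the parser; products are
    unique by construction (distinct cores, distinct R-groups).
    """
    molecules: dict[str, Molecule] = {}
    seen: set[str] = set()
    for si in range(cfg.n_scaffolds):
        template = SCAFFOLD_TEMPLATES[si]
        for ri in range(cfg.substituents_per_scaffold):
            smiles = template.format(R=SUBSTITUENTS[ri])
            canon = canonicalize_smiles(smiles)  # raises on invalid template
            if canon in seen:
                raise ValueError(f"duplicate product {canon} from {template}")
            seen.add(canon)
            cid = _compound_id(si, ri)
            molecules[cid] = featurize(cid, canon, radius=cfg.radius,
                                       n_bits=cfg.n_bits)
    return molecules


def generate_affinities(library: dict[str, Molecule],
                        cfg: SyntheticConfig):
    """Draw the additive affinity surface and noisy observations.

    Returns ``(records, truth)``: one observed InteractionRecord per
    (compound, target) and the GroundTruth with noise-free latents.
    """
    rng = np.random.default_rng(cfg.seed)
    targets = [f"T{k}" for k in range(cfg.n_targets)]
    base = {(si, t): rng.uniform(4.0, 9.0)
            for si in range(cfg.n_scaffolds) for t in targets}
    effect = {(ri, t): rng.normal(0.0, cfg.substituent_effect_sd)
              for ri in range(cfg.substituents_per_scaffold) for t in targets}
    lo, hi = cfg.cliff_magnitude_range
    # cliff-prone (target, R-group) combinations, sign shared across series
    prone: dict[tuple[str, int], float] = {}
    for t in targets:
        for ri in range(cfg.substituents_per_scaffold):
            if rng.random() < cfg.cliff_rate:
                prone[(t, ri)] = 1.0 if rng.random() < 0.5 else -1.0
    cliff: dict[tuple[int, str, int], float] = {}
    for si in range(cfg.n_scaffolds):
        for t in targets:
            for ri in range(cfg.substituents_per_scaffold):
                sign = prone.get((t, ri))
                if sign is not None:
                    cliff[(si, t, ri)] = sign * rng.uniform(lo, hi)

    records: list[InteractionRecord] = []
    truth = GroundTruth(latent={}, cliff=cliff)
    for cid in sorted(library):
        si, ri = (int(x[1:]) for x in cid.split("_"))
        truth.scaffold_of_compound[cid] = si
        truth.substituent_of_compound[cid] = ri
        for t in targets:
            latent = base[(si, t)] + effect[(ri, t)] + cliff.get((si, t, ri), 0.0)
            observed = latent + rng.normal(0.0, cfg.noise_sd)
            truth.latent[(cid, t)] = latent
            records.append(InteractionRecord(cid, t, observed))
    return records, truth


def generate_dataset(cfg: SyntheticConfig):
    """Convenience: library, observed records, and ground truth in one call."""
    library = generate_library(cfg)
    records, truth = generate_affinities(library, cfg)
    return library, records, truth


def ground_truth_ac_labels(truth: GroundTruth, mined_pairs,
                           affinity_threshold: float = 1.0) -> list[int]:
    """Labels the miner would produce at zero noise, from latent affinities."""
    labels = []
    for pair in mined_pairs:
        key_a = (pair.compound_a, pair.target_id)
        key_b = (pair.compound_b, pair.target_id)
        if key_a not in truth.latent or key_b not in truth.latent:
            raise KeyError(f"pair ({pair.compound_a}, {pair.compound_b}, "
                           f"{pair.target_id}) not covered by ground truth")
        delta = abs(truth.latent[key_a] - truth.latent[key_b])
        labels.append(int(delta >= affinity_threshold))
    return labels
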