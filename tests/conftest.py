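import numpy as np
import pytest

from cliffdti.ac_mining import InteractionRecord, MiningConfig, mine_ac_dataset
from cliffdti.chemio import featurize
from cliffdti.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic dataset shared by mining/splitting/grid tests."""
    cfg = SyntheticConfig(n_scaffolds=4, substituents_per_scaffold=8,
                          n_targets=4, seed=42)
    library, records, truth = generate_dataset(cfg)
    return cfg, library, records, truth


@pytest.fixture(scope="session")
def mined_pairs(small_dataset):
    cfg, library, records, truth = small_dataset
    return mine_ac_dataset(records, library, MiningConfig())


@pytest.fixture(scope="session")
def simple_molecules():
    """A handful of hand-picked molecules with known structure."""
    smiles = {
        "ethanol": "CCO",
        "ethylamine": "CCN",
        "toluene": "Cc1ccccc1",
        "phenethylamine": "NCCc1ccccc1",
        "pyridine": "c1ccncc1",
    }
    return {name: featurize(name, s) for name, s in smiles.items()}


def brute_force_mine(records, molecules, sim_threshold=0.9, aff_threshold=1.0):
    """Independent O(n^2) reference miner used as the oracle in tests.

    Deliberately written without reusing the production code paths: direct
    double loop per target, explicit max over the three criteria.
    """
    from cliffdti.chemio import similarity_triple

    affinity = {}
    for r in records:
        affinity.setdefault((r.compound_id, r.target_id), []).append(r.affinity)
    affinity = {k: sum(v) / len(v) for k, v in affinity.items()}
    targets = sorted({t for _, t in affinity})
    out = []
    for t in targets:
        compounds = sorted({c for c, tt in affinity if tt == t})
        for i in range(len(compounds)):
            for j in range(i + 1, len(compounds)):
                a, b = compounds[i], compounds[j]
                if molecules[a].smiles == molecules[b].smiles:
                    continue
                tr = similarity_triple(molecules[a], molecules[b])
                best = max(tr.substructure_sim, tr.scaffold_sim, tr.smiles_sim)
                if best < sim_threshold:
                    continue
                delta = abs(affinity[(a, t)] - affinity[(b, t)])
                out.append((a, b, t, round(delta, 12),
                            int(delta >= aff_threshold)))
    return sorted(out)
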