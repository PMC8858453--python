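import numpy as np
import pandas as pd
import pytest

import seqpanel as sp


def make_pedigree(rows, breed="LR"):
    """rows: (id, sire, dam, sex, generation[, available])."""
    recs = []
    for r in rows:
        rid, sire, dam, sex, gen = r[:5]
        avail = r[5] if len(r) > 5 else True
        recs.append(
            {"id": rid, "sire": sire, "dam": dam, "sex": sex,
             "generation": gen, "breed": breed, "available": avail}
        )
    return sp.Pedigree(pd.DataFrame(recs))


def random_pedigree(n, rng, breed="LR"):
    """Random acyclic pedigree: each animal's parents drawn from earlier animals."""
    rows = []
    for i in range(n):
        rid = f"A{i:02d}"
        if i < 2 or rng.random() < 0.3:
            sire = dam = "0"
        else:
            males = [r[0] for r in rows if r[3] == "M"]
            females = [r[0] for r in rows if r[3] == "F"]
            sire = str(rng.choice(males)) if males and rng.random() < 0.9 else "0"
            dam = str(rng.choice(females)) if females and rng.random() < 0.9 else "0"
        sex = "M" if rng.random() < 0.5 else "F"
        rows.append((rid, sire, dam, sex, max(1, n - i)))
    return make_pedigree(rows, breed)


@pytest.fixture(scope="session")
def small_population():
    """One simulated breed small enough for exhaustive checks."""
    cfg = sp.SimConfig(
        n_founders=40, n_generations=4, n_sires_used=5, n_dams_used=15,
        offspring_per_mating=3, n_chromosomes=2, markers_per_chromosome=150,
        missing_rate=0.0, availability_rate=0.9, breed="LR", seed=17,
    )
    ped, H, G = sp.simulate_population(cfg)
    return cfg, ped, H, G
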