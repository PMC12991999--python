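import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import tcrgvhd as t

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def small_repertoire() -> t.Repertoire:
    """Six clonotypes with singletons and doubletons: Chao1 = 6 + 9/4."""
    return t.Repertoire.from_counts(
        {
            "CASSIRSSYEQYF": 1,
            "CASSLGQAYEQYF": 1,
            "CASRTGELFF": 1,
            "CASSPDRGAYGYTF": 2,
            "CASSQDLNTEAFF": 2,
            "CASSYSTGDEQFF": 5,
        }
    )


@pytest.fixture
def random_repertoire_factory():
    """Random small repertoires for oracle-equivalence checks."""

    def make(rng: np.random.Generator, max_richness: int = 50) -> t.Repertoire:
        n = int(rng.integers(1, max_richness + 1))
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        seen = set()
        while len(seen) < n:
            L = int(rng.integers(8, 18))
            seen.add("C" + "".join(rng.choice(letters, L - 2)) + "F")
        counts = rng.integers(1, 50, size=n)
        df = pd.DataFrame(
            {
                "cdr3_aa": sorted(seen),
                "v_gene": [f"TRBV{int(g)}" for g in rng.integers(1, 10, size=n)],
                "j_gene": [f"TRBJ1-{int(g)}" for g in rng.integers(1, 7, size=n)],
                "count": counts,
            }
        )
        return t.Repertoire(sample_id="rand", clonotypes=df)

    return make


@pytest.fixture
def tiny_cohort() -> list[t.Repertoire]:
    cfg = t.CohortConfig(
        n_per_group={"GVHD": 3, "NO_GVHD": 3},
        richness={"GVHD": 150, "NO_GVHD": 100},
        total_reads=12_000,
        motif_spike_fraction=0.05,
        seed=42,
    )
    return t.generate_cohort(cfg)
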