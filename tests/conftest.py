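import numpy as np
import pytest

from proximap.ingest import Interactome, PreyRecord, build_interactomes, filter_preys
from proximap.synthetic import GeneratorConfig, generate_bioid


def make_record(**kw) -> PreyRecord:
    """A valid PreyRecord with overridable fields."""
    defaults = dict(
        bait="RAD51B",
        condition="untreated",
        prey="CHEK1",
        avg_spec=5.0,
        unique_peptides=2,
        iprophet_prob=0.99,
        protein_length_aa=476,
        n_replicates=2,
    )
    defaults.update(kw)
    return PreyRecord(**defaults)


@pytest.fixture(scope="session")
def small_noiseless_config() -> GeneratorConfig:
    """Scaled-down noiseless study design for exact set-recovery checks."""
    return GeneratorConfig(
        seed=11,
        n_all_common=50,
        n_bcdx2_exclusive=12,
        n_cx3_exclusive=6,
        n_bait_specific=10,
        n_background=40,
        n_hu_modulated=10,
        noiseless=True,
    )


@pytest.fixture(scope="session")
def noiseless_bioid(small_noiseless_config):
    records, truth = generate_bioid(small_noiseless_config)
    return records, truth


@pytest.fixture(scope="session")
def noiseless_interactomes(noiseless_bioid):
    records, truth = noiseless_bioid
    kept, _ = filter_preys(records)
    return build_interactomes(kept, "untreated"), truth


def random_interactomes(rng: np.random.Generator, n_preys: int = 60) -> dict:
    """Five baits with random prey subsets, for brute-force oracles."""
    from proximap.setalgebra import BAITS

    preys = [f"P{i:03d}" for i in range(n_preys)]
    out = {}
    for bait in BAITS:
        chosen = [p for p in preys if rng.random() < 0.4]
        out[bait] = Interactome(
            bait=bait,
            condition="untreated",
            preys={p: float(rng.integers(1, 30)) for p in chosen} or {"P000": 1.0},
        )
    return out
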