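import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from decurate.synth import DEFAULT_ARCHETYPES, SimDesign, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One shared synthetic study (150 contigs) with planted truth."""
    design = SimDesign(n_contigs=150, seed=42)
    ds, counts = simulate_dataset(design)
    return ds, counts


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def archetype_manifest(
    n: int, rng: np.random.Generator, archetypes=None, shapes=None
) -> pd.DataFrame:
    """Minimal manifest for count simulation without sequence generation."""
    shapes = shapes or DEFAULT_ARCHETYPES
    man = pd.DataFrame({"contig_id": [f"c{i:05d}" for i in range(n)]})
    base = np.exp(rng.uniform(np.log(20), np.log(200), n))
    arch = np.zeros(n, dtype=int) if archetypes is None else np.asarray(archetypes)
    man["archetype"] = arch
    for j, tp in enumerate((0, 3, 20, 96)):
        offs = np.array([shapes[a][j] if a else 0.0 for a in arch])
        man[f"mean_fpkm_{tp}"] = base * 2.0 ** offs
    return man


def random_lengths(n: int, rng: np.random.Generator) -> pd.Series:
    return pd.Series(
        rng.integers(300, 2000, n), index=[f"c{i:05d}" for i in range(n)]
    )
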