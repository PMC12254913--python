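import numpy as np
import pandas as pd
import pytest

from mycobloom import AsvTable, SimulationConfig, simulate_table


def make_table(counts: dict, fungal: set, dates=None, fractions=None,
               station="SOLA") -> AsvTable:
    """Build a small AsvTable from {asv_id: [counts per sample]}."""
    df = pd.DataFrame(counts).T
    n = df.shape[1]
    df.columns = [f"S{i+1}" for i in range(n)]
    df.index.name = "asv_id"
    tax = pd.DataFrame({
        "domain": "Eukaryota", "supergroup": "unassigned",
        "division": ["Fungi" if a in fungal else "Dinoflagellata" for a in df.index],
        "class": "unassigned", "order": "unassigned", "family": "unassigned",
        "genus": "unassigned", "species": "unassigned",
        "is_fungal": [a in fungal for a in df.index],
    }, index=df.index)
    dates = dates or [f"2015-01-{d:02d}" for d in range(1, n + 1)]
    fractions = fractions or ["gt3um"] * n
    meta = pd.DataFrame({
        "date": pd.to_datetime(dates),
        "size_fraction": fractions,
        "station": station,
    }, index=df.columns)
    meta.index.name = "sample_id"
    return AsvTable(counts=df.astype(np.int64), taxonomy=tax, samples=meta)


def random_table(rng: np.random.Generator, n_asvs=20, n_samples=10,
                 n_fungal=8, max_count=400) -> AsvTable:
    ids = [f"A{i:03d}" for i in range(n_asvs)]
    counts = {a: rng.integers(0, max_count, size=n_samples).tolist() for a in ids}
    # guarantee every sample has reads
    counts[ids[0]] = (rng.integers(1, max_count, size=n_samples)).tolist()
    return make_table(counts, fungal=set(ids[:n_fungal]))


@pytest.fixture(scope="session")
def sim_default():
    """The default synthetic series, seed 42 (shared across tests)."""
    return simulate_table(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def sim_small():
    """A fast small series for structural tests."""
    cfg = SimulationConfig(seed=7, years=2.0, n_background_asvs=30,
                           n_rhythmic=3, n_chaotic=3, n_ephemeral=3)
    return simulate_table(cfg)
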