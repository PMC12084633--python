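import numpy as np
import pandas as pd
import pytest

import neurosplice as ns


@pytest.fixture(scope="session")
def small_dataset() -> ns.SyntheticDataset:
    """A seeded 8-cell dataset with planted signals, shared across tests."""
    cfg = ns.SimulationConfig(
        n_cells=8, n_events=80, n_planted_unique=2, seed=11
    )
    return ns.generate_splicing_dataset(cfg)


@pytest.fixture(scope="session")
def small_results(small_dataset) -> pd.DataFrame:
    psi = ns.compute_psi_table(small_dataset.counts, small_dataset.events)
    return ns.run_all_pairs(psi, small_dataset.events)


def make_extreme_psi(n_cells: int, n_reps: int, target_psi: float, other_psi: float,
                     target_cell: str = "N01") -> tuple[pd.DataFrame, list[ns.SplicingEvent]]:
    """One cassette event with a flat PSI contrast between one cell and the rest."""
    event = ns.SplicingEvent(
        "EV1", "G1", "chrI", "+", "cassette",
        ((100, 300), (100, 600), (400, 600)), (0, 2),
    )
    cells = [f"N{i + 1:02d}" for i in range(n_cells)]
    rows = [
        {"event_id": "EV1", "cell_type": c, "replicate": r + 1,
         "psi": target_psi if c == target_cell else other_psi, "coverage": 200}
        for c in cells for r in range(n_reps)
    ]
    return pd.DataFrame(rows), [event]
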