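import numpy as np
import pandas as pd
import pytest

from painrhythm.phenotyping import N_DAYS, SLOT_HOURS


def grid_to_diary(grids: dict[str, np.ndarray], scale: str = "pain") -> pd.DataFrame:
    """Build a diary table whose entries sit exactly on the scheduled slots."""
    rows = []
    start = pd.Timestamp("2020-01-06")
    for pid, g in grids.items():
        for d in range(N_DAYS):
            for s, hour in enumerate(SLOT_HOURS):
                v = g[d][s]
                if np.isnan(v):
                    continue
                rows.append(
                    {
                        "participant_id": pid,
                        "timestamp": start + pd.Timedelta(days=d, hours=hour),
                        "scale": scale,
                        "score": int(v),
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_grids(rng, n_participants: int, missing_rate: float = 0.15) -> dict[str, np.ndarray]:
    grids = {}
    for i in range(n_participants):
        g = rng.integers(0, 11, size=(N_DAYS, 3)).astype(float)
        mask = rng.random((N_DAYS, 3)) < missing_rate
        g[mask] = np.nan
        # guarantee at least one SD-evaluable day so everyone is classifiable
        g[0, :2] = rng.integers(0, 11, size=2)
        grids[f"P{i:02d}"] = g
    return grids
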