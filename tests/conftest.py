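import numpy as np
import pandas as pd
import pytest

from tracknest.io import REQUIRED_COLUMNS, trackset_from_frame
from tracknest.simulate import Design, SimConfig, simulate_experiment


def make_track_frame(tracks: dict, *, dt: float = 60.0, date="day1", mouse="m1",
                     node="LN1", fld="f1", population="WT", dye="CFSE") -> pd.DataFrame:
    """Build a canonical track frame from {track_id: [(x, y, z), ...]}.

    Per-track metadata can be overridden by passing
    {track_id: {"points": [...], "population": ..., "dye": ...}}.
    """
    rows = []
    for tid, spec in tracks.items():
        if isinstance(spec, dict):
            points = spec["points"]
            meta = {k: spec.get(k, v) for k, v in
                    dict(date=date, mouse=mouse, lymph_node=node, field=fld,
                         population=population, dye=dye).items()}
        else:
            points = spec
            meta = dict(date=date, mouse=mouse, lymph_node=node, field=fld,
                        population=population, dye=dye)
        for i, (x, y, z) in enumerate(points):
            rows.append({**meta, "track_id": tid, "time_s": i * dt,
                         "x_um": x, "y_um": y, "z_um": z})
    return pd.DataFrame(rows)[list(REQUIRED_COLUMNS)]


@pytest.fixture
def simple_trackset():
    """Two 3-point tracks: a 3-4-5 right angle and a straight line."""
    frame = make_track_frame({
        "t1": [(0, 0, 0), (3, 0, 0), (3, 4, 0)],
        "t2": [(0, 0, 0), (5, 0, 0), (10, 0, 0)],
    })
    return trackset_from_frame(frame)


@pytest.fixture
def null_sim():
    """Small null-effect experiment with cell-level heterogeneity."""
    cfg = SimConfig(
        design=Design(n_dates=2, n_mice=2, n_nodes=4, n_fields=4,
                      cells_per_field=15, max_frames=25),
        sigma_cell=0.35, sigma_step=0.35, censor_on_exit=False, seed=11,
    )
    return simulate_experiment(cfg)


def child_seeds(seed: int, n: int) -> list[int]:
    """Independent sub-seeds below 2**31 for replicate loops."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]
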