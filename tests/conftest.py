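import numpy as np
import pandas as pd
import pytest

from wellmotion import PlateMap, SceneConfig, simulate_well_pair


def small_scene(**kw) -> SceneConfig:
    """Fast 256-px scene used throughout the suite."""
    defaults = dict(
        shape=(256, 256),
        n_worms=6,
        worm_length_px=(24, 36),
        worm_width_px=(3, 5),
        displacement_px=14.0,
        moving_fraction=0.5,
        seed=0,
    )
    defaults.update(kw)
    return SceneConfig(**defaults)


@pytest.fixture(scope="session")
def well_pair():
    """One deterministic half-moving scene with ground truth."""
    return simulate_well_pair(small_scene(seed=11))


@pytest.fixture()
def mini_plate_map() -> PlateMap:
    rows = []
    doses = [0.25, 0.5, 1.0, 2.0, 4.0]
    for c in range(1, 7):
        well = f"A{c:02d}"
        if c == 1:
            rows.append(dict(well=well, compound="none", dose=0.0, unit="mM",
                             strain="N2", stage="L1", is_control=True))
        else:
            rows.append(dict(well=well, compound="aldicarb", dose=doses[c - 2],
                             unit="mM", strain="N2", stage="L1", is_control=False))
    return PlateMap(pd.DataFrame(rows))


def make_results(plate_map: PlateMap, times, fms_fn) -> pd.DataFrame:
    """Tidy results table from a function (well_row, t) -> fms."""
    rows = []
    pm = plate_map.table
    for _, meta in pm.iterrows():
        for t in times:
            fms = fms_fn(meta, t)
            rows.append(dict(
                well=meta["well"], time_min=float(t), compound=meta["compound"],
                dose=meta["dose"], unit=meta["unit"], strain=meta["strain"],
                stage=meta["stage"], is_control=meta["is_control"],
                fms=fms, moving_px=int(1000 * fms), total_px=1000, valid=True,
            ))
    return pd.DataFrame(rows)
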