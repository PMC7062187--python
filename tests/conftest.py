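import numpy as np
import pandas as pd
import pytest

from mitoscreen import ScreenDataset, get_layout
from mitoscreen.screen import META_COLUMNS, default_parameter_names
from mitoscreen.synthetic import ScreenSimConfig, simulate_screen


def make_dataset(values_by_well, parameter_names=None, layout="primary", replicates=1):
    """Build a small dataset from {well: value-vector-or-scalar} mappings.

    ``values_by_well`` maps well name to either a scalar (same value for
    every parameter/replicate) or a list of per-replicate scalars.
    """
    layout = get_layout(layout)
    params = parameter_names or default_parameter_names(4)
    rows = []
    for rep in range(1, replicates + 1):
        for well, vals in values_by_well.items():
            role = layout.role_map[well]
            v = vals[rep - 1] if isinstance(vals, (list, tuple)) else vals
            row = {
                "plate_id": "P001",
                "replicate": rep,
                "well": well,
                "role": role,
                "gene_id": f"GENE_{well}" if role == "sample" else None,
                "sirna_id": f"GENE_{well}_s1" if role == "sample" else None,
            }
            row.update({p: float(v) for p in params})
            rows.append(row)
    wells = pd.DataFrame(rows, columns=list(META_COLUMNS) + params)
    return ScreenDataset(layout, params, wells)


@pytest.fixture(scope="session")
def planted_screen():
    """A small primary screen with planted modulators and a bad plate."""
    cfg = ScreenSimConfig(
        n_plates=4,
        replicates=3,
        seed=7,
        planted_positive_modulators=[f"POS{i:02d}" for i in range(8)],
        planted_negative_modulators=[f"NEG{i:02d}" for i in range(8)],
        row_slope=0.4,
        col_slope=-0.25,
        bad_plate_ids=["P003"],
    )
    return simulate_screen(cfg), cfg


@pytest.fixture(scope="session")
def null_screen():
    """A small screen with no planted effects and no gradients."""
    cfg = ScreenSimConfig(n_plates=3, replicates=3, seed=13)
    return simulate_screen(cfg), cfg


@pytest.fixture
def rng():
    return np.random.default_rng(0)
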