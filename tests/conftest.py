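import numpy as np
import pandas as pd
import pytest

from volatilome import simulate
from volatilome.simulate import (
    DEFAULT_AREA_ISTD,
    DEFAULT_MASS_ISTD,
    DEFAULT_MASS_POWDER,
)


def replicate_table(cells: dict[tuple[str, str], list[float | None]]) -> pd.DataFrame:
    """Build a tidy replicate table whose semi-quantified values equal the
    given concentrations (None = missing run)."""
    rows = []
    for (sample, volatile), values in cells.items():
        for run, val in enumerate(values, start=1):
            area = (
                np.nan
                if val is None
                else val * DEFAULT_AREA_ISTD * DEFAULT_MASS_POWDER / (DEFAULT_MASS_ISTD * 100.0)
            )
            rows.append(
                {
                    "sample": sample,
                    "volatile": volatile,
                    "run": run,
                    "area": area,
                    "area_istd": DEFAULT_AREA_ISTD,
                    "mass_istd": DEFAULT_MASS_ISTD,
                    "mass_powder": DEFAULT_MASS_POWDER,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_panel():
    """40 varieties (4 clone pairs + 1 triple = 46 samples), 12 volatiles."""
    design = simulate.default_design(
        seed=3, n_varieties=40, n_volatiles=12, clone_groups=(2,) * 4 + (3,)
    )
    return simulate.simulate_panel(design)


@pytest.fixture(scope="session")
def small_matrix(small_panel):
    """Noise-free log-scale matrix of the small panel."""
    return np.log(small_panel.expected)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
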