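import numpy as np
import pandas as pd
import pytest

from aquarisk import METALS, generate
from aquarisk.synthetic_data import default_config

#: Published per-metal survey statistics (ug/L): mean, sd, min, max.
TABLE_STATS = {
    "Cr": (0.35, 0.24, 0.09, 2.26),
    "As": (1.61, 0.89, 0.42, 8.52),
    "Cd": (0.03, 0.02, 0.01, 0.13),
    "Pb": (0.39, 0.18, 0.08, 0.97),
    "Cu": (1.08, 1.02, 0.11, 9.17),
    "Zn": (11.49, 6.10, 2.40, 44.6),
    "Ni": (0.35, 0.25, 0.06, 2.03),
}


@pytest.fixture(scope="session")
def default_table() -> pd.DataFrame:
    """One default synthetic transect (110 sites, fixed seed)."""
    return generate(default_config(), seed=42)


@pytest.fixture()
def mean_concentration_table() -> pd.DataFrame:
    """Single pseudo-site at the published mean concentrations."""
    row = {"site_id": "M01", "bank": "left", "position": 1}
    row.update({m: TABLE_STATS[m][0] for m in METALS})
    return pd.DataFrame([row])


def make_table(values: dict[str, float], site_id: str = "S01",
               bank: str = "left", position: int = 1) -> pd.DataFrame:
    """One-site concentration table with zeros for unspecified metals."""
    row = {"site_id": site_id, "bank": bank, "position": position}
    row.update({m: 0.0 for m in METALS})
    row.update(values)
    return pd.DataFrame([row])


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
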