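import pandas as pd
import pytest

from soilqualkit import load_published_pca_table
from soilqualkit.simulate import default_factor_spec, generate_indicator_table
from soilqualkit.tables import AllometricCoef, PlotMeta, TreeInventory


@pytest.fixture(scope="session")
def pub_table():
    """The packaged published-table fixture."""
    return load_published_pca_table()


@pytest.fixture(scope="session")
def study_table():
    """Study-like synthetic table: 10 patterns x 3 plot-level samples."""
    return generate_indicator_table(default_factor_spec(seed=11))


@pytest.fixture
def tiny_inventory():
    df = pd.DataFrame(
        {
            "plot_id": ["p1", "p1", "p1"],
            "species": ["fir", "fir", "schima"],
            "is_broadleaf": [False, False, True],
            "dbh": [10.0, 20.0, 30.0],
            "height": [8.0, 14.0, 18.0],
        }
    )
    return TreeInventory(df)


@pytest.fixture
def tiny_coefs():
    return {
        "fir": AllometricCoef("fir", 0.05, 0.9),
        "schima": AllometricCoef("schima", 0.07, 0.88),
    }


@pytest.fixture
def tiny_meta():
    return PlotMeta("p1", "MIX", area=600.0, stand_age=20.0)
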