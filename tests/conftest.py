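import numpy as np
import pandas as pd
import pytest

from maizefrontier.io import Dataset, NORMALIZED_COLUMNS


def make_dataset(latitude, planting_doy, yield_mgha, **cols) -> Dataset:
    """Build a minimal in-memory Dataset for unit tests."""
    n = len(yield_mgha)
    df = pd.DataFrame({
        "year": pd.array(cols.get("year", [2014] * n), dtype="Int64"),
        "state": cols.get("state", ["KS"] * n),
        "county": cols.get("county", [f"KS-{i:03d}" for i in range(n)]),
        "latitude": np.asarray(latitude, dtype=float),
        "planting_doy": np.asarray(planting_doy, dtype=int),
        "yield_mgha": np.asarray(yield_mgha, dtype=float),
        "irrigated": pd.array(cols.get("irrigated", [pd.NA] * n), dtype="boolean"),
        "tillage": cols.get("tillage", [pd.NA] * n),
        "row_spacing_cm": cols.get("row_spacing_cm", [np.nan] * n),
        "seeding_rate": cols.get("seeding_rate", [np.nan] * n),
        "n_kgha": cols.get("n_kgha", [np.nan] * n),
        "p_kgha": cols.get("p_kgha", [np.nan] * n),
        "k_kgha": cols.get("k_kgha", [np.nan] * n),
        "dataset": cols.get("dataset", ["test"] * n),
    }, columns=list(NORMALIZED_COLUMNS))
    return Dataset(df=df, provenance="test")


@pytest.fixture
def tiny_csv(tmp_path):
    """Well-formed 3-row input CSV."""
    path = tmp_path / "tiny.csv"
    path.write_text(
        "year,state,county,latitude,planting_date,yield_value,yield_unit,"
        "grain_moisture,irrigated,tillage,row_spacing_cm,seeding_rate,"
        "n_kgha,p_kgha,k_kgha,dataset\n"
        "2015,KS,Riley,39.2,2015-04-15,14.5,mg_ha,0.155,true,NT,76,80000,200,80,90,contest\n"
        "2014,IA,Story,42.0,110,15.2,mg_ha,,false,CT,76,85000,220,90,95,contest\n"
        "2016,GA,Tift,31.4,75,12.1,mg_ha,0.155,,RT,,,,,,contest\n"
    )
    return path
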