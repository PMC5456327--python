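import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py


@pytest.fixture
def studies_df() -> pd.DataFrame:
    """Three studies spanning platforms, fluids and groups."""
    return pd.DataFrame({
        "study_id": ["S1", "S2", "S3"],
        "platform": ["transcriptomics", "proteomics", "proteomics"],
        "fluid": ["urine", "blood", "urine"],
        "group": ["naive", "naive", "ERT"],
        "n_case": pd.array([10, 8, pd.NA], dtype="Int64"),
        "n_control": pd.array([10, 6, pd.NA], dtype="Int64"),
        "ratio_convention": ["ratio"] * 3,
    })


@pytest.fixture
def alias_df() -> pd.DataFrame:
    """Alias map: C_GLA has three aliases, C_A..C_G are singletons."""
    rows = [("GLA", "C_GLA", "ENZ"), ("P06280", "C_GLA", "ENZ"),
            ("GLA_HUMAN", "C_GLA", "ENZ")]
    rows += [(f"g{i}", f"C_{c}", "MET")
             for i, c in enumerate("ABCDEFG")]
    return pd.DataFrame(rows, columns=["raw_id", "cluster_id", "tag"])


def write_tsv(df: pd.DataFrame, path) -> str:
    df.to_csv(path, sep="\t", index=False)
    return str(path)


@pytest.fixture
def write_studies(tmp_path, studies_df):
    return write_tsv(studies_df, tmp_path / "studies.tsv")
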