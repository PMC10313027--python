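"""Shared fixtures: small in-memory datasets and CSV builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sensorgamm.io import AlignedDataset


def make_dataset(columns: dict[str, np.ndarray], response: np.ndarray,
                 metadata: dict | None = None) -> AlignedDataset:
    """Aligned dataset on a synthetic 15-minute grid from raw arrays."""
    n = len(response)
    grid = pd.date_range("2020-01-01", periods=n, freq="15min", tz="UTC")
    cov = pd.DataFrame({k: np.asarray(v, dtype=float)
                        for k, v in columns.items()})
    if "time" not in cov.columns:
        cov["time"] = np.arange(n) * 15.0 / 1440.0
    return AlignedDataset(grid=grid, response=np.asarray(response, dtype=float),
                          covariates=cov, site_label="test",
                          metadata=metadata or {})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sensor_csv(tmp_path):
    """Write a canonical-layout sensor CSV and return its path."""

    def _write(name, rows, columns=("timestamp", "value", "qc_flag")):
        path = tmp_path / f"{name}.csv"
        pd.DataFrame(rows, columns=list(columns)).to_csv(path, index=False)
        return path

    return _write


CANONICAL_DIALECT = {"timestamp": "timestamp", "value": "value",
                     "flag": "qc_flag", "variable": "nitrate"}
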