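"""Sensor-table ingestion, QC filtering, grid alignment and collinearity screening.

The pipeline's inputs are delimited-text tables of timestamped sensor
measurements (one variable per file, arbitrary column names mapped through a
small *dialect* config).  This module turns those tables into an
:class:`AlignedDataset`: the response (nitrate) and every covariate matched
onto a common 15-minute grid, with anomalous measurements removed before
matching, plus a continuous ``time`` covariate in days.

Downstream model fitting always works on complete-case rows: a grid row is
usable only if the response and every candidate covariate are non-missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    DataValidityError,
    EmptyInputError,
    IdentifiabilityError,
)

logger = logging.getLogger(__name__)

#: Canonical variable names and their measurement units.
UNITS: dict[str, str] = {
    "nitrate": "umol/L",
    "specific_conductance": "uS/cm",
    "dissolved_oxygen": "mg/L",
    "temperature": "degC",
    "turbidity": "FNU",
    "elevation": "m",
}

VARIABLES: tuple[str, ...] = tuple(UNITS)

RESPONSE = "nitrate"
TIME_COLUMN = "time"

#: Nominal spacing of the response grid.
GRID_STEP = pd.Timedelta(minutes=15)

#: Default nearest-match window when joining covariates onto the grid.
DEFAULT_TOLERANCE = pd.Timedelta(seconds=60)


@dataclass(frozen=True)
class SensorRecord:
    """One timestamped measurement of one variable.

    ``qc_flag=True`` marks the measurement as anomalous; flagged records are
    discarded before grid alignment.
    """

    timestamp: pd.Timestamp
    variable: str
    value: float
    qc_flag: bool = False


@dataclass
class AlignedDataset:
    """Response and covariates on a common, regularly spaced time grid.

    Attributes
    ----------
    grid : pandas.DatetimeIndex
        Regular 15-minute timestamps (UTC).
    response : numpy.ndarray
        Nitrate on the grid; NaN where missing.
    covariates : pandas.DataFrame
        One float column per covariate (NaN = missing) plus a ``time``
        column in days since the first grid point.
    """

    grid: pd.DatetimeIndex
    response: np.ndarray
    covariates: pd.DataFrame
    site_label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        if len(self.grid) != len(self.response):
            raise ValueError("response length does not match grid")
        if len(self.covariates) != len(self.grid):
            raise ValueError("covariate rows do not match grid")
        if len(self.grid) > 1:
            steps = np.diff(self.grid.view("int64"))
            if not (steps == steps[0]).all():
                raise DataValidityError("grid spacing is not uniform")

    @property
    def n(self) -> int:
        return len(self.grid)

    @property
    def candidate_names(self) -> list[str]:
        """Covariate columns available for modelling (includes ``time``)."""
        return list(self.covariates.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask, True where a cell is missing."""
        mask = self.covariates.isna().copy()
        mask.insert(0, RESPONSE, np.isnan(self.response))
        return mask

    def complete_rows(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Rows where the response and the named covariates are all present."""
        if names is None:
            names = self.candidate_names
        ok = ~np.isnan(self.response)
        for name in names:
            if name not in self.covariates.columns:
                raise KeyError(f"unknown covariate {name!r}")
            ok &= self.covariates[name].notna().to_numpy()
        return ok

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path: str | Path) -> None:
        """Write one row per grid point, plus a ``.meta.yaml`` sidecar."""
        path = Path(path)
        out = pd.DataFrame({"timestamp": self.grid})
        out[RESPONSE] = self.response
        for col in self.covariates.columns:
            out[col] = self.covariates[col].to_numpy()
        out.to_csv(path, index=False)
        meta = {"site_label": self.site_label, **self.metadata}
        Path(f"{path}.meta.yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def from_csv(cls, path: str | Path) -> "AlignedDataset":
        path = Path(path)
        df = pd.read_csv(path)
        if df.empty:
            raise EmptyInputError(f"{path} is empty")
        grid = pd.DatetimeIndex(pd.to_datetime(df["timestamp"], utc=True))
        response = df[RESPONSE].to_numpy(dtype=float)
        covariates = df.drop(columns=["timestamp", RESPONSE]).astype(float)
        meta_path = Path(f"{path}.meta.yaml")
        metadata: dict = {}
        site = ""
        if meta_path.exists():
            metadata = yaml.safe_load(meta_path.read_text()) or {}
            site = metadata.pop("site_label", "")
        return cls(grid=grid, response=response, covariates=covariates,
                   site_label=site, metadata=metadata)


@dataclass
class VifReport:
    """Outcome of the greedy VIF elimination.

    ``vif`` holds, for retained covariates, the VIF in the final candidate
    set and, for dropped covariates, the VIF at the step where they were
    eliminated.
    """

    vif: dict[str, float]
    retained: list[str]
    dropped: list[str]
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"covariate": name, "vif": self.vif[name],
             "retained": name in self.retained}
            for name in self.vif
        ]
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Reading

_TRUTHY = {"1", "true", "t", "yes", "y"}


def load_dialect(path: str | Path) -> dict:
    """Load a column-mapping dialect from a YAML key-value file."""
    dialect = yaml.safe_load(Path(path).read_text())
    if not isinstance(dialect, dict):
        raise ConfigurationError(f"dialect file {path} is not a mapping")
    return dialect


def read_sensor_table(path: str | Path, dialect: Mapping) -> list[SensorRecord]:
    """Parse one delimited-text sensor table into records.

    ``dialect`` maps file columns onto record fields::

        timestamp: startDateTime        # required, ISO-8601 timestamps
        value: surfWaterNitrateMean     # required
        flag: finalQF                   # optional anomaly column
        variable: nitrate               # fixed name, or use variable_column

    Rows with unparseable timestamps or values are rejected and counted in
    the log; flagged rows are kept here (alignment removes them) so QC
    bookkeeping stays in one place.
    """
    for key in ("timestamp", "value"):
        if key not in dialect:
            raise ConfigurationError(f"dialect missing required key {key!r}")
    if "variable" not in dialect and "variable_column" not in dialect:
        raise ConfigurationError("dialect needs 'variable' or 'variable_column'")

    df = pd.read_csv(path)
    if df.empty:
        raise EmptyInputError(f"{path} contains no rows")

    needed = [dialect["timestamp"], dialect["value"]]
    if "flag" in dialect and dialect["flag"]:
        needed.append(dialect["flag"])
    if "variable_column" in dialect:
        needed.append(dialect["variable_column"])
    for col in needed:
        if col not in df.columns:
            raise ConfigurationError(f"{path}: missing required column {col!r}")

    ts = pd.to_datetime(df[dialect["timestamp"]], errors="coerce", utc=True)
    values = pd.to_numeric(df[dialect["value"]], errors="coerce")
    bad = ts.isna() | values.isna()
    n_rejected = int(bad.sum())
    if n_rejected:
        logger.info("%s: rejected %d unparseable row(s)", path, n_rejected)

    if "flag" in dialect and dialect["flag"]:
        raw = df[dialect["flag"]]
        flags = raw.astype(str).str.strip().str.lower().isin(_TRUTHY)
        flags |= pd.to_numeric(raw, errors="coerce").fillna(0) != 0
    else:
        flags = pd.Series(False, index=df.index)

    if "variable_column" in dialect:
        names = df[dialect["variable_column"]].astype(str)
    else:
        names = pd.Series(dialect["variable"], index=df.index)

    keep = df.index[~bad]
    order = ts[keep].sort_values(kind="stable").index
    return [
        SensorRecord(timestamp=ts[i], variable=names[i],
                     value=float(values[i]), qc_flag=bool(flags[i]))
        for i in order
    ]


# --------------------------------------------------------------------------
# Alignment

def align_to_response_grid(
    records: Iterable[SensorRecord],
    tolerance: pd.Timedelta = DEFAULT_TOLERANCE,
    site_label: str = "",
) -> AlignedDataset:
    """Match every variable onto the nitrate measurement grid.

    The grid is regular at 15 minutes from the first to the last nitrate
    timestamp.  Each variable takes, at each grid point, its measurement
    nearest in time within ``tolerance``; anything further is missing.
    Records flagged anomalous are excluded before matching, and
    measurements that match no grid point are discarded.
    """
    tolerance = pd.Timedelta(tolerance)
    if tolerance >= GRID_STEP:
        raise ValueError("tolerance must be smaller than the 15-minute grid step")

    rows = [(r.variable, r.timestamp, r.value, r.qc_flag) for r in records]
    if not rows:
        raise EmptyInputError("no records supplied")
    df = pd.DataFrame(rows, columns=["variable", "timestamp", "value", "qc_flag"])

    flagged_counts = (
        df[df["qc_flag"]].groupby("variable").size().to_dict()
    )
    df = df[~df["qc_flag"]].drop(columns="qc_flag")

    nit = df[df["variable"] == RESPONSE]
    if nit.empty:
        raise EmptyInputError("no (unflagged) nitrate records; cannot build grid")

    grid = pd.date_range(nit["timestamp"].min(), nit["timestamp"].max(),
                         freq=GRID_STEP)
    base = pd.DataFrame({"timestamp": grid})

    def nearest(series: pd.DataFrame) -> np.ndarray:
        s = (series.sort_values("timestamp")
                   .drop_duplicates("timestamp", keep="first"))
        merged = pd.merge_asof(base, s[["timestamp", "value"]],
                               on="timestamp", direction="nearest",
                               tolerance=tolerance)
        return merged["value"].to_numpy(dtype=float)

    response = nearest(nit)
    covariates = {}
    for name, sub in df[df["variable"] != RESPONSE].groupby("variable"):
        covariates[name] = nearest(sub)

    cov = pd.DataFrame(covariates, index=range(len(grid)))
    # continuous time covariate, days since the first grid point
    cov[TIME_COLUMN] = (grid - grid[0]).total_seconds() / 86400.0

    metadata = {
        "qc_flagged_removed": {k: int(v) for k, v in flagged_counts.items()},
        "alignment_tolerance_s": float(tolerance.total_seconds()),
    }
    return AlignedDataset(grid=grid, response=response, covariates=cov,
                          site_label=site_label, metadata=metadata)


# --------------------------------------------------------------------------
# Transforms

TURBIDITY = "turbidity"


def transform_covariates(data: AlignedDataset) -> AlignedDataset:
    """Replace turbidity by ``log(turbidity + 1)``; refuse a second pass."""
    if data.metadata.get("turbidity_transform"):
        raise DataValidityError("turbidity already transformed (metadata check)")
    if TURBIDITY not in data.covariates.columns:
        raise DataValidityError("no turbidity column to transform")
    turb = data.covariates[TURBIDITY].to_numpy(dtype=float)
    if np.nanmin(turb) < 0:
        raise DataValidityError("negative turbidity is not physical (FNU >= 0)")
    cov = data.covariates.copy()
    cov[TURBIDITY] = np.log1p(turb)
    meta = dict(data.metadata)
    meta["turbidity_transform"] = "log1p"
    return AlignedDataset(grid=data.grid, response=data.response.copy(),
                          covariates=cov, site_label=data.site_label,
                          metadata=meta)


# --------------------------------------------------------------------------
# Collinearity screen

def _single_vif(X: np.ndarray, j: int) -> float:
    """VIF of column j: 1/(1-R^2) from its regression on the other columns."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    design = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 0:
        return np.inf
    r2 = 1.0 - float(resid @ resid) / tss
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return max(1.0, 1.0 / (1.0 - r2))


def vif_screen(
    data: AlignedDataset,
    candidates: Sequence[str],
    threshold: float = 6.0,
) -> VifReport:
    """Greedy variance-inflation-factor elimination.

    Recomputes all VIFs on the current candidate set, drops the worst
    covariate while its VIF is at or above ``threshold``, and repeats until
    every remaining VIF is below threshold (or only one covariate is left).
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least two candidates for a VIF screen")
    rows = data.complete_rows(candidates)
    # response completeness is irrelevant here but the fit uses these rows too
    if int(rows.sum()) < len(candidates) + 1:
        raise IdentifiabilityError(
            f"only {int(rows.sum())} complete rows for {len(candidates)} candidates"
        )

    full = data.covariates.loc[rows, candidates].to_numpy(dtype=float)
    current = list(candidates)
    vif_out: dict[str, float] = {}
    dropped: list[str] = []

    while True:
        X = full[:, [candidates.index(c) for c in current]]
        vifs = {c: _single_vif(X, i) for i, c in enumerate(current)}
        worst = max(current, key=lambda c: (vifs[c], -candidates.index(c)))
        if vifs[worst] >= threshold and len(current) > 1:
            vif_out[worst] = vifs[worst]
            dropped.append(worst)
            current.remove(worst)
            logger.info("vif_screen: dropped %s (VIF=%.3g)", worst, vifs[worst])
            if len(current) == 1:
                vif_out[current[0]] = 1.0
                break
            continue
        vif_out.update(vifs)
        break

    return VifReport(vif=vif_out, retained=current, dropped=dropped,
                     threshold=float(threshold))


# --------------------------------------------------------------------------
# Descriptive summaries

def summarise_variables(data: AlignedDataset) -> pd.DataFrame:
    """Per-variable n / mean / median / quartiles / range.

    Turbidity is summarised on the raw FNU scale even if the dataset holds
    the log-transformed column (display convention).  The continuous time
    covariate is omitted — it is a modelling device, not a sensor stream.
    """
    series: dict[str, np.ndarray] = {RESPONSE: data.response}
    for col in data.covariates.columns:
        if col == TIME_COLUMN:
            continue
        vals = data.covariates[col].to_numpy(dtype=float)
        if col == TURBIDITY and data.metadata.get("turbidity_transform") == "log1p":
            vals = np.expm1(vals)
        series[col] = vals

    rows = []
    for name, vals in series.items():
        obs = vals[np.isfinite(vals)]
        if obs.size == 0:
            rows.append({"variable": name, "n": 0, "mean": np.nan,
                         "median": np.nan, "q1": np.nan, "q3": np.nan,
                         "min": np.nan, "max": np.nan})
            continue
        q1, med, q3 = np.quantile(obs, [0.25, 0.5, 0.75])  # type-7 default
        rows.append({"variable": name, "n": int(obs.size),
                     "mean": float(obs.mean()), "median": float(med),
                     "q1": float(q1), "q3": float(q3),
                     "min": float(obs.min()), "max": float(obs.max())})
    return pd.DataFrame(rows).set_index("variable")
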