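"""Temperature-and-greenness (TG) model core.

The TG model estimates monthly gross primary production (GPP, gC m⁻² day⁻¹)
from two satellite quantities only — the enhanced vegetation index (EVI) and
land surface temperature (LST, °C) — as a proportionally linear function of
their scaled product:

    GPP = m · EVI_scaled · LST_scaled

``EVI_scaled = max(EVI − 0.1, 0)`` (0.1 is the greenness level at which GPP
drops to zero) and ``LST_scaled`` is a piecewise-linear temperature response
built from three parameters, the minimum (``x_n``), optimum (``x_o``) and
maximum (``x_m``) LST for photosynthesis:

    LST_scaled = max( min[ (LST − x_n)/(x_o − x_n),
                           (x_m − LST)/(x_m − x_o) ], 0 )

It rises linearly from 0 at ``x_n`` to 1 at ``x_o`` and falls back to 0 at
``x_m``.  Defaults are 0, 30 and 50 °C.  The proportionality scalar ``m``
carries the flux units; the temperature parameters are the quantities subject
to sensitivity screening and Bayesian calibration elsewhere in this package,
while ``m`` is profiled out by origin-constrained least squares (``fit_m``).

The module also defines the site-level monthly container
(:class:`SiteMonthlySeries`) and its CSV round trip, used by every other
stage of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PFT_CODES",
    "DEFAULT_PARAMS",
    "TGParams",
    "SiteMonthlySeries",
    "DegenerateFitError",
    "scale_evi",
    "scale_lst",
    "predict_gpp",
    "fit_m",
    "read_series_csv",
    "write_series_csv",
]

#: The twelve plant functional types (PFTs) the pipeline recognises.
PFT_CODES = (
    "CRO", "CSH", "DBF", "DNF", "EBF", "ENF",
    "GRA", "MF", "OSH", "SAV", "WET", "WSA",
)

#: EVI value at which GPP drops to zero.
EVI_OFFSET = 0.1

#: LST screening threshold (°C) applied by QA upstream; kept here for reference.
COLD_LST_THRESHOLD = -2.0


class DegenerateFitError(ValueError):
    """Raised when the origin-constrained slope is undefined (all-zero driver)."""


@dataclass(frozen=True)
class TGParams:
    """The TG model's temperature parameters plus the proportionality scalar.

    Parameters
    ----------
    x_n, x_o, x_m
        Minimum, optimum and maximum LST for photosynthesis (°C), with the
        strict ordering ``x_n < x_o < x_m`` enforced at construction.
    m
        Proportionality scalar (gC m⁻² day⁻¹), non-negative.  ``None`` while
        the scalar has not been fitted yet (it is profiled out during
        screening and calibration).
    """

    x_n: float = 0.0
    x_o: float = 30.0
    x_m: float = 50.0
    m: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x_n) and np.isfinite(self.x_o) and np.isfinite(self.x_m)):
            raise ValueError("temperature parameters must be finite")
        if not (self.x_n < self.x_o < self.x_m):
            raise ValueError(
                f"invalid ordering: require x_n < x_o < x_m, got "
                f"({self.x_n}, {self.x_o}, {self.x_m})"
            )
        if self.m is not None and not (np.isfinite(self.m) and self.m >= 0):
            raise ValueError(f"m must be finite and non-negative, got {self.m}")

    def with_m(self, m: float) -> "TGParams":
        return replace(self, m=float(m))


#: Published default parameter values (°C); m left unset.
DEFAULT_PARAMS = TGParams(0.0, 30.0, 50.0)


def scale_evi(evi) -> np.ndarray:
    """Scaled EVI: ``max(EVI − 0.1, 0)``.

    EVI below the 0.1 offset implies no photosynthesis, so the scalar is
    clamped at zero rather than allowed to go negative.
    """
    evi = np.asarray(evi, dtype=float)
    if not np.all(np.isfinite(evi)):
        raise ValueError("EVI contains non-finite values")
    return np.maximum(evi - EVI_OFFSET, 0.0)


def scale_lst(lst, params: TGParams = DEFAULT_PARAMS) -> np.ndarray:
    """Scaled LST in [0, 1]: min of the warming and cooling ramps, floored at 0.

    Equals 1 exactly at ``x_o`` and 0 at or beyond ``x_n`` and ``x_m``;
    piecewise linear in between.  Under the strict parameter ordering the min
    of the two ramps can never exceed 1, so no upper clamp is needed.
    """
    lst = np.asarray(lst, dtype=float)
    if not np.all(np.isfinite(lst)):
        raise ValueError("LST contains non-finite values")
    up = (lst - params.x_n) / (params.x_o - params.x_n)
    down = (params.x_m - lst) / (params.x_m - params.x_o)
    return np.maximum(np.minimum(up, down), 0.0)


def predict_gpp(evi, lst, params: TGParams) -> np.ndarray:
    """TG forward prediction: ``m · EVI_scaled · LST_scaled`` (gC m⁻² day⁻¹)."""
    evi = np.asarray(evi, dtype=float)
    lst = np.asarray(lst, dtype=float)
    if evi.shape != lst.shape:
        raise ValueError(f"EVI and LST length mismatch: {evi.shape} vs {lst.shape}")
    if params.m is None:
        raise ValueError("params.m is unset; fit it first (see fit_m)")
    return params.m * scale_evi(evi) * scale_lst(lst, params)


def fit_m(gpp_obs, product) -> float:
    """Origin-constrained least-squares slope of observed GPP on the scaled product.

    ``m = Σ(pᵢ gᵢ) / Σ(pᵢ²)`` minimises ``Σ(gᵢ − m pᵢ)²`` through the origin;
    truncated at 0 so the flux scalar stays physical.  The temperature
    parameters are the model's free parameters; ``m`` is re-estimated this way
    for every candidate parameter set ("profiled out").

    Raises
    ------
    DegenerateFitError
        If the scaled product is zero everywhere (slope undefined).
    """
    g = np.asarray(gpp_obs, dtype=float)
    p = np.asarray(product, dtype=float)
    if g.shape != p.shape:
        raise ValueError("gpp_obs and product must have the same length")
    keep = np.isfinite(g) & np.isfinite(p)
    g, p = g[keep], p[keep]
    denom = float(p @ p)
    if denom <= 0.0:
        raise DegenerateFitError("scaled EVI×LST product is zero everywhere")
    return max(float(p @ g) / denom, 0.0)


# ---------------------------------------------------------------------------
# Site-level monthly container and CSV round trip
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["site_id", "pft", "date", "gpp", "evi", "lst", "prc", "rad", "snow_flag"]


@dataclass
class SiteMonthlySeries:
    """Aligned monthly vectors for one flux site.

    ``data`` is indexed by a strictly increasing monthly ``DatetimeIndex``
    (first of month) with float columns ``gpp`` (gC m⁻² day⁻¹), ``evi``,
    ``lst`` (°C), ``prc`` (mm month⁻¹), ``rad`` (MJ m⁻² day⁻¹), boolean
    ``snow_flag`` and, after QA screening, boolean ``masked``.  Missing
    values are NaN.
    """

    site_id: str
    pft: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.pft not in PFT_CODES:
            raise ValueError(f"unknown PFT {self.pft!r}; expected one of {PFT_CODES}")
        idx = self.data.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise ValueError("data must be indexed by a DatetimeIndex")
        if len(idx) > 1:
            steps = idx.to_period("M").astype("int64")
            if not np.all(np.diff(steps) == 1):
                raise ValueError("time index must increase in strict monthly steps")
        for col in ("gpp", "evi", "lst", "prc", "rad", "snow_flag"):
            if col not in self.data.columns:
                raise ValueError(f"missing column {col!r}")
        gpp = self.data["gpp"].to_numpy(dtype=float)
        if np.any(gpp[np.isfinite(gpp)] < 0):
            raise ValueError("observed GPP must be non-negative where present")
        if "masked" not in self.data.columns:
            self.data = self.data.assign(masked=False)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_months(self) -> int:
        return len(self.data)

    def valid_rows(self) -> pd.DataFrame:
        """Months usable for fitting: unmasked with finite gpp/evi/lst."""
        d = self.data
        ok = (~d["masked"]) & np.isfinite(d["gpp"]) & np.isfinite(d["evi"]) & np.isfinite(d["lst"])
        return d.loc[ok]


def write_series_csv(series: Sequence[SiteMonthlySeries] | SiteMonthlySeries, path) -> None:
    """Write one or more site series to a single CSV (long format).

    Columns: site_id, pft, date (ISO-8601, first of month), gpp, evi, lst,
    prc, rad, snow_flag (0/1) and masked (0/1) if present; missing values as
    empty cells.
    """
    if isinstance(series, SiteMonthlySeries):
        series = [series]
    frames = []
    for s in series:
        df = s.data.reset_index(names="date").copy()
        df["date"] = df["date"].dt.strftime("%Y-%m-%d")
        df.insert(0, "pft", s.pft)
        df.insert(0, "site_id", s.site_id)
        df["snow_flag"] = df["snow_flag"].astype(int)
        if "masked" in df.columns:
            df["masked"] = df["masked"].astype(int)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    cols = _CSV_COLUMNS + (["masked"] if "masked" in out.columns else [])
    out[cols].to_csv(path, index=False)


def read_series_csv(path) -> list[SiteMonthlySeries]:
    """Read the CSV written by :func:`write_series_csv` back into site series."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"CSV missing required columns: {sorted(missing)}")
    out = []
    for (site_id, pft), grp in df.groupby(["site_id", "pft"], sort=False):
        data = grp.copy()
        data.index = pd.DatetimeIndex(pd.to_datetime(data.pop("date")))
        data = data.drop(columns=["site_id", "pft"])
        data["snow_flag"] = data["snow_flag"].fillna(0).astype(float).astype(bool)
        if "masked" in data.columns:
            data["masked"] = data["masked"].fillna(0).astype(float).astype(bool)
        out.append(SiteMonthlySeries(site_id=str(site_id), pft=str(pft), data=data))
    return out
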