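"""Normalized Taylor-diagram statistics for model skill.

A Taylor diagram summarises how well a modelled series matches observations
with three linked quantities: the Pearson correlation R, the ratio of model
to observation standard deviation (normalized STD), and the centered
root-mean-square difference normalized by the observation standard deviation
(normalized RMSD).  They obey the law-of-cosines identity

    RMSD'² = 1 + STD'² − 2 · STD' · R

so the three plot as one point in polar coordinates (radius = STD',
azimuth = arccos R) with the reference "observations" at (R = 1, STD' = 1,
RMSD' = 0).  The RMSD here is the *centered* (bias-removed) pattern
difference — required for the diagram geometry to close — with the mean bias
reported separately in observation-SD units.

Statistics are computed over pooled unmasked months; per-PFT skill pools all
months of all sites within the PFT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TaylorStats",
    "TaylorComparison",
    "UndefinedNormalizationError",
    "taylor_stats",
    "compare_runs",
    "taylor_frame",
    "polar_coordinates",
]


class UndefinedNormalizationError(ValueError):
    """Observation SD is zero: normalized statistics are undefined."""


@dataclass(frozen=True)
class TaylorStats:
    """Normalized skill triple plus bias and sample size."""

    r: float
    std_norm: float
    crmsd_norm: float
    bias_norm: float
    n: int


@dataclass(frozen=True)
class TaylorComparison:
    default: TaylorStats
    optimized: TaylorStats
    delta_r: float
    delta_std_norm: float
    delta_crmsd_norm: float
    distance: float  # Euclidean distance between the two points on the Taylor plane


def _paired(obs, mod):
    obs = np.asarray(obs, dtype=float)
    mod = np.asarray(mod, dtype=float)
    if obs.shape != mod.shape:
        raise ValueError("series must be aligned (equal lengths)")
    keep = np.isfinite(obs) & np.isfinite(mod)
    return obs[keep], mod[keep]


def taylor_stats(obs, mod) -> TaylorStats:
    """Normalized Taylor statistics of ``mod`` against ``obs``.

    Months missing in either series are excluded pairwise; at least 3 pairs
    are required.  Raises :class:`UndefinedNormalizationError` when the
    observations are constant.
    """
    o, m = _paired(obs, mod)
    n = len(o)
    if n < 3:
        raise ValueError(f"need at least 3 paired months, got {n}")
    so = float(np.std(o, ddof=1))
    if so == 0.0:
        raise UndefinedNormalizationError("observation SD is zero")
    sm = float(np.std(m, ddof=1))
    oc, mc = o - o.mean(), m - m.mean()
    r = float(mc @ oc / ((n - 1) * sm * so)) if sm > 0 else 0.0
    crmsd = float(np.sqrt(((mc - oc) @ (mc - oc)) / (n - 1)))
    return TaylorStats(
        r=r,
        std_norm=sm / so,
        crmsd_norm=crmsd / so,
        bias_norm=float((m.mean() - o.mean()) / so),
        n=n,
    )


def _plane_point(s: TaylorStats) -> tuple[float, float]:
    theta = np.arccos(np.clip(s.r, -1.0, 1.0))
    return s.std_norm * np.cos(theta), s.std_norm * np.sin(theta)


def compare_runs(obs, mod_default, mod_optimized) -> TaylorComparison:
    """Taylor statistics of two model runs against the same observations.

    Returns both triples, their deltas (optimized − default), and the
    distance moved on the Taylor plane — the visual measure of how much
    calibration changed the model.
    """
    sd = taylor_stats(obs, mod_default)
    so = taylor_stats(obs, mod_optimized)
    p0, p1 = _plane_point(sd), _plane_point(so)
    dist = float(np.hypot(p1[0] - p0[0], p1[1] - p0[1]))
    return TaylorComparison(
        default=sd, optimized=so,
        delta_r=so.r - sd.r,
        delta_std_norm=so.std_norm - sd.std_norm,
        delta_crmsd_norm=so.crmsd_norm - sd.crmsd_norm,
        distance=dist,
    )


def taylor_frame(stats: dict[tuple[str, str], TaylorStats]) -> pd.DataFrame:
    """Tabulate {(pft, run): TaylorStats} for CSV export."""
    rows = [
        {"pft": pft, "run": run, "r": s.r, "std_norm": s.std_norm,
         "crmsd_norm": s.crmsd_norm, "bias_norm": s.bias_norm, "n": s.n}
        for (pft, run), s in stats.items()
    ]
    return pd.DataFrame(rows)


def polar_coordinates(s: TaylorStats) -> tuple[float, float]:
    """(azimuth, radius) = (arccos R, normalized STD) for diagram plotting."""
    return float(np.arccos(np.clip(s.r, -1.0, 1.0))), s.std_norm
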