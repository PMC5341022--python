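"""Morris elementary-effects screening of the TG temperature parameters.

Morris screening ranks parameter influence with a handful of model runs: a
set of r one-at-a-time (OAT) trajectories walks a p-level grid on the unit
cube, and each coordinate move yields an elementary effect (EE) — a finite
difference of the model output with respect to that parameter.  The mean of
absolute EEs (μ*) measures overall influence; their standard deviation (σ)
flags non-linearity and interaction (the conventional check being whether
σ exceeds 2 μ*).

For the TG model the screened output is the root-mean-square error between
TG predictions (with the proportionality scalar m profiled out by
origin-constrained least squares) and observed GPP over the pooled per-PFT
series — a single fit-quality scalar consistent with the Gaussian likelihood
used later in calibration.

Design conventions:

* grid step Δ = p / (2(p − 1)), the standard choice that makes levels and
  their Δ-shifts cover the grid symmetrically; p must be even;
* EEs are oriented as derivatives, Δf divided by the *signed* coordinate
  step, so downward moves measure the same local slope as upward ones;
* parameter triples that violate the x_n < x_o < x_m ordering after mapping
  to °C are avoided by rejection-resampling whole trajectories, so the model
  is never evaluated at invalid parameters;
* ties in μ* are broken by parameter declaration order, deterministically.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tg_model import SiteMonthlySeries, TGParams, fit_m, scale_evi, scale_lst

__all__ = [
    "ParamRanges",
    "MorrisResult",
    "DEFAULT_RANGES",
    "morris_design",
    "map_to_physical",
    "elementary_effects",
    "summarize_effects",
    "screen_tg",
    "pooled_arrays",
    "rmse_statistic",
    "morris_result_frame",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParamRanges:
    """Uniform prior/screening box per parameter (lower, upper), in °C."""

    x_n: tuple[float, float] = (-15.0, 10.0)
    x_o: tuple[float, float] = (10.0, 40.0)
    x_m: tuple[float, float] = (40.0, 65.0)

    def __post_init__(self) -> None:
        for name in self.names:
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"range for {name} must have lower < upper, got ({lo}, {hi})")

    @property
    def names(self) -> tuple[str, ...]:
        return ("x_n", "x_o", "x_m")

    @property
    def lower(self) -> np.ndarray:
        return np.array([getattr(self, n)[0] for n in self.names])

    @property
    def upper(self) -> np.ndarray:
        return np.array([getattr(self, n)[1] for n in self.names])

    def contains(self, theta) -> bool:
        theta = np.asarray(theta, dtype=float)
        return bool(np.all(theta >= self.lower) and np.all(theta <= self.upper))


#: Screening/calibration box used throughout: x_n −15–10, x_o 10–40, x_m 40–65 °C.
DEFAULT_RANGES = ParamRanges()


@dataclass
class MorrisResult:
    """Per-parameter Morris summaries plus design metadata."""

    names: tuple[str, ...]
    mu_star: np.ndarray
    sigma: np.ndarray
    rank: np.ndarray              # 1 = most influential
    interaction_flag: np.ndarray  # sigma > 2 * mu_star
    r: int
    p: int
    seed: int
    effects: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


def _delta(p: int) -> float:
    return p / (2.0 * (p - 1.0))


def morris_design(n_params: int, r: int, p: int = 8, seed: int = 0,
                  rng: np.random.Generator | None = None) -> list[np.ndarray]:
    """Generate ``r`` OAT trajectories on the p-level unit-cube grid.

    Each trajectory is an (n_params + 1) × n_params array of points in
    [0, 1]; consecutive points differ in exactly one coordinate by ±Δ with
    Δ = p/(2(p−1)), and each parameter moves exactly once per trajectory.
    """
    if r < 2:
        raise ValueError("need r >= 2 trajectories")
    if p < 4 or p % 2:
        raise ValueError("p must be even and >= 4")
    if rng is None:
        rng = np.random.default_rng(seed)
    return [_one_trajectory(n_params, p, rng) for _ in range(r)]


def _one_trajectory(k: int, p: int, rng: np.random.Generator) -> np.ndarray:
    delta = _delta(p)
    # base levels from which a +Δ step stays inside [0, 1]
    base_levels = np.arange(p // 2) / (p - 1.0)
    x_star = rng.choice(base_levels, size=k)
    d_star = rng.choice([-1.0, 1.0], size=k)
    perm = rng.permutation(k)
    b = np.tril(np.ones((k + 1, k)), -1)
    j = np.ones((k + 1, k))
    # permute which parameter moves at which step (columns of B), keeping
    # x_star and d_star attached to their parameters
    bp = np.zeros_like(b)
    bp[:, perm] = b
    traj = x_star + (delta / 2.0) * ((2.0 * bp - j) * d_star + j)
    return np.clip(traj, 0.0, 1.0)


def map_to_physical(traj: np.ndarray, ranges: ParamRanges) -> np.ndarray:
    """Affine map from unit-cube coordinates to °C per the screening box."""
    lo, hi = ranges.lower, ranges.upper
    return lo + traj * (hi - lo)


def elementary_effects(trajectories: list[np.ndarray], outputs: list[np.ndarray],
                       names: tuple[str, ...]) -> dict[str, list[float]]:
    """Signed elementary effects per parameter from trajectory outputs.

    EE = (f(after) − f(before)) / (u_after − u_before) in unit-cube
    coordinates; the signed denominator orients every effect as the local
    +direction derivative.  Trajectories yielding non-finite outputs at the
    moved pair are excluded with a warning.
    """
    effects: dict[str, list[float]] = {n: [] for n in names}
    for traj, y in zip(trajectories, outputs):
        y = np.asarray(y, dtype=float)
        if len(y) != len(traj):
            raise ValueError("outputs misaligned with design points")
        for t in range(len(traj) - 1):
            moved = np.nonzero(~np.isclose(traj[t + 1], traj[t]))[0]
            if len(moved) != 1:
                raise ValueError("trajectory is not one-at-a-time")
            i = int(moved[0])
            if not (np.isfinite(y[t]) and np.isfinite(y[t + 1])):
                warnings.warn(f"non-finite output; dropping one EE for {names[i]}")
                continue
            step = traj[t + 1, i] - traj[t, i]
            effects[names[i]].append(float((y[t + 1] - y[t]) / step))
    return effects


def summarize_effects(effects: dict[str, list[float]], r: int, p: int,
                      seed: int) -> MorrisResult:
    """μ*, σ, ranking (descending μ*, declaration-order ties) and interaction flags."""
    names = tuple(effects)
    mu_star = np.array([float(np.mean(np.abs(effects[n]))) if effects[n] else 0.0
                        for n in names])
    sigma = np.array([float(np.std(effects[n], ddof=1)) if len(effects[n]) > 1 else 0.0
                      for n in names])
    order = np.lexsort((np.arange(len(names)), -mu_star))
    rank = np.empty(len(names), dtype=int)
    rank[order] = np.arange(1, len(names) + 1)
    interaction = sigma > 2.0 * mu_star
    return MorrisResult(names=names, mu_star=mu_star, sigma=sigma, rank=rank,
                        interaction_flag=interaction, r=r, p=p, seed=seed,
                        effects={n: np.asarray(v) for n, v in effects.items()})


def pooled_arrays(series: list[SiteMonthlySeries] | SiteMonthlySeries):
    """Pool unmasked, finite months across sites into flat gpp/evi/lst arrays."""
    if isinstance(series, SiteMonthlySeries):
        series = [series]
    rows = [s.valid_rows() for s in series]
    rows = [r for r in rows if len(r)]
    if not rows:
        raise ValueError("no usable months after QA masking")
    pooled = pd.concat(rows)
    return (pooled["gpp"].to_numpy(float), pooled["evi"].to_numpy(float),
            pooled["lst"].to_numpy(float))


def rmse_statistic(gpp: np.ndarray, evi_scaled: np.ndarray, lst: np.ndarray,
                   theta: np.ndarray) -> float:
    """RMSE of TG predictions vs observations with m profiled out."""
    params = TGParams(*theta)
    prod = evi_scaled * scale_lst(lst, params)
    try:
        m = fit_m(gpp, prod)
    except ValueError:
        m = 0.0
    resid = gpp - m * prod
    return float(np.sqrt(np.mean(resid ** 2)))


def screen_tg(series: list[SiteMonthlySeries] | SiteMonthlySeries,
              ranges: ParamRanges = DEFAULT_RANGES, r: int = 20, p: int = 8,
              seed: int = 0, max_tries: int = 1000) -> MorrisResult:
    """Morris screening of (x_n, x_o, x_m) against pooled per-PFT fit quality.

    Trajectories whose physical-space points violate the parameter ordering
    are rejection-resampled so the TG model is only evaluated at valid
    parameter sets.
    """
    gpp, evi, lst = pooled_arrays(series)
    evi_s = scale_evi(evi)
    rng = np.random.default_rng(seed)
    trajectories: list[np.ndarray] = []
    while len(trajectories) < r:
        for _ in range(max_tries):
            traj = _one_trajectory(3, p, rng)
            phys = map_to_physical(traj, ranges)
            if np.all((phys[:, 0] < phys[:, 1]) & (phys[:, 1] < phys[:, 2])):
                trajectories.append(traj)
                break
        else:
            raise RuntimeError("could not sample an ordering-valid trajectory")
    outputs = []
    for traj in trajectories:
        phys = map_to_physical(traj, ranges)
        outputs.append(np.array([rmse_statistic(gpp, evi_s, lst, th) for th in phys]))
    effects = elementary_effects(trajectories, outputs, ranges.names)
    res = summarize_effects(effects, r=r, p=p, seed=seed)
    log.info("morris screen: mu*=%s ranks=%s", np.round(res.mu_star, 4), res.rank)
    return res


def morris_result_frame(result: MorrisResult, long_format: bool = False) -> pd.DataFrame:
    """Tabular export: wide summary or radar-plot-ready long format."""
    wide = pd.DataFrame({
        "parameter": result.names,
        "mu_star": result.mu_star,
        "sigma": result.sigma,
        "rank": result.rank,
        "interaction_flag": result.interaction_flag.astype(int),
    })
    if not long_format:
        return wide
    return wide.melt(id_vars="parameter", value_vars=["mu_star", "sigma"],
                     var_name="metric", value_name="value")
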