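"""QA screening and singular-spectrum-analysis (SSA) smoothing.

Satellite EVI and LST series carry retrieval noise and snow/cold
contamination.  The cleaning pipeline, applied per site before any model
fitting, is:

1. ``qa_screen`` — mask EVI for months with a snow/ice flag or with
   LST < −2.0 °C (strict inequality).  Masked months are excluded from all
   likelihoods and skill statistics downstream; they are never imputed into
   the statistics.
2. gap filling — SSA needs a complete series, so masked/missing EVI and LST
   values are bridged: internal gaps of at most ``max_gap`` months (default 3)
   by linear interpolation, edge gaps by nearest value.  Site-years containing
   longer gaps are flagged entirely masked so they drop out of calibration.
3. ``ssa_reconstruct`` — SSA with a 37-month window and 6 leading components:
   embed the series in a Hankel trajectory matrix, SVD it, keep the leading
   rank-one terms, and Hankelize back by anti-diagonal averaging.  This keeps
   the seasonal cycle and low-frequency variability while shedding
   high-frequency retrieval noise.

The screen → fill → smooth order is a documented package choice; the masked
flags survive smoothing so that screened months stay out of the fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tg_model import COLD_LST_THRESHOLD, SiteMonthlySeries

__all__ = [
    "SSAConfig",
    "InsufficientDataError",
    "qa_screen",
    "fill_gaps",
    "flag_long_gap_years",
    "ssa_reconstruct",
    "preprocess_series",
]

log = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Series too short (or too gappy) for the requested operation."""


@dataclass(frozen=True)
class SSAConfig:
    """SSA window length (months) and number of leading components kept."""

    window: int = 37
    n_components: int = 6

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be at least 2 months")
        if not (1 <= self.n_components <= self.window):
            raise ValueError("n_components must lie in [1, window]")


def qa_screen(series: SiteMonthlySeries) -> SiteMonthlySeries:
    """Mask EVI for snow-flagged months and months with LST < −2.0 °C.

    Returns a new series with the ``masked`` column set (existing masks are
    kept, so the operation is idempotent); other fields untouched.  The count
    of newly masked months is logged.
    """
    d = series.data.copy()
    lst = d["lst"].to_numpy(dtype=float)
    cold = np.where(np.isfinite(lst), lst < COLD_LST_THRESHOLD, False)
    flagged = d["snow_flag"].to_numpy(dtype=bool) | cold
    newly = int((flagged & ~d["masked"].to_numpy(dtype=bool)).sum())
    d["masked"] = d["masked"].to_numpy(dtype=bool) | flagged
    out = SiteMonthlySeries(site_id=series.site_id, pft=series.pft, data=d)
    log.info("qa_screen site=%s pft=%s masked %d month(s), %d total",
             series.site_id, series.pft, newly, int(d["masked"].sum()))
    if bool(d["masked"].all()):
        log.warning("qa_screen site=%s: every month masked", series.site_id)
    return out


def fill_gaps(x, max_gap: int = 3) -> np.ndarray:
    """Bridge NaN runs so SSA can run on a complete series.

    Internal runs of at most ``max_gap`` NaNs are linearly interpolated;
    leading/trailing runs are filled with the nearest valid value.  Longer
    internal runs raise :class:`InsufficientDataError` — callers decide
    whether to drop the site (see :func:`flag_long_gap_years`).
    """
    s = pd.Series(np.asarray(x, dtype=float))
    if s.isna().all():
        raise InsufficientDataError("series has no valid values")
    isna = s.isna().to_numpy()
    # lengths of internal NaN runs
    run_id = np.cumsum(np.diff(np.concatenate([[0], isna.astype(int)])) == 1)
    first_valid, last_valid = s.first_valid_index(), s.last_valid_index()
    for rid in np.unique(run_id[isna]):
        pos = np.nonzero(isna & (run_id == rid))[0]
        internal = pos[0] > first_valid and pos[-1] < last_valid
        if internal and len(pos) > max_gap:
            raise InsufficientDataError(
                f"internal gap of {len(pos)} months exceeds max_gap={max_gap}"
            )
    return s.interpolate(method="linear", limit_direction="both").to_numpy()


def flag_long_gap_years(series: SiteMonthlySeries, max_gap: int = 3) -> SiteMonthlySeries:
    """Mask whole calendar years whose EVI/LST gaps are too long to bridge.

    A pragmatic stand-in for per-site-year completeness screening: any
    calendar year containing an internal masked/missing run longer than
    ``max_gap`` in EVI or LST is excluded from calibration wholesale.
    """
    d = series.data.copy()
    masked = d["masked"].to_numpy(dtype=bool)
    bad = masked | ~np.isfinite(d["evi"].to_numpy(float)) | ~np.isfinite(d["lst"].to_numpy(float))
    years = d.index.year.to_numpy()
    for yr in np.unique(years):
        sel = years == yr
        runs = _max_run(bad[sel])
        if runs > max_gap:
            d.loc[sel, "masked"] = True
            log.info("site=%s year=%d excluded (gap run of %d months)",
                     series.site_id, yr, runs)
    return SiteMonthlySeries(site_id=series.site_id, pft=series.pft, data=d)


def _max_run(flags: np.ndarray) -> int:
    best = cur = 0
    for f in flags:
        cur = cur + 1 if f else 0
        best = max(best, cur)
    return best


def ssa_reconstruct(x, cfg: SSAConfig = SSAConfig()) -> np.ndarray:
    """SSA reconstruction from the leading ``cfg.n_components`` eigentriples.

    The series of length N is embedded in the L×K Hankel trajectory matrix
    (L = window, K = N − L + 1), decomposed by SVD, truncated to the leading
    rank-one terms, and mapped back to a length-N series by averaging over
    anti-diagonals.  With ``n_components == window`` the reconstruction is the
    identity up to numerical error.
    """
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("SSA input must be gap-free; fill gaps first")
    n = len(x)
    L = cfg.window
    if n < L + 1:
        raise InsufficientDataError(f"need at least window+1={L + 1} months, got {n}")
    K = n - L + 1
    traj = np.lib.stride_tricks.sliding_window_view(x, L).T  # L × K
    u, s, vt = np.linalg.svd(traj, full_matrices=False)
    k = min(cfg.n_components, len(s))
    rec = (u[:, :k] * s[:k]) @ vt[:k]
    out = np.zeros(n)
    counts = np.zeros(n)
    for i in range(L):
        out[i:i + K] += rec[i]
        counts[i:i + K] += 1.0
    return out / counts


def preprocess_series(
    series: SiteMonthlySeries,
    cfg: SSAConfig = SSAConfig(),
    max_gap: int = 3,
    smooth: bool = True,
) -> SiteMonthlySeries:
    """Full per-site cleaning: QA screen → long-gap exclusion → fill → SSA.

    EVI and LST are smoothed separately.  If the series is shorter than
    ``window + 1`` months SSA is skipped with a warning (short synthetic
    cohorts remain usable).  Masked months keep their flag and stay excluded
    from every downstream fit.
    """
    s = qa_screen(series)
    s = flag_long_gap_years(s, max_gap=max_gap)
    d = s.data.copy()
    if smooth:
        for col in ("evi", "lst"):
            vals = d[col].to_numpy(dtype=float).copy()
            hide = d["masked"].to_numpy(dtype=bool) if col == "evi" else ~np.isfinite(vals)
            vals[hide] = np.nan
            try:
                filled = fill_gaps(vals, max_gap=max(max_gap, len(vals)))
                d[col] = ssa_reconstruct(filled, cfg)
            except InsufficientDataError as exc:
                log.warning("site=%s: SSA skipped for %s (%s)", s.site_id, col, exc)
                d[col] = pd.Series(vals, index=d.index).interpolate(
                    method="linear", limit_direction="both")
    return SiteMonthlySeries(site_id=s.site_id, pft=s.pft, data=d)
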