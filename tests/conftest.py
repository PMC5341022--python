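import numpy as np
import pandas as pd
import pytest

from tggpp.tg_model import SiteMonthlySeries


def make_series(n=24, pft="GRA", site_id="S1", seed=0, snow_months=(),
                gpp=None, evi=None, lst=None, prc=None, rad=None) -> SiteMonthlySeries:
    """Hand-built monthly series with controllable fields."""
    rng = np.random.default_rng(seed)
    month = np.arange(n) % 12
    if lst is None:
        lst = 12.0 - 15.0 * np.cos(2 * np.pi * month / 12)
    if evi is None:
        evi = np.clip(0.4 - 0.25 * np.cos(2 * np.pi * month / 12), 0, 1)
    if gpp is None:
        gpp = np.maximum(8.0 * np.maximum(np.asarray(evi) - 0.1, 0)
                         * np.clip(np.asarray(lst) / 30.0, 0, 1)
                         + rng.normal(0, 0.2, n), 0)
    if prc is None:
        prc = rng.lognormal(np.log(60), 0.5, n)
    if rad is None:
        rad = 15.0 - 8.0 * np.cos(2 * np.pi * month / 12)
    snow = np.zeros(n, dtype=bool)
    snow[list(snow_months)] = True
    data = pd.DataFrame(
        {"gpp": np.asarray(gpp, float), "evi": np.asarray(evi, float),
         "lst": np.asarray(lst, float), "prc": np.asarray(prc, float),
         "rad": np.asarray(rad, float), "snow_flag": snow},
        index=pd.date_range("2001-01-01", periods=n, freq="MS"))
    return SiteMonthlySeries(site_id=site_id, pft=pft, data=data)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_series():
    return make_series()
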