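import numpy as np
import pandas as pd
import pytest

from smokeitsa.itsa import MODEL_SPECS, SegmentedPolynomialITS, build_design
from smokeitsa.panel_io import AGE_OLD, AGE_YOUNG, CountryMeta


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_panel_frame(countries=("AAA", "BBB"), years=range(1995, 2016)):
    """Small valid long panel with both age bands, deterministic counts."""
    rows = []
    for c in countries:
        ci = ord(c[0]) - ord("A")  # stable per country, not per position
        for y in years:
            pop = 1_000_000 + 50_000 * ci
            sm = 120_000 + 10_000 * ci - 1500 * (y - 1995)
            rows.append([c, y, AGE_YOUNG, sm, pop, 0, 0])
            ever = 400_000 + 20_000 * ci
            former = int(0.3 * ever) + 500 * (y - 1995)
            rows.append([c, y, AGE_OLD, ever - former, int(0.9 * pop), former, ever])
    return pd.DataFrame(
        rows,
        columns=[
            "country_id",
            "year",
            "age_band",
            "current_smokers",
            "population",
            "former_smokers",
            "ever_smokers",
        ],
    )


def make_metas(**overrides):
    """A small meta map: four ratifiers across income groups plus extras."""
    base = {
        "AAA": CountryMeta("AAA", 2005, "high", 45.0, 12.0, 15),
        "BBB": CountryMeta("BBB", 2006, "upper-middle", 40.0, 3.0, 8),
        "CCC": CountryMeta("CCC", 2004, "lower-middle", 30.0, -2.0, 11),
        "DDD": CountryMeta("DDD", 2008, "low", None, None, 5),
        "CHN": CountryMeta("CHN", 2005, "upper-middle", 38.0, 1.0, 20),
    }
    base.update(overrides)
    return base


def exact_fit(model_id, coef, n_pre=10, n_post=10, noise=None, rng=None, hac_lags=None):
    """Fit a specification to data generated exactly from its own design."""
    t = np.arange(-n_pre, n_post + 1, dtype=float)
    M = build_design(t, model_id).to_numpy()
    assert len(coef) == MODEL_SPECS[model_id].n_params
    y = M @ np.asarray(coef, dtype=float)
    if noise is not None:
        y = y + noise
    elif rng is not None:
        y = y + rng.normal(0, 1e-12, len(t))
    return SegmentedPolynomialITS(model_id=model_id, hac_lags=hac_lags).fit(t, y)


def random_coef(model_id, rng, scale=0.01):
    k = MODEL_SPECS[model_id].n_params
    coef = rng.normal(0, scale, k)
    coef[0] = rng.normal(12.0, 1.0)  # intercept on a log-count scale
    return coef
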