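import numpy as np
import pandas as pd
import pytest

from metnorm import (
    Climatology,
    MeteoNormalizer,
    SeasonalVariable,
    SyntheticMetConfig,
    build_features,
    generate_met,
)


@pytest.fixture(scope="session")
def met_2y() -> pd.DataFrame:
    """Two years of daily synthetic meteorology (all 15 stored variables)."""
    return generate_met(SyntheticMetConfig("2015-01-01", "2016-12-31", seed=11))


@pytest.fixture(scope="session")
def climatology_2y(met_2y) -> Climatology:
    return Climatology.from_met(met_2y)


@pytest.fixture(scope="session")
def temperature_model(met_2y):
    """A small forest fitted to a noise-free linear-in-temperature target."""
    target = pd.Series(2.0 * met_2y["t"].to_numpy(), index=met_2y.index)
    feats = build_features(met_2y, met_2y.index, target=target)
    # random-row folds: for a deterministic target the CV skill should be
    # pure interpolation, not the blocked scheme's mild extrapolation
    model = MeteoNormalizer(n_estimators=60, blocked_cv=False,
                            random_state=0).fit(feats)
    return model, feats


def flat_met(start: str, end: str) -> pd.DataFrame:
    """Deterministic constant meteorology (zero amplitude, zero noise)."""
    variables = {
        name: SeasonalVariable(mean=m)
        for name, m in [
            ("u10", 2.0), ("v10", 0.5), ("t", 288.0), ("blh", 500.0),
            ("sr", 1.5e7), ("sp", 101325.0), ("tcc", 0.5), ("tp", 0.003),
            ("rh", 70.0), ("u500", 10.0), ("v500", 1.0), ("w500", 0.0),
            ("u850", 4.0), ("v850", 1.0), ("w850", 0.0),
        ]
    }
    return generate_met(SyntheticMetConfig(start, end, variables=variables, seed=0))
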