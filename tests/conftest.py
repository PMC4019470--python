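import numpy as np
import pandas as pd
import pytest

import batpass as bp
from batpass.design import ModelSpec, build_design


@pytest.fixture(scope="session")
def profiles5():
    return bp.make_species_profiles(5, seed=11)


@pytest.fixture(scope="session")
def clean_profiles():
    """Zero-jitter profiles: every call of a species is identical."""
    return bp.make_species_profiles(4, seed=7, feature_sd=0.0)


@pytest.fixture(scope="session")
def small_library(profiles5):
    return bp.simulate_reference_library(profiles5, 40, seed=21)


@pytest.fixture(scope="session")
def clean_library(clean_profiles):
    return bp.simulate_reference_library(
        clean_profiles, 20, seed=5, quality_rate=1.0
    )


def toy_records(n_nights=3, counts=None, seed=0):
    """A tiny crossed design: n_nights x 2 transects x 3 distances."""
    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    for j in range(n_nights):
        night = f"n{j + 1}"
        for tr, site in (("T1", "DOED"), ("T2", "SAPA")):
            for d in (0, 100, 300):
                c = counts[k] if counts is not None else int(rng.poisson(30))
                rows.append(
                    dict(
                        site=site, transect=tr, dist_road=d, night_id=night,
                        year=2010 if j < n_nights / 2 else 2011,
                        temp_max=20.0 + 3 * j,
                        light_100=(tr == "T1" and d == 0),
                        count=c,
                    )
                )
                k += 1
    return pd.DataFrame(rows)


@pytest.fixture()
def toy_design():
    df = toy_records()
    return build_design(df, ModelSpec()), df
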