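import numpy as np
import pytest

from dietscope.data_model import GutRecord, Site
from dietscope.synthetic import (
    CategoryEffect,
    SyntheticScenario,
    generate_records,
    generate_sites,
    get_preset,
)


def recovery_scenario(seed, n_total, cla=CategoryEffect(-8.0, 0.4), **kw):
    """Parameter-recovery study conditions: every gut contains prey, so the
    focal category's presence follows its logistic model exactly; DIP is
    near-ubiquitous so the at-least-one-item rule never touches CLA."""
    effects = {"CLA": cla, "DIP": CategoryEffect(30.0, mean_count=3.0)}
    base = SyntheticScenario(
        seed=seed,
        empty_gut_prob=0.0,
        detritus_or_unid_only_prob=0.0,
        category_effects=effects,
        rgl_pop_means=kw.pop("rgl_pop_means", (0.5,) * 9),
        **kw,
    )
    return base.scaled_to(n_total)


def make_record(
    fish_id="f1",
    population_id="P1",
    sex="F",
    sl=20.0,
    gut_length=12.0,
    fullness=0.5,
    pregnant=None,
    counts=None,
    detritus=False,
    unid=False,
):
    """Terse GutRecord factory for hand-built fixtures."""
    if pregnant is None:
        pregnant = "no" if sex == "F" else "not-applicable"
    return GutRecord(
        fish_id=fish_id,
        population_id=population_id,
        sex=sex,
        standard_length=sl,
        gut_length=gut_length,
        fullness=fullness,
        pregnant=pregnant,
        prey_counts=counts or {},
        detritus_present=detritus,
        unidentifiable_present=unid,
    )


def make_site(population_id="P1", lat=40.0, lon=10.0, **kw):
    defaults = dict(
        country="IT",
        conductivity=1.0,
        dissolved_oxygen=8.0,
        ph=7.5,
        water_temperature=25.0,
        daily_mean_temp=24.0,
        daily_max_temp=28.0,
        daily_min_temp=20.0,
        precipitation=1.0,
    )
    defaults.update(kw)
    return Site(population_id=population_id, latitude=lat, longitude=lon, **defaults)


@pytest.fixture(scope="session")
def paper_like_records():
    scenario = get_preset("paper_like", seed=7)
    return generate_records(scenario)


@pytest.fixture(scope="session")
def paper_like_sites():
    return generate_sites(get_preset("paper_like", seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


# Published two-triangle dietary overlap matrix for nine mosquitofish
# populations: Schoener index in the upper triangle, Pianka in the lower.
# Used as a consistency fixture for the overlap-index correlation.
PUBLISHED_SCHOENER = {
    ("P1", "P2"): 0.53, ("P1", "P3"): 0.68, ("P1", "P4"): 0.30, ("P1", "P5"): 0.75,
    ("P1", "P6"): 0.70, ("P1", "P7"): 0.64, ("P1", "P8"): 0.28, ("P1", "P9"): 0.35,
    ("P2", "P3"): 0.68, ("P2", "P4"): 0.52, ("P2", "P5"): 0.36, ("P2", "P6"): 0.28,
    ("P2", "P7"): 0.25, ("P2", "P8"): 0.61, ("P2", "P9"): 0.30,
    ("P3", "P4"): 0.48, ("P3", "P5"): 0.61, ("P3", "P6"): 0.54, ("P3", "P7"): 0.50,
    ("P3", "P8"): 0.29, ("P3", "P9"): 0.23,
    ("P4", "P5"): 0.12, ("P4", "P6"): 0.11, ("P4", "P7"): 0.00, ("P4", "P8"): 0.39,
    ("P4", "P9"): 0.42,
    ("P5", "P6"): 0.86, ("P5", "P7"): 0.81, ("P5", "P8"): 0.11, ("P5", "P9"): 0.18,
    ("P6", "P7"): 0.13, ("P6", "P8"): 0.05, ("P6", "P9"): 0.13,
    ("P7", "P8"): 0.00, ("P7", "P9"): 0.00,
    ("P8", "P9"): 0.33,
}

PUBLISHED_PIANKA = {
    ("P1", "P2"): 0.70, ("P1", "P3"): 0.88, ("P1", "P4"): 0.18, ("P1", "P5"): 0.96,
    ("P1", "P6"): 0.93, ("P1", "P7"): 0.91, ("P1", "P8"): 0.40, ("P1", "P9"): 0.27,
    ("P2", "P3"): 0.77, ("P2", "P4"): 0.71, ("P2", "P5"): 0.52, ("P2", "P6"): 0.28,
    ("P2", "P7"): 0.41, ("P2", "P8"): 0.86, ("P2", "P9"): 0.51,
    ("P3", "P4"): 0.53, ("P3", "P5"): 0.86, ("P3", "P6"): 0.84, ("P3", "P7"): 0.83,
    ("P3", "P8"): 0.36, ("P3", "P9"): 0.24,
    ("P4", "P5"): 0.06, ("P4", "P6"): 0.03, ("P4", "P7"): 0.00, ("P4", "P8"): 0.53,
    ("P4", "P9"): 0.36,
    ("P5", "P6"): 0.99, ("P5", "P7"): 0.99, ("P5", "P8"): 0.14, ("P5", "P9"): 0.10,
    ("P6", "P7"): 0.06, ("P6", "P8"): 0.04, ("P6", "P9"): 0.00,
    ("P7", "P8"): 0.00, ("P7", "P9"): 0.00,
    ("P8", "P9"): 0.63,
}
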