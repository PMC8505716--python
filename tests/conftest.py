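import numpy as np
import pytest

from screenagree.instruments import Instrument, InstrumentItem
from screenagree.synthetic import SimConfig, calibrate_to_paper, simulate_dyads


@pytest.fixture
def colors_item() -> InstrumentItem:
    """Language item with a 44-month 95%-limit age (the identify-colors case)."""
    return InstrumentItem(
        item_id="lang_colors",
        domain="language_logico_math",
        admin_min_age=36,
        admin_max_age=50,
        p50_age=38.0,
        p95_limit_age=44.0,
        text="Identify colors",
    )


@pytest.fixture
def tiny_direct() -> Instrument:
    items = [
        InstrumentItem("ps_a", "personal_social", 24, 40, 28.0, 33.0),
        InstrumentItem("ps_b", "personal_social", 30, 50, 36.0, 42.0),
        InstrumentItem("lg_a", "language_logico_math", 24, 45, 30.0, 35.0),
        InstrumentItem("fm_a", "fine_motor_adaptive", 26, 55, 34.0, 40.0),
        InstrumentItem("gm_a", "gross_motor", 24, 59, 32.0, 38.0),
    ]
    return Instrument("tiny-direct", "direct", items)


@pytest.fixture
def tiny_parent() -> Instrument:
    items = [
        InstrumentItem("ps_a", "personal_social", 24, 35, 28.0, 33.0),
        InstrumentItem("lg_a", "language_logico_math", 24, 35, 30.0, 35.0),
        InstrumentItem("ps_b", "personal_social", 36, 59, 36.0, 42.0),
        InstrumentItem("fm_a", "fine_motor_adaptive", 36, 59, 36.0, 40.0),
        InstrumentItem("gm_a", "gross_motor", 36, 59, 36.0, 38.0),
    ]
    return Instrument("tiny-parent", "parent_report", items)


@pytest.fixture(scope="session")
def small_calibrated_config() -> SimConfig:
    """Sparse item bank calibrated to the 75% direct at-risk prevalence,
    small enough for the exact enumeration oracle."""
    base = SimConfig(n_items_per_domain=(4, 4, 4, 4), admin_tail_months=12.0, seed=20260924)
    return calibrate_to_paper(base)


@pytest.fixture(scope="session")
def cohort_dataset():
    """A study-sized (n=52) simulated dyad cohort with the default bank."""
    cfg = SimConfig(n_children=52, delay_shift=2.0, seed=7)
    return simulate_dyads(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
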