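import pytest

from o3hia.synthetic_data import SyntheticWorldConfig


@pytest.fixture(scope="session")
def tiny_cfg() -> SyntheticWorldConfig:
    """A small two-year world used by several integration tests."""
    return SyntheticWorldConfig(
        n_cities=4, n_countries=2, n_models=2, members_per_model=2,
        scenarios=("ssp126", "ssp370"),
        years_hist=(2013, 2014), years_present=(2013, 2014),
        years_future=(2053, 2054),
        lat_range=(40.0, 48.0), lon_range=(0.0, 10.0),
        seed=7,
    )
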