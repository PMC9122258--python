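import pytest

from thermosalmon import heat, synth


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale synthetic river: 10 nodes, 12-day window, 2-day flush."""
    return synth.SyntheticConfig(
        seed=7, n_nodes=10, start_date="2019-06-10", end_date="2019-06-21", flush_days=2
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return synth.make_dataset(small_cfg)


@pytest.fixture(scope="session")
def physical_substrate():
    return heat.SubstrateParams.physical_sediment()


@pytest.fixture(scope="session")
def small_field(small_dataset, physical_substrate):
    return synth.run_truth(small_dataset, physical_substrate)
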