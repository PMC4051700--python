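import pytest

import binacle as b


@pytest.fixture(scope="session")
def profile():
    return b.default_profile()


@pytest.fixture(scope="session")
def small_sim():
    """8 species, one with two 5%-divergent haplogroups; QC'd and aligned."""
    cfg = b.SimConfig(
        n_species=8, specimens_per_species=(3, 6), split_species=((2, 0.05),), seed=11
    )
    records, specimens, truth = b.simulate(cfg)
    matrix, reports = b.align_records(records, b.default_profile())
    dm = b.distance_matrix(matrix)
    return {
        "config": cfg,
        "records": records,
        "specimens": specimens,
        "truth": truth,
        "matrix": matrix,
        "reports": reports,
        "dm": dm,
    }


@pytest.fixture(scope="session")
def fixture_table():
    return b.load_incidence_fixture()


@pytest.fixture(scope="session")
def fixture_results(fixture_table):
    return b.classify_species(b.incidence_to_specimens(fixture_table))
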