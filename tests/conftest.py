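import numpy as np
import pytest

from srpmotif import defaults, fixtures
from srpmotif.pipeline import build_db, run_query


@pytest.fixture(scope="session")
def codebook():
    return defaults.default_codebook()


@pytest.fixture(scope="session")
def sasm():
    return defaults.default_sasm()


@pytest.fixture(scope="session")
def template_query():
    return fixtures.make_template_query(seed=1)


@pytest.fixture(scope="session")
def synthetic_world():
    """Query + database (5 planted homologs, 10 decoys, query itself) and the
    ground-truth table, seed 1."""
    query = fixtures.make_template_query(seed=1)
    db_complexes, truth = fixtures.build_synthetic_db(5, 10, rng_seed=1)
    db_complexes = db_complexes + [query]
    db = build_db(db_complexes)
    return query, db, {c.id: c for c in db_complexes}, truth


@pytest.fixture(scope="session")
def pipeline_result(synthetic_world):
    query, db, db_complexes, truth = synthetic_world
    return run_query(query, db, db_complexes)


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
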