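import pytest

from gfdeval import default_food_table, generate, study_design_spec


@pytest.fixture(scope="session")
def foods():
    return default_food_table()


def small_spec(seed=42):
    """A reduced cohort (same study design, fewer participants) so unit
    tests stay fast; the acceptance tests use larger cohorts."""
    return study_design_spec(
        seed=seed, adults_per_visit=(10, 6, 3), children_per_visit=(10, 7, 4))


@pytest.fixture(scope="session")
def small_cohort(foods):
    bundle, gt = generate(small_spec(), foods)
    return bundle, gt
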