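import pytest

from orrisk import (
    SyntheticConfig,
    VariableSpec,
    Item,
    VariableType,
    build_itemset,
    generate_population,
    mimic_like_config,
)


@pytest.fixture(scope="session")
def small_population():
    """A small MIMIC-like synthetic population, shared across tests."""
    return generate_population(mimic_like_config("small", seed=11))


@pytest.fixture(scope="session")
def small_candidates(small_population):
    from orrisk import mine_candidates

    return mine_candidates(small_population, "full")


@pytest.fixture
def tiny_cases():
    """Eight handcrafted cases, 3 deaths / 5 survivors, mixed item types."""
    mk = build_itemset
    icu = (VariableType.WARD, "ICU")
    male = (VariableType.GENDER, "Male")
    female = (VariableType.GENDER, "Female")
    sepsis = (VariableType.DIAGNOSIS, "Sepsis")
    return [
        mk([icu, male, sepsis], "died", "t1"),
        mk([icu, female, sepsis], "died", "t2"),
        mk([male], "died", "t3"),
        mk([icu, male], "survived", "t4"),
        mk([female, sepsis], "survived", "t5"),
        mk([female], "survived", "t6"),
        mk([male], "survived", "t7"),
        mk([], "survived", "t8"),
    ]


def null_population(n_vars, q, n_cases, seed, prefix="N"):
    """Population in which every item has planted OR exactly 1."""
    specs = tuple(
        VariableSpec(Item(VariableType.DIAGNOSIS, f"{prefix}{i:04d}"), q, 1.0)
        for i in range(n_vars)
    )
    return generate_population(
        SyntheticConfig(n_cases=n_cases, variables=specs, seed=seed)
    )
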