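import dendropy
import numpy as np
import pytest

import germclock as gc


@pytest.fixture(scope="session")
def builtin_decs():
    return gc.load_builtin_studies()


@pytest.fixture(scope="session")
def builtin_table(builtin_decs):
    return gc.decomposition_table(builtin_decs)


@pytest.fixture(scope="session")
def relaxed_fit(builtin_decs):
    return gc.RelaxedClockModel(builtin_decs).fit()


@pytest.fixture(scope="session")
def three_taxon_tree():
    """((A:1,B:1):1,C:2); shared AB history of length 1, root-to-tip 2."""
    return dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")


@pytest.fixture(scope="session")
def yule_tree_50():
    return gc.generate_tree(50, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, sig - 1 - floor(log10(abs(x))))


def assert_matches_printed(value: float, printed: float, sig: int) -> None:
    """Check a computed value against a published figure at its printed
    precision: the value must either round to the published figure at its
    number of significant digits, or sit within 1% of it (published figures
    are sometimes truncated rather than rounded)."""
    rounded = round_sig(value, sig)
    ok = rounded == pytest.approx(printed, rel=1e-9) or value == pytest.approx(
        printed, rel=1e-2
    )
    assert ok, (
        f"computed {value:.6g} rounds to {rounded:.6g}, printed value is {printed:.6g}"
    )
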