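import numpy as np
import pytest

from matlact import pedigree as pg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def trio():
    """Child listed first; sire and dam are unrelated founders."""
    return [("child", "sire", "dam"), ("sire", "0", "0"), ("dam", "0", "0")]


@pytest.fixture
def fullsib_mating():
    """Offspring of two full sibs whose parents are unrelated founders."""
    return [
        ("gs", "0", "0"), ("gd", "0", "0"),
        ("s", "gs", "gd"), ("d", "gs", "gd"),
        ("x", "s", "d"),
    ]


def random_pedigree(n: int, n_founders: int, seed: int) -> pg.Pedigree:
    """Random acyclic pedigree: parents drawn from earlier individuals."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        if i < n_founders:
            rows.append((f"i{i}", "0", "0"))
        else:
            s, d = rng.integers(0, i, 2)
            rows.append((f"i{i}", f"i{s}", f"i{d}" if d != s else "0"))
    return pg.validate_and_order(rows)


@pytest.fixture
def random_ped_300():
    return random_pedigree(300, 30, seed=7)
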