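import numpy as np
import pytest

from sortalign.simulate import SortRecord

FOUR_CATS = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}


def make_sort(positions, ids=("A1", "A2", "B1", "B2"), pid="p", cond="x",
              canvas=(1024, 768)):
    return SortRecord(
        participant_id=pid, condition=cond, item_ids=tuple(ids),
        positions=tuple(map(tuple, positions)), canvas_w=canvas[0], canvas_h=canvas[1],
    )


@pytest.fixture
def four_item_sort():
    """Hand-checkable fixture: two tight category columns 10 px apart."""
    return make_sort([(0, 0), (0, 1), (10, 0), (10, 1)])


@pytest.fixture
def four_item_sort_b():
    """Second sort over the same items, for dyadic alignment checks."""
    return make_sort([(0, 0), (0, 2), (4, 0), (9, 1)], pid="q")


@pytest.fixture
def twenty_ids():
    return tuple(f"A{i:02d}" for i in range(1, 11)) + tuple(
        f"B{i:02d}" for i in range(1, 11)
    )


@pytest.fixture
def twenty_cats(twenty_ids):
    return {i: i[0] for i in twenty_ids}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
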