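import numpy as np
import pytest

from emonet.model import Cohort, DepressionSeries, EmaPanel

ITEMS4 = ["worried", "irritable", "content", "energetic"]
VALENCE4 = {
    "worried": "negative",
    "irritable": "negative",
    "content": "positive",
    "energetic": "positive",
}


def make_panel(values, items=None, valence=None, scale="likert", pid="p1"):
    items = items or ITEMS4[: np.asarray(values).shape[1]]
    valence = valence or {k: VALENCE4.get(k, "negative") for k in items}
    return EmaPanel(
        participant_id=pid,
        item_names=items,
        item_valence=valence,
        values=np.asarray(values, dtype=float),
        scale=scale,
    )


@pytest.fixture
def tiny_panel():
    """4 assessments x 2 items, fully observed."""
    return make_panel(
        [[1, 2], [0, 1], [-1, 0], [2, -2]], items=["worried", "content"]
    )


@pytest.fixture
def random_panel():
    """Continuous 300 x 5 panel of white noise (fits always succeed)."""
    rng = np.random.default_rng(7)
    items = ["a", "b", "c", "d", "e"]
    return make_panel(
        rng.standard_normal((300, 5)),
        items=items,
        valence={i: "negative" for i in items},
        scale="continuous",
    )


def make_cohort(panels, scores=None):
    cohort = Cohort(panels={p.participant_id: p for p in panels})
    if scores:
        cohort.depression = {
            pid: DepressionSeries(participant_id=pid, scores=np.asarray(s, float))
            for pid, s in scores.items()
        }
    return cohort
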