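import numpy as np
import pytest

from ltrcmiss import LTRCSample


def make_sample(entry, time, status, x, w, **kw):
    """Build an LTRCSample from plain lists (w as list of rows)."""
    entry = np.asarray(entry, dtype=float)
    w = np.asarray(w, dtype=int)
    if w.ndim == 1:
        w = w[:, None]
    return LTRCSample(entry=entry, time=np.asarray(time, dtype=float),
                      status=np.asarray(status, dtype=int),
                      x=np.asarray(x, dtype=float), w=w, **kw)


@pytest.fixture
def six_subjects():
    """Six subjects, one binary covariate, no truncation, all events."""
    return make_sample(entry=[0, 0, 0, 0, 0, 0],
                       time=[2, 4, 5, 7, 9, 10],
                       status=[1, 1, 1, 0, 1, 1],
                       x=[1, 0, 1, 0, 1, 0],
                       w=np.zeros((6, 0), dtype=int))


@pytest.fixture
def six_subjects_truncated(six_subjects):
    """Same outcomes with entry times removing two subjects from early
    risk sets."""
    return make_sample(entry=[0, 0, 3, 0, 0, 8],
                       time=[2, 4, 5, 7, 9, 10],
                       status=[1, 1, 1, 0, 1, 1],
                       x=[1, 0, 1, 0, 1, 0],
                       w=np.zeros((6, 0), dtype=int))


@pytest.fixture
def three_subjects():
    """The minimal worked example for hazard estimators."""
    return make_sample(entry=[0, 1, 2.5], time=[2, 3, 4], status=[1, 1, 0],
                       x=[1, 0, 1], w=np.zeros((3, 0), dtype=int))
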