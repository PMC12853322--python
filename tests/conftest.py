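import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture()
def small_cohort_frame():
    """A scored synthetic UK-like cohort small enough for fast tests."""
    from gemana.cohort import UK, default_config, generate_cohort_frame
    from gemana.scores import score_frame

    config = default_config(UK, n=800, seed=11)
    return score_frame(generate_cohort_frame(config))


def brute_force_c(scores, times, events):
    """Exhaustive pair enumeration oracle for Harrell's c.

    Usable pairs: the shorter time is an event; tied times only when both
    are events with tied scores (0.5 credit).  Kept deliberately loop-based
    and independent of the package implementation.
    """
    n = len(scores)
    num = 0.0
    den = 0
    for i in range(n):
        for j in range(i + 1, n):
            ti, tj = times[i], times[j]
            ei, ej = events[i], events[j]
            si, sj = scores[i], scores[j]
            if ti == tj:
                if ei and ej and si == sj:
                    den += 1
                    num += 0.5
                continue
            if ti < tj and ei:
                den += 1
                num += 1.0 if si > sj else (0.5 if si == sj else 0.0)
            elif tj < ti and ej:
                den += 1
                num += 1.0 if sj > si else (0.5 if si == sj else 0.0)
    if den == 0:
        return None
    return num / den
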