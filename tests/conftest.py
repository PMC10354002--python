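import pytest

import dce_cea as dc


@pytest.fixture(scope="session")
def fixtures():
    return dc.load_fixtures()


@pytest.fixture(scope="session")
def coeffs(fixtures):
    """The six significant attribute levels with their published coefficients."""
    return fixtures.coefficients


@pytest.fixture(scope="session")
def clinic_a(fixtures):
    return fixtures.profiles["Clinic A"]


@pytest.fixture(scope="session")
def clinic_b(fixtures):
    return fixtures.profiles["Clinic B"]


@pytest.fixture(scope="session")
def strategies_a(fixtures):
    return dc.strategies_from_table(fixtures.clinic_a)


@pytest.fixture(scope="session")
def strategies_b(fixtures):
    return dc.strategies_from_table(fixtures.clinic_b)


def frontier_oracle(points):
    """Independent frontier characterization via a willingness-to-pay sweep.

    A strategy survives dominance + extended dominance iff it is the unique
    minimizer of cost - lambda * effect for some lambda > 0, over the
    strategy cloud plus the origin (support-function view of the lower-left
    convex hull).  Exact duplicates keep the first name only.
    """
    dedup: dict[tuple[float, float], str] = {}
    for name, effect, cost in points:
        key = (effect, cost)
        if key not in dedup or name < dedup[key]:
            dedup[key] = name
    cloud = [(name, e, c) for (e, c), name in dedup.items()] + [("__origin__", 0.0, 0.0)]
    slopes = set()
    for i, (_, e1, c1) in enumerate(cloud):
        for _, e2, c2 in cloud[i + 1 :]:
            if e1 != e2:
                s = (c1 - c2) / (e1 - e2)
                if s > 0:
                    slopes.add(s)
    ordered = sorted(slopes)
    lambdas = [s / 2 for s in ordered[:1]]
    lambdas += [(a + b) / 2 for a, b in zip(ordered, ordered[1:])]
    lambdas += [ordered[-1] * 2] if ordered else [1.0]
    survivors = set()
    for lam in lambdas:
        scores = [(c - lam * e, name) for name, e, c in cloud]
        best = min(s for s, _ in scores)
        winners = [name for s, name in scores if s == best]
        if len(winners) == 1 and winners[0] != "__origin__":
            survivors.add(winners[0])
    return survivors


@pytest.fixture(scope="session")
def hull_oracle():
    return frontier_oracle
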