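import numpy as np
import pytest

from clusterfis import (
    FuzzyRule,
    FuzzyVariable,
    MembershipFunction,
    RuleBase,
    assemble_fis,
)


def make_variable(name, centers, domain):
    """Ordered shoulder/triangle family from sorted centers (test-side builder)."""
    c = sorted(centers)
    lo, hi = domain
    mfs = [MembershipFunction("left_shoulder", c[0], lo, c[1])]
    for j in range(1, len(c) - 1):
        mfs.append(MembershipFunction("triangular", c[j], c[j - 1], c[j + 1]))
    mfs.append(MembershipFunction("right_shoulder", c[-1], c[-2], hi))
    return FuzzyVariable(name=name, domain=domain, mfs=mfs)


def random_toy_fis(rng, n_features=None, grid_points=1001):
    """A random small FIS: 2-3 input variables with 2-4 mfs, 2-3 output mfs."""
    if n_features is None:
        n_features = int(rng.integers(2, 4))
    names = [f"X{j}" for j in range(n_features)]
    input_vars = {}
    for name in names:
        k = int(rng.integers(2, 5))
        centers = np.sort(rng.uniform(0.5, 9.5, size=k))
        while np.any(np.diff(centers) < 0.3):  # keep apexes separated
            centers = np.sort(rng.uniform(0.5, 9.5, size=k))
        input_vars[name] = make_variable(name, centers, (0.0, 10.0))
    k_out = int(rng.integers(2, 4))
    out_centers = np.sort(rng.uniform(1.05, 1.95, size=k_out))
    while np.any(np.diff(out_centers) < 0.1):
        out_centers = np.sort(rng.uniform(1.05, 1.95, size=k_out))
    output_var = make_variable("class", out_centers, (1.0, 2.0))

    n_rules = int(rng.integers(2, 9))
    seen = set()
    rules = []
    for _ in range(n_rules):
        ant = tuple(
            (name, int(rng.integers(0, input_vars[name].k))) for name in names
        )
        if ant in seen:
            continue
        seen.add(ant)
        rules.append(FuzzyRule(ant, consequent=int(rng.integers(0, k_out))))
    rule_base = RuleBase(rules=rules, features=names)
    return assemble_fis(
        input_vars, output_var, rule_base, {"grid_points": grid_points}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230510)
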