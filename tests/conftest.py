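import numpy as np
import pytest

import ragcut as rc


@pytest.fixture(scope="session")
def catalog11():
    """Topology catalog for 2..11 vertices (shared: enumeration is cached)."""
    return rc.build_catalog(2, 11)


@pytest.fixture(scope="session")
def paper_graphs():
    return {rid: rc.paper_graph(rid).graph() for rid in rc.FIXTURE_IDS}


def random_nested_dotbracket(rng: np.random.Generator) -> str:
    """A random pseudoknot-free dot-bracket string with at least one helix.

    Exercises hairpins, internal loops, junctions, 1-nt bulges, and
    isolated pairs, so conversion-rule edge cases appear by construction.
    """

    def unit(depth: int) -> str:
        stem = int(rng.integers(2, 5))
        roll = rng.random()
        if depth >= 3 or roll < 0.45:
            loop = "." * int(rng.integers(3, 7))
            body = loop
        elif roll < 0.75:  # internal loop or bulge (possibly 1x0)
            left = int(rng.integers(0, 3))
            right = int(rng.integers(0, 3)) if left else int(rng.integers(1, 3))
            body = "." * left + unit(depth + 1) + "." * right
        else:  # junction of 2-3 arms
            arms = [unit(depth + 1) for _ in range(int(rng.integers(2, 4)))]
            spacers = ["." * int(rng.integers(0, 3)) for _ in range(len(arms) + 1)]
            body = spacers[0] + "".join(
                a + s for a, s in zip(arms, spacers[1:])
            )
        s = "(" * stem + body + ")" * stem
        if rng.random() < 0.2:  # sprinkle an isolated pair around it
            s = "(." + s + ".)"
        return s

    tails = "." * int(rng.integers(0, 4)), "." * int(rng.integers(0, 4))
    n_top = int(rng.integers(1, 3))
    middle = "." * int(rng.integers(1, 3))
    return tails[0] + middle.join(unit(0) for _ in range(n_top)) + tails[1]


@pytest.fixture(scope="session")
def nested_structure_factory():
    return random_nested_dotbracket
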