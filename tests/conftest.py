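import pytest

from meritrank.framework import (
    CriteriaFramework,
    Criterion,
    CriterionLevel,
)
from meritrank.io import load_default_framework


def make_framework(spec: dict[str, int], elicited: dict[str, set[int]] | None = None):
    """Build a framework from {criterion name: n_levels}; all levels elicited
    unless an elicited-rank set is given per criterion."""
    criteria = []
    for name, n in spec.items():
        el = elicited.get(name) if elicited else None
        criteria.append(
            Criterion(
                name=name,
                levels=[
                    CriterionLevel(
                        label=f"L{r}",
                        rank=r,
                        elicited=(el is None or r in el),
                    )
                    for r in range(1, n + 1)
                ],
            )
        )
    return CriteriaFramework(name="test", version="0", criteria=criteria)


@pytest.fixture(scope="session")
def fw():
    """The packaged default framework: 4 criteria x 5 levels, 3 elicited."""
    return load_default_framework()


@pytest.fixture(scope="session")
def toy2():
    """Smallest legal framework: 2 criteria x 2 levels, both elicited."""
    return make_framework({"X": 2, "Y": 2})


@pytest.fixture(scope="session")
def toy23():
    """2 criteria x 3 levels (all elicited): 9 tasks, quick LP work."""
    return make_framework({"X": 3, "Y": 3})
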