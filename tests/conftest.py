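import numpy as np
import pytest

from cowtag.classifier import TemplateClassifier
from cowtag.confirmation import Roster, build_checklists
from cowtag.synthetic import TagRenderSpec, render_tag


@pytest.fixture(scope="session")
def paper_roster():
    return Roster.from_iterable(
        ["0004", "0647", "1127", "1246", "1249",
         "1733", "3140", "5202", "5208", "9230"]
    )


@pytest.fixture(scope="session")
def paper_lists(paper_roster):
    return build_checklists(paper_roster)


@pytest.fixture(scope="session")
def template_model():
    return TemplateClassifier()


def random_tag_id(rng) -> str:
    return f"{rng.integers(0, 10000):04d}"


@pytest.fixture(scope="session")
def clean_renders():
    """50 clean tag renders (no skew/blur/occlusion), fixed seed."""
    rng = np.random.default_rng(99)
    out = []
    for _ in range(50):
        tag = random_tag_id(rng)
        spec = TagRenderSpec(tag_id=tag, seed=int(rng.integers(2**31)))
        out.append((spec, *render_tag(spec)))
    return out
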