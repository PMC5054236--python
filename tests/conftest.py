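import numpy as np
import pytest

from newsworthy import Citation, LabeledCorpus


@pytest.fixture
def toy_corpus() -> LabeledCorpus:
    """Three small citations with hand-checkable features."""
    return LabeledCorpus(citations=[
        Citation(id="c1", title="Magnetic resonance imaging study",
                 abstract="imaging results of the brain study",
                 mesh_terms=("Great Britain", "Humans"),
                 journal="J Test", year=2011, issue="1", label="positive"),
        Citation(id="c2", title="Brain imaging",
                 abstract="results were great",
                 mesh_terms=("Humans",),
                 journal="J Test", year=2011, issue="1", label="negative"),
        Citation(id="c3", title="Mice thyroid study",
                 abstract="thyroid signaling in mice",
                 mesh_terms=("Mice", "Thyroid Gland"),
                 journal="J Test", year=2012, issue="2", label="negative"),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_pool(rng, n, journals=("a", "b"), issues=("1", "2"), years=(2011, 2012),
                prefix="p") -> list[Citation]:
    """Random unlabeled pool citations over a small key space."""
    return [
        Citation(
            id=f"{prefix}{i}",
            title=f"pool article {i}",
            journal=str(rng.choice(journals)),
            issue=str(rng.choice(issues)),
            year=int(rng.choice(years)),
            label="unlabeled",
        )
        for i in range(n)
    ]
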