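import numpy as np
import pytest

from sagphage import ScenarioConfig, build_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(20110809)


@pytest.fixture(scope="session")
def default_scenario():
    """The default end-to-end study, built once per session."""
    return build_scenario(ScenarioConfig(seed=7))


def make_gene(i, contig="c1", start=None, end=None, strand="+",
              characterized=False, annotation="hypothetical protein",
              protein=""):
    from sagphage import Gene

    start = start if start is not None else 100 * i + 1
    end = end if end is not None else start + 299
    return Gene(
        id=f"{contig}_g{i}",
        contig_id=contig,
        start=start,
        end=end,
        strand=strand,
        protein=protein,
        characterized=characterized,
        annotation_text=annotation,
    )
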