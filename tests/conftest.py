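"""Shared fixtures: a small synthetic corpus, templates and rendered stacks.

Session-scoped so the template build and rendering run once for the whole
suite.  The deterministic classical-MDS embedding is used throughout the
tests.
"""

import numpy as np
import pytest

import rnagrid as rg


@pytest.fixture(scope="session")
def small_corpus() -> rg.LabeledCorpus:
    return rg.generate_synthetic_corpus(15, "coding", (150, 300), seed=42)


@pytest.fixture(scope="session")
def templates(small_corpus):
    seqs = small_corpus.sequences
    tpl_d = rg.build_template(seqs, "D", method="mds", seed=1)
    tpl_g = rg.build_template(seqs, "G", method="mds", seed=1)
    return tpl_d, tpl_g


@pytest.fixture(scope="session")
def rendered(small_corpus, templates):
    tpl_d, tpl_g = templates
    xd, xg = rg.render_corpus_channels(small_corpus.sequences, tpl_d, tpl_g)
    return xd, xg, small_corpus.y()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_rna(rng: np.random.Generator, length: int,
               sid: str = "r") -> rg.RnaSequence:
    bases = "".join(np.array(list("ACGU"))[rng.integers(0, 4, length)])
    return rg.RnaSequence(id=sid, residues=bases)
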