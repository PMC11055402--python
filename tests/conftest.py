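import numpy as np
import pytest

from seqtok import corpus as corpus_mod
from seqtok import synthgen


@pytest.fixture
def dna_corpus():
    """Small DNA corpus with visible repeat structure."""
    return corpus_mod.from_sequences(
        ["AAGTCAAGGATC", "AAGAAGTC", "GATCGATC", "AAGTCGA"],
        alphabet=corpus_mod.DNA,
    )


@pytest.fixture
def protein_corpus():
    rng = np.random.default_rng(11)
    chars = corpus_mod.PROTEIN_CHARS
    seqs = ["".join(rng.choice(list(chars), size=40)) + "WWWHHH" for _ in range(8)]
    return corpus_mod.from_sequences(seqs, alphabet=corpus_mod.PROTEIN)


@pytest.fixture(scope="session")
def small_class_dataset():
    """3-class planted-motif dataset, desk-sized for fast harness tests."""
    spec = synthgen.ClassTaskSpec(
        n_classes=3, sequences_per_class=(60, 10, 40), seed=7
    )
    return synthgen.gen_classification_corpus(spec)
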