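import numpy as np
import pytest

from emothreads import Corpus, Thread

SYMBOLS = {"+": 1, "-": -1, "0": 0}


def corpus_from_strings(*seqs: str, provenance: str = "test") -> Corpus:
    """Build a corpus from compact valence strings like '++-00'."""
    threads = [
        Thread(f"t{i}", [SYMBOLS[ch] for ch in s]) for i, s in enumerate(seqs)
    ]
    return Corpus(threads, provenance=provenance)


def random_small_corpus(rng: np.random.Generator, max_posts: int = 50) -> Corpus:
    """A random corpus of at most max_posts posts split into random threads."""
    total = int(rng.integers(1, max_posts + 1))
    threads, i = [], 0
    remaining = total
    while remaining > 0:
        L = int(rng.integers(1, remaining + 1))
        v = rng.choice([-1, 0, 1], size=L)
        threads.append(Thread(f"t{i}", v))
        remaining -= L
        i += 1
    return Corpus(threads)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
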