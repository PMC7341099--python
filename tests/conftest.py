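import random

import pytest

from loopscreen.sequences import RnaSequence


@pytest.fixture
def random_sequences():
    """Factory: n random RNA sequences of bounded length, seeded."""

    def make(n: int, min_len: int = 5, max_len: int = 20, seed: int = 0):
        rng = random.Random(seed)
        return [
            RnaSequence(
                id=f"rand{i}",
                bases="".join(
                    rng.choice("ACGU") for _ in range(rng.randint(min_len, max_len))
                ),
            )
            for i in range(n)
        ]

    return make
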