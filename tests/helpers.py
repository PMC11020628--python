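"""Shared helpers for the test suite."""
import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(n: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(_BASES, size=n, p=p).tobytes().decode()
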