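"""Buffer of previously generated image pairs for discriminator updates.

While filling (up to capacity) the current pair is stored and returned.
Once full, each query returns the current pair with probability 0.5;
otherwise a uniformly drawn buffered pair is returned and replaced by
the current one.  All randomness comes from the seeded generator, so a
query sequence is reproducible.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

__all__ = ["ImagePool", "pool_query"]


class ImagePool:
    def __init__(self, capacity: int = 64, seed: int = 0):
        if capacity < 0:
            raise ValueError("capacity must be non-negative")
        self.capacity = capacity
        self.buffer = []
        self.rng = np.random.default_rng(seed)

    def __len__(self):
        return len(self.buffer)

    def query(self, pair: Tuple[np.ndarray, np.ndarray]):
        if self.capacity == 0:
            return pair
        if len(self.buffer) < self.capacity:
            self.buffer.append(pair)
            return pair
        if self.rng.random() < 0.5:
            return pair
        idx = int(self.rng.integers(self.capacity))
        stored = self.buffer[idx]
        self.buffer[idx] = pair
        return stored


def pool_query(pool: ImagePool, pair):
    return pool.query(pair)
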