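"""Deterministic expansion of one global seed into independent per-stage streams.

Splitting rule: the child seed for stage labels ``(a, b, ...)`` is the first
word of ``numpy.random.SeedSequence([root, crc32(a), crc32(b), ...])``,
reduced modulo 2**31 so it is valid everywhere an ``int`` seed is accepted
(scikit-learn, xgboost).  Distinct label paths give statistically
independent streams; the same path always gives the same seed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "derive_rng"]


def derive_seed(root: int, *labels: str | int) -> int:
    """Derive an integer child seed for a named stage from the root seed."""
    keys = [int(root)]
    for lab in labels:
        if isinstance(lab, int):
            keys.append(lab)
        else:
            keys.append(zlib.crc32(str(lab).encode("utf8")))
    ss = np.random.SeedSequence(keys)
    return int(ss.generate_state(1)[0] % (2**31))


def derive_rng(root: int, *labels: str | int) -> np.random.Generator:
    """A ``numpy`` Generator seeded from the derived child seed."""
    return np.random.default_rng(derive_seed(root, *labels))
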