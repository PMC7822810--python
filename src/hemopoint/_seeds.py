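"""Deterministic seed splitting.

One master seed drives an entire corpus / run.  Child streams are derived with
``numpy.random.SeedSequence`` from the tuple ``(master, *path)`` where *path*
is a sequence of small integers and/or short strings identifying the consumer
(e.g. ``("expand", model_index)``).  The same (master, path) always yields the
same stream; distinct paths yield statistically independent streams.
"""

from __future__ import annotations

import numpy as np

__all__ = ["child_rng", "child_seed"]


def _encode(part) -> int:
    if isinstance(part, (int, np.integer)):
        if part < 0:
            raise ValueError("seed path parts must be non-negative")
        return int(part)
    if isinstance(part, str):
        # stable small-int encoding of a short ASCII tag
        h = 0
        for ch in part.encode("ascii"):
            h = (h * 131 + ch) % (2**31 - 1)
        return h
    raise TypeError(f"unsupported seed path part: {part!r}")


def child_seed(master: int, *path) -> np.random.SeedSequence:
    """SeedSequence for the child stream identified by *path*."""
    return np.random.SeedSequence([int(master)] + [_encode(p) for p in path])


def child_rng(master: int, *path) -> np.random.Generator:
    """Generator seeded by :func:`child_seed`."""
    return np.random.default_rng(child_seed(master, *path))
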