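"""Named random substreams derived from a single master seed.

Every stochastic stage of the pipeline draws from a substream keyed by a
stable name (e.g. ``("crw", tag_id, index)``), so that runs are reproducible
from one integer and stages can be re-run in isolation.
"""

from __future__ import annotations

import hashlib

import numpy as np


def substream_key(*names: object) -> int:
    """Stable 31-bit key for a tuple of names (independent of PYTHONHASHSEED)."""
    h = hashlib.sha256("/".join(str(n) for n in names).encode("utf-8")).digest()
    return int.from_bytes(h[:4], "big") & 0x7FFFFFFF


def substream(master_seed: int, *names: object) -> np.random.Generator:
    """A Generator for the substream named by ``names`` under ``master_seed``."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, substream_key(*names)])
    )
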