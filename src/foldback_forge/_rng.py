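"""Named random substreams derived from one master seed.

Each simulation task (genome construction, read simulation, fluctuation
cultures, ...) draws from its own substream so that modules can be re-run
independently without perturbing each other's randomness.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Generator for the substream `name` under `master_seed`.

    The stream key mixes the master seed with a CRC of the task name, so
    streams are stable across sessions and independent across names.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), key]))
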