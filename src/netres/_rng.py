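"""Seed derivation.

Every stochastic stage draws from a Generator derived from one master seed
plus a stage name, so that pipelines are bit-reproducible end to end and
stages can be re-run in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(master_seed: int, *names: str | int) -> np.random.Generator:
    """Return an independent Generator for a named stage.

    The stream is a pure function of (master_seed, names): the names are
    hashed (crc32) into SeedSequence entropy so adding a stage never shifts
    the streams of existing stages.
    """
    keys = [zlib.crc32(str(n).encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *keys]))


def subseed(master_seed: int, *names: str | int) -> int:
    """A plain integer sub-seed (< 2**31) for APIs that want one."""
    return int(substream(master_seed, *names).integers(0, 2**31 - 1))
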