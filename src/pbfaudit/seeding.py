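"""Named, reproducible random substreams derived from one master seed."""

from __future__ import annotations

import zlib

import numpy as np


def substream_seed(master_seed: int, name: str) -> int:
    """A stable 31-bit seed for the named pipeline stage."""
    ss = np.random.SeedSequence([master_seed, zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2**31))
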