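"""Named, replicate-indexed random substreams.

Each replicate of the experiment owns one independent random source per
model component (case arrivals, cancer types, identification sources,
treatment waits, suspense waits, abstraction times, external-record
delays).  Streams are derived from ``SeedSequence(seed, spawn_key=
(replicate, stream_index))`` with a fixed name-to-index map, so adding a new
sampler to one component never perturbs the draws of another, and the full
experiment is reproducible from the single top-level seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["STREAM_NAMES", "named_streams"]

STREAM_NAMES = (
    "arrivals",
    "types",
    "sources",
    "treatment",
    "suspense",
    "abstraction",
    "external",
)


def named_streams(seed: int, replicate: int = 0) -> dict[str, np.random.Generator]:
    """One independent generator per named model component."""
    if replicate < 0:
        raise ValueError("replicate index must be >= 0")
    return {
        name: np.random.default_rng(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(replicate, i))
        )
        for i, name in enumerate(STREAM_NAMES)
    }
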