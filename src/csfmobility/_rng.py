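"""Named random substreams derived from a single top-level seed.

Every stochastic stage of the pipeline (phantom traces, sampling pattern,
measurement noise, random binning, ...) draws from its own substream so that
stages can be re-run independently and the random negative control is
reproducible.
"""

from __future__ import annotations

import numpy as np

# Stable ids: appending is fine, renumbering is not (it would silently change
# every seeded result).
_STREAMS = {
    "phantom": 0,
    "traces": 1,
    "pattern": 2,
    "noise": 3,
    "random_binning": 4,
    "cohort": 5,
    "misc": 6,
}


def substream(seed: int, name: str, child: int | None = None) -> np.random.Generator:
    """Return the named generator for a top-level seed.

    ``child`` selects an independent sub-generator within the stream (e.g.
    one per subscan for measurement noise).
    """
    try:
        key = _STREAMS[name]
    except KeyError:
        raise KeyError(
            f"unknown substream {name!r}; known: {sorted(_STREAMS)}"
        ) from None
    spawn = (key,) if child is None else (key, int(child))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=spawn))
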