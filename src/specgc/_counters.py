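"""Package-wide warning/clamp counters.

Numerical guard events (log-ratio clamps, near-singular solves, correlated
innovation warnings) are counted here in addition to being logged, so that
batch runs can report them in a manifest instead of relying on stderr.
"""

from __future__ import annotations

import logging
from collections import Counter

logger = logging.getLogger("specgc")

_counters: Counter = Counter()


def count(event: str, n: int = 1) -> None:
    if n:
        _counters[event] += n


def snapshot() -> dict[str, int]:
    return dict(_counters)


def reset() -> None:
    _counters.clear()
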