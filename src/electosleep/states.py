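"""Sleep-wake state codes and canonical region order.

States are carried as small integer codes throughout the package:
``WAKE=0, NREM=1, REM=2, UNKNOWN=-1``.  The order (wake, NREM, REM) is the
tie-break and reporting order everywhere.
"""

from __future__ import annotations

import numpy as np

WAKE: int = 0
NREM: int = 1
REM: int = 2
UNKNOWN: int = -1

#: canonical state order for probabilities, logits, confusion tables
STATES: tuple[int, int, int] = (WAKE, NREM, REM)
STATE_NAMES: tuple[str, str, str] = ("wake", "nrem", "rem")
UNKNOWN_NAME: str = "unknown"

#: the eight recorded regions, in fixed order
DEFAULT_REGIONS: tuple[str, ...] = (
    "CxCg", "CxPrL", "CxIL", "NAc", "Amy", "ThalMD", "HippV", "VTA",
)

_NAME_TO_CODE = {n: c for c, n in zip(STATES, STATE_NAMES)}
_NAME_TO_CODE[UNKNOWN_NAME] = UNKNOWN


def state_name(code: int) -> str:
    """Human-readable name for a state code."""
    if code == UNKNOWN:
        return UNKNOWN_NAME
    return STATE_NAMES[code]


def state_code(name: str) -> int:
    """Inverse of :func:`state_name`; case-insensitive."""
    try:
        return _NAME_TO_CODE[name.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown state name: {name!r}") from None


def labels_to_names(labels: np.ndarray) -> list[str]:
    return [state_name(int(c)) for c in labels]


def names_to_labels(names) -> np.ndarray:
    return np.array([state_code(n) for n in names], dtype=np.int64)
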