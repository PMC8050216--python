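"""Sleep-stage vocabulary shared across the package.

Five AASM stages are scored; anything else (movement, unscored, lights-on)
is carried as a MASK token that is shown to the model but excluded from the
loss and from every evaluation metric.
"""

from __future__ import annotations

import numpy as np

#: Canonical stage order. Index into this tuple is the integer stage code.
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")

N_STAGES: int = len(STAGES)

#: Integer code for the non-stage (masked) token.
MASK_CODE: int = N_STAGES

MASK_TOKEN: str = "MASK"

STAGE_TO_CODE: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

#: Raw annotation tokens that map onto an AASM stage. R&K deep-sleep stages
#: S3/S4 merge into N3; common synonyms are accepted case-insensitively.
_RAW_STAGE_ALIASES: dict[str, str] = {
    "W": "W",
    "WAKE": "W",
    "N1": "N1",
    "S1": "N1",
    "N2": "N2",
    "S2": "N2",
    "N3": "N3",
    "S3": "N3",
    "S4": "N3",
    "REM": "REM",
    "R": "REM",
}


def code_of(token: str) -> int:
    """Map one raw annotation token to a stage code (total mapping).

    Unrecognized tokens — MOVEMENT, UNKNOWN, '?', vendor-specific strings —
    all map to :data:`MASK_CODE`.
    """
    stage = _RAW_STAGE_ALIASES.get(str(token).strip().upper())
    return STAGE_TO_CODE[stage] if stage is not None else MASK_CODE


def tokens_of(codes: np.ndarray) -> list[str]:
    """Inverse of :func:`code_of` on canonical codes."""
    vocab = STAGES + (MASK_TOKEN,)
    return [vocab[int(c)] for c in codes]
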