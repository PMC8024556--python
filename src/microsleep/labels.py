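"""Label vocabulary for the wake / microsleep scoring scheme.

Per-sample tracks use the four integer codes W, MSE, MSEC, ED.  Event
scorings may additionally carry SLEEP for consolidated-sleep episodes
longer than 15 s; when such events are rasterized for training they are
mapped to MSE by default (they show the same EEG slowing, just longer).
"""

from __future__ import annotations

from enum import IntEnum


class Label(IntEnum):
    """Integer class codes used in per-sample label tracks."""

    W = 0      # wakefulness
    MSE = 1    # microsleep episode (1-15 s, theta-dominant EEG)
    MSEC = 2   # microsleep episode candidate (borderline)
    ED = 3     # episode of drowsiness (vague, neither wake nor MSE)
    SLEEP = 4  # consolidated sleep > 15 s; event-level only


#: Classes a per-sample track may contain.
TRACK_CLASSES: tuple[Label, ...] = (Label.W, Label.MSE, Label.MSEC, Label.ED)

#: Case-insensitive aliases accepted when parsing scoring files.
LABEL_ALIASES: dict[str, Label] = {
    "w": Label.W,
    "wake": Label.W,
    "mse": Label.MSE,
    "msec": Label.MSEC,
    "mse_c": Label.MSEC,
    "ed": Label.ED,
    "sleep": Label.SLEEP,
}


def parse_label(text: str, aliases: dict[str, Label] | None = None) -> Label:
    """Resolve a scoring-file label string to a :class:`Label`.

    Raises
    ------
    ValueError
        If the string is not in the (case-insensitive) vocabulary.
    """
    table = LABEL_ALIASES if aliases is None else aliases
    key = text.strip().lower()
    if key not in table:
        raise ValueError(
            f"unknown event label {text!r}; known labels: {sorted(table)}"
        )
    return table[key]
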