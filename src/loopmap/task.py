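"""Timeline of the delayed-response licking task.

All trial times are in seconds, aligned to the auditory go cue at ``t = 0``.
The sample epoch (pole presentation, 1.3 s) is followed by a delay epoch
(1.3 s) during which the mouse must hold its choice in short-term memory;
licking is scored in a 1.5-s answer window after the go cue.  The 500 ms
immediately before sample onset serve as the baseline window.
"""

from __future__ import annotations

SAMPLE_DUR_S = 1.3
DELAY_DUR_S = 1.3
RESPONSE_DUR_S = 1.5
BASELINE_DUR_S = 0.5

GO_CUE_S = 0.0
DELAY_START_S = GO_CUE_S - DELAY_DUR_S          # -1.3
SAMPLE_START_S = DELAY_START_S - SAMPLE_DUR_S   # -2.6
TRIAL_START_S = SAMPLE_START_S - BASELINE_DUR_S  # -3.1
TRIAL_END_S = GO_CUE_S + RESPONSE_DUR_S          # +1.5

#: (start, stop) windows, seconds relative to the go cue.
EPOCHS: dict[str, tuple[float, float]] = {
    "baseline": (TRIAL_START_S, SAMPLE_START_S),
    "sample": (SAMPLE_START_S, DELAY_START_S),
    "delay": (DELAY_START_S, GO_CUE_S),
    "response": (GO_CUE_S, TRIAL_END_S),
}

TRIAL_TYPES = ("lick-left", "lick-right")
OUTCOMES = ("correct", "error", "early-lick", "ignore")


def epoch_window(epoch: str) -> tuple[float, float]:
    """Return the (start, stop) window of a named epoch, go-cue-aligned."""
    try:
        return EPOCHS[epoch]
    except KeyError:
        raise ValueError(f"unknown epoch {epoch!r}; expected one of {sorted(EPOCHS)}")
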