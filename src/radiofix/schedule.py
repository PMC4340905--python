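"""Frequency-channel scan scheduling.

A station tracks many transmitters by tuning to their channels in a
round-robin: each channel is listened to for a dwell long enough to span
several pulse periods (5–20 s), then the receiver moves on.  With n
channels the revisit period is n·dwell; very long revisit periods are
flagged since they thin each animal's fix rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .types import PulseTemplate

__all__ = ["ChannelPlan", "schedule_scan", "MAX_REVISIT_S"]

#: revisit periods above this (s) are flagged as operationally thin
MAX_REVISIT_S = 600.0


@dataclass
class ChannelPlan:
    """Channels to scan, each with its expected pulse timing."""

    channels: Sequence[tuple[float, PulseTemplate]]
    dwell_s: float = 10.0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("channel plan must contain at least one channel")
        freqs = [c[0] for c in self.channels]
        if len(set(freqs)) != len(freqs):
            raise ValueError("channel frequencies must be unique")
        if not (5.0 <= self.dwell_s <= 20.0):
            raise ValueError("dwell_s must lie in [5, 20] seconds")
        for f, tpl in self.channels:
            if self.dwell_s < 3 * tpl.period_s:
                raise ValueError(
                    f"dwell {self.dwell_s}s spans fewer than 3 pulse periods "
                    f"on channel {f} kHz")

    @property
    def revisit_period_s(self) -> float:
        return len(self.channels) * self.dwell_s


def schedule_scan(plan: ChannelPlan, t_start_s: float, duration_s: float):
    """Round-robin channel windows covering [t_start, t_start+duration).

    Returns a list of ``(channel_khz, window_start_s, window_end_s)``;
    the final window is truncated at the end of the span.  Warns when the
    revisit period exceeds ``MAX_REVISIT_S``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if plan.revisit_period_s > MAX_REVISIT_S:
        warnings.warn(f"revisit period {plan.revisit_period_s:.0f}s exceeds "
                      f"{MAX_REVISIT_S:.0f}s; fix rate per channel will be low")
    windows = []
    t = t_start_s
    end = t_start_s + duration_s
    i = 0
    while t < end:
        ch = plan.channels[i % len(plan.channels)][0]
        w_end = min(t + plan.dwell_s, end)
        windows.append((ch, t, w_end))
        t = w_end
        i += 1
    return windows
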