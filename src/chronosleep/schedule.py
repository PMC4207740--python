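"""Light-dark schedule and zeitgeber-time (ZT) helpers.

ZT 0 is lights-on by convention; under the standard 12:12 LD cycle the
light phase L spans ZT 0-12 and the dark phase D spans ZT 12-24.  Recording
time is expressed in hours since ZT 0 of the first recorded day, so hour 30
is ZT 6 of day 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class LightSchedule:
    """A periodic light/dark schedule anchored at lights-on.

    Parameters
    ----------
    lights_on_zt
        ZT of lights-on, 0.0 by convention.
    light_hours, dark_hours
        Duration of the light and dark phase in hours (12 + 12 by default).
    """

    lights_on_zt: float = 0.0
    light_hours: float = 12.0
    dark_hours: float = 12.0

    def __post_init__(self) -> None:
        if self.light_hours < 0 or self.dark_hours < 0:
            raise ValueError("phase durations must be non-negative")
        if self.cycle_hours <= 0:
            raise ValueError("cycle must have positive duration")

    @property
    def cycle_hours(self) -> float:
        return self.light_hours + self.dark_hours

    def is_light(self, zt):
        """True where time-of-cycle falls in the light phase.

        Accepts scalars or arrays of hours (any number of elapsed days).
        """
        phase = np.asarray(zt, dtype=float) - self.lights_on_zt
        phase = np.mod(phase, self.cycle_hours)
        out = phase < self.light_hours
        return bool(out) if np.isscalar(zt) else out
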