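"""Unit conventions.

Half-lives are entered in days and scan schedules in hours (the units they
are quoted in clinically); every rate used internally is per second, so that
time-integrated activity comes out in MBq*s -- the unit voxel S-values
[Gy/(MBq*s)] expect.
"""

import math

HOUR_S = 3600.0
DAY_S = 86400.0
LN2 = math.log(2.0)


def hours_to_seconds(t_h):
    return t_h * HOUR_S


def days_to_seconds(t_d):
    return t_d * DAY_S


def rate_per_s_from_half_life_d(half_life_d):
    """Decay constant (1/s) of a half-life given in days; inf half-life -> 0."""
    if half_life_d == math.inf:
        return 0.0
    return LN2 / (half_life_d * DAY_S)
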