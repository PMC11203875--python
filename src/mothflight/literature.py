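"""Published flight-speed values used for cross-study comparison.

Free-flight speed of *Spodoptera litura* measured by the stereo
point-cloud method, against tethered flight-mill measurements from
earlier work.  These are inputs to ratio computations, not outputs of
this package.
"""

from __future__ import annotations

__all__ = [
    "FREE_FLIGHT_SPEED_MEAN_MPS",
    "FREE_FLIGHT_SPEED_SD_MPS",
    "FREE_FLIGHT_SPEED_MEDIAN_MPS",
    "FLIGHT_MILL_SPEED_TU2010_MPS",
    "FLIGHT_MILL_SPEED_NODA1988_MPS",
    "free_flight_to_flight_mill_ratio",
]

# stereo free-flight measurement (mean ± SD, median), 24 °C
FREE_FLIGHT_SPEED_MEAN_MPS = 1.81
FREE_FLIGHT_SPEED_SD_MPS = 0.68
FREE_FLIGHT_SPEED_MEDIAN_MPS = 1.75

# flight-mill means from earlier studies (tethered flight)
FLIGHT_MILL_SPEED_TU2010_MPS = 1.14    # unmated females, 3 d post-eclosion, 24 °C
FLIGHT_MILL_SPEED_NODA1988_MPS = 0.88  # non-laying females, 3 d post-eclosion


def free_flight_to_flight_mill_ratio(
    free_flight_mps: float = FREE_FLIGHT_SPEED_MEAN_MPS,
    flight_mill_mps: float = FLIGHT_MILL_SPEED_TU2010_MPS,
) -> float:
    """How much faster free flight is than the flight-mill measurement."""
    return free_flight_mps / flight_mill_mps
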