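"""Solar geometry: daylength and extraterrestrial radiation.

Standard FAO-56 formulas; everything is vectorized over day of year.
"""

from __future__ import annotations

import numpy as np

SOLAR_CONSTANT = 0.0820  # MJ m-2 min-1


def solar_declination(doy):
    """Solar declination (radians) for day of year 1-366."""
    return 0.409 * np.sin(2.0 * np.pi * np.asarray(doy) / 365.0 - 1.39)


def sunset_hour_angle(lat_deg, doy):
    """Sunset hour angle (radians); clipped for polar day/night."""
    phi = np.deg2rad(lat_deg)
    delta = solar_declination(doy)
    x = -np.tan(phi) * np.tan(delta)
    return np.arccos(np.clip(x, -1.0, 1.0))


def daylength_hours(lat_deg, doy):
    """Astronomical daylength in hours."""
    return 24.0 / np.pi * sunset_hour_angle(lat_deg, doy)


def extraterrestrial_radiation(lat_deg, doy):
    """Daily top-of-atmosphere shortwave radiation, MJ m-2 d-1."""
    phi = np.deg2rad(lat_deg)
    delta = solar_declination(doy)
    ws = sunset_hour_angle(lat_deg, doy)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * np.asarray(doy) / 365.0)
    ra = (24.0 * 60.0 / np.pi) * SOLAR_CONSTANT * dr * (
        ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws)
    )
    return np.maximum(ra, 0.0)
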