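"""Small unit conversions and sphere geometry helpers used across the package."""

from __future__ import annotations

import math

#: mm^3 per mL
MM3_PER_ML = 1000.0

#: MBq per mCi
MBQ_PER_MCI = 37.0

#: Conversion factor sigma = FWHM * FWHM_TO_SIGMA for a Gaussian profile.
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def sphere_volume_ml(diameter_mm: float) -> float:
    """Volume of a sphere of the given diameter, in mL."""
    r = diameter_mm / 2.0
    return 4.0 / 3.0 * math.pi * r**3 / MM3_PER_ML


def equivalent_diameter_mm(volume_ml: float) -> float:
    """Diameter of the sphere having the given volume (equivalent-sphere diameter)."""
    if volume_ml <= 0:
        raise ValueError(f"volume must be positive, got {volume_ml}")
    return 2.0 * (3.0 * volume_ml * MM3_PER_ML / (4.0 * math.pi)) ** (1.0 / 3.0)


def mbq_to_mci(activity_mbq: float) -> float:
    """Convert an activity from MBq to mCi."""
    return activity_mbq / MBQ_PER_MCI


def mci_to_mbq(activity_mci: float) -> float:
    """Convert an activity from mCi to MBq."""
    return activity_mci * MBQ_PER_MCI


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian sigma corresponding to a full-width-half-maximum."""
    return fwhm * FWHM_TO_SIGMA
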