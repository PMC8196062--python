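"""Circular statistics for compass-convention bearing samples.

All public angles are degrees clockwise from geographic north in [0, 360),
the convention of ship compasses, wind roses and orientation tables.
Internally angles are converted so that ``sin`` gives the east component and
``cos`` the north component; with that mapping ``atan2(sin, cos)`` returns the
compass bearing directly and no counterclockwise-from-east detour is exposed.

The module provides the mean bearing and mean resultant length of a sample,
the circular standard deviation ``sqrt(-2 ln r)``, the Rayleigh test of
uniformity (first order on positions, second order on per-individual mean
bearings), and element-wise re-referencing of bearings against per-sample
goal directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AngleSample",
    "CircularSummary",
    "circular_mean_and_r",
    "circular_sd",
    "rayleigh_p_from_nr",
    "rayleigh_test",
    "second_order_rayleigh",
    "relative_bearings",
]

#: below this resultant length the mean bearing is numerically meaningless
_R_UNDEFINED = 1e-12


def canonicalize_deg(angles) -> np.ndarray:
    """Map angles (degrees) onto [0, 360)."""
    a = np.asarray(angles, dtype=float) % 360.0
    # -1e-9 % 360 == 360.0 - 1e-9 which then rounds to 360.0; fold exactly
    a[a >= 360.0] = 0.0
    return a


@dataclass
class AngleSample:
    """A sample of compass bearings with free-text provenance.

    Parameters
    ----------
    angles_deg : array-like
        Bearings, degrees clockwise from north; canonicalized to [0, 360).
    label : str
        Provenance (deployment id, frame of reference, ...).
    """

    angles_deg: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.angles_deg = canonicalize_deg(self.angles_deg)
        if self.angles_deg.ndim != 1:
            raise ValueError("angles_deg must be one-dimensional")
        if self.angles_deg.size < 1:
            raise ValueError(f"empty angle sample ({self.label!r})")

    def __len__(self) -> int:
        return self.angles_deg.size


@dataclass
class CircularSummary:
    """First- or second-order summary of one circular sample.

    ``mean_bearing_deg`` is NaN when the resultant vanishes (r = 0), in which
    case ``circ_sd_rad`` is +inf: a perfectly balanced sample has no mean
    direction and infinite dispersion.
    """

    n: int
    mean_bearing_deg: float
    r: float
    circ_sd_rad: float
    rayleigh_Z: float
    p_value: float
    label: str = field(default="", compare=False)


def _mean_vector(angles_deg: np.ndarray) -> tuple[float, float]:
    rad = np.deg2rad(angles_deg)
    return float(np.mean(np.sin(rad))), float(np.mean(np.cos(rad)))


def circular_mean_and_r(sample: AngleSample) -> tuple[float, float]:
    """Mean bearing (deg CW from north) and mean resultant length r.

    The sample's unit vectors are averaged; the mean bearing is the direction
    of the resultant and r its norm, in [0, 1]. For r = 0 (e.g. an antipodal
    pair) the mean is undefined and returned as NaN.
    """
    e, n = _mean_vector(sample.angles_deg)
    r = math.hypot(e, n)
    if r < _R_UNDEFINED:
        return float("nan"), 0.0
    mean = math.degrees(math.atan2(e, n)) % 360.0
    return mean, min(r, 1.0)


def circular_sd(r: float) -> float:
    """Circular standard deviation sqrt(-2 ln r), radians.

    Monotone decreasing on (0, 1]; r = 0 maps to +inf (infinite dispersion),
    r outside [0, 1] is a caller error.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"mean resultant length must be in [0, 1], got {r}")
    if r == 0.0:
        return float("inf")
    return math.sqrt(-2.0 * math.log(r))


def rayleigh_p_from_nr(n: int, r: float) -> float:
    """Rayleigh-test p-value from sample size and mean resultant length.

    Uses Z = n r^2 and the standard fourth-order series approximation

        p = exp(-Z) [1 + (2Z - Z^2)/(4n) - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)]

    clamped to [0, 1]. Accurate to well under 0.01 for n >= 5.
    """
    if n < 2:
        raise ValueError("Rayleigh test needs n >= 2")
    z = n * r * r
    p = math.exp(-z) * (
        1.0
        + (2.0 * z - z * z) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n * n)
    )
    return min(1.0, max(0.0, p))


def rayleigh_test(sample: AngleSample) -> CircularSummary:
    """Rayleigh test of circular uniformity on a bearing sample.

    Rejection (small p) means the bearings cluster around a mean direction
    rather than spreading uniformly around the circle.
    """
    n = len(sample)
    if n < 2:
        raise ValueError("Rayleigh test needs n >= 2")
    mean, r = circular_mean_and_r(sample)
    return CircularSummary(
        n=n,
        mean_bearing_deg=mean,
        r=r,
        circ_sd_rad=circular_sd(r),
        rayleigh_Z=n * r * r,
        p_value=rayleigh_p_from_nr(n, r),
        label=sample.label,
    )


def second_order_rayleigh(mean_bearings: AngleSample) -> CircularSummary:
    """Population-level Rayleigh test on per-individual mean bearings.

    Each individual's mean bearing enters as an unweighted unit vector (its
    own concentration is ignored); the computation is then identical to the
    first-order test. Rejection indicates a common direction shared across
    individuals, not merely within-individual directionality.
    """
    return rayleigh_test(mean_bearings)


def relative_bearings(bearings: AngleSample, references_deg) -> AngleSample:
    """Re-express bearings relative to per-element reference directions.

    An individual heading exactly toward its reference maps to 0°, so a
    cue-following population shows up as clustering near 0° in the
    transformed sample.
    """
    refs = canonicalize_deg(references_deg)
    if refs.shape != bearings.angles_deg.shape:
        raise ValueError(
            f"length mismatch: {bearings.angles_deg.size} bearings vs {refs.size} references"
        )
    return AngleSample(
        angles_deg=(bearings.angles_deg - refs) % 360.0,
        label=f"{bearings.label} (relative)".strip(),
    )


def circular_mean_deg(angles_deg) -> float:
    """Plain circular mean of angles in degrees (helper for compass fusion)."""
    return circular_mean_and_r(AngleSample(np.atleast_1d(angles_deg)))[0]
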