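"""Parametric toy volume conductor for forward simulation and source localization.

The head is a unit sphere: sensors sit on the upper hemisphere, sources in an
inner ball. The lead field (gain) couples each source to each sensor through a
Gaussian decay of the sensor-source distance, so nearby sensors see a smooth,
spatially compact projection of every source -- the qualitative behaviour of a
real EEG lead field without any anatomical template. Columns are scaled to unit
maximum, so a unit-amplitude source produces a 1 uV peak on the scalp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HeadModel", "build_toy_headmodel"]


@dataclass(frozen=True)
class HeadModel:
    """Sensor/source geometry plus the lead-field matrix.

    Attributes
    ----------
    sensor_positions : ndarray, shape (n_channels, 3)
        Unit-sphere coordinates, upper hemisphere (z >= 0). Axes: x = right,
        y = anterior, z = superior.
    source_positions : ndarray, shape (n_sources, 3)
        Coordinates inside the inner ball (radius < 1).
    gain : ndarray, shape (n_channels, n_sources)
        Lead field in uV per unit source amplitude; column max is 1.
    """

    sensor_positions: np.ndarray
    source_positions: np.ndarray
    gain: np.ndarray
    spread: float = field(default=0.6)

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]

    def __post_init__(self) -> None:
        if self.gain.shape != (len(self.sensor_positions), len(self.source_positions)):
            raise ValueError("gain shape inconsistent with sensor/source counts")


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Quasi-uniform sensor layout on the upper unit hemisphere."""
    i = np.arange(n)
    golden = (1 + np.sqrt(5)) / 2
    # z from just above the rim to near the vertex; azimuth by golden angle
    z = (i + 0.5) / n
    r = np.sqrt(1 - z**2)
    theta = 2 * np.pi * i / golden
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def build_toy_headmodel(
    n_channels: int = 128,
    n_sources: int = 16,
    spread: float = 0.6,
    seed: int = 0,
    source_radius: float = 0.7,
) -> HeadModel:
    """Build the default spherical head model.

    Sensors are placed deterministically on a Fibonacci lattice over the upper
    hemisphere; sources are drawn (seeded) uniformly in the upper half of a
    ball of radius ``source_radius``. The gain entry for sensor i and source j
    is ``exp(-d_ij^2 / (2 spread^2))`` with d the Euclidean distance, scaled so
    each column has unit maximum.

    Parameters
    ----------
    spread : float
        Spatial scale of the Gaussian decay, in head-radius units. Smaller
        values give more focal scalp projections (better-conditioned gain).

    Raises
    ------
    ValueError
        If ``n_channels < 2``, ``n_sources < 1`` or ``spread <= 0``.
    """
    if n_channels < 2:
        raise ValueError(f"n_channels must be >= 2, got {n_channels}")
    if n_sources < 1:
        raise ValueError(f"n_sources must be >= 1, got {n_sources}")
    if spread <= 0:
        raise ValueError(f"spread must be positive, got {spread}")

    sensors = _fibonacci_hemisphere(n_channels)

    rng = np.random.default_rng(seed)
    sources = np.empty((n_sources, 3))
    k = 0
    while k < n_sources:  # rejection-sample the upper half ball
        p = rng.uniform(-1.0, 1.0, size=3) * source_radius
        if p @ p <= source_radius**2 and p[2] >= 0:
            sources[k] = p
            k += 1

    d2 = ((sensors[:, None, :] - sources[None, :, :]) ** 2).sum(-1)
    gain = np.exp(-d2 / (2 * spread**2))
    gain /= gain.max(axis=0, keepdims=True)
    return HeadModel(sensors, sources, gain, spread=spread)


def nearest_sources(head: HeadModel, anchor, k: int = 1) -> np.ndarray:
    """Indices of the ``k`` sources closest to an anchor point.

    Used to resolve anatomical labels ("fronto-central", "posterior") into
    concrete source indices of a given head model.
    """
    anchor = np.asarray(anchor, dtype=float)
    d2 = ((head.source_positions - anchor) ** 2).sum(1)
    return np.argsort(d2)[:k]
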