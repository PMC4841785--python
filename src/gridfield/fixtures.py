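"""Ideal rate-map generators for testing and for patterned initialisation.

Pure functions of their arguments: ``hexagonal`` is the sum of three plane
waves whose wavevectors are 60 degrees apart (the ideal grid-cell map),
``square`` the sum of two orthogonal plane waves, ``stripes`` a single
plane wave, ``noise`` smoothed Gaussian noise.  These serve as ground
truth for the gridness statistics and as shaped initial conditions for
stability experiments.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["make_fixture"]


def make_fixture(
    kind: str,
    wavelength: float,
    size: int = 128,
    angle: float = 0.0,
    seed: int = 0,
    phase: tuple[float, ...] | None = None,
) -> np.ndarray:
    """Ideal rate map of the requested lattice type.

    Parameters
    ----------
    kind
        ``hexagonal`` | ``square`` | ``stripes`` | ``noise``.
    wavelength
        Wavelength of each cosine component, in pixels; must exceed 2
        (the Nyquist limit of the raster).
    size
        Raster side in pixels.
    angle
        Rotation of the pattern, degrees.
    seed
        Used by ``noise`` only.
    phase
        Optional per-component phases (radians).

    Notes
    -----
    For the hexagonal fixture the centre-to-peak grid spacing is
    ``2 * wavelength / sqrt(3)``, not the wavelength itself.
    """
    if wavelength <= 2:
        raise ValueError("wavelength must exceed 2 pixels (aliasing)")
    yy, xx = np.indices((size, size)).astype(float)
    k = 2.0 * np.pi / wavelength
    a0 = np.radians(angle)

    def wave(theta, ph):
        return np.cos(k * (xx * np.cos(theta) + yy * np.sin(theta)) + ph)

    if kind == "hexagonal":
        ph = phase or (0.0, 0.0, 0.0)
        return sum(wave(a0 + i * np.pi / 3.0, ph[i]) for i in range(3))
    if kind == "square":
        ph = phase or (0.0, 0.0)
        return sum(wave(a0 + i * np.pi / 2.0, ph[i]) for i in range(2))
    if kind == "stripes":
        ph = phase or (0.0,)
        return wave(a0, ph[0])
    if kind == "noise":
        rng = np.random.default_rng(seed)
        return ndimage.gaussian_filter(rng.standard_normal((size, size)), wavelength / 4.0,
                                       mode="wrap")
    raise ValueError(f"unknown fixture kind {kind!r}")
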