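"""Circular (wrapped-Gaussian) peak model shared by the generator and the fitter.

The cortical crescent of a polarity reporter is modelled as a single unimodal
bump on the circle: a Gaussian in angle, wrapped onto [0, 2pi) and normalised
so the peak value at the centre is exactly 1.  Intensity around a cell is then

    I(theta) = b + A * g(theta; mu, sigma)

with baseline ``b`` (AU), amplitude ``A`` (AU, the "peak height"), centre
``mu`` (rad) and width ``sigma`` (rad).
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi

# +/- 4 wraps is ample: at sigma = 2*pi the next neglected term is < 1e-3
# relative and sigma is bounded above by 2*pi in the fitter.
_N_WRAPS = 4


def wrapped_gaussian(theta, mu: float, sigma: float):
    """Unnormalised wrapped Gaussian: sum of Gaussian images over 2*pi shifts."""
    theta = np.asarray(theta, dtype=float)
    d = theta - mu
    out = np.zeros_like(d)
    for k in range(-_N_WRAPS, _N_WRAPS + 1):
        out += np.exp(-0.5 * ((d + k * TWO_PI) / sigma) ** 2)
    return out


def peak_profile(theta, baseline: float, amplitude: float, mu: float, sigma: float):
    """Evaluate I(theta) = b + A * g(theta) with g normalised to 1 at mu."""
    g = wrapped_gaussian(theta, mu, sigma)
    return baseline + amplitude * g / wrapped_gaussian(mu, mu, sigma)


def fwhm(sigma: float) -> float:
    """Full width at half maximum of the *unwrapped* Gaussian bump, radians."""
    return 2.0 * sigma * np.sqrt(2.0 * np.log(2.0))


def half_max_angular_fraction(sigma: float) -> float:
    """Fraction of the circle where the wrapped bump is >= half its maximum.

    Solved numerically on the wrapped model; equals fwhm(sigma)/(2*pi) for
    narrow bumps and saturates at 1 when the bump never falls below half max.
    """
    theta = np.linspace(0.0, TWO_PI, 20001, endpoint=False)
    g = wrapped_gaussian(theta, 0.0, sigma)
    gmax = wrapped_gaussian(np.array([0.0]), 0.0, sigma)[0]
    return float(np.mean(g >= 0.5 * gmax))


def wrap_angle(theta):
    """Wrap angle(s) to [0, 2*pi)."""
    return np.mod(theta, TWO_PI)
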