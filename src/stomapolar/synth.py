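"""Ground-truthed synthetic data emulating cortical-polarity microscopy.

Three generators, all seed-deterministic:

* :func:`render_cell_image` — a two-channel image of a single cell: a
  membrane channel with a uniform cortical band, and a reporter channel
  whose band intensity is a constant baseline plus a wrapped-Gaussian
  crescent, with additive truncated-Gaussian noise.  A label mask and a
  ground-truth record (including the crescent's true periphery fraction)
  accompany the image.
* :func:`render_time_series` — a stack of such frames with the crescent
  amplitude following an exponential half-life decay and vanishing after a
  disappearance time, emulating post-division crescent dynamics.
* :func:`generate_lineage` — lineage-tracing records with true division
  labels, from the branching state machine in
  :mod:`stomapolar.simulator`.

:func:`synthesize_profile` additionally evaluates the peak model directly at
portion midpoints (no rasterisation), the right input for testing the BPI
statistic and peak-fit recovery at tight tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import simulator
from .lineage import LineageRecord
from .peakmodel import TWO_PI, peak_profile, wrap_angle, wrapped_gaussian
from .polarity import CorticalProfile

MEMBRANE_INTENSITY = 100.0  # AU, uniform band level of the membrane channel


class SizingError(ValueError):
    """Requested outline does not fit inside the image bounds."""


@dataclass
class SynthCellParams:
    """Geometry and signal parameters of one synthetic cell."""

    ellipse_axes: tuple[float, float] = (30.0, 22.0)  # semi-axes a, b in px
    jitter_amplitude: float = 0.0   # px, smooth polygonal perturbation of the radius
    band_width: float = 7.0         # px, rendered cortical band thickness
    #   (kept wider than the 3 px measurement band so band means sample the
    #   band interior, not its anti-aliased edges)
    baseline_intensity: float = 20.0   # AU
    crescent_amplitude: float = 80.0   # AU, peak height above baseline
    crescent_center: float = np.pi / 2  # rad
    crescent_width_sigma: float = 0.35  # rad
    noise_sd: float = 4.0           # AU, additive Gaussian, truncated at 0
    image_size: tuple[int, int] = (160, 160)  # (H, W) px
    seed: int = 0
    cell_id: int = 1

    def __post_init__(self):
        if self.baseline_intensity < 0 or self.crescent_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("intensities and noise_sd must be >= 0")
        if self.crescent_amplitude > 0 and self.crescent_width_sigma <= 0:
            raise ValueError("crescent_width_sigma must be > 0 when the crescent is present")
        self.crescent_center = float(wrap_angle(self.crescent_center))


@dataclass
class SynthTimeSeriesParams:
    """Post-division crescent decay sampled at a fixed frame cadence."""

    frame_interval: float = 40.0    # minutes between frames
    n_frames: int = 13
    initial_amplitude: float = 80.0  # AU at cytokinesis (frame 0)
    half_life: float = 160.0        # minutes; np.inf = no decay
    disappearance_time: float = 480.0  # minutes; true amplitude 0 at/after this
    seed: int = 0

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def true_amplitudes(self) -> np.ndarray:
        t = self.frame_times()
        amp = self.initial_amplitude * np.exp2(-t / self.half_life)
        amp[t >= self.disappearance_time] = 0.0
        return amp


@dataclass
class SynthLineageParams:
    """Branching-model parameters for synthetic lineage-tracing records."""

    n_founders: int = 100
    p_entry: float = 1.0
    p_amp: float = 0.5
    p_spacing: float = 0.0
    max_steps: int = 5
    seed: int = 0


# ---------------------------------------------------------------------------
# outline geometry

def _radius_profile(params: SynthCellParams, n: int = 2048) -> tuple[np.ndarray, np.ndarray]:
    """Boundary radius R(phi) about the cell centre: ellipse + smooth jitter."""
    a, b = params.ellipse_axes
    phi = np.linspace(0.0, TWO_PI, n, endpoint=False)
    r = a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
    if params.jitter_amplitude > 0:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 7]))
        jitter = np.zeros(n)
        for m in range(2, 6):
            jitter += rng.normal() * np.cos(m * phi) + rng.normal() * np.sin(m * phi)
        peak = np.abs(jitter).max()
        if peak > 0:
            jitter *= params.jitter_amplitude / peak
        r = r + jitter
    return phi, r


def _interp_radius(phi_query: np.ndarray, phi: np.ndarray, r: np.ndarray) -> np.ndarray:
    idx = phi_query / (TWO_PI / len(phi))
    i0 = np.floor(idx).astype(int) % len(phi)
    frac = idx - np.floor(idx)
    return r[i0] * (1 - frac) + r[(i0 + 1) % len(phi)] * frac


def true_half_max_fraction(params: SynthCellParams, n: int = 20000) -> float:
    """Fraction of the boundary *arc* where the noise-free crescent bump is at
    or above half its own maximum — the generator-side "crescent size"."""
    if params.crescent_amplitude <= 0:
        return 0.0
    phi, r = _radius_profile(params)
    phis = np.linspace(0.0, TWO_PI, n, endpoint=False)
    rr = _interp_radius(phis, phi, r)
    x, y = rr * np.cos(phis), rr * np.sin(phis)
    seg = np.hypot(np.diff(x, append=x[0]), np.diff(y, append=y[0]))
    g = wrapped_gaussian(phis, params.crescent_center, params.crescent_width_sigma)
    gmax = wrapped_gaussian(np.array([params.crescent_center]),
                            params.crescent_center, params.crescent_width_sigma)[0]
    above = g >= 0.5 * gmax
    return float(seg[above].sum() / seg.sum())


# ---------------------------------------------------------------------------
# rendering

def render_cell_image(params: SynthCellParams, supersample: int = 4):
    """Render one synthetic cell.

    Returns ``(image, mask, truth)``: a float (2, H, W) image with the
    reporter in channel 0 and the membrane in channel 1, a uint16 label mask
    of the cell interior, and a ground-truth dict of all generator
    parameters plus the crescent's true periphery fraction.  Identical
    params and seed render bit-identical arrays.
    """
    h, w = params.image_size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    phi_tab, r_tab = _radius_profile(params)
    margin = min(cx, cy, (w - 1) - cx, (h - 1) - cy)
    if r_tab.max() + params.band_width / 2.0 + 2.0 > margin:
        raise SizingError(
            f"outline radius {r_tab.max():.1f}px + band does not fit in {params.image_size}")

    s = supersample
    sub = (np.arange(s) + 0.5) / s - 0.5
    ys = (np.arange(h)[:, None] + sub[None, :]).ravel()   # h*s supersampled rows
    xs = (np.arange(w)[:, None] + sub[None, :]).ravel()
    dy = ys[:, None] - cy
    dx = xs[None, :] - cx
    phi = wrap_angle(np.arctan2(dy, dx))
    rad = np.hypot(dy, dx)
    r_bound = _interp_radius(phi.ravel(), phi_tab, r_tab).reshape(phi.shape)
    in_band = np.abs(rad - r_bound) <= params.band_width / 2.0

    reporter_level = peak_profile(
        phi, params.baseline_intensity, params.crescent_amplitude,
        params.crescent_center, params.crescent_width_sigma,
    ) if params.crescent_amplitude > 0 else np.full_like(phi, params.baseline_intensity)

    def downsample(fine: np.ndarray) -> np.ndarray:
        return fine.reshape(h, s, w, s).mean(axis=(1, 3))

    reporter = downsample(np.where(in_band, reporter_level, 0.0))
    membrane = downsample(np.where(in_band, MEMBRANE_INTENSITY, 0.0))

    if params.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 11]))
        reporter = np.clip(reporter + rng.normal(0.0, params.noise_sd, (h, w)), 0.0, None)

    # interior mask at pixel centres (inside the band's inner edge counts too)
    phi_c = wrap_angle(np.arctan2(np.arange(h)[:, None] - cy, np.arange(w)[None, :] - cx))
    rad_c = np.hypot(np.arange(h)[:, None] - cy, np.arange(w)[None, :] - cx)
    rb_c = _interp_radius(phi_c.ravel(), phi_tab, r_tab).reshape(phi_c.shape)
    mask = np.where(rad_c <= rb_c, params.cell_id, 0).astype(np.uint16)

    truth = {
        "cell_id": params.cell_id,
        "ellipse_axes": list(params.ellipse_axes),
        "jitter_amplitude": params.jitter_amplitude,
        "band_width": params.band_width,
        "baseline_intensity": params.baseline_intensity,
        "crescent_amplitude": params.crescent_amplitude,
        "crescent_center": params.crescent_center,
        "crescent_width_sigma": params.crescent_width_sigma,
        "noise_sd": params.noise_sd,
        "image_size": list(params.image_size),
        "seed": params.seed,
        "centroid": [cx, cy],
        "true_periphery_fraction": true_half_max_fraction(params),
    }
    image = np.stack([reporter, membrane])
    return image, mask, truth


def render_time_series(ts: SynthTimeSeriesParams, cell: SynthCellParams):
    """Render a (n_frames, 2, H, W) stack with decaying crescent amplitude.

    Ground truth records frame times, per-frame true amplitudes and the
    first frame index at which the true amplitude is zero (None if the
    crescent outlives the series).
    """
    amps = ts.true_amplitudes()
    frames = []
    mask = None
    for i, amp in enumerate(amps):
        # geometry keeps the cell's own seed; only the noise stream is per-frame
        frame_params = _replace_cell(cell, crescent_amplitude=float(amp), noise_sd=0.0)
        img, mask, _ = render_cell_image(frame_params)
        if cell.noise_sd > 0:
            rng = np.random.default_rng(
                np.random.SeedSequence([int(ts.seed), int(cell.seed), i, 11]))
            img[0] = np.clip(img[0] + rng.normal(0.0, cell.noise_sd, img[0].shape), 0.0, None)
        frames.append(img)
    zero = np.flatnonzero(amps == 0.0)
    truth = {
        "frame_times": ts.frame_times().tolist(),
        "true_amplitudes": amps.tolist(),
        "disappearance_frame": int(zero[0]) if zero.size else None,
        "half_life": ts.half_life,
        "disappearance_time": ts.disappearance_time,
    }
    return np.stack(frames), mask, truth


def _child_seed(*parts: int) -> int:
    return int(np.random.SeedSequence([int(p) for p in parts]).generate_state(1)[0] % (2 ** 31))


def _replace_cell(cell: SynthCellParams, **kw) -> SynthCellParams:
    from dataclasses import replace

    return replace(cell, **kw)


# ---------------------------------------------------------------------------
# model-space profiles (no rasterisation)

def synthesize_profile(
    baseline: float = 20.0,
    amplitude: float = 80.0,
    mu: float = np.pi / 2,
    sigma: float = 0.35,
    noise_sd: float = 0.0,
    n_portions: int = 63,
    rng=None,
    cell_id: int = 0,
    timepoint: int = 0,
) -> CorticalProfile:
    """Evaluate the peak model directly at the portion midpoints of a circle.

    Noise is additive Gaussian truncated at zero, drawn from ``rng`` (or a
    fresh default generator).  This is the exact measurement model the
    fitter assumes, so parameter recovery can be checked at tight tolerance.
    """
    theta = (np.arange(n_portions) + 0.5) * TWO_PI / n_portions
    if amplitude > 0:
        values = peak_profile(theta, baseline, amplitude, mu, sigma)
    else:
        values = np.full(n_portions, float(baseline))
    if noise_sd > 0:
        rng = np.random.default_rng() if rng is None else rng
        values = np.clip(values + rng.normal(0.0, noise_sd, n_portions), 0.0, None)
    return CorticalProfile(
        cell_id=cell_id,
        timepoint=timepoint,
        angles=theta,
        arc_fractions=(np.arange(n_portions) + 0.5) / n_portions,
        reporter=values,
        membrane=np.full(n_portions, MEMBRANE_INTENSITY),
    )


def synthesize_decay_profiles(
    ts: SynthTimeSeriesParams,
    baseline: float = 20.0,
    mu: float = np.pi / 2,
    sigma: float = 0.35,
    noise_sd: float = 0.0,
    n_portions: int = 63,
    cell_id: int = 0,
) -> tuple[np.ndarray, list[CorticalProfile], dict]:
    """Per-frame model-space profiles under the amplitude decay law."""
    rng = np.random.default_rng(np.random.SeedSequence([int(ts.seed), 13]))
    amps = ts.true_amplitudes()
    profiles = [
        synthesize_profile(baseline, float(a), mu, sigma, noise_sd, n_portions,
                           rng=rng, cell_id=cell_id, timepoint=i)
        for i, a in enumerate(amps)
    ]
    zero = np.flatnonzero(amps == 0.0)
    truth = {
        "true_amplitudes": amps,
        "disappearance_frame": int(zero[0]) if zero.size else None,
    }
    return ts.frame_times(), profiles, truth


# ---------------------------------------------------------------------------
# lineages

def generate_lineage(params: SynthLineageParams) -> LineageRecord:
    """Synthetic lineage-tracing record with true division-type labels.

    Thin wrapper over the branching engine in :mod:`stomapolar.simulator`
    (``max_steps`` maps to the simulator's per-line round cap).
    """
    _, record = simulator.simulate(simulator.SimParams(
        n_founders=params.n_founders,
        p_entry=params.p_entry,
        p_amp=params.p_amp,
        p_spacing=params.p_spacing,
        max_rounds=params.max_steps,
        seed=params.seed,
    ), record=True)
    return record
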