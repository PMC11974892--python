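"""Synthetic two-channel movies, FRAP curves, flow kymographs and shapes.

Every downstream stage of the pipeline is validated against data produced
here, with exhaustively known ground truth: a spreading cell whose leading
edge fluctuates as a sum of traveling sine waves, a lamellipodial network
band whose probe-channel brightness is a tunable fraction ``rho`` of the
reference-channel network signal on top of a diffuse monomer background,
mono-exponential photobleaching, Poisson shot noise plus Gaussian read
noise, retrograde speckle drift, and single-exponential FRAP recovery with
a set immobile fraction.

The generator deliberately stays at the level of image phenomenology: it
does not simulate monomer diffusion or Arp2/3 branching kinetics.  All
randomness is driven by an explicit seed; the same configuration and seed
produce bit-identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "SimConfig",
    "SimGroundTruth",
    "edge_height",
    "simulate_cell_movie",
    "simulate_frap_series",
    "simulate_flow_kymograph",
    "simulate_shapes",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Parameters of the synthetic spreading-cell movie.

    Geometry: the cell occupies rows ``y >= h(x, t)`` where the edge height
    ``h(x, t) = edge_offset_px + sum_k A_k sin(2*pi*(x/lambda_k - t/T_k) + phi_k)``
    is a sum of traveling sinusoids.  The lamellipodial network appears as a
    band of brightness decaying exponentially with depth from the edge with
    length scale ``network_decay_depth_um``.

    Intensities (before bleaching and noise)::

        reference = monomer_background_ref   + network_amplitude * exp(-depth/delta)
        probe     = monomer_background_probe + rho * network_amplitude * exp(-depth/delta)

    Both channels are multiplied by ``exp(-bleach_rate * t)`` per channel,
    Poisson shot noise is applied at ``poisson_scale`` (expected counts per
    intensity unit; 0 disables), then Gaussian read noise of standard
    deviation ``read_noise_sd`` and a constant camera offset are added.
    """

    image_width_px: int = 96
    image_height_px: int = 224
    pixel_size_um: float = 0.1
    frame_interval_s: float = 1.0
    n_frames: int = 100
    rho: float = 1.0
    monomer_background_ref: float = 100.0
    monomer_background_probe: float = 100.0
    network_amplitude: float = 200.0
    network_decay_depth_um: float = 1.0
    edge_offset_px: float = 24.0
    edge_wave_amplitudes_px: tuple = (3.0, 2.0)
    edge_wave_periods_s: tuple = (23.0, 41.0)
    edge_wave_lengths_px: tuple = (48.0, 29.0)
    edge_wave_phases: tuple = (0.0, 1.3)
    bleach_rate_ref_per_s: float = 0.002
    bleach_rate_probe_per_s: float = 0.002
    flow_speed_um_s: float = 0.10
    poisson_scale: float = 1.0
    read_noise_sd: float = 2.0
    camera_offset: float = 0.0
    mobile_fraction: float = 0.6
    recovery_tau_s: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError(f"rho must lie in [0, 1], got {self.rho}")
        if not (0.0 <= self.mobile_fraction <= 1.0):
            raise ValueError(
                f"mobile_fraction must lie in [0, 1], got {self.mobile_fraction}"
            )
        for name in ("image_width_px", "image_height_px", "n_frames"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        for name in (
            "pixel_size_um",
            "frame_interval_s",
            "network_decay_depth_um",
            "recovery_tau_s",
        ):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive and finite")
        for name in (
            "monomer_background_ref",
            "monomer_background_probe",
            "network_amplitude",
            "bleach_rate_ref_per_s",
            "bleach_rate_probe_per_s",
            "poisson_scale",
            "read_noise_sd",
            "camera_offset",
            "flow_speed_um_s",
        ):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be non-negative and finite")
        n_waves = len(self.edge_wave_amplitudes_px)
        if not (
            len(self.edge_wave_periods_s) == n_waves
            and len(self.edge_wave_lengths_px) == n_waves
        ):
            raise ValueError("edge wave amplitude/period/length lists must match")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


@dataclass
class SimGroundTruth:
    """Everything the generator knew: the answer key for recovery tests."""

    rho: float
    edge_height_px: np.ndarray  # (T, W) true edge row per column per frame
    bleach_factors: np.ndarray  # (T, 2) multiplicative decay, ref then probe
    flow_speed_um_s: float
    mobile_fraction: float
    masks: np.ndarray  # (T, Y, X) boolean true cell masks
    config: SimConfig | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Movie generation
# ---------------------------------------------------------------------------

def edge_height(config: SimConfig, x: np.ndarray, t_s: float) -> np.ndarray:
    """True edge row h(x, t) in pixels for columns ``x`` at time ``t_s``."""
    h = np.full_like(np.asarray(x, dtype=float), config.edge_offset_px)
    phases = config.edge_wave_phases or (0.0,) * len(config.edge_wave_amplitudes_px)
    for amp, period, lam, phi in zip(
        config.edge_wave_amplitudes_px,
        config.edge_wave_periods_s,
        config.edge_wave_lengths_px,
        phases,
    ):
        h = h + amp * np.sin(2.0 * np.pi * (x / lam - t_s / period) + phi)
    return h


def _noisify(frame: np.ndarray, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    out = frame
    if config.poisson_scale > 0:
        out = rng.poisson(out * config.poisson_scale) / config.poisson_scale
    out = out + config.camera_offset
    if config.read_noise_sd > 0:
        out = out + rng.normal(0.0, config.read_noise_sd, size=out.shape)
    return np.maximum(out, 0.0)


def simulate_cell_movie(config: SimConfig):
    """Render a two-channel (reference, probe) movie of a fluctuating edge.

    Returns
    -------
    movie : MovieStack
        T x 2 x Y x X stack; channel 0 is the actin reference, channel 1 the
        probe.
    truth : SimGroundTruth
    """
    from .stackio import MovieStack  # local import to avoid cycle at import time

    rng = np.random.default_rng(config.rng_seed)
    W, H, T = config.image_width_px, config.image_height_px, config.n_frames
    delta_px = config.network_decay_depth_um / config.pixel_size_um

    x = np.arange(W, dtype=float)
    rows = np.arange(H, dtype=float)[:, None]  # (H, 1)

    data = np.empty((T, 2, H, W), dtype=float)
    edges = np.empty((T, W), dtype=float)
    masks = np.empty((T, H, W), dtype=bool)
    bleach = np.empty((T, 2), dtype=float)

    for t in range(T):
        t_s = t * config.frame_interval_s
        h = edge_height(config, x, t_s)  # (W,)
        edges[t] = h
        depth_px = rows - h[None, :]  # >=0 inside the cell
        inside = depth_px >= 0.0
        masks[t] = inside
        band = np.where(inside, np.exp(-np.maximum(depth_px, 0.0) / delta_px), 0.0)

        b_ref = np.exp(-config.bleach_rate_ref_per_s * t_s)
        b_probe = np.exp(-config.bleach_rate_probe_per_s * t_s)
        bleach[t] = (b_ref, b_probe)

        ref = np.where(
            inside, config.monomer_background_ref + config.network_amplitude * band, 0.0
        )
        probe = np.where(
            inside,
            config.monomer_background_probe
            + config.rho * config.network_amplitude * band,
            0.0,
        )
        data[t, 0] = _noisify(ref * b_ref, config, rng)
        data[t, 1] = _noisify(probe * b_probe, config, rng)

    movie = MovieStack(
        intensities=data,
        pixel_size_um=config.pixel_size_um,
        frame_interval_s=config.frame_interval_s,
        channel_names=("reference", "probe"),
    )
    truth = SimGroundTruth(
        rho=config.rho,
        edge_height_px=edges,
        bleach_factors=bleach,
        flow_speed_um_s=config.flow_speed_um_s,
        mobile_fraction=config.mobile_fraction,
        masks=masks,
        config=config,
    )
    return movie, truth


# ---------------------------------------------------------------------------
# FRAP curve generation
# ---------------------------------------------------------------------------

def simulate_frap_series(
    config: SimConfig,
    f_pre: float = 100.0,
    bleach_depth: float = 0.8,
    n_pre: int = 5,
    n_post: int = 60,
    noise_sd: float = 0.0,
):
    """Generate a photobleaching recovery time series.

    The post-bleach signal follows
    ``F(t) = F0 + M (F_pre - F0) (1 - exp(-t / tau))`` where ``M`` is the
    mobile fraction and ``tau`` the recovery time constant, optionally with
    additive Gaussian noise.

    Returns ``(times, intensities, n_pre, truth_dict)``; the bleach event
    happens between sample ``n_pre - 1`` and sample ``n_pre``.
    """
    if config.recovery_tau_s <= 0:
        raise ValueError("recovery_tau_s must be positive")
    rng = np.random.default_rng(config.rng_seed)
    dt = config.frame_interval_s
    M = config.mobile_fraction
    f0 = f_pre * (1.0 - bleach_depth)

    times = np.arange(n_pre + n_post, dtype=float) * dt
    t_post = times[n_pre:] - times[n_pre]
    series = np.empty_like(times)
    series[:n_pre] = f_pre
    series[n_pre:] = f0 + M * (f_pre - f0) * (1.0 - np.exp(-t_post / config.recovery_tau_s))
    if noise_sd > 0:
        series = series + rng.normal(0.0, noise_sd, size=series.shape)
    truth = {
        "mobile_fraction": M,
        "tau_s": config.recovery_tau_s,
        "f_pre": f_pre,
        "f0": f0,
    }
    return times, series, n_pre, truth


# ---------------------------------------------------------------------------
# Retrograde-flow kymograph generation
# ---------------------------------------------------------------------------

def simulate_flow_kymograph(
    config: SimConfig,
    n_space_px: int = 100,
    speckle_density_per_px: float = 0.08,
    speckle_amplitude: float = 120.0,
    speckle_sigma_px: float = 1.0,
    background: float = 20.0,
):
    """Render a space-time kymograph of fiduciary speckles drifting with flow.

    The spatial axis is rows, time is columns.  Each speckle is a Gaussian
    streak of slope ``flow_speed * frame_interval / pixel_size`` px/frame.
    Speckles are seeded upstream of the field of view so density stays
    stationary as markers flow through.

    Returns ``(kymograph, truth)`` where ``truth`` is a SimGroundTruth with
    empty image fields.
    """
    rng = np.random.default_rng(config.rng_seed)
    T = config.n_frames
    v_px = config.flow_speed_um_s * config.frame_interval_s / config.pixel_size_um

    span = v_px * T
    lo = -span - 6 * speckle_sigma_px if v_px >= 0 else -6 * speckle_sigma_px
    hi = n_space_px + 6 * speckle_sigma_px
    n_speckles = max(1, int(round(speckle_density_per_px * (hi - lo))))
    s0 = rng.uniform(lo, hi, size=n_speckles)
    amps = speckle_amplitude * rng.uniform(0.5, 1.5, size=n_speckles)

    s = np.arange(n_space_px, dtype=float)[:, None, None]  # (S, 1, 1)
    t = np.arange(T, dtype=float)[None, :, None]  # (1, T, 1)
    centers = s0[None, None, :] + v_px * t  # (1, T, N)
    kymo = background + np.sum(
        amps[None, None, :] * np.exp(-0.5 * ((s - centers) / speckle_sigma_px) ** 2),
        axis=2,
    )
    if config.poisson_scale > 0:
        kymo = rng.poisson(kymo * config.poisson_scale) / config.poisson_scale
    if config.read_noise_sd > 0:
        kymo = kymo + rng.normal(0.0, config.read_noise_sd, size=kymo.shape)
    kymo = np.maximum(kymo, 0.0)

    truth = SimGroundTruth(
        rho=config.rho,
        edge_height_px=np.empty((0, 0)),
        bleach_factors=np.empty((0, 2)),
        flow_speed_um_s=config.flow_speed_um_s,
        mobile_fraction=config.mobile_fraction,
        masks=np.empty((0, 0, 0), dtype=bool),
        config=config,
    )
    return kymo, truth


# ---------------------------------------------------------------------------
# Shape generation for morphometrics
# ---------------------------------------------------------------------------

def simulate_shapes(kind: str, **params) -> np.ndarray:
    """Rasterize a deterministic binary test shape.

    Parameters
    ----------
    kind : {"disk", "square", "star"}
    params : radius (disk, px), side (square, px), or for "star":
        outer_radius, inner_radius, n_points.
    """
    if kind == "disk":
        r = float(params.get("radius", 50))
        size = int(np.ceil(2 * r)) + 5
        c = size / 2.0
        yy, xx = np.mgrid[0:size, 0:size]
        return (yy - c) ** 2 + (xx - c) ** 2 <= r**2
    if kind == "square":
        side = int(params.get("side", 80))
        size = side + 10
        mask = np.zeros((size, size), dtype=bool)
        mask[5 : 5 + side, 5 : 5 + side] = True
        return mask
    if kind == "star":
        from skimage.draw import polygon

        r_out = float(params.get("outer_radius", 60))
        r_in = float(params.get("inner_radius", 25))
        n = int(params.get("n_points", 5))
        size = int(np.ceil(2 * r_out)) + 5
        c = size / 2.0
        angles = np.arange(2 * n) * np.pi / n - np.pi / 2
        radii = np.where(np.arange(2 * n) % 2 == 0, r_out, r_in)
        rr, cc = polygon(c + radii * np.sin(angles), c + radii * np.cos(angles), (size, size))
        mask = np.zeros((size, size), dtype=bool)
        mask[rr, cc] = True
        return mask
    raise ValueError(f"unknown shape kind: {kind!r}")
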