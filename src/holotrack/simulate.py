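"""Synthetic inline holograms of swimming point-like scatterers.

The generator stands in for recorded video: bacteria-like cells perform
run-and-tumble swimming with Brownian jitter inside a chamber, and each
frame is rendered as the inline hologram of weak (Rayleigh-Gans) point
scatterers.  Because the exact 3D positions are known, every downstream
stage — reconstruction, calibration, detection, depth mapping, tracking,
evaluation — can be tested as a round trip.

A scatterer's field at the camera is synthesized by placing a discrete
delta of amplitude ε on its axial plane and propagating it to the focal
plane with the same angular-spectrum kernel used for reconstruction, so
simulator and reconstructor share one optical model by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.fft as _fft

from .config import OpticalConfig
from .reconstruct import Localization3D, angular_spectrum_phase
from .track import Track

__all__ = [
    "Scatterer",
    "SceneFrame",
    "MotionParams",
    "simulate_scene",
    "render_hologram",
    "render_point_contrast",
]

#: default weak-scattering amplitude; must stay well inside the
#: single-scattering regime (contract: ε ≤ 0.2)
DEFAULT_AMPLITUDE = 0.15


@dataclass(frozen=True)
class Scatterer:
    """A point-like weak scatterer: lateral position, unsigned depth, ε."""

    x: float
    y: float
    z: float
    amplitude: float = DEFAULT_AMPLITUDE

    def __post_init__(self) -> None:
        if self.z < 0:
            raise ValueError("z is an unsigned distance from the focal plane")
        if not 0 < self.amplitude <= 0.2:
            raise ValueError("amplitude must lie in (0, 0.2] (single scattering)")


@dataclass
class SceneFrame:
    """All scatterers present in one video frame."""

    frame_index: int
    scatterers: list[Scatterer] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")


@dataclass(frozen=True)
class MotionParams:
    """Run-and-tumble motion model parameters.

    Defaults are typical literature values for swimming *E. coli*:
    runs at ~20 μm/s interrupted by ~1 s⁻¹ tumbles that redraw the
    heading uniformly on the sphere, plus translational diffusion
    D ≈ 0.4 μm²/s.
    """

    speed: float = 20.0
    tumble_rate: float = 1.0
    diffusion_coeff: float = 0.4
    n_cells: int = 40
    n_frames: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed < 0 or self.tumble_rate < 0 or self.diffusion_coeff < 0:
            raise ValueError("rates and coefficients must be non-negative")
        if self.n_cells < 0 or self.n_frames < 0:
            raise ValueError("n_cells and n_frames must be non-negative")


def _random_headings(rng: np.random.Generator, n: int) -> np.ndarray:
    """n unit vectors uniform on the sphere."""
    v = rng.normal(size=(n, 3))
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    # a draw of exactly zero norm has probability zero; guard anyway
    norm[norm == 0] = 1.0
    return v / norm


def _reflect(pos: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fold positions back into [lo, hi] and report which axes reflected."""
    span = hi - lo
    p = np.mod(pos - lo, 2.0 * span)
    over = p > span
    p[over] = 2.0 * span[np.newaxis, :].repeat(len(p), 0)[over] - p[over]
    return p + lo, over


def simulate_scene(
    params: MotionParams,
    optics: OpticalConfig,
    amplitude: float = DEFAULT_AMPLITUDE,
) -> tuple[list[SceneFrame], list[Track]]:
    """Simulate run-and-tumble swimmers and return frames plus ground truth.

    Each cell moves at constant ``speed`` along its heading between
    tumble events (exponential waiting times, rate ``tumble_rate``) that
    redraw the heading uniformly on the sphere; an isotropic Brownian
    displacement with per-axis variance ``2·D·Δt`` is added every step.
    Boundaries are reflecting both laterally (cells stay in view) and
    axially at z ∈ {0, chamber_depth}.

    Returns one :class:`SceneFrame` per frame and the matching
    ground-truth :class:`~holotrack.track.Track` list (source tag
    ``"ground_truth"``).
    """
    rng = np.random.default_rng(params.seed)
    n, f = params.n_cells, params.n_frames
    if n == 0 or f == 0:
        return [], []

    fov_x, fov_y = optics.fov
    lo = np.array([0.0, 0.0, 0.0])
    hi = np.array([fov_x, fov_y, optics.chamber_depth])
    pos = rng.uniform(lo, hi, size=(n, 3))
    heading = _random_headings(rng, n)
    dt = optics.dt
    sigma = np.sqrt(2.0 * params.diffusion_coeff * dt)
    p_tumble = 1.0 - np.exp(-params.tumble_rate * dt)

    positions = np.empty((f, n, 3))
    for t in range(f):
        positions[t] = pos
        if t + 1 == f:
            break
        tumbled = rng.uniform(size=n) < p_tumble
        if tumbled.any():
            heading[tumbled] = _random_headings(rng, int(tumbled.sum()))
        step = params.speed * dt * heading
        if sigma > 0:
            step = step + rng.normal(scale=sigma, size=(n, 3))
        pos, reflected = _reflect(pos + step, lo, hi)
        heading[reflected] *= -1.0

    frames = [
        SceneFrame(
            frame_index=t,
            scatterers=[
                Scatterer(x=positions[t, j, 0], y=positions[t, j, 1],
                          z=positions[t, j, 2], amplitude=amplitude)
                for j in range(n)
            ],
        )
        for t in range(f)
    ]
    tracks = [
        Track(
            track_id=j,
            points=[
                Localization3D(
                    x=positions[t, j, 0], y=positions[t, j, 1], z=positions[t, j, 2],
                    frame_index=t, source="ground_truth",
                )
                for t in range(f)
            ],
        )
        for j in range(n)
    ]
    return frames, tracks


def _scene_spectrum(
    scatterers: list[Scatterer],
    optics: OpticalConfig,
    numerical_aperture: float | None,
) -> np.ndarray:
    """Accumulated camera-plane spectrum of all scatterer fields."""
    ny, nx = optics.shape
    fx = _fft.fftfreq(nx, d=optics.pixel_pitch)
    fy = _fft.fftfreq(ny, d=optics.pixel_pitch)
    phase, propagating = angular_spectrum_phase(
        optics.shape, optics.pixel_pitch, optics.wavelength_eff
    )
    na = optics.numerical_aperture if numerical_aperture is None else numerical_aperture
    f_cut = na / optics.wavelength_vacuum
    mask = propagating & (
        (fx[np.newaxis, :] ** 2 + fy[:, np.newaxis] ** 2) <= f_cut**2
    )

    spectrum = np.zeros(optics.shape, dtype=complex)
    for s in scatterers:
        shift = np.exp(-2j * np.pi * fy * s.y)[:, np.newaxis] * np.exp(
            -2j * np.pi * fx * s.x
        )[np.newaxis, :]
        spectrum += s.amplitude * shift * np.exp(1j * s.z * phase)
    spectrum[~mask] = 0.0
    return spectrum


def render_hologram(
    scene: SceneFrame,
    optics: OpticalConfig,
    noise_sd: float = 0.0,
    artifact_pattern: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
    numerical_aperture: float | None = None,
    margin_frac: float = 0.25,
) -> np.ndarray:
    """Render the camera-plane intensity I = |1 + Σ_j ψ_j|².

    Each ψ_j is a discrete delta of amplitude ε_j placed at the
    scatterer's subpixel position on its plane at depth z_j and
    propagated to the focal plane with the angular-spectrum kernel.
    An optional static multiplicative ``artifact_pattern`` (dust,
    diffraction from optics) and additive zero-mean Gaussian sensor
    noise of standard deviation ``noise_sd`` follow; the result is
    clipped at 0.

    The scattered field is band-limited by the objective pupil
    (``optics.numerical_aperture`` unless overridden here): it is the
    finite aperture that makes the apparent extent of a scattering
    pattern grow linearly with depth.  Pass ``numerical_aperture =
    optics.medium_index`` for an aperture-free (evanescent-cutoff-only)
    rendering.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    fov_x, fov_y = optics.fov
    for s in scene.scatterers:
        if not (-margin_frac * fov_x <= s.x <= (1 + margin_frac) * fov_x
                and -margin_frac * fov_y <= s.y <= (1 + margin_frac) * fov_y):
            warnings.warn(
                f"scatterer at ({s.x:.1f}, {s.y:.1f}) μm lies outside the "
                "field of view plus margin; its fringes may be unreliable",
                stacklevel=2,
            )
        if s.z > optics.max_reliable_z:
            warnings.warn(
                f"scatterer depth {s.z:.1f} μm exceeds the reliably "
                f"band-limited depth {optics.max_reliable_z:.1f} μm for this "
                "grid (aliasing risk)",
                stacklevel=2,
            )

    if scene.scatterers:
        psi = _fft.ifft2(_scene_spectrum(scene.scatterers, optics, numerical_aperture))
        intensity = np.abs(1.0 + psi) ** 2
    else:
        intensity = np.ones(optics.shape)

    if artifact_pattern is not None:
        pattern = np.asarray(artifact_pattern, dtype=float)
        if pattern.shape != optics.shape:
            raise ValueError("artifact_pattern geometry does not match optics")
        intensity = intensity * pattern
    if noise_sd > 0:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        intensity = intensity + rng.normal(scale=noise_sd, size=optics.shape)
    return np.clip(intensity, 0.0, None)


def render_point_contrast(
    z: float,
    optics: OpticalConfig,
    amplitude: float = 0.02,
    numerical_aperture: float | None = None,
) -> np.ndarray:
    """Noise-free contrast image (I − 1) of one centred weak scatterer.

    Used as a matched template by the reference detector and for
    measuring the apparent extent of a scattering pattern at depth z.
    ``numerical_aperture`` overrides the optics' pupil (e.g. a narrower
    detection band).
    """
    fov_x, fov_y = optics.fov
    scene = SceneFrame(
        frame_index=0,
        scatterers=[Scatterer(x=fov_x / 2.0, y=fov_y / 2.0, z=z, amplitude=amplitude)],
    )
    return render_hologram(scene, optics, numerical_aperture=numerical_aperture) - 1.0
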