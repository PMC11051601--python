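"""Optical system description shared by every pipeline stage.

All lengths are micrometres, all lateral positions are measured in the
camera/focal plane with the origin at the top-left pixel centre
(x = column, y = row), and axial depth ``z`` is the unsigned distance of
an object from the focal plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass(frozen=True)
class OpticalConfig:
    """Geometry and illumination of an inline holographic microscope.

    Parameters
    ----------
    wavelength_vacuum : float
        Vacuum illumination wavelength in μm.  Default 0.642 μm (red
        laser diode).
    medium_index : float
        Refractive index of the suspending medium.  All propagation
        kernels use the effective wavelength ``wavelength_vacuum /
        medium_index``.
    pixel_pitch : float
        Object-plane size of one camera pixel in μm/px.  The default
        maps a 512 px frame onto a 360 μm field of view.
    frame_width, frame_height : int
        Frame geometry in pixels.
    frame_rate : float
        Acquisition rate in Hz; sets the time step of the motion model.
    chamber_depth : float
        Axial extent of the sample chamber in μm; depths are confined to
        ``[0, chamber_depth]``.
    numerical_aperture : float
        NA of the imaging objective.  Used as a pupil cut-off when a
        band-limited (finite-aperture) image is requested; pure
        angular-spectrum propagation ignores it.
    """

    wavelength_vacuum: float = 0.642
    medium_index: float = 1.33
    pixel_pitch: float = 360.0 / 512.0
    frame_width: int = 512
    frame_height: int = 512
    frame_rate: float = 30.0
    chamber_depth: float = 280.0
    numerical_aperture: float = 0.5

    def __post_init__(self) -> None:
        if self.wavelength_vacuum <= 0:
            raise ValueError("wavelength_vacuum must be positive")
        if self.medium_index < 1.0:
            raise ValueError("medium_index must be >= 1")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.frame_width < 16 or self.frame_height < 16:
            raise ValueError("frame dimensions must be at least 16 px")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.chamber_depth <= 0:
            raise ValueError("chamber_depth must be positive")
        if not 0 < self.numerical_aperture <= self.medium_index:
            raise ValueError("numerical_aperture must lie in (0, medium_index]")

    @property
    def wavelength_eff(self) -> float:
        """Wavelength in the medium, μm."""
        return self.wavelength_vacuum / self.medium_index

    @property
    def shape(self) -> tuple[int, int]:
        """Frame shape as (rows, cols) = (frame_height, frame_width)."""
        return (self.frame_height, self.frame_width)

    @property
    def fov(self) -> tuple[float, float]:
        """Lateral field of view (x extent, y extent) in μm."""
        return (self.frame_width * self.pixel_pitch,
                self.frame_height * self.pixel_pitch)

    @property
    def dt(self) -> float:
        """Inter-frame interval in seconds."""
        return 1.0 / self.frame_rate

    @property
    def max_reliable_z(self) -> float:
        """Largest depth for which the frame grid samples the hologram
        chirp below Nyquist (paraxial estimate N·Δx²/λ_eff)."""
        n = min(self.frame_width, self.frame_height)
        return n * self.pixel_pitch ** 2 / self.wavelength_eff

    def replace(self, **kwargs) -> "OpticalConfig":
        vals = {f.name: getattr(self, f.name) for f in fields(self)}
        vals.update(kwargs)
        return OpticalConfig(**vals)
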