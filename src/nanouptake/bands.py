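"""Raman band library for the three cellular-scene components.

The synthetic Raman scenes mix three spectral components: bulk water
(a single broad H-O-H bending band near 1644 cm^-1), intracellular lipid
droplets, and polystyrene nanoparticles.  Each component is described as a
list of :class:`BandSpec` entries; :func:`ComponentLibrary.reference_spectrum`
renders the sum of the band profiles on an arbitrary wavenumber axis,
peak-normalized to 1.

Band positions are the literature assignments for polystyrene (aromatic
ring deformation 621, ring breathing 1001, C-H deformation 1031, C6H5-C
1201, CH2 scissoring 1450, ring skeletal stretch 1604, CH2 stretches
2913/3057) and for lipids (CH2 twist 1302, CH2/CH3 scissoring 1442, C=C
stretch 1656, CH2/CH3 stretches 2882/2929).  Relative intensities and
widths are model choices, not measured values; downstream recovery checks
depend only on the positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BandSpec",
    "ComponentLibrary",
    "default_library",
    "DEFAULT_AXIS",
    "default_axis",
]

#: Working wavenumber axis: 600-3100 cm^-1 sampled every 2 cm^-1.
DEFAULT_AXIS = np.arange(600.0, 3100.0 + 1e-9, 2.0)


def default_axis() -> np.ndarray:
    """Return a fresh copy of the default 600-3100 cm^-1 axis (2 cm^-1 step)."""
    return DEFAULT_AXIS.copy()


@dataclass(frozen=True)
class BandSpec:
    """One vibrational band: position, relative height, width and line shape.

    Parameters
    ----------
    center : float
        Band position in cm^-1; must be positive.
    rel_intensity : float
        Peak height relative to the strongest band of the component,
        in (0, 1].
    fwhm : float
        Full width at half maximum in cm^-1; must be positive.
    shape : {"gaussian", "lorentzian", "pseudo_voigt"}
        Line shape; pseudo-Voigt is the 50/50 Gaussian/Lorentzian sum.
    """

    center: float
    rel_intensity: float
    fwhm: float
    shape: str = "pseudo_voigt"

    def __post_init__(self) -> None:
        if self.center <= 0:
            raise ValueError(f"band center must be > 0, got {self.center}")
        if not 0 < self.rel_intensity <= 1:
            raise ValueError(
                f"rel_intensity must be in (0, 1], got {self.rel_intensity}"
            )
        if self.fwhm <= 0:
            raise ValueError(f"fwhm must be > 0, got {self.fwhm}")
        if self.shape not in ("gaussian", "lorentzian", "pseudo_voigt"):
            raise ValueError(f"unknown line shape {self.shape!r}")

    def profile(self, axis: np.ndarray) -> np.ndarray:
        """Evaluate the unit-height line profile on ``axis`` and scale it."""
        x = np.asarray(axis, dtype=float)
        hw = self.fwhm / 2.0
        gauss = np.exp(-4.0 * np.log(2.0) * ((x - self.center) / self.fwhm) ** 2)
        lorentz = hw**2 / ((x - self.center) ** 2 + hw**2)
        if self.shape == "gaussian":
            prof = gauss
        elif self.shape == "lorentzian":
            prof = lorentz
        else:
            prof = 0.5 * gauss + 0.5 * lorentz
        return self.rel_intensity * prof


# Positions from the literature assignments; heights/widths are model choices.
POLYSTYRENE_BANDS: tuple[BandSpec, ...] = (
    BandSpec(621.0, 0.40, 12.0),   # aromatic ring deformation
    BandSpec(1001.0, 1.00, 12.0),  # aromatic ring breathing (fingerprint)
    BandSpec(1031.0, 0.45, 12.0),  # C-H deformation
    BandSpec(1201.0, 0.25, 12.0),  # C6H5-C vibration
    BandSpec(1450.0, 0.30, 13.0),  # CH2 scissoring
    BandSpec(1604.0, 0.30, 12.0),  # ring skeletal stretch
    BandSpec(2913.0, 0.60, 14.0),  # antisym. CH2 stretch
    BandSpec(3057.0, 0.40, 13.0),  # aromatic C-H stretch
)

LIPID_BANDS: tuple[BandSpec, ...] = (
    BandSpec(1302.0, 0.50, 14.0),  # CH2 twist
    BandSpec(1442.0, 0.80, 14.0),  # CH2/CH3 scissoring
    BandSpec(1656.0, 0.60, 11.0),  # C=C stretch
    BandSpec(2882.0, 1.00, 16.0),  # antisym. =CH2 stretch
    BandSpec(2929.0, 0.55, 14.0),  # =CH3 sym. stretch
)

WATER_BANDS: tuple[BandSpec, ...] = (
    # broad H-O-H bending hump of bulk water
    BandSpec(1644.0, 1.00, 200.0, shape="gaussian"),
)


@dataclass(frozen=True)
class ComponentLibrary:
    """Map from component label to its band list.

    The default library (see :func:`default_library`) holds the three
    components of the cellular scene: ``polystyrene``, ``lipid``, ``water``.
    """

    components: dict[str, tuple[BandSpec, ...]] = field(
        default_factory=lambda: {
            "polystyrene": POLYSTYRENE_BANDS,
            "lipid": LIPID_BANDS,
            "water": WATER_BANDS,
        }
    )

    def __post_init__(self) -> None:
        for label, bands in self.components.items():
            if not bands:
                raise ValueError(f"component {label!r} has no bands")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.components)

    def reference_spectrum(self, label: str, axis: np.ndarray) -> np.ndarray:
        """Render the component's reference spectrum on ``axis``.

        The spectrum is the sum of the band profiles, peak-normalized so the
        global maximum equals 1.  Every band whose center lies on the axis
        produces a local maximum within one channel of its position (bands
        in the default library are well separated relative to their widths).

        Parameters
        ----------
        label : str
            Component label, one of :attr:`labels`.
        axis : array-like
            Strictly increasing wavenumber axis in cm^-1.

        Returns
        -------
        numpy.ndarray
            Intensity per channel, max 1 (all-zero if no band overlaps
            the axis is impossible for the default library axes; a spectrum
            whose bands all fall outside the axis raises ``ValueError``).
        """
        if label not in self.components:
            raise KeyError(f"unknown component label {label!r}")
        x = np.asarray(axis, dtype=float)
        if x.size == 0:
            raise ValueError("empty wavenumber axis")
        if x.size > 1 and not np.all(np.diff(x) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        spec = np.zeros_like(x)
        for band in self.components[label]:
            spec += band.profile(x)
        peak = spec.max()
        if peak <= 0:
            raise ValueError(
                f"no band of component {label!r} contributes on this axis"
            )
        return spec / peak


def default_library() -> ComponentLibrary:
    """The three-component water / lipid / polystyrene band library."""
    return ComponentLibrary()
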