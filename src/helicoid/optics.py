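"""Chiral Bragg reflection optics for helicoidal cell walls.

A helicoidal (Bouligand) stack of birefringent cellulose layers selectively
reflects circularly polarized light of its own handedness in a band centred,
at normal incidence, on

    lambda = n_m * p

where ``p`` is the pitch (one full 360-degree rotation of fibril orientation)
and ``n_m`` the mean of the ordinary and extraordinary refractive indices of
the wall material.  The best available estimate for hydrated plant cell walls
is ``n_m = 1.50``, which is the default here.

Because orientations 180 degrees apart are indistinguishable in section, the
lamellar banding seen under TEM repeats every *half* pitch; the quantities
exchanged with microscopy are therefore half-pitches, ``p/2 = lambda/(2 n_m)``.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "OpticalConstants",
    "pitch_to_wavelength",
    "wavelength_to_half_pitch",
    "propagate_sd",
    "round_half_even",
]

#: Mean refractive index of hydrated plant cell-wall material.
DEFAULT_N_MEAN = 1.50


@dataclass(frozen=True)
class OpticalConstants:
    """Optical constants of the wall material.

    Parameters
    ----------
    n_mean:
        Mean of the ordinary and extraordinary refractive indices
        (dimensionless, > 1).
    """

    n_mean: float = DEFAULT_N_MEAN

    def __post_init__(self) -> None:
        if not self.n_mean > 1.0:
            raise ValueError(f"n_mean must exceed 1, got {self.n_mean}")


def pitch_to_wavelength(pitch_nm: float, oc: OpticalConstants | None = None) -> float:
    """Peak reflected wavelength (nm) for a helicoid of full pitch ``pitch_nm``.

    Normal-incidence centre of the chiral reflection band: ``lambda = n_mean * p``.
    """
    if oc is None:
        oc = OpticalConstants()
    if not pitch_nm > 0:
        raise ValueError(f"pitch must be positive, got {pitch_nm}")
    return oc.n_mean * pitch_nm


def wavelength_to_half_pitch(
    wavelength_nm: float,
    oc: OpticalConstants | None = None,
    report_rounding: bool = False,
) -> float:
    """Predicted lamellar half-pitch (nm) from a peak wavelength.

    Inverts ``lambda = n_mean * p`` and halves: ``p/2 = lambda / (2 n_mean)``.
    With ``report_rounding`` the value is rounded half-to-even to integer nm
    for table display; callers needing both should call twice (the raw value
    is always the default return).
    """
    if oc is None:
        oc = OpticalConstants()
    if not wavelength_nm > 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_nm}")
    half = wavelength_nm / (2.0 * oc.n_mean)
    return round_half_even(half) if report_rounding else half


def propagate_sd(sd_wavelength_nm: float, oc: OpticalConstants | None = None) -> float:
    """Standard deviation of the predicted half-pitch from the SD of the peak.

    Division by the constant ``2 n_mean`` scales an SD linearly.
    """
    if oc is None:
        oc = OpticalConstants()
    if sd_wavelength_nm < 0:
        raise ValueError(f"sd must be non-negative, got {sd_wavelength_nm}")
    return sd_wavelength_nm / (2.0 * oc.n_mean)


def round_half_even(x: float) -> float:
    """Round to nearest integer, ties to even (display convention for tables)."""
    return float(round(x))
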