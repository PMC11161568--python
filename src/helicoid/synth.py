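"""Synthetic circular-polarization spectra and TEM-style images with ground truth.

The generators stand in for the raw microscope data of a structural-colour
survey: per-cell reflectance spectra measured through left- and right-handed
circular polarization filters, transverse-section band images whose lamellar
repeat is the half-pitch, and oblique-section images showing the nested-arc
texture diagnostic of helicoids.

The spectral band is a Gaussian bump centred at ``lambda_c = n_mean * p`` with
full width at half maximum ``delta_n * p`` (the chiral stop band spans
``n_o p .. n_e p``) and saturating amplitude

    A = tanh^2( n_turns * pi * delta_n / (2 * n_mean) )

— the coupled-wave reflectance of a chiral Bragg reflector, so thin walls of a
few helicoids give weak bands and 70-turn walls reflect almost totally.  Only
the channel matching the helicoid's handedness carries the band; the opposite
channel is baseline plus noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .spectra import CellSpectrumPair, Spectrum, write_spectrum
from .tem_pitch import BandImage, write_band_image

__all__ = [
    "HelicoidParams",
    "SpeciesPanel",
    "default_grid",
    "simulate_cp_spectrum",
    "simulate_band_image",
    "simulate_arc_image",
    "simulate_species_panel",
    "write_panel",
]

#: Default wavelength grid, nm — full spectroradiometer coverage at 1-nm
#: spacing; peak analysis later restricts itself to the visible 400-800 nm.
GRID_START, GRID_STOP, GRID_STEP = 350.0, 900.0, 1.0


def default_grid() -> np.ndarray:
    return np.arange(GRID_START, GRID_STOP + 0.5 * GRID_STEP, GRID_STEP)


@dataclass(frozen=True)
class HelicoidParams:
    """Ground-truth description of one helicoidal wall stack.

    Parameters
    ----------
    pitch_nm:
        Full pitch ``p`` — the distance along the stacking axis for one full
        360-degree rotation of fibril orientation.  The TEM banding repeat is
        ``p/2``.
    handedness:
        ``"left"`` or ``"right"``; the reflected circular polarization matches
        the helicoid's own handedness.
    n_turns:
        Number of full helicoids in the stack (sets band amplitude).
    n_ordinary, n_extraordinary:
        Refractive indices of the birefringent wall material.
    """

    pitch_nm: float
    handedness: str = "left"
    n_turns: int = 20
    n_ordinary: float = 1.475
    n_extraordinary: float = 1.525

    def __post_init__(self) -> None:
        if not self.pitch_nm > 0:
            raise ValueError(f"pitch_nm must be positive, got {self.pitch_nm}")
        if self.handedness not in ("left", "right"):
            raise ValueError(f"handedness must be 'left' or 'right', got {self.handedness!r}")
        if self.n_turns < 1:
            raise ValueError("n_turns must be >= 1")
        if not (self.n_extraordinary >= self.n_ordinary > 1.0):
            raise ValueError("need n_extraordinary >= n_ordinary > 1")

    @property
    def n_mean(self) -> float:
        return 0.5 * (self.n_ordinary + self.n_extraordinary)

    @property
    def birefringence(self) -> float:
        return self.n_extraordinary - self.n_ordinary

    @property
    def band_centre_nm(self) -> float:
        """Normal-incidence reflection-band centre, ``n_mean * p``."""
        return self.n_mean * self.pitch_nm

    @property
    def band_fwhm_nm(self) -> float:
        """Chiral stop-band width, ``delta_n * p``."""
        return self.birefringence * self.pitch_nm

    @property
    def band_amplitude(self) -> float:
        """Saturating peak reflectance of the matched channel."""
        x = self.n_turns * np.pi * self.birefringence / (2.0 * self.n_mean)
        return float(np.tanh(x) ** 2)

    @property
    def matched_channel(self) -> str:
        return "LCP" if self.handedness == "left" else "RCP"


@dataclass
class SpeciesPanel:
    """A simulated per-species panel: one spectrum pair and band image per cell."""

    true_params: HelicoidParams
    cell_pitches_nm: np.ndarray
    pairs: list[CellSpectrumPair]
    images: list[BandImage]
    seed: int
    species: str = "synthetic"


# ------------------------------------------------------------------ spectra


def simulate_cp_spectrum(
    params: HelicoidParams,
    grid: np.ndarray | None = None,
    baseline: float = 0.02,
    noise_sd: float = 0.005,
    seed: int = 0,
) -> CellSpectrumPair:
    """Simulate one cell's matched LCP/RCP reflectance spectra.

    The channel matching ``params.handedness`` carries a Gaussian band at
    ``n_mean * p`` with FWHM ``delta_n * p`` and coupled-wave amplitude on top
    of ``baseline``; the opposite channel is baseline only.  Independent white
    Gaussian noise of ``noise_sd`` is added to both channels and the result is
    clipped to [0, 1].
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be ascending with at least 2 points")
    if grid[0] < 350.0 or grid[-1] > 900.0:
        raise ValueError("grid must lie within [350, 900] nm")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    centre = params.band_centre_nm
    fwhm = params.band_fwhm_nm
    flags: list[str] = []
    if not (grid[0] <= centre <= grid[-1]):
        import warnings

        warnings.warn(
            f"band centre {centre:.1f} nm lies outside the grid "
            f"[{grid[0]:g}, {grid[-1]:g}] nm",
            stacklevel=2,
        )
        flags.append("band_centre_outside_grid")

    if fwhm > 0:
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        band = params.band_amplitude * np.exp(-0.5 * ((grid - centre) / sigma) ** 2)
    else:
        band = np.zeros_like(grid)  # zero birefringence: no band at all

    rng = np.random.default_rng(seed)
    matched = baseline + band + rng.normal(0.0, noise_sd, grid.size)
    opposite = baseline + rng.normal(0.0, noise_sd, grid.size)
    matched = np.clip(matched, 0.0, 1.0)
    opposite = np.clip(opposite, 0.0, 1.0)

    by_channel = {params.matched_channel: matched}
    other = "RCP" if params.matched_channel == "LCP" else "LCP"
    by_channel[other] = opposite
    pair = CellSpectrumPair(
        lcp=Spectrum(grid, by_channel["LCP"], channel="LCP"),
        rcp=Spectrum(grid, by_channel["RCP"], channel="RCP"),
    )
    pair.flags.extend(flags)
    return pair


# ------------------------------------------------------------------- images


def simulate_band_image(
    params: HelicoidParams,
    nm_per_px: float = 2.0,
    shape: tuple[int, int] = (256, 2048),
    tilt_deg: float = 0.0,
    contrast: float = 0.5,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> BandImage:
    """Simulate a transverse-section micrograph of lamellar banding.

    Intensity varies sinusoidally along the x axis with apparent spatial
    period ``(p/2) / cos(tilt_deg)`` — a section tilted away from the true
    transverse plane stretches the banding.  The true half-pitch and tilt are
    recorded in the metadata.
    """
    if not nm_per_px > 0:
        raise ValueError("nm_per_px must be positive")
    if not (0 <= tilt_deg < 85):
        raise ValueError(f"tilt must be in [0, 85) degrees, got {tilt_deg}")
    half_pitch = params.pitch_nm / 2.0
    apparent_nm = half_pitch / np.cos(np.radians(tilt_deg))
    x_nm = np.arange(shape[1]) * nm_per_px
    wave = 0.5 + 0.5 * contrast * np.cos(2.0 * np.pi * x_nm / apparent_nm)
    img = np.tile(wave, (shape[0], 1))
    rng = np.random.default_rng(seed)
    img = np.clip(img + rng.normal(0.0, noise_sd, img.shape), 0.0, 1.0)
    return BandImage(
        intensity=img,
        nm_per_px=nm_per_px,
        tilt_deg=tilt_deg,
        metadata={
            "true_half_pitch_nm": half_pitch,
            "apparent_half_pitch_nm": float(apparent_nm),
            "handedness": params.handedness,
            "kind": "bands",
        },
    )


def simulate_arc_image(
    params: HelicoidParams,
    cut_angle_deg: float = 30.0,
    segment_density: int = 6000,
    nm_per_px: float = 2.0,
    shape: tuple[int, int] = (256, 256),
    segment_len_px: int = 9,
    seed: int = 0,
) -> BandImage:
    """Simulate an oblique-section micrograph showing nested Bouligand arcs.

    Short fibril segments are drawn at random positions; the in-plane
    orientation of a segment rotates with depth as ``phi(z) = +/- 2 pi z / p``
    (sign from handedness), and depth maps to the image y axis through the
    oblique cut, ``z = y * nm_per_px * sin(cut_angle)``.  The arc texture
    repeats along the cut every ``(p/2) / sin(cut_angle)``.  Mirroring the
    image horizontally exchanges the two handednesses.
    """
    if not (5 <= cut_angle_deg <= 85):
        raise ValueError(f"cut angle must be in [5, 85] degrees, got {cut_angle_deg}")
    if not nm_per_px > 0:
        raise ValueError("nm_per_px must be positive")
    from skimage.draw import line_aa

    h, w = shape
    sin_cut = np.sin(np.radians(cut_angle_deg))
    rng = np.random.default_rng(seed)
    img = np.zeros(shape, dtype=float)
    sign = 1.0 if params.handedness == "right" else -1.0

    ys = rng.integers(0, h, size=segment_density)
    xs = rng.integers(0, w, size=segment_density)
    if params.handedness == "left":
        xs = (w - 1) - xs  # exact mirror counterpart of the right-handed draw
    half_len = segment_len_px / 2.0
    for x, y in zip(xs, ys):
        z_nm = y * nm_per_px * sin_cut
        phi = sign * 2.0 * np.pi * z_nm / params.pitch_nm
        dx = np.rint(half_len * np.cos(phi))
        dy = np.rint(half_len * np.sin(phi))
        r0, c0 = int(y - dy), int(x - dx)
        r1, c1 = int(y + dy), int(x + dx)
        r0, r1 = np.clip([r0, r1], 0, h - 1)
        c0, c1 = np.clip([c0, c1], 0, w - 1)
        rr, cc, val = line_aa(r0, c0, r1, c1)
        img[rr, cc] += val

    img = np.clip(img / max(img.max(), 1e-12), 0.0, 1.0)
    repeat_nm = (params.pitch_nm / 2.0) / sin_cut
    return BandImage(
        intensity=img,
        nm_per_px=nm_per_px,
        tilt_deg=None,
        metadata={
            "true_half_pitch_nm": params.pitch_nm / 2.0,
            "arc_repeat_along_cut_nm": float(repeat_nm),
            "cut_angle_deg": float(cut_angle_deg),
            "handedness": params.handedness,
            "kind": "arcs",
        },
    )


# -------------------------------------------------------------------- panels


def simulate_species_panel(
    true_params: HelicoidParams,
    n_cells: int = 10,
    pitch_cv: float = 0.05,
    seed: int = 0,
    grid: np.ndarray | None = None,
    baseline: float = 0.02,
    noise_sd: float = 0.005,
    image_noise_sd: float = 0.05,
    nm_per_px: float = 2.0,
    species: str = "synthetic",
) -> SpeciesPanel:
    """Simulate a ten-cell species panel with cell-to-cell pitch variability.

    Per-cell pitches are drawn from a normal law with mean ``pitch_nm`` and SD
    ``pitch_cv * pitch_nm`` (redrawn if non-positive); each cell receives one
    spectrum pair and one transverse band image.  All per-cell seeds are
    derived from the master seed by stable offsets, so the panel regenerates
    bit-identically.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not (0 <= pitch_cv < 0.3):
        raise ValueError("pitch_cv must be in [0, 0.3)")
    rng = np.random.default_rng(seed)
    sd = pitch_cv * true_params.pitch_nm
    pitches = rng.normal(true_params.pitch_nm, sd, size=n_cells)
    while np.any(pitches <= 0):  # truncate to positive pitches
        bad = pitches <= 0
        pitches[bad] = rng.normal(true_params.pitch_nm, sd, size=bad.sum())

    pairs, images = [], []
    for i, p in enumerate(pitches):
        cell = HelicoidParams(
            pitch_nm=float(p),
            handedness=true_params.handedness,
            n_turns=true_params.n_turns,
            n_ordinary=true_params.n_ordinary,
            n_extraordinary=true_params.n_extraordinary,
        )
        pair = simulate_cp_spectrum(
            cell, grid=grid, baseline=baseline, noise_sd=noise_sd, seed=seed + 1000 + i
        )
        pair.lcp.cell_id = pair.rcp.cell_id = f"{species}_cell{i:02d}"
        pairs.append(pair)
        images.append(
            simulate_band_image(
                cell, nm_per_px=nm_per_px, noise_sd=image_noise_sd, seed=seed + 2000 + i
            )
        )
        images[-1].image_id = f"{species}_cell{i:02d}"
    return SpeciesPanel(
        true_params=true_params,
        cell_pitches_nm=pitches,
        pairs=pairs,
        images=images,
        seed=seed,
        species=species,
    )


def write_panel(panel: SpeciesPanel, outdir: str | Path) -> Path:
    """Write a panel to disk: per-cell ``*_LCP.csv`` / ``*_RCP.csv`` spectra and
    ``*.tif`` band images with metadata sidecars, plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_lines = ["cell_id\tlcp\trcp\timage"]
    for pair, img in zip(panel.pairs, panel.images):
        cid = pair.cell_id
        lcp = write_spectrum(pair.lcp, outdir / f"{cid}_LCP.csv")
        rcp = write_spectrum(pair.rcp, outdir / f"{cid}_RCP.csv")
        tif = write_band_image(img, outdir / f"{cid}.tif")
        manifest_lines.append(f"{cid}\t{lcp.name}\t{rcp.name}\t{tif.name}")
    manifest = outdir / "manifest.tsv"
    manifest.write_text("\n".join(manifest_lines) + "\n")
    truth = outdir / "truth.txt"
    truth.write_text(
        f"pitch_nm: {panel.true_params.pitch_nm}\n"
        f"half_pitch_nm: {panel.true_params.pitch_nm / 2.0}\n"
        f"handedness: {panel.true_params.handedness}\n"
        f"n_turns: {panel.true_params.n_turns}\n"
        f"seed: {panel.seed}\n"
    )
    return manifest
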