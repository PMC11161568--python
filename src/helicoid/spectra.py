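"""Paired circular-polarization reflectance spectra: IO, normalization, peaks.

A structurally coloured epidermal cell is measured twice through a circular
polarization analyser — once transmitting left- (LCP) and once right-handed
(RCP) circularly polarized light.  A photonic helicoid reflects only the
handedness matching its own twist, so the matched channel carries a single
reflection band while the opposite channel stays near baseline.  The per-cell
statistic is the peak wavelength of the dominant channel; per-species panels
(conventionally ten cells) are summarised as mean +/- sample SD.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "CellSpectrumPair",
    "PeakResult",
    "PanelSummary",
    "read_spectrum",
    "read_pair",
    "write_spectrum",
    "normalize_to_reference",
    "resample_to_common_grid",
    "find_peak",
    "cp_selectivity",
    "classify_colour_bin",
    "summarize_cells",
    "analyze_pair",
    "results_table",
]

#: Wavelength window over which visible peaks are sought, nm.
ANALYSIS_RANGE = (400.0, 800.0)

#: Colour bins as half-open intervals [lo, hi), upper edge of the last bin closed.
COLOUR_BINS = (
    ("violet", 400.0, 450.0),
    ("blue", 450.0, 500.0),
    ("green", 500.0, 570.0),
    ("long", 570.0, 800.0),
)


@dataclass
class Spectrum:
    """A single-channel reflectance spectrum on an ascending wavelength grid."""

    wavelengths: np.ndarray
    reflectance: np.ndarray
    channel: str = "LCP"
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.shape != self.reflectance.shape:
            raise ValueError("wavelengths and reflectance must have equal length")
        if self.wavelengths.size and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly ascending")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance contains non-finite values")
        if self.channel not in ("LCP", "RCP"):
            raise ValueError(f"channel must be 'LCP' or 'RCP', got {self.channel!r}")

    def __len__(self) -> int:
        return int(self.wavelengths.size)


@dataclass
class CellSpectrumPair:
    """Matched LCP/RCP spectra for one epidermal cell."""

    lcp: Spectrum
    rcp: Spectrum
    on_common_grid: bool = False
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.on_common_grid = bool(
            len(self.lcp) == len(self.rcp)
            and np.array_equal(self.lcp.wavelengths, self.rcp.wavelengths)
        )

    @property
    def cell_id(self) -> str:
        return self.lcp.cell_id or self.rcp.cell_id

    def channel(self, name: str) -> Spectrum:
        if name == "LCP":
            return self.lcp
        if name == "RCP":
            return self.rcp
        raise KeyError(name)


@dataclass
class PeakResult:
    """Per-cell peak statistics and circular-polarization selectivity."""

    cell_id: str
    peak_wavelength_nm: float
    peak_reflectance: float
    prominence: float
    selectivity_ratio: float
    docp: float
    colour_bin: str
    is_selective: bool
    dominant_channel: str
    peak_defined: bool = True
    flags: list[str] = field(default_factory=list)


@dataclass
class PanelSummary:
    """Per-species aggregate over a panel of cells."""

    mean_peak_nm: float
    sd_peak_nm: float
    n_cells: int
    per_cell: list[PeakResult]
    flags: list[str] = field(default_factory=list)


# ----------------------------------------------------------------- IO

_CHANNEL_SUFFIX = re.compile(r"_(LCP|RCP)$", re.IGNORECASE)


def read_spectrum(path: str | Path, channel: str | None = None, cell_id: str | None = None) -> Spectrum:
    """Read a two-column (wavelength nm, reflectance) delimited text file.

    Delimiter may be comma, tab or whitespace; one optional header line is
    tolerated.  Rows are sorted ascending; duplicate wavelengths are an error.
    Channel defaults from an ``_LCP`` / ``_RCP`` filename suffix.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty spectrum file")
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]

    def parse_row(ln: str) -> tuple[float, float] | None:
        parts = re.split(r"[,\t;]+|\s+", ln.strip())
        parts = [p for p in parts if p]
        if len(parts) < 2:
            return None
        try:
            return float(parts[0]), float(parts[1])
        except ValueError:
            return None

    start = 0
    if parse_row(lines[0]) is None:
        start = 1  # single header line
    rows = []
    for ln in lines[start:]:
        row = parse_row(ln)
        if row is None:
            raise ValueError(f"{path}: non-numeric row {ln!r}")
        rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no numeric rows")

    arr = np.array(rows, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    dup = np.flatnonzero(np.diff(arr[:, 0]) == 0)
    if dup.size:
        raise ValueError(f"{path}: duplicate wavelength {arr[dup[0], 0]:g} nm")

    if channel is None:
        m = _CHANNEL_SUFFIX.search(path.stem)
        channel = m.group(1).upper() if m else "LCP"
    if cell_id is None:
        cell_id = _CHANNEL_SUFFIX.sub("", path.stem)
    return Spectrum(arr[:, 0], arr[:, 1], channel=channel, cell_id=cell_id)


def read_pair(lcp_path: str | Path, rcp_path: str | Path) -> CellSpectrumPair:
    return CellSpectrumPair(
        lcp=read_spectrum(lcp_path, channel="LCP"),
        rcp=read_spectrum(rcp_path, channel="RCP"),
    )


def write_spectrum(s: Spectrum, path: str | Path) -> Path:
    """Write as two-column CSV with the standard header."""
    path = Path(path)
    buf = io.StringIO()
    buf.write("wavelength_nm,reflectance\n")
    for w, r in zip(s.wavelengths, s.reflectance):
        buf.write(f"{w:.6g},{r:.8g}\n")
    path.write_text(buf.getvalue())
    return path


# ------------------------------------------------- normalization / resampling


def normalize_to_reference(raw: Spectrum, white: Spectrum, dark: Spectrum) -> Spectrum:
    """White-reference normalization: R = (raw - dark) / (white - dark).

    All three spectra must share a grid (resample first).  ``white - dark``
    must be strictly positive everywhere in the shared range.
    """
    for other, name in ((white, "white"), (dark, "dark")):
        if not np.array_equal(raw.wavelengths, other.wavelengths):
            raise ValueError(f"{name} reference not on the raw spectrum's grid; resample first")
    denom = white.reflectance - dark.reflectance
    bad = denom <= 0
    if np.any(bad):
        w = raw.wavelengths[bad][0]
        raise ValueError(f"white <= dark at {w:g} nm; reference unusable there")
    return replace(raw, reflectance=(raw.reflectance - dark.reflectance) / denom)


def resample_to_common_grid(pair: CellSpectrumPair, step_nm: float = 1.0) -> CellSpectrumPair:
    """Linearly interpolate both channels onto a shared uniform grid.

    The grid spans the overlap of the two channels' ranges at ``step_nm``
    spacing.  Pairs already on identical grids are returned as-is.
    """
    if pair.on_common_grid:
        return pair
    lo = max(pair.lcp.wavelengths[0], pair.rcp.wavelengths[0])
    hi = min(pair.lcp.wavelengths[-1], pair.rcp.wavelengths[-1])
    if hi - lo < step_nm:
        raise ValueError(f"wavelength ranges overlap by less than one step ({lo:g}..{hi:g} nm)")
    grid = np.arange(lo, hi + 0.5 * step_nm, step_nm)
    grid = grid[grid <= hi + 1e-9]

    def interp(s: Spectrum) -> Spectrum:
        return replace(s, wavelengths=grid, reflectance=np.interp(grid, s.wavelengths, s.reflectance))

    return CellSpectrumPair(lcp=interp(pair.lcp), rcp=interp(pair.rcp), flags=list(pair.flags))


# ----------------------------------------------------------- peak analysis


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with odd window, edges reflected."""
    if window < 1:
        raise ValueError("smooth_window must be >= 1")
    if window % 2 == 0:
        raise ValueError("smooth_window must be odd")
    if window == 1:
        return y.copy()
    half = window // 2
    padded = np.pad(y, half, mode="reflect")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def find_peak(
    s: Spectrum,
    analysis_range: tuple[float, float] = ANALYSIS_RANGE,
    smooth_window: int = 5,
    min_prominence: float = 0.0,
) -> tuple[float, float, float, bool]:
    """Locate the reflection-band peak within the analysis range.

    The spectrum is smoothed by a centered moving average of odd ``smooth_window``
    samples; the peak is the global maximum of the smoothed curve in range
    (ties broken toward the lowest wavelength).  Prominence is the peak value
    minus the larger of the two minima flanking it (between each range
    boundary and the peak).  A flat spectrum, or a maximum sitting on a range
    boundary (a band centred outside the window, not a peak), has prominence 0
    and is reported ``defined = False``; ``min_prominence`` raises that floor
    so noise ripples are not mistaken for bands.

    Returns ``(peak_wavelength_nm, peak_reflectance, prominence, defined)``.
    """
    lo, hi = analysis_range
    mask = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    if mask.sum() < 5:
        raise ValueError(f"fewer than 5 samples in analysis range [{lo:g}, {hi:g}] nm")
    w = s.wavelengths[mask]
    y = _moving_average(s.reflectance[mask], smooth_window)

    i = int(np.argmax(y))  # first occurrence = lowest wavelength
    peak_w, peak_r = float(w[i]), float(y[i])
    if np.ptp(y) == 0.0:
        return peak_w, peak_r, 0.0, False
    left_min = float(y[: i + 1].min())
    right_min = float(y[i:].min())
    prominence = float(peak_r - max(left_min, right_min))
    defined = prominence > max(min_prominence, 0.0)
    return peak_w, peak_r, prominence, defined


def cp_selectivity(
    pair: CellSpectrumPair,
    wavelength_nm: float,
    window_nm: float = 20.0,
    ratio_threshold: float = 2.0,
    prominence_fraction: float = 0.05,
    smooth_window: int = 5,
    analysis_range: tuple[float, float] = ANALYSIS_RANGE,
) -> tuple[float, float, bool, str, list[str]]:
    """Circular-polarization selectivity metrics at a candidate peak.

    Each channel's reflectance is averaged over ``[lambda - w/2, lambda + w/2]``.
    The selectivity ratio is dominant/other; DOCP = (L - R)/(L + R).  A cell is
    *selective* when the ratio reaches ``ratio_threshold`` and the dominant
    channel's band prominence is at least ``prominence_fraction`` of its peak
    height — i.e. there is a real band, not just a brightness offset.

    Returns ``(selectivity_ratio, docp, is_selective, dominant_channel, flags)``.
    """
    if not pair.on_common_grid:
        pair = resample_to_common_grid(pair)
    grid = pair.lcp.wavelengths
    if not (grid[0] <= wavelength_nm <= grid[-1]):
        raise ValueError(f"{wavelength_nm:g} nm outside the common grid")
    step = float(np.median(np.diff(grid)))
    window_nm = max(window_nm, step)
    sel = np.abs(grid - wavelength_nm) <= window_nm / 2.0

    flags: list[str] = []
    eps = 1e-9
    mean_l = float(pair.lcp.reflectance[sel].mean())
    mean_r = float(pair.rcp.reflectance[sel].mean())
    dominant = "LCP" if mean_l >= mean_r else "RCP"
    hi, lo_val = max(mean_l, mean_r), min(mean_l, mean_r)
    if lo_val <= eps:
        flags.append("epsilon_floor")
        lo_val = eps
    ratio = hi / lo_val
    denom = mean_l + mean_r
    docp = 0.0 if denom <= eps else (mean_l - mean_r) / denom

    _, peak_r, prom, defined = find_peak(
        pair.channel(dominant), analysis_range=analysis_range, smooth_window=smooth_window
    )
    rel_prom = prom / peak_r if peak_r > 0 else 0.0
    is_selective = bool(defined and ratio >= ratio_threshold and rel_prom >= prominence_fraction)
    return float(ratio), float(np.clip(docp, -1.0, 1.0)), is_selective, dominant, flags


def classify_colour_bin(wavelength_nm: float) -> str:
    """Colour bin of a peak wavelength: violet [400,450), blue [450,500),
    green [500,570), long [570,800]."""
    if not (400.0 <= wavelength_nm <= 800.0):
        raise ValueError(f"wavelength {wavelength_nm:g} nm outside [400, 800]")
    for name, lo, hi in COLOUR_BINS:
        if lo <= wavelength_nm < hi:
            return name
    return "long"  # closed upper edge at 800


def summarize_cells(results: Sequence[PeakResult]) -> PanelSummary:
    """Panel mean and sample SD (n-1) of defined per-cell peak wavelengths."""
    defined = [r for r in results if r.peak_defined]
    if not defined:
        raise ValueError("no defined peaks to summarize")
    peaks = np.array([r.peak_wavelength_nm for r in defined])
    flags = []
    if peaks.size == 1:
        sd = 0.0
        flags.append("n=1")
    else:
        sd = float(np.std(peaks, ddof=1))
    return PanelSummary(
        mean_peak_nm=float(peaks.mean()),
        sd_peak_nm=sd,
        n_cells=int(peaks.size),
        per_cell=list(results),
        flags=flags,
    )


# -------------------------------------------------------------- pipeline


def analyze_pair(
    pair: CellSpectrumPair,
    analysis_range: tuple[float, float] = ANALYSIS_RANGE,
    smooth_window: int = 5,
    window_nm: float = 20.0,
    ratio_threshold: float = 2.0,
    prominence_fraction: float = 0.05,
    min_prominence: float = 0.01,
) -> PeakResult:
    """Full per-cell analysis: resample, find the dominant-channel peak,
    score selectivity and assign the colour bin.

    Cells whose dominant-channel maximum sits on the analysis-range boundary
    or whose prominence stays below ``min_prominence`` (reflectance units) are
    reported with ``peak_defined=False`` — their band lies outside the window
    or below the noise floor — and are excluded from panel summaries.
    """
    pair = resample_to_common_grid(pair)
    cand = {}
    for ch in ("LCP", "RCP"):
        cand[ch] = find_peak(pair.channel(ch), analysis_range, smooth_window, min_prominence)
    dominant = max(cand, key=lambda ch: cand[ch][1])
    peak_w, peak_r, prom, defined = cand[dominant]

    ratio, docp, selective, dom_at_peak, flags = cp_selectivity(
        pair,
        peak_w,
        window_nm=window_nm,
        ratio_threshold=ratio_threshold,
        prominence_fraction=prominence_fraction,
        smooth_window=smooth_window,
        analysis_range=analysis_range,
    )
    in_visible = 400.0 <= peak_w <= 800.0
    return PeakResult(
        cell_id=pair.cell_id,
        peak_wavelength_nm=peak_w,
        peak_reflectance=peak_r,
        prominence=prom,
        selectivity_ratio=ratio,
        docp=docp,
        colour_bin=(
            classify_colour_bin(peak_w) if (defined and in_visible) else "undefined"
        ),
        is_selective=selective,
        dominant_channel=dom_at_peak,
        peak_defined=defined,
        flags=flags,
    )


def results_table(results: Iterable[PeakResult]) -> pd.DataFrame:
    """Per-cell results as a DataFrame ready for delimited output."""
    results = list(results)
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in results],
            "peak_wavelength_nm": [r.peak_wavelength_nm for r in results],
            "peak_reflectance": [r.peak_reflectance for r in results],
            "prominence": [r.prominence for r in results],
            "selectivity_ratio": [r.selectivity_ratio for r in results],
            "docp": [r.docp for r in results],
            "colour_bin": [r.colour_bin for r in results],
            "is_selective": [r.is_selective for r in results],
            "dominant_channel": [r.dominant_channel for r in results],
        }
    )
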