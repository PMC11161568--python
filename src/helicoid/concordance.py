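"""Structure-colour concordance and the four-step photonic-helicoid verdict.

Identifying a photonic helicoid in a leaf epidermis rests on four lines of
evidence: (1) wavelength-selective reflection of circularly polarized light of
a single handedness; (2) nested-arc (Bouligand) patterns in oblique TEM
section; (3) a measurable lamellar half-pitch in transverse section; and
(4) concordance between the optically predicted half-pitch,
``lambda / (2 n_m)``, and the TEM-measured one.  This module aggregates
per-species evidence into survey-table rows and issues the verdict.

The agreement rule for step 4 is an explicit stand-in for the qualitative
"correlates well": predicted and observed half-pitches agree when their
difference is within one combined standard deviation or 8 % of the predicted
value, whichever is larger.  Both knobs are configurable and the rule is
flagged as a convention in rendered reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .optics import OpticalConstants, propagate_sd, round_half_even, wavelength_to_half_pitch
from .spectra import PanelSummary
from .tem_pitch import PitchEstimate

__all__ = [
    "ConcordanceRow",
    "DiagnosticVerdict",
    "assess_agreement",
    "build_concordance",
    "four_step_verdict",
    "render_table",
    "rows_to_frame",
]

#: Default relative tolerance of the agreement rule.
DEFAULT_REL_TOL = 0.08

#: Arc-score threshold when arc evidence is a score rather than a judgement.
ARC_SCORE_THRESHOLD = 0.5


@dataclass
class ConcordanceRow:
    """One species' survey-table record."""

    species: str
    mean_peak_nm: float
    sd_peak_nm: float
    predicted_half_pitch_nm: float
    sd_predicted_nm: float
    observed_half_pitch_nm: float
    sd_observed_nm: float
    arcs_present: bool
    agreement: bool

    def __post_init__(self) -> None:
        for name in ("mean_peak_nm", "predicted_half_pitch_nm", "observed_half_pitch_nm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("sd_peak_nm", "sd_predicted_nm", "sd_observed_nm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class DiagnosticVerdict:
    """Outcome of the four-step identification procedure.

    Each step is True/False/None (None = evidence unavailable).  ``overall``
    is ``confirmed`` only when all four steps are affirmatively true;
    ``not_supported`` when any step is affirmatively false; ``partial`` when
    the available steps pass but some evidence is missing.
    """

    step1_cp_selective: bool | None
    step2_arcs: bool | None
    step3_pitch_measured: bool | None
    step4_concordant: bool | None
    overall: str = field(init=False)
    handedness: str = "undetermined"

    def __post_init__(self) -> None:
        steps = (
            self.step1_cp_selective,
            self.step2_arcs,
            self.step3_pitch_measured,
            self.step4_concordant,
        )
        if all(s is True for s in steps):
            self.overall = "confirmed"
        elif any(s is False for s in steps):
            self.overall = "not_supported"
        else:
            self.overall = "partial"


def assess_agreement(
    pred: float,
    obs: float,
    sd_pred: float = 0.0,
    sd_obs: float = 0.0,
    rel_tol: float = DEFAULT_REL_TOL,
) -> bool:
    """Do predicted and observed half-pitches agree?

    True iff ``|pred - obs| <= max(sqrt(sd_pred^2 + sd_obs^2), rel_tol * pred)``:
    within one combined SD, or within the relative tolerance when the SDs are
    small or absent.
    """
    if not (pred > 0 and obs > 0):
        raise ValueError("pred and obs must be positive lengths")
    combined_sd = math.hypot(sd_pred, sd_obs)
    return abs(pred - obs) <= max(combined_sd, rel_tol * pred)


def build_concordance(
    summary: PanelSummary,
    pitch: PitchEstimate,
    arcs: bool | float,
    oc: OpticalConstants | None = None,
    species: str = "",
    rel_tol: float = DEFAULT_REL_TOL,
) -> ConcordanceRow:
    """Assemble one species row from its spectral summary and pitch estimate.

    ``arcs`` may be a human-judged boolean or an ``arc_score`` value, which is
    thresholded at ``ARC_SCORE_THRESHOLD``.
    """
    if oc is None:
        oc = OpticalConstants()
    pred = wavelength_to_half_pitch(summary.mean_peak_nm, oc)
    sd_pred = propagate_sd(summary.sd_peak_nm, oc)
    arcs_present = bool(arcs) if isinstance(arcs, bool) else bool(arcs >= ARC_SCORE_THRESHOLD)
    return ConcordanceRow(
        species=species or "unnamed",
        mean_peak_nm=summary.mean_peak_nm,
        sd_peak_nm=summary.sd_peak_nm,
        predicted_half_pitch_nm=pred,
        sd_predicted_nm=sd_pred,
        observed_half_pitch_nm=pitch.half_pitch_nm,
        sd_observed_nm=pitch.sd_nm,
        arcs_present=arcs_present,
        agreement=assess_agreement(
            pred, pitch.half_pitch_nm, sd_pred, pitch.sd_nm, rel_tol=rel_tol
        ),
    )


def four_step_verdict(
    summary: PanelSummary | None,
    pitch: PitchEstimate | None,
    arcs: bool | None,
    agreement: bool | None,
    selective_fraction_threshold: float = 0.5,
) -> DiagnosticVerdict:
    """Apply the four-step decision rule.

    Step 1 (gating proxy): a majority of cells show handedness-selective
    reflection.  Step 2: arcs seen in oblique section.  Step 3: a half-pitch
    was measured.  Step 4: predicted and observed half-pitches agree.  Any
    step may be unavailable (None), which caps the verdict at ``partial``.
    Handedness is the dominant reflected channel when step 1 holds.
    """
    step1: bool | None = None
    handedness = "undetermined"
    if summary is not None:
        cells = [r for r in summary.per_cell if r.peak_defined]
        if cells:
            frac = sum(r.is_selective for r in cells) / len(cells)
            step1 = frac >= selective_fraction_threshold
            if step1:
                dominant = pd.Series([r.dominant_channel for r in cells]).mode()[0]
                handedness = "left" if dominant == "LCP" else "right"
    step3 = None if pitch is None else bool(pitch.half_pitch_nm > 0)
    return DiagnosticVerdict(
        step1_cp_selective=step1,
        step2_arcs=arcs,
        step3_pitch_measured=step3,
        step4_concordant=agreement,
        handedness=handedness,
    )


def rows_to_frame(rows: Sequence[ConcordanceRow]) -> pd.DataFrame:
    """Machine-readable companion table with raw (unrounded) values."""
    return pd.DataFrame(
        {
            "species": [r.species for r in rows],
            "mean_peak_nm": [r.mean_peak_nm for r in rows],
            "sd_peak_nm": [r.sd_peak_nm for r in rows],
            "predicted_half_pitch_nm": [r.predicted_half_pitch_nm for r in rows],
            "sd_predicted_nm": [r.sd_predicted_nm for r in rows],
            "observed_half_pitch_nm": [r.observed_half_pitch_nm for r in rows],
            "sd_observed_nm": [r.sd_observed_nm for r in rows],
            "arcs_present": [r.arcs_present for r in rows],
            "agreement": [r.agreement for r in rows],
        }
    )


def render_table(rows: Sequence[ConcordanceRow]) -> str:
    """Human-readable survey table with integer-nm display values.

    Display rounding is half-to-even; raw values are preserved in the
    machine-readable companion (``rows_to_frame``).
    """
    if not rows:
        raise ValueError("need at least one row")
    header = (
        "Species\tMean peak reflectance (nm)\t1/2 Pitch predicted (nm)\t"
        "1/2 Pitch observed (nm)\tArcs present\tAgreement"
    )
    lines = [header]
    for i, r in enumerate(rows):
        name = r.species or f"species_{i + 1:02d}"

        def disp(v: float, sd: float) -> str:
            return f"{round_half_even(v):.0f} ± {round_half_even(sd):.0f}"

        lines.append(
            "\t".join(
                [
                    name,
                    disp(r.mean_peak_nm, r.sd_peak_nm),
                    disp(r.predicted_half_pitch_nm, r.sd_predicted_nm),
                    disp(r.observed_half_pitch_nm, r.sd_observed_nm),
                    "✓" if r.arcs_present else "✗",
                    "✓" if r.agreement else "✗",
                ]
            )
        )
    lines.append(
        "# agreement rule: |pred - obs| <= max(combined SD, "
        f"{DEFAULT_REL_TOL:.0%} of predicted) — an explicit convention"
    )
    return "\n".join(lines) + "\n"
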