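"""Bundled reference data.

``load_reference_panel`` returns the published 20-species survey of
structurally coloured leaf epidermes: per-species mean peak reflectance
wavelength (+/- SD, nm) from circular-polarization microspectrophotometry of
ten adaxial epidermal cells, the half-pitch predicted from it via
``lambda / (2 * 1.50)``, the half-pitch observed by TEM band-spacing
measurement (+/- SD), and whether nested arcs were seen in oblique section.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reference_panel"]


def load_reference_panel() -> pd.DataFrame:
    """The 20-species structure-colour concordance survey as a DataFrame.

    Columns: species, mean_peak_nm, sd_peak_nm, predicted_half_pitch_nm,
    sd_predicted_nm, observed_half_pitch_nm, sd_observed_nm, arcs_present
    (bool).  Lengths in nm; predicted columns are the published integer-nm
    display values.
    """
    with resources.files("helicoid.data").joinpath("reference_panel.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["arcs_present"] = df["arcs_present"].astype(bool)
    return df
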