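"""Packaged study fixtures.

The library ships a byte-stable transcription of the published study
tables: the 36-sample protein-powder panel (20 reported elements; Mg
exceeded the calibration range in every sample and is absent), the
per-sample serving and digestion masses, the toxicological reference
constants, and the batch QC recovery table. These drive the worked
examples, the test oracles and the default CLI behaviour.
"""

from __future__ import annotations

import pandas as pd

from .core import SampleRecord, ToxReference
from .io import load_panel, load_tox_reference, packaged_data
from .qc import CRM_BAND, MATRIX_SPIKE_BAND, QCControl


def protein_powder_panel() -> list[SampleRecord]:
    """The 36-sample powder panel (P1–P36) with serving/digestion masses."""
    with packaged_data("panel_concentrations.csv") as conc:
        with packaged_data("sample_metadata.csv") as meta:
            return load_panel(conc, meta)


def tox_reference() -> dict[str, ToxReference]:
    """Default toxicological constants for the 21-element panel.

    The hazard-index list holds exactly the 15 elements of the additive
    screen; the carcinogen list holds Be, Cd and Pb. The Cr row carries the
    Cr(VI) constants but sits on neither list because only total Cr was
    measured.
    """
    with packaged_data("tox_reference.csv") as path:
        return load_tox_reference(path)


def paper_fixture() -> tuple[list[SampleRecord], dict[str, ToxReference]]:
    """Panel records plus toxicological reference set, as one call."""
    return protein_powder_panel(), tox_reference()


def qc_recovery_controls() -> list[QCControl]:
    """Batch QC recoveries as control objects with matrix-spike bands.

    Readback rows (diluent standards substituted where the matrix spike
    could not be read) keep the matrix-spike band; their provenance is in
    the annotation field.
    """
    with packaged_data("qc_recoveries.csv") as path:
        df = pd.read_csv(path, keep_default_na=False)
    controls = []
    for _, row in df.iterrows():
        level = float(row["level_ug_per_L"])
        band = CRM_BAND if row["control_kind"] == "crm" else MATRIX_SPIKE_BAND
        controls.append(
            QCControl(
                element=row["element"],
                expected=level,
                measured_mean=level * float(row["pct_recovery"]) / 100.0,
                rsd=float(row["rsd_percent"]),
                n_replicates=int(row["n"]),
                band=band,
                annotation=str(row["annotation"]),
            )
        )
    return controls
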