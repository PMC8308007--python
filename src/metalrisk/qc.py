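"""ICP-SFMS batch quality-control rules.

Three gates are implemented as pure functions over small value objects:

* percent recovery of matrix-spiked controls and certified reference
  material, against an inclusive acceptance band (100 ± 25 % for matrix
  spikes, 100 ± 20 % for CRM);
* resolution-transmission ratios of the ¹¹⁵In reference isotope between
  low/medium/high resolution modes (MR/LR within 10–12 %, HR/LR within
  1–2 %);
* raw low-resolution sensitivity (≥ 100,000 cps for ¹¹⁵In).

Replicate RSD is carried and reported but does not gate a verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

MATRIX_SPIKE_BAND = (75.0, 125.0)
CRM_BAND = (80.0, 120.0)
MIN_LR_CPS = 100_000.0
MR_OVER_LR_BAND = (10.0, 12.0)
HR_OVER_LR_BAND = (1.0, 2.0)


@dataclass(frozen=True)
class QCControl:
    """One control observation with its acceptance band.

    expected/measured_mean in µg·L⁻¹; rsd is the replicate relative
    standard deviation in percent. ``annotation`` records footnote-style
    provenance (carryover reruns, diluent readback standards) without
    changing the verdict logic.
    """

    element: str
    expected: float
    measured_mean: float
    rsd: float = 0.0
    n_replicates: int = 3
    band: tuple[float, float] = MATRIX_SPIKE_BAND
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.expected <= 0:
            raise ValueError(f"expected level must be > 0, got {self.expected}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.band[0] >= self.band[1]:
            raise ValueError(f"acceptance band low must be < high: {self.band}")


@dataclass(frozen=True)
class TuningCheck:
    """¹¹⁵In intensities (cps) in the three resolution modes."""

    lr_intensity: float
    mr_intensity: float
    hr_intensity: float
    min_lr_cps: float = MIN_LR_CPS

    def __post_init__(self) -> None:
        for v in (self.lr_intensity, self.mr_intensity, self.hr_intensity):
            if v < 0:
                raise ValueError("intensities must be >= 0")


@dataclass(frozen=True)
class TransmissionReport:
    mr_over_lr: float
    hr_over_lr: float
    transmission_pass: bool
    sensitivity_pass: bool

    @property
    def ok(self) -> bool:
        return self.transmission_pass and self.sensitivity_pass


def recovery_percent(measured_mean: float, expected: float) -> float:
    """100 × measured / expected."""
    if expected <= 0:
        raise ValueError(f"expected level must be > 0, got {expected}")
    return 100.0 * measured_mean / expected


def recovery_verdict(q: QCControl) -> str:
    """``"pass"`` iff recovery lies inside the band, endpoints inclusive."""
    rec = recovery_percent(q.measured_mean, q.expected)
    return "pass" if q.band[0] <= rec <= q.band[1] else "fail"


def transmission_check(t: TuningCheck, tolerance: float = 0.0) -> TransmissionReport:
    """Resolution-transmission and sensitivity gates from one tuning run.

    ``tolerance`` (percentage points) widens the transmission bands
    symmetrically; the nominal bands are hard inclusive bounds.
    """
    if t.lr_intensity == 0:
        raise ValueError("LR intensity must be > 0 to form transmission ratios")
    mr = 100.0 * t.mr_intensity / t.lr_intensity
    hr = 100.0 * t.hr_intensity / t.lr_intensity
    mr_ok = MR_OVER_LR_BAND[0] - tolerance <= mr <= MR_OVER_LR_BAND[1] + tolerance
    hr_ok = HR_OVER_LR_BAND[0] - tolerance <= hr <= HR_OVER_LR_BAND[1] + tolerance
    return TransmissionReport(
        mr_over_lr=mr,
        hr_over_lr=hr,
        transmission_pass=mr_ok and hr_ok,
        sensitivity_pass=t.lr_intensity >= t.min_lr_cps,
    )


def load_controls(source) -> list[QCControl]:
    """Read a QC CSV (element, level_ug_per_L, measured_mean, rsd_percent,
    n, control_kind ∈ {matrix_spike, crm, readback}) into control objects.

    CRM rows get the 80–120% band; matrix spikes and readback standards the
    75–125% band.
    """
    df = pd.read_csv(source, keep_default_na=False)
    controls = []
    for _, row in df.iterrows():
        kind = str(row.get("control_kind", "matrix_spike")).strip()
        controls.append(
            QCControl(
                element=row["element"],
                expected=float(row["level_ug_per_L"]),
                measured_mean=float(row["measured_mean"]),
                rsd=float(row["rsd_percent"]) if str(row.get("rsd_percent", "")).strip() else 0.0,
                n_replicates=int(row["n"]) if str(row.get("n", "")).strip() else 1,
                band=CRM_BAND if kind == "crm" else MATRIX_SPIKE_BAND,
                annotation=str(row.get("annotation", "")),
            )
        )
    return controls


def batch_report(controls: list[QCControl]) -> pd.DataFrame:
    """Per-control verdict table for a QC batch."""
    rows = [
        {
            "element": q.element,
            "level_ug_per_L": q.expected,
            "recovery_percent": recovery_percent(q.measured_mean, q.expected),
            "rsd_percent": q.rsd,
            "n": q.n_replicates,
            "band_low": q.band[0],
            "band_high": q.band[1],
            "verdict": recovery_verdict(q),
            "annotation": q.annotation,
        }
        for q in controls
    ]
    return pd.DataFrame(rows)
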