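"""Synthetic panel generator.

Emulates the measurement chain end to end: a true powder concentration per
sample × element, the solution concentration the instrument would see
after digestion and dilution, multiplicative Gaussian read noise at
replicate-RSD levels, then censoring — values whose back-calculated powder
concentration falls below the element's quantification limit become
left-censored records, and readings whose solution concentration exceeds
the top calibration standard become above-range records.

True concentrations are log-uniform over each element's observed span
(the packaged panel spans 2–4 orders of magnitude per element; uniform
sampling would make censoring events either vanishingly rare or
dominant). Each (sample, element) pair gets its own counter-keyed random
stream derived from the single global seed, so enlarging the element set
never perturbs draws already made for other elements.

What this generator does *not* emulate: spectral interferences, plasma
drift, internal-standard correction, or between-digestion recovery
variation. Synthetic panels exercise the pipeline's arithmetic and
censoring logic, not the instrument's failure modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ConcentrationValue, SampleRecord
from .digestion import (
    DEFAULT_DILUTION_FACTOR,
    InstrumentReading,
    back_calculate,
    forward_reading,
)
from .elements import PANEL, PANEL_INDEX
from .fixtures import protein_powder_panel, qc_recovery_controls

#: Serving masses (g) occurring in the packaged panel's metadata.
SERVING_MASS_CHOICES: tuple[float, ...] = (
    10.0, 25.0, 28.0, 28.5, 29.4, 30.0, 30.4, 33.0, 35.0, 42.0, 50.0, 60.0,
)

WEIGHED_MASS_RANGE_G = (0.41, 0.52)
NOMINAL_RETURNED_VOLUME_ML = 10.0
DEFAULT_UPPER_CALIBRATION = 50.0  # µg·L⁻¹, top calibration standard

#: Quantification limits in powder-equivalent units (µg·kg⁻¹), as printed
#: for the censored cells of the packaged panel.
DEFAULT_LOQ_LIMITS: dict[str, float] = {
    "Li": 17.4, "Be": 0.9, "Sn": 17.4, "Hg": 0.2, "Cd": 0.61,
    "Bi": 0.1, "V": 0.6,
}


def _observed_ranges() -> dict[str, tuple[float, float]]:
    """(min, max) of quantified values per element in the packaged panel."""
    ranges: dict[str, tuple[float, float]] = {}
    for record in protein_powder_panel():
        for el, c in record.concentrations.items():
            if c.value is None:
                continue
            if c.value <= 0:
                continue
            lo, hi = ranges.get(el, (c.value, c.value))
            ranges[el] = (min(lo, c.value), max(hi, c.value))
    return ranges


def _observed_rsds() -> dict[str, float]:
    """Median replicate RSD per element from the packaged QC batch."""
    rows: dict[str, list[float]] = {}
    for q in qc_recovery_controls():
        rows.setdefault(q.element, []).append(q.rsd)
    return {el: float(np.median(v)) for el, v in rows.items()}


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for one synthetic panel.

    Defaults mirror the packaged study: element set and concentration
    spans from the observed panel, quantification limits from its censored
    cells, noise RSDs from the QC batch, 0.001–50 µg·L⁻¹ calibration.
    """

    n_samples: int = 36
    elements: tuple[str, ...] = ()
    true_concentration_ranges: dict[str, tuple[float, float]] = field(
        default_factory=dict
    )
    loq_limits: dict[str, float] = field(default_factory=dict)
    upper_calibration: float = DEFAULT_UPPER_CALIBRATION
    noise_rsd: dict[str, float] = field(default_factory=dict)
    dilution_factor: float = DEFAULT_DILUTION_FACTOR
    returned_volume: float = NOMINAL_RETURNED_VOLUME_ML
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for el in self.elements:
            if el not in PANEL_INDEX:
                raise ValueError(f"unknown element {el!r}")
        for el, (lo, hi) in self.true_concentration_ranges.items():
            if not (0 < lo <= hi):
                raise ValueError(f"{el}: range must satisfy 0 < min <= max")
        for el, loq in self.loq_limits.items():
            if loq < 0:
                raise ValueError(f"{el}: loq must be >= 0")
        for el, rsd in self.noise_rsd.items():
            if rsd < 0:
                raise ValueError(f"{el}: noise_rsd must be >= 0")

    def resolved(self) -> "GeneratorSpec":
        """Fill empty fields from the packaged study's observed values."""
        ranges = dict(self.true_concentration_ranges) or _observed_ranges()
        elements = self.elements or tuple(
            el for el in PANEL if el in ranges
        )
        missing = [el for el in elements if el not in ranges]
        if missing:
            raise ValueError(f"no concentration range for elements: {missing}")
        loq = self.loq_limits if self.loq_limits else dict(DEFAULT_LOQ_LIMITS)
        rsd = dict(self.noise_rsd) if self.noise_rsd else _observed_rsds()
        return GeneratorSpec(
            n_samples=self.n_samples,
            elements=elements,
            true_concentration_ranges=ranges,
            loq_limits=loq,
            upper_calibration=self.upper_calibration,
            noise_rsd=rsd,
            dilution_factor=self.dilution_factor,
            returned_volume=self.returned_volume,
            seed=self.seed,
        )


def _stream(seed: int, sample_idx: int, element_idx: int | None) -> np.random.Generator:
    # Counter-keyed: one independent stream per (sample, element); the
    # sample-level stream uses element slot len(PANEL), outside any element.
    key = (sample_idx, len(PANEL) if element_idx is None else element_idx)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def generate_panel(
    spec: GeneratorSpec,
) -> tuple[pd.DataFrame, list[SampleRecord], list[tuple[str, InstrumentReading]]]:
    """Simulate a panel: truth table, censored records, instrument readings.

    Returns
    -------
    truth : DataFrame
        sample_id-indexed true powder concentrations (µg·kg⁻¹).
    records : list of SampleRecord
        What an analyst would report after censoring.
    readings : list of (sample_id, InstrumentReading)
        Noisy solution-level readings, one per sample × element.
    """
    spec = spec.resolved()
    if not spec.elements:
        raise ValueError("element set must not be empty")

    truth_rows = []
    records: list[SampleRecord] = []
    readings: list[tuple[str, InstrumentReading]] = []
    for i in range(spec.n_samples):
        sid = f"S{i + 1}"
        srng = _stream(spec.seed, i, None)
        weighed_g = srng.uniform(*WEIGHED_MASS_RANGE_G)
        serving_g = float(srng.choice(SERVING_MASS_CHOICES))
        weighed_kg = weighed_g / 1000.0

        truth: dict[str, float] = {}
        concentrations: dict[str, ConcentrationValue] = {}
        for el in spec.elements:
            rng = _stream(spec.seed, i, PANEL_INDEX[el])
            lo, hi = spec.true_concentration_ranges[el]
            true_c = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            truth[el] = true_c

            c_inst_true = forward_reading(
                true_c, spec.dilution_factor, spec.returned_volume, weighed_kg
            )
            rsd = spec.noise_rsd.get(el, 0.0)
            noisy = c_inst_true * (1.0 + rng.normal(0.0, rsd / 100.0))
            noisy = max(noisy, 0.0)
            reading = InstrumentReading(
                element=el,
                c_inst=noisy,
                returned_volume=spec.returned_volume,
                weighed_mass=weighed_kg,
                dilution_factor=spec.dilution_factor,
            )
            readings.append((sid, reading))

            if noisy > spec.upper_calibration:
                concentrations[el] = ConcentrationValue.above_range()
                continue
            c_final = back_calculate(reading)
            loq = spec.loq_limits.get(el, 0.0)
            if c_final < loq:
                concentrations[el] = ConcentrationValue.below_limit(loq)
            else:
                concentrations[el] = ConcentrationValue.quantified(c_final)

        truth_rows.append({"sample_id": sid} | truth)
        records.append(
            SampleRecord(
                sample_id=sid,
                protein_type="synthetic",
                serving_mass=serving_g,
                weighed_mass=weighed_g,
                returned_volume=spec.returned_volume,
                concentrations=concentrations,
            )
        )
    truth_df = pd.DataFrame(truth_rows).set_index("sample_id")
    return truth_df, records, readings


def write_simulation(spec: GeneratorSpec, out_dir) -> None:
    """Write panel.csv, meta.csv, readings.csv and truth.csv for a spec."""
    from pathlib import Path

    from .io import write_panel

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth, records, readings = generate_panel(spec)
    write_panel(records, out / "panel.csv", out / "meta.csv")
    truth.to_csv(out / "truth.csv")
    pd.DataFrame(
        [
            {
                "sample_id": sid,
                "element": r.element,
                "c_inst_ug_per_L": r.c_inst,
                "df": r.dilution_factor,
                "returned_volume_ml": r.returned_volume,
                "weighed_mass_g": r.weighed_mass * 1000.0,
            }
            for sid, r in readings
        ]
    ).to_csv(out / "readings.csv", index=False)
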