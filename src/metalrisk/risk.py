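"""Exposure and health-risk arithmetic.

The screening chain for one element in one powder sample is:

    EDI = C × (m_serving × k) / BW        µg per kg body weight per day
    HQ  = EDI / RfD                       non-carcinogenic hazard quotient
    HI  = Σ HQ  over the additive list    hazard index
    CR  = slope-factor transform of EDI   lifetime incremental cancer risk

with C the powder concentration (µg·kg⁻¹, censor-resolved), m_serving the
serving mass in kg, k the daily serving count and BW the consumer body
weight (70 kg default). HI sums HQs over a fixed 15-element additive list
(Li, Be, Mo, Cd, Sn, Ba, Hg, Tl, Pb, Al, V, Mn, Fe, Co, Cu); carcinogenic
risk covers Be, Cd and Pb. Elements whose concentration is above-range, or
which lack the needed reference constant, contribute nothing and are
flagged as excluded rather than silently imputed.

The slope-factor transform is applied under one of two conventions (see
:class:`metalrisk.core.CRConvention`): the default ``table_match`` divides
the intake by the slope-factor constant; ``literal`` multiplies. They
differ by a factor CSF² and every report names the mode in force.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import (
    EXCLUDED,
    AssessmentConfig,
    CensorPolicy,
    CRConvention,
    SampleRecord,
    apply_censor_policy,
)
from .core import ToxReference

G_PER_KG = 1000.0

HI_THRESHOLD = 1.0
CR_THRESHOLD = 1e-4


@dataclass(frozen=True)
class ExposureResult:
    """EDI/HQ/CR for one sample × element × serving count.

    ``excluded`` is True when no number could be produced (above-range
    concentration, or missing RfD/CSF for the requested metric); the
    numeric fields are then None.
    """

    sample_id: str
    element: str
    servings: int
    edi: float | None
    hq: float | None = None
    cr: float | None = None
    policy_used: CensorPolicy = CensorPolicy.ZERO
    excluded: bool = False


def compute_edi(
    c_final: float, serving_mass: float, servings: int = 1, body_weight: float = 70.0
) -> float:
    """Estimated daily intake, µg per kg body weight per day.

    ``serving_mass`` is in grams; the g→kg conversion happens here and
    nowhere else.
    """
    if serving_mass <= 0:
        raise ValueError("serving_mass must be > 0")
    if body_weight <= 0:
        raise ValueError("body_weight must be > 0")
    if servings < 1:
        raise ValueError("servings must be >= 1")
    intake_kg_per_day = serving_mass / G_PER_KG * servings
    return c_final * intake_kg_per_day / body_weight


def compute_hq(edi: float, rfd: float) -> float:
    """Hazard quotient EDI/RfD; > 1 flags potential non-cancer risk."""
    if rfd <= 0:
        raise ValueError("rfd must be > 0")
    return edi / rfd


def compute_cr(
    edi: float, csf: float, convention: CRConvention | str = CRConvention.TABLE_MATCH
) -> float:
    """Lifetime incremental cancer risk from chronic intake.

    ``table_match`` (default): EDI / CSF. ``literal``: EDI × CSF.
    """
    if csf <= 0:
        raise ValueError("csf must be > 0")
    convention = CRConvention(convention)
    if convention is CRConvention.TABLE_MATCH:
        return edi / csf
    return edi * csf


def compute_exposures(
    sample: SampleRecord,
    refs: dict[str, ToxReference],
    config: AssessmentConfig,
) -> list[ExposureResult]:
    """Per-element exposure rows for one sample under one scenario."""
    rows: list[ExposureResult] = []
    for element, conc in sample.concentrations.items():
        ref = refs.get(element)
        resolved = apply_censor_policy(
            conc, config.censor_policy, config.above_range_policy
        )
        if resolved is EXCLUDED:
            rows.append(
                ExposureResult(
                    sample.sample_id,
                    element,
                    config.servings_per_day,
                    edi=None,
                    policy_used=config.censor_policy,
                    excluded=True,
                )
            )
            continue
        edi = compute_edi(
            resolved, sample.serving_mass, config.servings_per_day, config.body_weight
        )
        hq = (
            compute_hq(edi, ref.rfd)
            if ref is not None and ref.in_hi_list
            else None
        )
        cr = (
            compute_cr(edi, ref.csf, config.cr_convention)
            if ref is not None and ref.in_cr_list
            else None
        )
        rows.append(
            ExposureResult(
                sample.sample_id,
                element,
                config.servings_per_day,
                edi=edi,
                hq=hq,
                cr=cr,
                policy_used=config.censor_policy,
            )
        )
    return rows


def compute_hi(
    sample: SampleRecord,
    refs: dict[str, ToxReference],
    config: AssessmentConfig,
) -> float:
    """Hazard index: sum of available HQs over the additive element list.

    Excluded elements (above-range, censored-to-nothing, or absent from the
    sample) contribute zero to the sum.
    """
    return sum(
        r.hq for r in compute_exposures(sample, refs, config) if r.hq is not None
    )


def classify_hi(hi: float) -> str:
    """``elevated`` iff HI strictly exceeds 1, else ``low``."""
    if hi < 0:
        raise ValueError("hi must be >= 0")
    return "elevated" if hi > HI_THRESHOLD else "low"


def classify_cr(cr: float, threshold: float = CR_THRESHOLD) -> str:
    """``low`` iff CR ≤ threshold (inclusive), else ``elevated``."""
    if cr < 0:
        raise ValueError("cr must be >= 0")
    return "elevated" if cr > threshold else "low"


def percent_of_reference(edi: float, reference: float) -> float:
    """EDI as a percentage of a reference intake (RfD, RDA or UL)."""
    if reference <= 0:
        raise ValueError("reference must be > 0")
    return 100.0 * edi / reference


def risk_table(
    records: list[SampleRecord],
    refs: dict[str, ToxReference],
    config: AssessmentConfig,
    servings: tuple[int, ...] = (1, 3),
) -> pd.DataFrame:
    """Long-format per-sample risk table over the requested serving counts.

    Columns: sample_id, protein_type, servings, hi, hi_class,
    n_excluded (elements dropped from the HI sum), and one ``cr_<El>``
    plus ``cr_<El>_class`` pair per carcinogen-list element.
    """
    cr_elements = [el for el, ref in refs.items() if ref.in_cr_list]
    rows = []
    for record in records:
        for k in servings:
            cfg = AssessmentConfig(
                body_weight=config.body_weight,
                servings_per_day=k,
                censor_policy=config.censor_policy,
                above_range_policy=config.above_range_policy,
                cr_convention=config.cr_convention,
            )
            exposures = compute_exposures(record, refs, cfg)
            by_element = {r.element: r for r in exposures}
            hi = sum(r.hq for r in exposures if r.hq is not None)
            n_excluded = sum(
                1
                for r in exposures
                if r.excluded and refs.get(r.element) is not None
                and refs[r.element].in_hi_list
            )
            row = {
                "sample_id": record.sample_id,
                "protein_type": record.protein_type,
                "servings": k,
                "hi": hi,
                "hi_class": classify_hi(hi),
                "n_excluded": n_excluded,
            }
            for el in cr_elements:
                r = by_element.get(el)
                cr = r.cr if r is not None else None
                row[f"cr_{el}"] = cr
                row[f"cr_{el}_class"] = classify_cr(cr) if cr is not None else None
            rows.append(row)
    return pd.DataFrame(rows)


def count_exceedances(
    table: pd.DataFrame, metric: str, threshold: float, servings: int
) -> int:
    """Number of samples whose ``metric`` column strictly exceeds ``threshold``
    at the given serving count. ``metric`` is ``"hi"`` or ``"cr_<El>"``."""
    if metric not in table.columns:
        raise ValueError(f"unknown metric column {metric!r}")
    sub = table[table["servings"] == servings]
    return int((sub[metric] > threshold).sum())
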