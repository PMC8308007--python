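"""Model/Results interface over the risk arithmetic.

:class:`RiskAssessment` is built from a sample panel, a toxicological
reference set and an exposure scenario; ``fit()`` evaluates the full
EDI → HQ → HI and slope-factor risk chain for every sample at every
requested serving count and returns a :class:`RiskResults` carrying the
tables, classifications, exceedance counts and a ``summary()`` report.
The evaluation is deterministic — "fit" here means running the exposure
model over the data, not estimating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .core import AssessmentConfig, SampleRecord, ToxReference
from .fixtures import paper_fixture
from .io import load_panel, load_tox_reference
from .risk import (
    CR_THRESHOLD,
    HI_THRESHOLD,
    compute_exposures,
    count_exceedances,
    risk_table,
)


class RiskAssessment:
    """Dietary trace-element risk screen for a panel of powder samples.

    Parameters
    ----------
    records : list of SampleRecord
        The sample panel with censoring-aware concentrations.
    refs : dict of str to ToxReference
        Per-element RfD/CSF constants and risk-list memberships.
    config : AssessmentConfig
        Body weight, censoring and slope-factor convention. The serving
        count in the config is ignored in favour of ``servings``.
    servings : tuple of int
        Daily serving counts to evaluate (default 1 and 3).
    """

    def __init__(
        self,
        records: list[SampleRecord],
        refs: dict[str, ToxReference],
        config: AssessmentConfig | None = None,
        servings: tuple[int, ...] = (1, 3),
    ) -> None:
        if not records:
            raise ValueError("sample panel must not be empty")
        self.records = list(records)
        self.refs = dict(refs)
        self.config = config or AssessmentConfig()
        self.servings = tuple(servings)

    @classmethod
    def from_csv(
        cls,
        panel_path,
        metadata_path,
        tox_path=None,
        config: AssessmentConfig | None = None,
        servings: tuple[int, ...] = (1, 3),
    ) -> "RiskAssessment":
        """Build from the CSV interchange formats; packaged toxicological
        constants are used when ``tox_path`` is omitted."""
        records = load_panel(panel_path, metadata_path)
        if tox_path is None:
            from .fixtures import tox_reference

            refs = tox_reference()
        else:
            refs = load_tox_reference(tox_path)
        return cls(records, refs, config, servings)

    @classmethod
    def from_study(
        cls,
        config: AssessmentConfig | None = None,
        servings: tuple[int, ...] = (1, 3),
    ) -> "RiskAssessment":
        """Build on the packaged 36-sample study panel."""
        records, refs = paper_fixture()
        return cls(records, refs, config, servings)

    def fit(self) -> "RiskResults":
        table = risk_table(self.records, self.refs, self.config, self.servings)
        exposures = []
        for k in self.servings:
            cfg = replace(self.config, servings_per_day=k)
            for record in self.records:
                exposures.extend(compute_exposures(record, self.refs, cfg))
        exposure_df = pd.DataFrame(
            {
                "sample_id": e.sample_id,
                "element": e.element,
                "servings": e.servings,
                "edi": e.edi,
                "hq": e.hq,
                "cr": e.cr,
                "policy": e.policy_used.value,
                "excluded": e.excluded,
            }
            for e in exposures
        )
        return RiskResults(self, table, exposure_df)


@dataclass
class RiskResults:
    """Fitted risk tables with report formatting and exceedance queries."""

    model: RiskAssessment
    table: pd.DataFrame
    exposures: pd.DataFrame

    def hi_table(self) -> pd.DataFrame:
        """Wide hazard-index table: one row per sample, one column per
        serving count (values rounded to 3 decimals for reporting)."""
        wide = self.table.pivot_table(
            index=["sample_id", "protein_type"], columns="servings", values="hi",
            sort=False,
        )
        wide.columns = [f"hi_{k}_serving" for k in wide.columns]
        return wide.round(3).reset_index()

    def cr_table(self) -> pd.DataFrame:
        """Wide slope-factor risk table, 2-significant-figure scientific
        notation per carcinogen-list element and serving count."""
        cr_cols = [c for c in self.table.columns
                   if c.startswith("cr_") and not c.endswith("_class")]
        wide = self.table.pivot_table(
            index=["sample_id", "protein_type"], columns="servings",
            values=cr_cols, sort=False,
        )
        wide.columns = [f"{metric}_{k}_serving" for metric, k in wide.columns]
        formatted = wide.map(lambda v: f"{v:.1e}" if pd.notna(v) else "")
        return formatted.reset_index()

    def edi_summary(self) -> pd.DataFrame:
        """Per-element min/max EDI (µg per kg body weight per day) at one
        serving, over non-excluded samples."""
        sub = self.exposures[
            (self.exposures["servings"] == self.exposures["servings"].min())
            & ~self.exposures["excluded"]
        ]
        return (
            sub.groupby("element")["edi"]
            .agg(["min", "max", "count"])
            .rename(columns={"count": "n_samples"})
            .reset_index()
        )

    def exceedance_summary(
        self,
        hi_threshold: float = HI_THRESHOLD,
        cr_threshold: float = CR_THRESHOLD,
    ) -> pd.DataFrame:
        """Counts of samples above the HI and slope-factor risk thresholds
        per serving count."""
        rows = []
        cr_cols = [c for c in self.table.columns
                   if c.startswith("cr_") and not c.endswith("_class")]
        for k in self.model.servings:
            row = {
                "servings": k,
                f"n_hi_gt_{hi_threshold:g}": count_exceedances(
                    self.table, "hi", hi_threshold, k
                ),
            }
            for col in cr_cols:
                row[f"n_{col}_gt_{cr_threshold:g}"] = count_exceedances(
                    self.table, col, cr_threshold, k
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable report naming the scenario and conventions used."""
        cfg = self.model.config
        n_above_range = int(
            self.exposures[
                self.exposures["servings"] == self.model.servings[0]
            ]["excluded"].sum()
        )
        lines = [
            "Trace-element dietary risk screen",
            "=" * 49,
            f"samples: {len(self.model.records)}   "
            f"serving counts: {', '.join(map(str, self.model.servings))}",
            f"body weight: {cfg.body_weight:g} kg   "
            f"censoring: {cfg.censor_policy.value}   "
            f"slope-factor convention: {cfg.cr_convention.value}",
            f"above-range measurements excluded per scenario: {n_above_range}",
            "",
            "Hazard index (sum of HQ over the additive element list)",
            self.hi_table().to_string(index=False),
            "",
            "Cancer risk per carcinogen-list element",
            self.cr_table().to_string(index=False),
            "",
            "Exceedance counts",
            self.exceedance_summary().to_string(index=False),
        ]
        return "\n".join(lines)

    def to_csv(self, out_dir) -> None:
        """Write hi_table.csv, cr_table.csv and exceedance_summary.csv."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.hi_table().to_csv(out / "hi_table.csv", index=False)
        self.cr_table().to_csv(out / "cr_table.csv", index=False)
        self.exceedance_summary().to_csv(out / "exceedance_summary.csv", index=False)
        (out / "report.txt").write_text(self.summary() + "\n")
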