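"""Reading and writing the tabular interchange formats.

Concentration panel: one row per sample, one column per element; cells are
plain numbers, ``<X`` for left-censored values, or ``NR*`` for above-range.
Metadata and toxicological reference tables are ordinary CSV/TSV. All
parsing goes through pandas; censoring semantics are applied here, once.
"""

from __future__ import annotations

import math
from importlib import resources
from os import PathLike
from typing import IO

import pandas as pd

from .core import ConcentrationValue, SampleRecord, Status, ToxReference
from .elements import normalize_element

ABOVE_RANGE_TOKEN = "NR*"

_Readable = str | PathLike | IO[str]


def _read_table(source: _Readable) -> pd.DataFrame:
    sep = None
    if isinstance(source, (str, PathLike)) and str(source).endswith((".tsv", ".tab")):
        sep = "\t"
    return pd.read_csv(source, sep=sep if sep else ",", dtype=str).rename(
        columns=str.strip
    )


def parse_cell(text: str) -> ConcentrationValue:
    """Parse one concentration cell: number, ``<limit`` or ``NR*``."""
    s = str(text).strip()
    if s == ABOVE_RANGE_TOKEN or s.upper() == "NR":
        return ConcentrationValue.above_range()
    if s.startswith("<"):
        return ConcentrationValue.below_limit(float(s[1:]))
    return ConcentrationValue.quantified(float(s))


def format_cell(c: ConcentrationValue) -> str:
    if c.status is Status.ABOVE_RANGE:
        return ABOVE_RANGE_TOKEN
    if c.status is Status.BELOW_LIMIT:
        return f"<{c.limit:g}"
    return f"{c.value:g}"


def load_panel(
    concentration_table: _Readable, metadata_table: _Readable
) -> list[SampleRecord]:
    """Join a concentration panel with its sample metadata.

    Every sample row in the concentration table must have a metadata row;
    element columns are normalised from isotope labels to symbols.
    """
    conc = _read_table(concentration_table)
    meta = _read_table(metadata_table).set_index("sample_id")

    records: list[SampleRecord] = []
    element_cols = {col: normalize_element(col) for col in conc.columns[1:]}
    for _, row in conc.iterrows():
        sid = str(row.iloc[0]).strip()
        if sid not in meta.index:
            raise ValueError(f"sample {sid!r} missing from metadata table")
        m = meta.loc[sid]
        vol = m.get("returned_volume_ml")
        vol_f = float(vol) if vol is not None and not _isna(vol) else None
        concentrations = {
            sym: parse_cell(row[col]) for col, sym in element_cols.items()
        }
        records.append(
            SampleRecord(
                sample_id=sid,
                protein_type=str(m["protein_type"]).strip(),
                serving_mass=float(m["serving_mass_g"]),
                weighed_mass=float(m["weighed_mass_g"]),
                returned_volume=vol_f,
                concentrations=concentrations,
            )
        )
    return records


def _isna(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or pd.isna(v)


def write_panel(records: list[SampleRecord], conc_path, meta_path) -> None:
    """Write records back to the two-table interchange format (round-trip safe)."""
    elements = list(records[0].concentrations) if records else []
    conc_rows = []
    meta_rows = []
    for r in records:
        conc_rows.append(
            {"sample_id": r.sample_id}
            | {el: format_cell(r.concentrations[el]) for el in elements}
        )
        meta_rows.append(
            {
                "sample_id": r.sample_id,
                "protein_type": r.protein_type,
                "serving_mass_g": r.serving_mass,
                "weighed_mass_g": r.weighed_mass,
                "returned_volume_ml": r.returned_volume,
            }
        )
    pd.DataFrame(conc_rows).to_csv(conc_path, index=False)
    pd.DataFrame(meta_rows).to_csv(meta_path, index=False)


def load_tox_reference(source: _Readable) -> dict[str, ToxReference]:
    """Load per-element RfD/CSF/RDA/UL constants and list memberships."""
    df = _read_table(source)
    refs: dict[str, ToxReference] = {}
    for _, row in df.iterrows():
        el = normalize_element(row["element"])
        refs[el] = ToxReference(
            element=el,
            rfd=_opt_float(row.get("rfd_ug_per_kg_day")),
            csf=_opt_float(row.get("csf_per_ug_per_kg_day")),
            rda=_opt_float(row.get("rda_ug_day")),
            ul=_opt_float(row.get("ul_ug_day")),
            in_hi_list=_parse_bool(row.get("in_hi_list")),
            in_cr_list=_parse_bool(row.get("in_cr_list")),
        )
    return refs


def _opt_float(v) -> float | None:
    if _isna(v) or str(v).strip() in ("", "-"):
        return None
    return float(v)


def _parse_bool(v) -> bool:
    return str(v).strip().lower() in ("true", "1", "yes")


def packaged_data(name: str):
    """Context-manager path to a CSV packaged with the library."""
    return resources.as_file(resources.files("metalrisk.data").joinpath(name))
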