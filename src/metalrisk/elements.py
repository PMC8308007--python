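"""The 21-element analyte panel and isotope-label normalisation.

Element identity throughout the package is the bare chemical symbol.
Input tables may label columns with the measured isotope (``7Li``,
``208Pb``, unicode superscripts, or caret markup like ``^63^Cu``);
those aliases are normalised to symbols at ingestion and nowhere else.
"""

from __future__ import annotations

import re

# Panel order is fixed: it keys the per-element random streams of the
# synthetic generator, so appending (never reordering) is the only safe edit.
PANEL: tuple[str, ...] = (
    "Li", "Be", "Mo", "Cd", "Sn", "Ba", "Pt", "Au", "Hg", "Tl",
    "Pb", "Bi", "Mg", "Al", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Cu",
)

PANEL_INDEX: dict[str, int] = {sym: i for i, sym in enumerate(PANEL)}

_SUPERSCRIPTS = str.maketrans("⁰¹²³⁴⁵⁶⁷⁸⁹", "0123456789")

_ISOTOPE_RE = re.compile(r"^\^?(\d+)\^?\s*([A-Z][a-z]?)$")


def normalize_element(label: str) -> str:
    """Map an element or isotope label to its panel symbol.

    Accepts bare symbols (``Pb``), mass-number prefixes (``208Pb``,
    ``²⁰⁸Pb``, ``^208^Pb``) and surrounding whitespace/markup asterisks.

    Raises
    ------
    ValueError
        If the label does not resolve to a symbol in the 21-element panel.
    """
    s = label.strip().strip("*").replace("**", "").strip()
    s = s.translate(_SUPERSCRIPTS)
    m = _ISOTOPE_RE.match(s)
    if m:
        s = m.group(2)
    if s not in PANEL_INDEX:
        raise ValueError(f"unknown element column: {label!r}")
    return s
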