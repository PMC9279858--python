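"""Packaged summary tables.

The TERT-CLPTM1L table holds the 29 published significant association
summaries (variant, disease, group, printed OR with 95% CI, I², Venice
letters, FPRP and credibility label) used by the summary-mode grading
examples and the reproduction checks.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_PRINTED_LT = "<"


def parse_printed_p(text: str | float) -> float:
    """Numeric stand-in for a printed p-like value: '<0.001' -> 0.0005."""
    if isinstance(text, (int, float)):
        return float(text)
    text = text.strip().replace(" ", "")
    if text.startswith(_PRINTED_LT):
        return float(text[1:]) / 2.0
    return float(text)


def significant_associations() -> pd.DataFrame:
    """The 29 published significant TERT-CLPTM1L association summaries."""
    with resources.files("credmeta.data").joinpath(
        "tert_clptm1l_significant.csv"
    ).open() as fh:
        frame = pd.read_csv(fh, dtype={"p": str, "p_q": str, "fprp": str})
    frame["fprp_numeric"] = frame["fprp"].map(parse_printed_p)
    return frame
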