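"""Semi-quantitative immunohistochemistry scoring.

The score of a stained section is the product of a percent-positivity bin
(0–4: 0%, 1–10%, 11–50%, 51–80%, >80%) and a staining-intensity bin (0–3:
none, weak, moderate, strong), so it ranges over {0..4}×{0..3} products.
Group contrasts (e.g. multiple-primary vs metastatic vs solitary tumors,
or tumor vs matched normal) use the unpaired two-sided rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de import rank_sum_test

INTENSITY_BINS = {"none": 0, "weak": 1, "moderate": 2, "strong": 3}


def positivity_bin(fraction: float) -> int:
    """Bin a positivity fraction into the printed 0–4 percent bins.

    Fractions are rounded half-up to the nearest integer percent first, so
    the closed integer ranges 0, 1–10, 11–50, 51–80, >80 are exhaustive.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"positivity fraction {fraction} outside [0, 1]")
    percent = int(np.floor(fraction * 100.0 + 0.5))
    if percent == 0:
        return 0
    if percent <= 10:
        return 1
    if percent <= 50:
        return 2
    if percent <= 80:
        return 3
    return 4


def intensity_bin(grade: str) -> int:
    """Map a staining-intensity grade to its 0–3 bin."""
    try:
        return INTENSITY_BINS[str(grade).lower()]
    except KeyError:
        raise ValueError(
            f"unknown intensity grade {grade!r}; expected one of "
            f"{sorted(INTENSITY_BINS)}"
        ) from None


def ihc_score(positivity: float, intensity: str) -> int:
    """Product of positivity and intensity bins (0–12)."""
    return positivity_bin(positivity) * intensity_bin(intensity)


@dataclass
class IHCRecord:
    """One scored section."""

    sample: str
    group: str  # e.g. MPLC / IPM / solitary
    tissue: str  # tumor / normal
    positivity: float
    intensity: str
    score: int = field(init=False)

    def __post_init__(self) -> None:
        self.score = ihc_score(self.positivity, self.intensity)


def records_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": r.sample,
                "group": r.group,
                "tissue": r.tissue,
                "positivity": r.positivity,
                "intensity": r.intensity,
                "score": r.score,
            }
            for r in records
        ]
    )


def group_compare(records, pairs=None) -> pd.DataFrame:
    """Unpaired two-sided rank-sum contrasts of IHC scores.

    Default contrasts: every unordered group pair on tumor tissue, plus
    tumor-vs-normal within each group. ``records`` is a list of
    :class:`IHCRecord` or an equivalent DataFrame.
    """
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    rows = []
    groups = sorted(df["group"].unique())
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    for a, b in pairs:
        xa = df.query("group == @a and tissue == 'tumor'")["score"]
        xb = df.query("group == @b and tissue == 'tumor'")["score"]
        rows.append(_contrast(f"{a} vs {b} (tumor)", xa, xb))
    for g in groups:
        xt = df.query("group == @g and tissue == 'tumor'")["score"]
        xn = df.query("group == @g and tissue == 'normal'")["score"]
        if len(xn):
            rows.append(_contrast(f"{g}: tumor vs normal", xt, xn))
    return pd.DataFrame(rows).set_index("comparison")


def _contrast(name: str, xa: pd.Series, xb: pd.Series) -> dict:
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError(f"contrast {name!r}: degenerate group")
    return {
        "comparison": name,
        "n_a": len(xa),
        "n_b": len(xb),
        "median_a": float(xa.median()),
        "median_b": float(xb.median()),
        "p_value": rank_sum_test(xa.to_numpy(), xb.to_numpy()),
    }
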