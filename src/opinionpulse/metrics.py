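"""Opinion Polarity Ratio (OPR) and trend ratios.

OPR(s) for a topic s in a period is the ratio of negative to positive post
counts, with additive smoothing δ applied only when the positive count is
zero:

    OPR = n⁻ / n⁺                 if n⁺ ≠ 0
    OPR = (n⁻ + δ) / (n⁺ + δ)     if n⁺ = 0,   0 < δ ≤ 1

``always_smooth=True`` applies the smoothed form unconditionally (a common
variant).  Series are binned by calendar year; neutral posts enter neither
count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["MetricsError", "OprInput", "opr", "opr_series", "trend_ratio"]


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class OprInput:
    n_pos: int
    n_neg: int
    delta: float = 1.0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise MetricsError("counts must be non-negative")
        if not 0.0 < self.delta <= 1.0:
            raise MetricsError(f"delta must lie in (0, 1], got {self.delta}")


def opr(x: OprInput, always_smooth: bool = False) -> float:
    """Opinion polarity ratio with the zero-denominator smoothing branch."""
    if x.n_pos != 0 and not always_smooth:
        return x.n_neg / x.n_pos
    return (x.n_neg + x.delta) / (x.n_pos + x.delta)


def opr_series(
    stances: Mapping[str, str] | Iterable[tuple[str, str]],
    timestamps: Mapping[str, str],
    delta: float = 1.0,
    always_smooth: bool = False,
) -> pd.DataFrame:
    """Yearly OPR series from per-post stance labels.

    ``stances`` maps post id → label in {pos, neg, neu}; ``timestamps`` maps
    post id → ISO-8601 timestamp.  Years between the first and last observed
    year are emitted even when empty (counts 0/0, smoothed OPR).
    """
    items = stances.items() if isinstance(stances, Mapping) else list(stances)
    counts: dict[int, list[int]] = {}
    for pid, lab in items:
        year = int(str(timestamps[pid])[:4])
        c = counts.setdefault(year, [0, 0])
        if lab == "pos":
            c[0] += 1
        elif lab == "neg":
            c[1] += 1
    if not counts:
        return pd.DataFrame(columns=["year", "n_pos", "n_neg", "opr"])
    rows = []
    for year in range(min(counts), max(counts) + 1):
        n_pos, n_neg = counts.get(year, [0, 0])
        rows.append(
            {
                "year": year,
                "n_pos": n_pos,
                "n_neg": n_neg,
                "opr": opr(OprInput(n_pos, n_neg, delta), always_smooth=always_smooth),
            }
        )
    return pd.DataFrame(rows)


def trend_ratio(values: Sequence[float] | pd.Series | pd.DataFrame, column: str = "opr") -> float:
    """Last-period over first-period ratio of a positive series."""
    if isinstance(values, pd.DataFrame):
        values = values[column]
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise MetricsError("trend ratio needs at least two periods")
    if arr[0] == 0:
        raise MetricsError("first period value is zero")
    return float(arr[-1] / arr[0])
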