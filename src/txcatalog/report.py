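"""Report arithmetic: the percentage/summation bookkeeping used in the
catalogue summary tables."""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

__all__ = ["percentage", "fold_change", "summed_total"]


def percentage(part: float, whole: float, digits: int = 1) -> float:
    """``part / whole`` as a percentage rounded to *digits* decimals."""
    if whole == 0:
        raise ZeroDivisionError("percentage of an empty total")
    return round(100.0 * part / whole, digits)


def fold_change(a: float, b: float, digits: int = 1) -> float:
    """Ratio a/b rounded to *digits* decimals."""
    if b == 0:
        raise ZeroDivisionError("fold change over zero")
    return round(a / b, digits)


def summed_total(parts: Sequence[float]) -> float:
    return sum(parts)
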