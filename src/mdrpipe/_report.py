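"""Small report-formatting helpers shared by the pipeline and CLI."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def percent(numerator: float, denominator: float) -> float:
    """Percentage rounded to one decimal, half-up (printed-report style)."""
    if denominator == 0:
        raise ValueError("denominator must be positive")
    value = Decimal(str(numerator)) * 100 / Decimal(str(denominator))
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def format_cvc(cvc: int, n_folds: int) -> str:
    return f"{cvc}/{n_folds}"


def format_ba_percent(ba: float) -> str:
    return f"{100 * ba:.2f}%"
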