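"""Summary tables with a fixed percentage-rounding contract.

All percentage cells are computed as 100 * count / denominator and rounded
half away from zero to two decimals, so every printed percentage is exactly
re-derivable from its integer counts.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .errors import InputError

INHERITANCE_ORDER = ("F1a", "F1b_P1", "F1b_P2", "F1c", "F1d_over", "F1d_under")


def percent(count: int, denominator: int) -> float:
    """100*count/denominator rounded half away from zero to 2 decimals."""
    if denominator <= 0:
        raise InputError("percentage denominator must be positive")
    if count < 0:
        raise InputError("count must be non-negative")
    value = Decimal(100 * count) / Decimal(denominator)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def format_percent(count: int, denominator: int | None) -> str:
    """Two-decimal percentage string; an em dash when undefined."""
    if denominator is None or denominator == 0:
        return "—"
    return f"{percent(count, denominator):.2f}%"


def inheritance_table(calls: pd.DataFrame, overall: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-tissue (plus overall) counts and percentages of inheritance modes.

    Ambiguous calls are excluded; percentages are over each row's
    classified total.  All-zero rows are suppressed.
    """
    rows = []
    for tissue in sorted(calls["tissue"].unique()) if not calls.empty else []:
        sub = calls[calls["tissue"] == tissue]
        rows.append(_inheritance_row(tissue, sub))
    if overall is not None and not overall.empty:
        rows.append(_inheritance_row("Overall", overall))
    rows = [r for r in rows if r is not None]
    columns = ["tissue", "n_classified"]
    for cat in INHERITANCE_ORDER:
        columns += [f"n_{cat}", f"pct_{cat}"]
    return pd.DataFrame(rows, columns=columns)


def _inheritance_row(label: str, calls: pd.DataFrame) -> dict | None:
    counted = calls[calls["category"] != "ambiguous"]
    total = len(counted)
    if total == 0:
        return None
    row: dict = {"tissue": label, "n_classified": total}
    for cat in INHERITANCE_ORDER:
        n = int((counted["category"] == cat).sum())
        row[f"n_{cat}"] = n
        row[f"pct_{cat}"] = percent(n, total)
    return row


def hybrid_specific_fraction(venn: dict, hybrid: str = "hybrid") -> float:
    """Percentage of groups unique to the hybrid, over the union of groups."""
    key = f"only_{hybrid}"
    if key not in venn or "union" not in venn:
        raise InputError(f"venn counts lack {key!r} or 'union'")
    return percent(venn[key], venn["union"])


def format_table(table: pd.DataFrame) -> str:
    """Aligned plain-text rendering of a summary table."""
    return table.to_string(index=False)
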