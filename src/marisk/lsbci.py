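"""Liner Shipping Bilateral Connectivity Index (LSBCI) construction.

The LSBCI of a country pair summarizes five indicators of liner-service
connectivity: the number of transshipments needed between the pair, the
number of third countries with direct routes to both, the number of
common one-transshipment connections, carrier competition on the route,
and the size of the largest ship on the route with the fewest carriers.
Each indicator is min-max normalized across all pairs in the table and
the index is the simple average of the five normalized values, so every
LSBCI lies in [0, 1].

Orientation: a connectivity index must reward direct connections, so
the transshipment count is inverted by default (fewer transshipments =
better connectivity); the other four indicators count positively.  The
published index's exact convention is not public, so the orientation
map is fully configurable.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import INDICATOR_COLUMNS, SymmetricMatrix, ValidationError

__all__ = [
    "DEFAULT_ORIENTATIONS",
    "DegenerateRangeWarning",
    "normalize_indicator",
    "compute_lsbci",
]

#: Default per-indicator orientation: transshipments are a cost, the rest
#: are benefits.
DEFAULT_ORIENTATIONS: dict[str, str] = {
    "transshipments": "lower_better",
    "common_direct": "higher_better",
    "common_one_tranship": "higher_better",
    "competition": "higher_better",
    "max_ship_size": "higher_better",
}

_ORIENTATIONS = ("higher_better", "lower_better")


class DegenerateRangeWarning(UserWarning):
    """An indicator column with max == min normalizes to all zeros."""


def normalize_indicator(values: Sequence[float], orientation: str = "higher_better") -> np.ndarray:
    """Min-max normalize one indicator column to [0, 1].

    ``(x - min) / (max - min)`` for ``higher_better``; one minus that for
    ``lower_better``.  A degenerate column (max == min) maps to all
    zeros and emits :class:`DegenerateRangeWarning` — deterministic,
    bounded and explicit.
    """
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"unknown orientation: {orientation!r}")
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot normalize an empty indicator column")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("non-finite value in indicator column")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        warnings.warn(
            f"degenerate indicator range (all values == {lo}); normalized to 0",
            DegenerateRangeWarning,
            stacklevel=2,
        )
        return np.zeros_like(arr)
    scaled = (arr - lo) / (hi - lo)
    return 1.0 - scaled if orientation == "lower_better" else scaled


def compute_lsbci(
    table: pd.DataFrame,
    orientations: Mapping[str, str] | None = None,
    indicator_columns: Iterable[str] = INDICATOR_COLUMNS,
) -> SymmetricMatrix:
    """Compute the LSBCI for every pair in a raw indicator table.

    Parameters
    ----------
    table
        One row per unordered pair with columns ``origin``, ``partner``
        and the five indicator columns (as produced by
        ``read_pair_table(..., kind="indicators")``).
    orientations
        Per-indicator orientation map; defaults to
        :data:`DEFAULT_ORIENTATIONS`.

    Notes
    -----
    The normalization population is the full supplied pair table: each
    indicator's min and max are taken across all pairs, then the pair's
    LSBCI is the mean of its five normalized values.
    """
    if len(table) == 0:
        raise ValueError("empty indicator table")
    orientations = dict(orientations or DEFAULT_ORIENTATIONS)
    cols = list(indicator_columns)
    normalized = np.column_stack(
        [
            normalize_indicator(table[c].to_numpy(), orientations.get(c, "higher_better"))
            for c in cols
        ]
    )
    lsbci = normalized.mean(axis=1)
    out = SymmetricMatrix()
    for (o, p), v in zip(zip(table["origin"], table["partner"]), lsbci):
        out.set(o, p, float(v))
    return out
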