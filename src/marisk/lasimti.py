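"""LASIMTI: likelihood of *An. stephensi* introduction through maritime trade.

For a target country and one source country the index is

    LASIMTI = LSBCI / days at sea

i.e. bilateral shipping connectivity discounted by transit time (longer
voyages give desiccation and mortality more time to act on stowaway
eggs and larvae).  A target's risk score is the sum of LASIMTI over all
source-population countries, and targets are ranked by that sum, either
alone or combined with a per-country Habitat Suitability Index (HSI)
that captures the likelihood of establishment after introduction.

Missing country pairs contribute zero to the sum rather than raising:
real connectivity tables are sparse (some countries have no recorded
liner service), and a missing pair genuinely carries no measured trade.
Every skipped pair is logged.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable

import pandas as pd

from .data_io import SymmetricMatrix

__all__ = [
    "compute_lasimti",
    "sum_lasimti",
    "rank_by_lasimti",
    "rank_with_hsi",
    "STRATEGIES",
]

logger = logging.getLogger(__name__)

#: Supported HSI combination strategies.
STRATEGIES = ("hsi_then_lasimti", "product")


def compute_lasimti(lsbci: float, days: float) -> float:
    """LSBCI divided by days at sea; zero iff connectivity is zero."""
    if days <= 0:
        raise ValueError(f"days at sea must be > 0, got {days}")
    return lsbci / days


def sum_lasimti(
    target: str,
    sources: Iterable[str],
    conn: SymmetricMatrix,
    times: SymmetricMatrix,
) -> float:
    """Sum LASIMTI from every source country into ``target``.

    Only pairs present in *both* the connectivity and transit-time
    tables contribute; incomplete pairs add zero and are logged.  A
    target with no complete pair at all returns 0.0 with a warning.
    """
    sources = set(sources)
    if target in sources:
        raise ValueError(f"target {target} is itself a source population")
    total = 0.0
    complete = 0
    for s in sorted(sources):
        lsbci = conn.get(target, s)
        days = times.get(target, s)
        if lsbci is None or days is None:
            logger.warning(
                "pair %s-%s missing from %s table; contributes 0 to the LASIMTI sum",
                target, s, "connectivity" if lsbci is None else "transit-time",
            )
            continue
        total += compute_lasimti(lsbci, days)
        complete += 1
    if complete == 0:
        logger.warning("target %s has no complete pair with any source; sum is 0", target)
    return total


def _assign_ranks(df: pd.DataFrame, by: list[str], ascending: list[bool]) -> pd.DataFrame:
    df = df.sort_values(by=by, ascending=ascending, kind="mergesort").reset_index(drop=True)
    df["rank"] = range(1, len(df) + 1)
    return df


def rank_by_lasimti(
    targets: Iterable[str],
    sources: Iterable[str],
    conn: SymmetricMatrix,
    times: SymmetricMatrix,
) -> pd.DataFrame:
    """Rank target countries by their LASIMTI sum over the sources.

    Returns a risk table with columns ``country``, ``lasimti_sum`` and
    ``rank`` (1 = highest risk).  Exact ties are broken alphabetically
    by country code so output files are reproducible.
    """
    targets = sorted(set(targets))
    if not targets:
        raise ValueError("empty target set")
    sources = frozenset(sources)
    overlap = sources.intersection(targets)
    if overlap:
        raise ValueError(f"targets overlap sources: {sorted(overlap)}")
    df = pd.DataFrame(
        {
            "country": targets,
            "lasimti_sum": [sum_lasimti(t, sources, conn, times) for t in targets],
        }
    )
    return _assign_ranks(df, by=["lasimti_sum", "country"], ascending=[False, True])


def rank_with_hsi(
    table: pd.DataFrame,
    hsi: pd.DataFrame,
    strategy: str = "hsi_then_lasimti",
) -> pd.DataFrame:
    """Re-rank a LASIMTI risk table using the Habitat Suitability Index.

    Strategies
    ----------
    ``hsi_then_lasimti`` (default)
        Lexicographic: rank by HSI descending, LASIMTI sum as the
        tiebreaker.
    ``product``
        Composite score ``lasimti_sum * hsi``, ranked descending.

    Countries without an HSI value cannot be scored for establishment
    and are placed after every HSI-bearing country under both
    strategies, ordered among themselves by LASIMTI sum.  Remaining
    ties break alphabetically.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if "lasimti_sum" not in table.columns:
        raise ValueError("risk table lacks lasimti_sum; run rank_by_lasimti first")
    hsi_map = dict(zip(hsi["country"], hsi["hsi"]))
    df = table.drop(columns=["rank"], errors="ignore").copy()
    df["hsi"] = [hsi_map.get(c, float("nan")) for c in df["country"]]
    missing = df["hsi"].isna()
    if strategy == "product":
        df["composite"] = df["lasimti_sum"] * df["hsi"]
        primary = "composite"
    else:
        df["composite"] = float("nan")
        primary = "hsi"
    # Missing-HSI countries sort last regardless of their LASIMTI sum.
    df["_missing"] = missing.astype(int)
    df["_primary"] = df[primary].where(~missing, -math.inf)
    df = _assign_ranks(
        df,
        by=["_missing", "_primary", "lasimti_sum", "country"],
        ascending=[True, False, False, True],
    )
    return df.drop(columns=["_missing", "_primary"])
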