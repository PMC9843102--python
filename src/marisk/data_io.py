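"""Readers, writers and validation for the pipeline's tabular inputs.

All bilateral tables (connectivity indicators, LSBCI values, days at
sea) are *unordered* country-pair tables: the quantities are properties
of the pair, not of a direction of travel.  Direction only appears in
the constructed trade network.  Files are UTF-8 CSV with a mandatory
header row and decimal points.
"""

from __future__ import annotations

import json
import math
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .countries import canonical_code

__all__ = [
    "SchemaError",
    "ValidationError",
    "SymmetricMatrix",
    "INDICATOR_COLUMNS",
    "read_pair_table",
    "read_hsi_table",
    "read_sources",
    "write_rank_table",
    "read_rank_table",
    "export_graph",
]


class SchemaError(ValueError):
    """A required column is missing or a file's layout is wrong."""


class ValidationError(ValueError):
    """A row violates a value-level invariant (self-pair, negative, ...)."""


#: Raw LSBCI indicator columns, in canonical order.
INDICATOR_COLUMNS = (
    "transshipments",
    "common_direct",
    "common_one_tranship",
    "competition",
    "max_ship_size",
)

_VALUE_COLUMNS = {
    "lsbci": ("value",),
    "days": ("value",),
    "indicators": INDICATOR_COLUMNS,
}


class SymmetricMatrix:
    """Symmetric country-pair -> value mapping; absent pairs mean no data.

    Used for connectivity (LSBCI in [0,1]) and transit times (days > 0).
    Keys are stored under the sorted pair, so ``get(j, k) == get(k, j)``.
    """

    def __init__(self, data: dict[tuple[str, str], float] | None = None):
        self._d: dict[tuple[str, str], float] = {}
        if data:
            for (a, b), v in data.items():
                self.set(a, b, v)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        if a == b:
            raise ValidationError(f"self-pair not allowed: {a}")
        return (a, b) if a < b else (b, a)

    def set(self, a: str, b: str, value: float) -> None:
        self._d[self._key(a, b)] = float(value)

    def get(self, a: str, b: str, default: float | None = None) -> float | None:
        return self._d.get(self._key(a, b), default)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self._key(*pair) in self._d

    def __len__(self) -> int:
        return len(self._d)

    def pairs(self) -> Iterator[tuple[str, str, float]]:
        """Iterate (a, b, value) with a < b, in sorted pair order."""
        for (a, b) in sorted(self._d):
            yield a, b, self._d[(a, b)]

    def countries(self) -> list[str]:
        seen: set[str] = set()
        for a, b in self._d:
            seen.add(a)
            seen.add(b)
        return sorted(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a, b, v) for a, b, v in self.pairs()],
            columns=["origin", "partner", "value"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, value_col: str = "value") -> "SymmetricMatrix":
        m = cls()
        for row in df.itertuples(index=False):
            m.set(getattr(row, "origin"), getattr(row, "partner"), getattr(row, value_col))
        return m


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_pair_table(path, kind: str) -> pd.DataFrame:
    """Read and validate a bilateral country-pair CSV.

    Parameters
    ----------
    path
        CSV with header ``origin,partner,value`` (kind ``lsbci`` or
        ``days``) or ``origin,partner,<five indicator columns>``
        (kind ``indicators``).  Country fields may be alpha-3 codes or
        registered English names.
    kind
        One of ``{"indicators", "lsbci", "days"}``; sets the required
        columns and the value constraints (days must be > 0, all values
        must be finite and >= 0).

    Returns
    -------
    DataFrame with canonical codes, ``origin < partner`` per row, one row
    per unordered pair.  Symmetric duplicates with equal values are
    deduplicated; conflicting duplicates raise :class:`ValidationError`.
    """
    if kind not in _VALUE_COLUMNS:
        raise ValueError(f"unknown pair-table kind: {kind!r}")
    value_cols = list(_VALUE_COLUMNS[kind])
    df = pd.read_csv(path)
    _require_columns(df, ["origin", "partner", *value_cols], path)

    records: dict[tuple[str, str], tuple[float, ...]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        origin = canonical_code(getattr(row, "origin"))
        partner = canonical_code(getattr(row, "partner"))
        if origin == partner:
            raise ValidationError(f"{path}: line {i}: self-pair {origin}")
        values = []
        for col in value_cols:
            v = getattr(row, col)
            try:
                v = float(v)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: line {i}: non-numeric {col}={v!r}"
                ) from None
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{path}: line {i}: {col}={v} must be finite and >= 0")
            if kind == "days" and v <= 0:
                raise ValidationError(f"{path}: line {i}: days must be > 0, got {v}")
            values.append(v)
        key = (origin, partner) if origin < partner else (partner, origin)
        vt = tuple(values)
        if key in records:
            if records[key] != vt:
                raise ValidationError(
                    f"{path}: line {i}: conflicting duplicate for pair {key[0]}-{key[1]}"
                )
            continue  # symmetric duplicate with equal values: deduplicate
        records[key] = vt

    out = pd.DataFrame(
        [(a, b, *v) for (a, b), v in sorted(records.items())],
        columns=["origin", "partner", *value_cols],
    )
    return out


def read_hsi_table(path) -> pd.DataFrame:
    """Read a per-country Habitat Suitability Index CSV (``country,hsi``).

    HSI must lie in [0,1]; an empty cell means no HSI is available for
    that country (kept as NaN, handled explicitly by the ranking).
    """
    df = pd.read_csv(path)
    _require_columns(df, ["country", "hsi"], path)
    codes, values = [], []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        code = canonical_code(getattr(row, "country"))
        v = getattr(row, "hsi")
        v = float(v) if v == v and str(v).strip() != "" else float("nan")
        if v == v and not 0.0 <= v <= 1.0:
            raise ValidationError(f"{path}: line {i}: hsi={v} outside [0,1]")
        codes.append(code)
        values.append(v)
    if len(set(codes)) != len(codes):
        raise ValidationError(f"{path}: duplicate country in HSI table")
    return pd.DataFrame({"country": codes, "hsi": values})


def read_sources(spec) -> frozenset[str]:
    """Parse a source-population set from a comma list or a text file.

    Accepts ``"DJI,SDN"``, an iterable of tokens, or a path to a file
    with one country per line.
    """
    if isinstance(spec, (list, tuple, set, frozenset)):
        tokens = list(spec)
    else:
        text = str(spec)
        p = Path(text)
        if p.is_file():
            tokens = [ln for ln in p.read_text(encoding="utf-8").splitlines() if ln.strip()]
        else:
            tokens = [t for t in text.split(",") if t.strip()]
    codes = frozenset(canonical_code(t) for t in tokens)
    if not codes:
        raise ValidationError("empty source-population set")
    return codes


_RANK_COLUMNS = ["rank", "country", "lasimti_sum", "hsi", "composite"]


def write_rank_table(table: pd.DataFrame, path) -> None:
    """Write a risk table as CSV, sorted by rank ascending.

    Columns: ``rank,country,lasimti_sum,hsi,composite``; hsi/composite
    cells are blank when missing / not computed.
    """
    df = table.copy()
    for col in _RANK_COLUMNS:
        if col not in df.columns:
            df[col] = float("nan")
    df = df[_RANK_COLUMNS].sort_values("rank")
    df.to_csv(path, index=False)


def read_rank_table(path) -> pd.DataFrame:
    """Read back a rank table written by :func:`write_rank_table`."""
    # round_trip parsing keeps the sums bit-exact across a write/read cycle
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["rank", "country", "lasimti_sum"], path)
    return df


def export_graph(net, path, format: str = "graphml") -> None:
    """Export a trade network as GraphML or JSON node-link.

    Nodes carry ``in_degree``, ``source_population`` and, when computed,
    ``pagerank``; edges carry the pair's LSBCI as ``lsbci``.  Output is
    deterministic (nodes and edges in sorted order).
    """
    if format == "graphml":
        _write_graphml(net, path)
    elif format == "json":
        _write_json(net, path)
    else:
        raise ValueError(f"unknown export format: {format!r}")


def _node_attrs(net) -> dict[str, dict]:
    pr = getattr(net, "pagerank_scores", None) or {}
    return {
        n: {
            "in_degree": net.in_degree(n),
            "source_population": n in net.sources,
            **({"pagerank": pr[n]} if n in pr else {}),
        }
        for n in net.nodes
    }


def _write_graphml(net, path) -> None:
    NS = "http://graphml.graphdrawing.org/xmlns"
    ET.register_namespace("", NS)
    root = ET.Element(f"{{{NS}}}graphml")
    keys = [
        ("d_indeg", "node", "in_degree", "int"),
        ("d_src", "node", "source_population", "boolean"),
        ("d_pr", "node", "pagerank", "double"),
        ("d_w", "edge", "lsbci", "double"),
    ]
    for kid, dom, name, typ in keys:
        ET.SubElement(
            root, f"{{{NS}}}key",
            {"id": kid, "for": dom, "attr.name": name, "attr.type": typ},
        )
    g = ET.SubElement(root, f"{{{NS}}}graph", {"id": "trade", "edgedefault": "directed"})
    attrs = _node_attrs(net)
    for n in sorted(net.nodes):
        el = ET.SubElement(g, f"{{{NS}}}node", {"id": n})
        a = attrs[n]
        ET.SubElement(el, f"{{{NS}}}data", {"key": "d_indeg"}).text = str(a["in_degree"])
        ET.SubElement(el, f"{{{NS}}}data", {"key": "d_src"}).text = (
            "true" if a["source_population"] else "false"
        )
        if "pagerank" in a:
            ET.SubElement(el, f"{{{NS}}}data", {"key": "d_pr"}).text = repr(a["pagerank"])
    for (u, v) in sorted(net.edges):
        el = ET.SubElement(g, f"{{{NS}}}edge", {"source": u, "target": v})
        ET.SubElement(el, f"{{{NS}}}data", {"key": "d_w"}).text = repr(net.edges[(u, v)])
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="utf-8", xml_declaration=True)


def _write_json(net, path) -> None:
    attrs = _node_attrs(net)
    doc = {
        "directed": True,
        "graph": {"k": net.k, "max_days": net.max_days},
        "nodes": [{"id": n, **attrs[n]} for n in sorted(net.nodes)],
        "links": [
            {"source": u, "target": v, "lsbci": net.edges[(u, v)]}
            for (u, v) in sorted(net.edges)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True), encoding="utf-8")
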