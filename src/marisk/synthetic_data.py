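"""Synthetic connectivity, transit-time and HSI scenario generator.

Real inputs for this kind of analysis (published bilateral connectivity
indices, AIS-derived days at sea, habitat-suitability rasters) are
proprietary or external, so every pipeline stage is exercised on
generated data with controllable structure:

* pairwise connectivity: i.i.d. Beta(2, 6) marginals — bounded in
  [0, 1] and right-skewed, so most pairs are weakly connected with a
  few strong links;
* transit times: each country gets a port on the unit sphere and
  days(j, k) is the great-circle distance at a uniform vessel speed
  (default 14 knots), which guarantees symmetric, strictly positive,
  triangle-plausible times;
* port geometry: source-population ports cluster inside a small basin
  and target ports sit on an annulus roughly a quarter-sphere away, so
  every target-source route is a long haul of comparable length.  This
  deliberately suppresses transit-time heterogeneity across targets so
  that a planted connectivity signal — not port-placement luck — decides
  the ranking in recovery experiments.  Target-target distances still
  vary freely, which is what the max-days network cutoff exercises;
* a plantable signal: one target's connectivity to every source is
  multiplied by ``boost`` (capped at 1), giving scenarios with a known
  ground-truth rank-1 country.

All generators are deterministic functions of the spec (independent
seed substreams per table), and ``write_scenario`` emits byte-identical
CSVs in exactly the formats the readers consume.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import SymmetricMatrix

__all__ = [
    "ScenarioSpec",
    "ScenarioBundle",
    "gen_connectivity",
    "gen_transit_times",
    "gen_hsi",
    "gen_scenario",
    "write_scenario",
]

EARTH_RADIUS_KM = 6371.0
KM_PER_NM = 1.852


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic study scenario.

    The same spec always generates byte-identical outputs.
    """

    n_targets: int = 30
    n_sources: int = 4
    seed: int = 0
    beta_a: float = 2.0
    beta_b: float = 6.0
    speed_knots: float = 14.0
    missing_hsi_fraction: float = 0.0
    planted_target: str | None = None
    boost: float = 1.0
    #: Angular radius (degrees) of the source-port basin.
    source_spread_deg: float = 5.0
    #: Angular-distance band (degrees) of target ports from the basin center.
    target_band_deg: tuple[float, float] = (85.0, 95.0)
    #: Optional mixing of connectivity toward a transit-time decay
    #: exp(-days/14): 0 = pure topology-of-service (default), 1 = pure
    #: distance decay.
    distance_decay: float = 0.0

    def __post_init__(self):
        if self.n_targets < 1 or self.n_sources < 1:
            raise ValueError("n_targets and n_sources must be >= 1")
        if not 0.0 <= self.missing_hsi_fraction <= 1.0:
            raise ValueError("missing_hsi_fraction must lie in [0,1]")
        if self.boost < 1.0:
            raise ValueError("boost must be >= 1")
        if self.speed_knots <= 0:
            raise ValueError("speed_knots must be > 0")
        if not 0.0 <= self.distance_decay <= 1.0:
            raise ValueError("distance_decay must lie in [0,1]")

    @property
    def targets(self) -> tuple[str, ...]:
        return _codes("T", self.n_targets)

    @property
    def sources(self) -> tuple[str, ...]:
        return _codes("S", self.n_sources)

    @property
    def planted(self) -> str | None:
        if self.planted_target is not None:
            return self.planted_target
        return self.targets[0] if self.boost > 1.0 else None

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _codes(prefix: str, n: int) -> tuple[str, ...]:
    letters = string.ascii_uppercase
    if n > len(letters) ** 2:
        raise ValueError(f"cannot generate {n} synthetic codes with prefix {prefix}")
    return tuple(
        f"{prefix}{letters[i // 26]}{letters[i % 26]}" for i in range(n)
    )


def _ports(spec: ScenarioSpec) -> dict[str, np.ndarray]:
    """Deterministic unit-vector port positions for every country."""
    rng = spec._rng(2)
    lo, hi = spec.target_band_deg

    def unit(ang: np.ndarray, az: np.ndarray) -> np.ndarray:
        return np.stack(
            [np.sin(ang) * np.cos(az), np.sin(ang) * np.sin(az), np.cos(ang)], axis=-1
        )

    sang = np.deg2rad(rng.uniform(0.0, spec.source_spread_deg, spec.n_sources))
    saz = rng.uniform(0.0, 2 * np.pi, spec.n_sources)
    tang = np.deg2rad(rng.uniform(lo, hi, spec.n_targets))
    taz = rng.uniform(0.0, 2 * np.pi, spec.n_targets)
    pos = {}
    for code, p in zip(spec.sources, unit(sang, saz)):
        pos[code] = p
    for code, p in zip(spec.targets, unit(tang, taz)):
        pos[code] = p
    return pos


def great_circle_days(angle_rad: float, speed_knots: float) -> float:
    """Days at sea along a great-circle arc at a uniform vessel speed."""
    km_per_day = speed_knots * KM_PER_NM * 24.0
    return angle_rad * EARTH_RADIUS_KM / km_per_day


def gen_transit_times(spec: ScenarioSpec) -> SymmetricMatrix:
    """Pairwise days at sea between all countries' ports.

    Symmetric and strictly positive (floored at 0.01 days in the
    measure-zero event of coincident ports).
    """
    pos = _ports(spec)
    codes = sorted(pos)
    times = SymmetricMatrix()
    for i, a in enumerate(codes):
        for b in codes[i + 1:]:
            angle = math.acos(min(1.0, max(-1.0, float(pos[a] @ pos[b]))))
            times.set(a, b, max(great_circle_days(angle, spec.speed_knots), 0.01))
    return times


def gen_connectivity(spec: ScenarioSpec) -> SymmetricMatrix:
    """Symmetric pairwise connectivity in [0, 1] over all countries.

    Beta(a, b) i.i.d. per pair; the planted target's source pairs are
    multiplied by ``boost`` and capped at 1.  With ``distance_decay``
    > 0 the draw is mixed with exp(-days/14) for geographic realism
    experiments.
    """
    rng = spec._rng(1)
    codes = sorted(spec.targets + spec.sources)
    planted = spec.planted
    src = set(spec.sources)
    times = gen_transit_times(spec) if spec.distance_decay > 0 else None
    conn = SymmetricMatrix()
    for i, a in enumerate(codes):
        for b in codes[i + 1:]:
            x = float(rng.beta(spec.beta_a, spec.beta_b))
            if times is not None:
                decay = math.exp(-times.get(a, b) / 14.0)
                x = (1.0 - spec.distance_decay) * x + spec.distance_decay * decay
            if planted is not None and (
                (a == planted and b in src) or (b == planted and a in src)
            ):
                x = min(1.0, x * spec.boost)
            conn.set(a, b, x)
    return conn


def gen_hsi(spec: ScenarioSpec) -> pd.DataFrame:
    """Per-target-country HSI in [0, 1] with a configurable missing share.

    Exactly ``round(missing_hsi_fraction * n_targets)`` countries get a
    missing (NaN) HSI, chosen uniformly.
    """
    rng = spec._rng(3)
    values = rng.uniform(0.0, 1.0, spec.n_targets)
    n_missing = round(spec.missing_hsi_fraction * spec.n_targets)
    missing_idx = rng.choice(spec.n_targets, size=n_missing, replace=False)
    values[missing_idx] = np.nan
    return pd.DataFrame({"country": list(spec.targets), "hsi": values})


@dataclass(frozen=True)
class ScenarioBundle:
    """A complete, mutually consistent synthetic input set."""

    spec: ScenarioSpec
    conn: SymmetricMatrix
    times: SymmetricMatrix
    hsi: pd.DataFrame
    sources: frozenset[str]
    answer_key: dict = field(default_factory=dict)


def gen_scenario(spec: ScenarioSpec) -> ScenarioBundle:
    """Generate connectivity, transit times, HSI, sources and answer key."""
    return ScenarioBundle(
        spec=spec,
        conn=gen_connectivity(spec),
        times=gen_transit_times(spec),
        hsi=gen_hsi(spec),
        sources=frozenset(spec.sources),
        answer_key={
            "planted_target": spec.planted,
            "boost": spec.boost,
            "expected_rank1": spec.planted is not None and spec.boost > 1.0,
        },
    )


def write_scenario(bundle: ScenarioBundle, outdir) -> dict[str, Path]:
    """Write a bundle as the CSV/text formats the readers consume.

    Emits ``lsbci.csv``, ``days.csv``, ``hsi.csv``, ``sources.txt`` and
    ``answer_key.csv``; byte-identical for identical specs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "lsbci": outdir / "lsbci.csv",
        "days": outdir / "days.csv",
        "hsi": outdir / "hsi.csv",
        "sources": outdir / "sources.txt",
        "answer_key": outdir / "answer_key.csv",
    }
    bundle.conn.to_frame().to_csv(paths["lsbci"], index=False)
    bundle.times.to_frame().to_csv(paths["days"], index=False)
    bundle.hsi.to_csv(paths["hsi"], index=False)
    paths["sources"].write_text("\n".join(sorted(bundle.sources)) + "\n", encoding="utf-8")
    pd.DataFrame([bundle.answer_key]).to_csv(paths["answer_key"], index=False)
    return paths


def null_spec(spec: ScenarioSpec) -> ScenarioSpec:
    """The matched no-signal control: same scenario with boost 1."""
    return replace(spec, boost=1.0, planted_target=spec.planted)
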