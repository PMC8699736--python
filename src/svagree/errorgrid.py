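"""Expert-opinion error grid: harm scoring, risk zones, point classification.

The error grid translates measurement error into clinical consequence, in
the spirit of the Clarke grid for glucometers.  Clinician respondents rate
the harm of every (actual SV fall, measured SV fall) discrepancy as none /
mild / moderate / severe; the ratings are weighted (0 / 2 / 5 / 10),
summed across respondents into a score per grid cell (0 up to
10 x n_respondents) and rescaled to percent.  Thresholding the percent
scores bands each cell, and merging contiguous same-band cells yields four
rectilinear risk-zone polygons over the (actual, measured) reduction plane.
Paired device measurements are then classified by the zone their
(reference fall, device fall) point lands in; ties on a shared zone
boundary go to the higher-harm zone (conservative), and points outside the
grid domain are clamped to its edge.

The grid is deliberately NOT symmetrised: over-reading blood loss (needless
transfusion) and under-reading it (missed resuscitation) harm differently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union

from .simulate import HARM_CATEGORIES, QuestionnaireReturn
from .trend import DeltaPair

__all__ = [
    "HarmWeights",
    "HarmGrid",
    "ZoneSet",
    "ZoneSummary",
    "build_harm_grid",
    "derive_zones",
    "classify_points",
    "zone_summary",
    "DEFAULT_PCT_THRESHOLDS",
]


@dataclass(frozen=True)
class HarmWeights:
    """Numerical weights per harm category; must be strictly increasing with
    none = 0."""

    none: float = 0.0
    mild: float = 2.0
    moderate: float = 5.0
    severe: float = 10.0

    def __post_init__(self) -> None:
        if self.none != 0:
            raise ValueError("weight for 'none' must be 0")
        if not (self.none < self.mild < self.moderate < self.severe):
            raise ValueError("weights must be strictly increasing")

    def weight(self, category: str) -> float:
        return getattr(self, category)


#: Percent-score band edges (mild, moderate, severe).  13.3% is a mean
#: per-respondent weight below "mild" (1.33 of 10); 35% is midway between
#: mild- and moderate-dominant; 75% and above is severe-dominant.
DEFAULT_PCT_THRESHOLDS = (13.3, 35.0, 75.0)


class HarmGrid:
    """Combined scored grid over (actual, measured) SV-reduction cells.

    ``raw[i, j]`` is the summed weighted rating across respondents for
    actual fall ``grid_steps[i]`` and measured fall ``grid_steps[j]``;
    ``pct`` rescales by the maximum attainable score (severe weight times
    the number of respondents).
    """

    def __init__(
        self,
        grid_steps: tuple[float, ...],
        raw: np.ndarray,
        n_respondents: int,
        weights: HarmWeights | None = None,
    ):
        self.grid_steps = tuple(float(g) for g in grid_steps)
        self.raw = np.asarray(raw, dtype=float)
        self.n_respondents = int(n_respondents)
        self.weights = weights or HarmWeights()
        n = len(self.grid_steps)
        if self.raw.shape != (n, n):
            raise ValueError("raw score matrix must be square over grid_steps")
        if self.n_respondents < 1:
            raise ValueError("need at least one respondent")
        if np.any(self.raw < 0) or np.any(self.raw > self.max_score):
            raise ValueError("raw scores out of [0, max_score]")

    @property
    def max_score(self) -> float:
        return self.weights.severe * self.n_respondents

    @property
    def pct(self) -> np.ndarray:
        return 100.0 * self.raw / self.max_score

    @classmethod
    def from_returns(
        cls, returns: list[QuestionnaireReturn], weights: HarmWeights | None = None
    ) -> "HarmGrid":
        """Sum weighted ratings across respondents, cell by cell."""
        if not returns:
            raise ValueError("need at least one questionnaire return")
        weights = weights or HarmWeights()
        steps = returns[0].grid_steps
        for ret in returns[1:]:
            if ret.grid_steps != steps:
                raise ValueError("all returns must share identical grid_steps")
        n = len(steps)
        raw = np.zeros((n, n))
        for ret in returns:
            for i in range(n):
                for j in range(n):
                    raw[i, j] += weights.weight(ret.ratings[i][j])
        return cls(steps, raw, n_respondents=len(returns), weights=weights)

    def band(self, pct_thresholds=DEFAULT_PCT_THRESHOLDS) -> np.ndarray:
        """Band index per cell (0 none .. 3 severe) by thresholding pct."""
        t_mild, t_moderate, t_severe = pct_thresholds
        if not (0 < t_mild < t_moderate < t_severe <= 100):
            raise ValueError("pct_thresholds must satisfy 0 < mild < moderate < severe <= 100")
        return np.digitize(self.pct, [t_mild, t_moderate, t_severe])

    def cell_edges(self) -> np.ndarray:
        """Cell boundaries: domain ends plus midpoints between grid steps."""
        s = np.asarray(self.grid_steps)
        return np.concatenate([[s[0]], (s[:-1] + s[1:]) / 2.0, [s[-1]]])

    def to_frame(self, scale: str = "pct") -> pd.DataFrame:
        """Grid as a table, actual reduction in rows, measured in columns."""
        data = self.pct if scale == "pct" else self.raw
        idx = pd.Index(self.grid_steps, name="actual_reduction_pct")
        cols = pd.Index(self.grid_steps, name="measured_reduction_pct")
        return pd.DataFrame(data, index=idx, columns=cols)


def build_harm_grid(
    returns: list[QuestionnaireReturn], weights: HarmWeights | None = None
) -> HarmGrid:
    """Functional alias for :meth:`HarmGrid.from_returns`."""
    return HarmGrid.from_returns(returns, weights)


_ZONE_ORDER_DESC = tuple(reversed(HARM_CATEGORIES))  # severe first


class ZoneSet:
    """Four risk-zone geometries over the (actual, measured) reduction plane.

    ``zones`` maps category -> shapely geometry (possibly empty or
    multi-part: severe harm typically occupies both the over- and the
    under-estimation corner).  Zones jointly cover ``domain`` squared.
    """

    def __init__(self, zones: dict, domain: tuple[float, float], provenance: str):
        if set(zones) != set(HARM_CATEGORIES):
            raise ValueError(f"zones must have exactly the keys {HARM_CATEGORIES}")
        for name, geom in zones.items():
            if not geom.is_valid:
                raise ValueError(f"zone {name!r} polygon is invalid (self-intersecting?)")
        if provenance not in ("derived_from_grid", "loaded_from_file"):
            raise ValueError("unknown provenance")
        self.zones = dict(zones)
        self.domain = (float(domain[0]), float(domain[1]))
        self.provenance = provenance
        union = unary_union(list(zones.values()))
        dom = box(self.domain[0], self.domain[0], self.domain[1], self.domain[1])
        if not union.buffer(1e-9).contains(dom):
            raise ValueError("zones do not jointly cover the grid domain")

    def classify(self, actual_reduction: float, measured_reduction: float) -> str:
        """Zone label for one point.

        Zones are checked from severe downwards so a shared boundary
        resolves to the higher-harm zone; out-of-domain coordinates are
        clamped to the domain edge.  One precedence above that: a point with
        ``actual == measured`` carries no measurement error, so it is "none"
        whenever the none zone contains it, even where the diagonal grazes a
        harm cell's corner.
        """
        lo, hi = self.domain
        p = Point(
            float(np.clip(actual_reduction, lo, hi)),
            float(np.clip(measured_reduction, lo, hi)),
        )
        if actual_reduction == measured_reduction and shapely.covers(self.zones["none"], p):
            return "none"
        for name in _ZONE_ORDER_DESC:
            geom = self.zones[name]
            if (not geom.is_empty) and shapely.covers(geom, p):
                return name
        # Numerical sliver between zone edges: snap to the nearest zone.
        dists = {
            name: self.zones[name].distance(p)
            for name in _ZONE_ORDER_DESC
            if not self.zones[name].is_empty
        }
        return min(dists, key=dists.get)

    # -- serialisation ------------------------------------------------------

    def to_json(self, path=None) -> str:
        """Serialise as {"zones": {name: [ring, ...]}, "domain": [lo, hi]};
        each ring is a list of [x, y] vertices."""
        payload = {"zones": {}, "domain": list(self.domain)}
        for name in HARM_CATEGORIES:
            geom = self.zones[name]
            rings = []
            parts = getattr(geom, "geoms", [geom]) if not geom.is_empty else []
            for part in parts:
                rings.append([[float(x), float(y)] for x, y in part.exterior.coords])
            payload["zones"][name] = rings
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "ZoneSet":
        """Load zones from a JSON file path or string.  A zone's value may be
        a single vertex ring or a list of rings."""
        if isinstance(source, (str,)) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        zones = {}
        for name in HARM_CATEGORIES:
            rings = payload["zones"].get(name, [])
            if rings and isinstance(rings[0][0], (int, float)):
                rings = [rings]  # single ring shorthand
            polys = [Polygon(r) for r in rings if len(r) >= 3]
            zones[name] = unary_union(polys) if polys else Polygon()
        return cls(zones, tuple(payload["domain"]), provenance="loaded_from_file")


def derive_zones(
    grid: HarmGrid, pct_thresholds=DEFAULT_PCT_THRESHOLDS
) -> ZoneSet:
    """Band each cell by its percent score and merge contiguous same-band
    cells into rectilinear zone polygons covering the grid domain."""
    bands = grid.band(pct_thresholds)
    edges = grid.cell_edges()
    n = len(grid.grid_steps)
    zones = {}
    for b, name in enumerate(HARM_CATEGORIES):
        cells = [
            box(edges[i], edges[j], edges[i + 1], edges[j + 1])
            for i in range(n)
            for j in range(n)
            if bands[i, j] == b
        ]
        zones[name] = unary_union(cells) if cells else Polygon()
    return ZoneSet(zones, domain=(edges[0], edges[-1]), provenance="derived_from_grid")


def classify_points(
    deltas: list[DeltaPair], zones: ZoneSet
) -> list[tuple[DeltaPair, str]]:
    """Classify each delta pair by risk zone.

    Deltas are signed percent changes (negative = fall); the grid lives in
    reduction coordinates (positive = fall), so each point is negated before
    the point-in-polygon test.
    """
    out = []
    for d in deltas:
        label = zones.classify(-d.delta_ref, -d.delta_dev)
        out.append((d, label))
    return out


@dataclass(frozen=True)
class ZoneSummary:
    """Per-zone counts and display percentages (integers, half-up).  When a
    second strand is pooled, ``combined_severe_pct`` is the severe share of
    the pooled points, to one decimal."""

    n_points: int
    counts: dict
    percentages: dict
    combined_severe_pct: float | None = None


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _labels(classified) -> list[str]:
    labels = []
    for item in classified:
        if isinstance(item, str):
            labels.append(item)
        else:
            labels.append(item[1])
    for lab in labels:
        if lab not in HARM_CATEGORIES:
            raise ValueError(f"unknown zone label {lab!r}")
    return labels


def zone_summary(classified, pooled_strands=None) -> ZoneSummary:
    """Count classified points per zone; optionally pool a second strand for
    the combined severe-harm rate.

    ``classified`` may be a list of (DeltaPair, label) tuples or bare labels.
    """
    labels = _labels(classified)
    if not labels:
        raise ValueError("no classified points")
    n = len(labels)
    counts = {cat: labels.count(cat) for cat in HARM_CATEGORIES}
    percentages = {cat: _round_half_up(100.0 * counts[cat] / n) for cat in HARM_CATEGORIES}

    combined = None
    if pooled_strands is not None:
        other = _labels(pooled_strands)
        if not other:
            raise ValueError("pooled strand has no points")
        severe = counts["severe"] + other.count("severe")
        combined = round(100.0 * severe / (n + len(other)), 1)
    return ZoneSummary(
        n_points=n, counts=counts, percentages=percentages, combined_severe_pct=combined
    )
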