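"""Empirical %TOC distributions from a georeferenced sediment-sample library.

Sediment %TOC (total organic carbon, percent of dry weight) varies over
orders of magnitude between muddy coastal deposits and the clean sands
targeted by aggregate dredgers, so the carbon content of disturbed sediment
must be drawn from pools that represent the sediments each industry actually
touches.  This module filters a sample library into:

* a *coastal* pool for port dredging — subtidal samples below mean high
  water, within 5 km of the coastline, excluding seagrass and saltmarsh
  habitats (vegetated-habitat samples are not representative of dredged
  channels);
* *sand*, *coarse* and *mixed* pools for aggregate extraction, by
  point-in-polygon overlay of samples on a classed substrate map;
* a *combined* pool for aggregate records whose sediment type is unknown.

A "distribution" is the empirical pool itself: draws resample observed values
uniformly with replacement, which reproduces the pool's percentiles without
parametric assumptions.  All geometry is planar, in a projected equal-area
CRS in metres.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace, field
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import Point, shape, mapping
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

__all__ = [
    "TocSample", "EmpiricalTocDistribution", "SubstrateMap",
    "filter_coastal_samples", "classify_samples_by_substrate",
    "build_substrate_distributions", "build_combined_distribution",
    "draw_toc", "read_samples_csv", "write_samples_csv",
]

SUBSTRATE_CLASSES = ("sand", "coarse", "mixed")


@dataclass(frozen=True)
class TocSample:
    """One georeferenced %TOC measurement (x, y in projected metres)."""

    sample_id: str
    x: float
    y: float
    toc_pct: float
    habitat: str = "subtidal_other"  # seagrass | saltmarsh | subtidal_other
    elevation_class: str = "below_MHW"  # above_MHW | below_MHW
    substrate_class: str | None = None  # sand | coarse | mixed | mud | other

    def __post_init__(self) -> None:
        if not 0.0 <= self.toc_pct <= 100.0:
            raise ValueError(f"{self.sample_id}: toc_pct {self.toc_pct} outside [0, 100]")

    @property
    def point(self) -> Point:
        return Point(self.x, self.y)


@dataclass(frozen=True)
class EmpiricalTocDistribution:
    """A labelled pool of observed %TOC values with a resampling contract."""

    label: str  # coastal | sand | coarse | mixed | combined
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.size < 1:
            raise ValueError(f"{self.label}: empty %TOC pool")
        if vals.min() < 0.0 or vals.max() > 100.0:
            raise ValueError(f"{self.label}: %TOC values outside [0, 100]")

    @property
    def n(self) -> int:
        return int(self.values.size)

    def summary(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "mean": float(self.values.mean()),
            "median": float(np.median(self.values)),
            "p5": float(np.percentile(self.values, 5)),
            "p95": float(np.percentile(self.values, 95)),
            "min": float(self.values.min()),
            "max": float(self.values.max()),
        }

    def to_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["toc_pct"])
            for v in self.values:
                writer.writerow([repr(float(v))])


@dataclass
class SubstrateMap:
    """Classed seabed-substrate polygons plus a coastline.

    ``polygons`` is a list of (polygon_id, class_label, shapely geometry).
    Geometries must be valid; classification raises on the first invalid one.
    """

    polygons: list[tuple[str, str, BaseGeometry]] = field(default_factory=list)
    coastline: BaseGeometry | None = None

    def validate(self) -> None:
        for pid, _, geom in self.polygons:
            if not geom.is_valid:
                raise ValueError(f"invalid substrate polygon {pid!r}")

    def to_geojson(self, path) -> None:
        features = [
            {
                "type": "Feature",
                "properties": {"id": pid, "substrate_class": cls},
                "geometry": mapping(geom),
            }
            for pid, cls, geom in self.polygons
        ]
        if self.coastline is not None:
            features.append(
                {
                    "type": "Feature",
                    "properties": {"id": "coastline", "substrate_class": None},
                    "geometry": mapping(self.coastline),
                }
            )
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)

    @classmethod
    def from_geojson(cls, path) -> "SubstrateMap":
        with open(path, encoding="utf-8") as fh:
            fc = json.load(fh)
        smap = cls()
        for feat in fc["features"]:
            props = feat.get("properties", {})
            geom = shape(feat["geometry"])
            if props.get("id") == "coastline" or geom.geom_type in ("LineString", "MultiLineString"):
                smap.coastline = geom
            else:
                smap.polygons.append((str(props.get("id")), props["substrate_class"], geom))
        return smap


def filter_coastal_samples(
    samples: Sequence[TocSample],
    coastline: BaseGeometry,
    max_dist_km: float = 5.0,
) -> tuple[EmpiricalTocDistribution, list[TocSample]]:
    """Build the coastal %TOC pool for port dredging.

    Retains samples that are subtidal (habitat ``subtidal_other``), below
    mean high water, and within ``max_dist_km`` (closed interval) of the
    coastline by planar Euclidean distance.  Returns the pool and the
    retained samples (for audit).
    """
    max_dist_m = max_dist_km * 1000.0
    retained = [
        s
        for s in samples
        if s.habitat == "subtidal_other"
        and s.elevation_class == "below_MHW"
        and coastline.distance(s.point) <= max_dist_m
    ]
    if not retained:
        raise ValueError("no coastal samples after filtering")
    return (
        EmpiricalTocDistribution("coastal", np.array([s.toc_pct for s in retained])),
        retained,
    )


def classify_samples_by_substrate(
    samples: Sequence[TocSample],
    substrate_map: SubstrateMap,
) -> list[TocSample]:
    """Assign each sample a substrate class by point-in-polygon overlay.

    Points covered by no polygon get class ``other``.  A point on a shared
    boundary is assigned to the first covering polygon in map order
    (deterministic tie-break).  Each sample receives exactly one class.
    """
    substrate_map.validate()
    geoms = [geom for _, _, geom in substrate_map.polygons]
    tree = STRtree(geoms)
    out: list[TocSample] = []
    for s in samples:
        pt = s.point
        hits = sorted(int(i) for i in tree.query(pt, predicate="covered_by"))
        cls = substrate_map.polygons[hits[0]][1] if hits else "other"
        out.append(replace(s, substrate_class=cls))
    return out


def build_substrate_distributions(
    classified: Sequence[TocSample],
    classes: Iterable[str] = SUBSTRATE_CLASSES,
) -> dict[str, EmpiricalTocDistribution]:
    """One empirical pool per requested substrate class."""
    dists: dict[str, EmpiricalTocDistribution] = {}
    for cls in classes:
        vals = [s.toc_pct for s in classified if s.substrate_class == cls]
        if not vals:
            raise ValueError(f"no samples in substrate class {cls!r}")
        dists[cls] = EmpiricalTocDistribution(cls, np.array(vals))
    return dists


def build_combined_distribution(
    dists: dict[str, EmpiricalTocDistribution],
    weights: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
    n_resample: int = 10000,
) -> EmpiricalTocDistribution:
    """Pool sand/coarse/mixed into one distribution for untyped records.

    Default policy pools all raw values, so class weights are implied by the
    sample counts.  With explicit ``weights`` (summing to 1) a weighted
    mixture is materialised by stratified resampling of ``n_resample`` values
    (requires ``rng``); the alternative exists because the assumed sediment
    proportions are a recognised sensitivity.
    """
    for cls in SUBSTRATE_CLASSES:
        if cls not in dists:
            raise ValueError(f"missing substrate distribution {cls!r}")
    if weights is None:
        pooled = np.concatenate([dists[c].values for c in SUBSTRATE_CLASSES])
        return EmpiricalTocDistribution("combined", pooled)
    total = sum(weights.get(c, 0.0) for c in SUBSTRATE_CLASSES)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {total}")
    if rng is None:
        raise ValueError("weighted pooling needs an rng")
    counts = {c: int(round(weights.get(c, 0.0) * n_resample)) for c in SUBSTRATE_CLASSES}
    parts = [
        rng.choice(dists[c].values, size=k, replace=True)
        for c, k in counts.items()
        if k > 0
    ]
    return EmpiricalTocDistribution("combined", np.concatenate(parts))


def draw_toc(
    dist: EmpiricalTocDistribution,
    rng: np.random.Generator,
    size: int | tuple | None = None,
) -> float | np.ndarray:
    """Uniform draw(s) with replacement from the pool."""
    out = rng.choice(dist.values, size=size, replace=True)
    return float(out) if size is None else out


# ---------------------------------------------------------------------------
# CSV interface

_SAMPLE_COLUMNS = ["sample_id", "x", "y", "toc_pct", "habitat", "elevation_class", "substrate_class"]


def read_samples_csv(path) -> list[TocSample]:
    samples: list[TocSample] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            try:
                samples.append(
                    TocSample(
                        sample_id=row["sample_id"],
                        x=float(row["x"]),
                        y=float(row["y"]),
                        toc_pct=float(row["toc_pct"]),
                        habitat=row.get("habitat") or "subtidal_other",
                        elevation_class=row.get("elevation_class") or "below_MHW",
                        substrate_class=row.get("substrate_class") or None,
                    )
                )
            except (KeyError, ValueError) as err:
                raise ValueError(f"{path}: row {i + 2}: {err}") from err
    return samples


def write_samples_csv(samples: Sequence[TocSample], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=_SAMPLE_COLUMNS)
        writer.writeheader()
        for s in samples:
            writer.writerow(
                {
                    "sample_id": s.sample_id,
                    "x": repr(s.x),
                    "y": repr(s.y),
                    "toc_pct": repr(s.toc_pct),
                    "habitat": s.habitat,
                    "elevation_class": s.elevation_class,
                    "substrate_class": s.substrate_class or "",
                }
            )
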