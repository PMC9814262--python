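"""Property-space analytics.

All analyses run on the (-IP, -EA, ΔO) records produced upstream:
2D histograms and 1D kernel density estimates of projections of the
property space, per-molecule substituent shifts relative to the parent
skeleton, a topographic most-prevalent-skeleton grid over the
(-IP, -EA) plane, ring-count-conditioned distributions, convex hulls of
molecule subsets, and counting queries for (empty) property-space
regions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull, QhullError

from .chem_core import PROPERTY_NAMES, PropertyRecord
from .enumeration import Library

logger = logging.getLogger(__name__)


def _axis_values(records: Sequence[PropertyRecord], axes: tuple[str, str]) -> np.ndarray:
    return np.array([[r.value(axes[0]), r.value(axes[1])] for r in records])


# ---------------------------------------------------------------------------
# histograms and KDEs


def histogram2d(
    records: Sequence[PropertyRecord],
    axes: tuple[str, str] = ("minus_ip", "minus_ea"),
    bins: int | tuple[int, int] = 50,
    range: tuple | None = None,
):
    """Binned counts over a 2D projection; returns (counts, x_edges, y_edges)."""
    if not records:
        raise ValueError("histogram2d of empty record list")
    xy = _axis_values(records, axes)
    counts, xe, ye = np.histogram2d(xy[:, 0], xy[:, 1], bins=bins, range=range)
    return counts, xe, ye


def kde1d(
    values: Sequence[float],
    bandwidth: str | float = "silverman",
    n_grid: int = 512,
    pad_bandwidths: float = 4.0,
):
    """Gaussian-kernel density estimate; returns (grid, density).

    ``bandwidth`` is either a rule name understood by
    :class:`scipy.stats.gaussian_kde` (default Silverman) or a number,
    interpreted as the *absolute* kernel standard deviation in data
    units — the numeric form also covers zero-variance data, where a
    relative rule is undefined.  The evaluation grid extends
    ``pad_bandwidths`` kernel widths beyond the data extremes so the
    density integrates to ~1 on it.
    """
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("kde1d needs at least 2 values")
    if isinstance(bandwidth, (int, float)):
        width = float(bandwidth)
        if width <= 0:
            raise ValueError("numeric bandwidth must be positive")
        grid = np.linspace(
            x.min() - pad_bandwidths * width, x.max() + pad_bandwidths * width, n_grid
        )
        density = stats.norm.pdf(grid[:, None], loc=x[None, :], scale=width).mean(axis=1)
        return grid, density
    kde = stats.gaussian_kde(x, bw_method=bandwidth)
    width = np.sqrt(kde.covariance[0, 0])
    grid = np.linspace(x.min() - pad_bandwidths * width, x.max() + pad_bandwidths * width, n_grid)
    return grid, kde(grid)


# ---------------------------------------------------------------------------
# substituent shifts


def substituent_shifts(
    library: Library,
    records: Sequence[PropertyRecord],
    substituent_classes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-molecule property change relative to the unsubstituted parent.

    Returns a tidy frame with d_minus_ip / d_minus_ea / d_optical_gap,
    the substituent count and (optionally) class labels.  Molecules
    whose parent skeleton has no record are skipped and reported via the
    ``skipped`` attribute on the returned frame.
    """
    by_id = {r.molecule_id: r for r in records}
    parents = library.skeleton_entries()
    rows, skipped = [], []
    for entry in library:
        rec = by_id.get(entry.id)
        parent_entry = parents.get(entry.skeleton_id)
        parent_rec = by_id.get(parent_entry.id) if parent_entry else None
        if rec is None or parent_rec is None:
            skipped.append(entry.id)
            continue
        classes = (
            sorted({substituent_classes.get(s, "other") for s in entry.substituents})
            if substituent_classes
            else []
        )
        rows.append(
            {
                "id": entry.id,
                "skeleton_id": entry.skeleton_id,
                "n_substituents": len(entry.substituents),
                "classes": "+".join(classes),
                "d_minus_ip": rec.minus_ip - parent_rec.minus_ip,
                "d_minus_ea": rec.minus_ea - parent_rec.minus_ea,
                "d_optical_gap": rec.optical_gap - parent_rec.optical_gap,
                "parent_minus_ip": parent_rec.minus_ip,
                "parent_minus_ea": parent_rec.minus_ea,
            }
        )
    if skipped:
        logger.warning("substituent_shifts: %d molecule(s) without parent record", len(skipped))
    df = pd.DataFrame(rows)
    df.attrs["skipped"] = skipped
    return df


# ---------------------------------------------------------------------------
# topography


@dataclass(frozen=True)
class TopographyConfig:
    """Regular grid over the (-IP, -EA) plane."""

    ip_increment: float = 0.5
    ea_increment: float = 0.5
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.ip_increment <= 0 or self.ea_increment <= 0:
            raise ValueError("grid increments must be positive")

    def cell_of(self, minus_ip: float, minus_ea: float) -> tuple[int, int]:
        # half-open cells: low edge inclusive, points on the upper edge
        # belong to the next cell
        return (
            int(np.floor((minus_ip - self.origin[0]) / self.ip_increment)),
            int(np.floor((minus_ea - self.origin[1]) / self.ea_increment)),
        )


@dataclass
class TopographyMap:
    config: TopographyConfig
    # cell (i, j) -> (winning skeleton id, normalized prevalence, occupancy)
    cells: dict[tuple[int, int], tuple[str, float, int]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cell_i": i,
                "cell_j": j,
                "minus_ip_low": self.config.origin[0] + i * self.config.ip_increment,
                "minus_ea_low": self.config.origin[1] + j * self.config.ea_increment,
                "skeleton_id": sid,
                "prevalence": prev,
                "occupancy": occ,
            }
            for (i, j), (sid, prev, occ) in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows)


def topography(
    records: Sequence[PropertyRecord],
    library: Library,
    config: TopographyConfig | None = None,
) -> TopographyMap:
    """Most-prevalent-skeleton map over the (-IP, -EA) grid.

    In each occupied cell the winner is the skeleton maximizing the
    *normalized* prevalence — its molecule count in the cell divided by
    its molecule count in the whole dataset — so small skeleton families
    concentrated in a cell beat large families passing through it.
    Ties break to the lexicographically lowest skeleton id.
    """
    config = config or TopographyConfig()
    if not records:
        raise ValueError("topography of empty record list")
    skeleton_of = {e.id: e.skeleton_id for e in library}
    totals: dict[str, int] = {}
    for e in library:
        totals[e.skeleton_id] = totals.get(e.skeleton_id, 0) + 1

    per_cell: dict[tuple[int, int], dict[str, int]] = {}
    for rec in records:
        sid = skeleton_of.get(rec.molecule_id)
        if sid is None:
            continue
        cell = config.cell_of(rec.minus_ip, rec.minus_ea)
        per_cell.setdefault(cell, {})[sid] = per_cell.setdefault(cell, {}).get(sid, 0) + 1

    cells = {}
    for cell, counts in per_cell.items():
        scored = sorted(
            ((cnt / totals[sid], sid, cnt) for sid, cnt in counts.items()),
            key=lambda t: (-t[0], t[1]),
        )
        prev, sid, _ = scored[0]
        if len(scored) > 1 and scored[1][0] == prev:
            logger.info("topography tie in cell %s broken to %s", cell, sid)
        cells[cell] = (sid, prev, sum(counts.values()))
    return TopographyMap(config=config, cells=cells)


# ---------------------------------------------------------------------------
# convex hulls


@dataclass
class Hull2D:
    """Convex hull of a subset's projection onto an axis pair."""

    projection: tuple[str, str]
    vertices: np.ndarray  # (n, 2), counter-clockwise
    subset_label: str = ""
    degenerate: bool = False

    @property
    def area(self) -> float:
        if self.degenerate:
            return 0.0
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

    def contains(self, points, tol: float = 1e-9) -> np.ndarray:
        """Vectorized point-in-convex-polygon test (boundary counts as inside)."""
        pts = np.atleast_2d(np.asarray(points, float))
        if self.degenerate:
            # fall back to distance-to-segment/point membership
            out = np.zeros(len(pts), bool)
            for k, p in enumerate(pts):
                out[k] = bool(
                    np.any(np.linalg.norm(self.vertices - p, axis=1) <= tol)
                    or _on_segments(self.vertices, p, tol)
                )
            return out
        v = self.vertices
        edges = np.roll(v, -1, axis=0) - v
        rel = pts[:, None, :] - v[None, :, :]
        cross = edges[None, :, 0] * rel[:, :, 1] - edges[None, :, 1] * rel[:, :, 0]
        return np.all(cross >= -tol, axis=1)


def _on_segments(vertices: np.ndarray, p: np.ndarray, tol: float) -> bool:
    for a, b in zip(vertices[:-1], vertices[1:]):
        ab = b - a
        denom = np.dot(ab, ab)
        if denom == 0:
            continue
        t = np.clip(np.dot(p - a, ab) / denom, 0.0, 1.0)
        if np.linalg.norm(a + t * ab - p) <= tol:
            return True
    return False


def convex_hull2d(
    records: Sequence[PropertyRecord],
    axes: tuple[str, str] = ("minus_ip", "minus_ea"),
    subset_label: str = "",
) -> Hull2D:
    """Minimal convex polygon containing the subset's projected points.

    Fewer than three distinct points, or collinear point sets, yield a
    hull flagged ``degenerate`` whose vertices are the sorted distinct
    points.
    """
    if not records:
        raise ValueError(f"convex_hull2d of empty subset {subset_label!r}")
    pts = _axis_values(records, axes)
    uniq = np.unique(pts, axis=0)
    if len(uniq) < 3:
        return Hull2D(axes, uniq, subset_label, degenerate=True)
    try:
        hull = ConvexHull(uniq)
    except QhullError:  # collinear
        order = np.lexsort((uniq[:, 1], uniq[:, 0]))
        return Hull2D(axes, uniq[order], subset_label, degenerate=True)
    return Hull2D(axes, uniq[hull.vertices], subset_label)


# ---------------------------------------------------------------------------
# ring-count trends and region queries


def ring_count_distributions(
    library: Library, records: Sequence[PropertyRecord]
) -> pd.DataFrame:
    """Tidy frame of properties keyed by the molecule's aromatic-ring count."""
    by_id = {r.molecule_id: r for r in records}
    rows = [
        {
            "id": e.id,
            "n_aromatic_rings": e.n_aromatic_rings,
            "minus_ip": by_id[e.id].minus_ip,
            "minus_ea": by_id[e.id].minus_ea,
            "optical_gap": by_id[e.id].optical_gap,
        }
        for e in library
        if e.id in by_id
    ]
    return pd.DataFrame(rows)


_CONSTRAINT_RE = re.compile(r"^\s*(\w+)\s*([<>])\s*(-?\d+(?:\.\d+)?)\s*$")


def parse_constraints(text: str) -> list[tuple[str, str, float]]:
    """Parse e.g. ``"minus_ip>-6, minus_ea<-4"`` into constraint triples."""
    out = []
    for part in text.split(","):
        m = _CONSTRAINT_RE.match(part)
        if not m:
            raise ValueError(f"cannot parse constraint {part!r}")
        out.append((m.group(1), m.group(2), float(m.group(3))))
    return out


def region_count(
    records: Sequence[PropertyRecord],
    constraints: "Sequence[tuple[str, str, float]] | str",
) -> int:
    """Number of records satisfying all strict-inequality constraints."""
    if isinstance(constraints, str):
        constraints = parse_constraints(constraints)
    for prop, op, _ in constraints:
        if prop not in PROPERTY_NAMES:
            raise KeyError(f"unknown property {prop!r}")
        if op not in ("<", ">"):
            raise ValueError(f"unknown comparison {op!r}")
    n = 0
    for rec in records:
        ok = all(
            (rec.value(prop) > bound) if op == ">" else (rec.value(prop) < bound)
            for prop, op, bound in constraints
        )
        n += ok
    return n
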