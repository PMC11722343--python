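"""Proximity graphs, anchored neighborhood densities and TLS metrics.

Cells of one ROI become nodes of an undirected graph whose edges join
centroid pairs at most ``radius_um`` (default 100 um, inclusive) apart.
Densities around anchor cells are counts of target-phenotype cells inside
the same disk divided by the disk area, expressed in cells/mm^2, averaged
over anchors per ROI. TLS densities divide phenotype counts inside a
tertiary lymphoid structure by its area (convex hull of member cells by
default, fixed-radius disk optionally); the activation/exhaustion ratio
divides the activated T-cell density by the exhausted T-cell density within
the same TLS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, cKDTree

from .errors import ParameterError, ValidationError
from .io import CellTable


def build_neighbor_graph(cells: CellTable, radius_um: float = 100.0) -> nx.Graph:
    """Undirected graph over the cells of one ROI.

    Nodes are cell ids; an edge joins two cells when their centroid
    distance is <= ``radius_um`` (inclusive) and carries the distance as the
    ``distance`` attribute.
    """
    if radius_um <= 0:
        raise ParameterError("radius_um must be > 0")
    df = cells.df
    if df["roi_id"].nunique() > 1:
        raise ValidationError("build_neighbor_graph expects cells of a single ROI")
    g = nx.Graph()
    g.add_nodes_from(df["cell_id"])
    if len(df) < 2:
        return g
    pts = df[["x_um", "y_um"]].to_numpy()
    ids = df["cell_id"].to_numpy()
    tree = cKDTree(pts)
    for i, j in tree.query_pairs(radius_um):
        d = float(np.hypot(*(pts[i] - pts[j])))
        g.add_edge(ids[i], ids[j], distance=d)
    return g


@dataclass
class DensityResult:
    """Target-phenotype density around anchor cells, per ROI."""

    anchor: str
    target: str
    radius_um: float
    per_anchor: pd.DataFrame  # roi_id, anchor_id, count, density_per_mm2
    per_roi: pd.DataFrame  # roi_id, compartment, n_anchors, mean_count, mean_density


def _as_tuple(x) -> tuple:
    return (x,) if isinstance(x, str) else tuple(x)


def density_around(
    cells: CellTable,
    anchors,
    targets,
    radius_um: float = 100.0,
    pooled: bool = False,
) -> DensityResult:
    """Density of ``targets`` cells within ``radius_um`` of each ``anchors`` cell.

    The anchor itself never counts as its own neighbor. Density is
    count / (pi r^2) in cells/mm^2. Per-ROI aggregates are means over
    anchors (``pooled=True`` instead pools all counts over all anchors of
    the ROI before dividing by the summed disk area — same value, provided
    anchors share the radius, but kept for symmetry with per-TLS pooling).
    ROIs without anchor cells are omitted with a warning.
    """
    if radius_um <= 0:
        raise ParameterError("radius_um must be > 0")
    anchors, targets = _as_tuple(anchors), _as_tuple(targets)
    disk_mm2 = np.pi * (radius_um / 1000.0) ** 2
    rows, agg = [], []
    for roi in cells.rois():
        df = cells.df[cells.df["roi_id"] == roi]
        a = df[df["phenotype"].isin(anchors)]
        t = df[df["phenotype"].isin(targets)]
        if a.empty:
            warnings.warn(f"ROI {roi!r} has no anchor cell of {anchors}; omitted")
            continue
        counts = np.zeros(len(a), dtype=int)
        if not t.empty:
            tree = cKDTree(t[["x_um", "y_um"]].to_numpy())
            hits = tree.query_ball_point(a[["x_um", "y_um"]].to_numpy(), r=radius_um)
            t_ids = t["cell_id"].to_numpy()
            a_ids = a["cell_id"].to_numpy()
            for k, h in enumerate(hits):
                # exclude the anchor when it is also a target-phenotype cell
                counts[k] = sum(1 for idx in h if t_ids[idx] != a_ids[k])
        for aid, c in zip(a["cell_id"], counts):
            rows.append(dict(roi_id=roi, anchor_id=aid, count=int(c),
                             density_per_mm2=c / disk_mm2))
        mean_count = counts.mean()
        agg.append(dict(roi_id=roi, compartment=df["compartment"].iloc[0],
                        n_anchors=len(a), mean_count=float(mean_count),
                        mean_density_per_mm2=float(
                            counts.sum() / (len(a) * disk_mm2) if pooled
                            else mean_count / disk_mm2)))
    return DensityResult(
        "+".join(anchors), "+".join(targets), radius_um,
        pd.DataFrame(rows, columns=["roi_id", "anchor_id", "count", "density_per_mm2"]),
        pd.DataFrame(agg, columns=["roi_id", "compartment", "n_anchors", "mean_count",
                                   "mean_density_per_mm2"]),
    )


def tls_area_mm2(member_xy: np.ndarray, disk_radius_um: float | None = None) -> float:
    """TLS area from the convex hull of member centroids, or a disk override."""
    if disk_radius_um is not None:
        return np.pi * (disk_radius_um / 1000.0) ** 2
    if len(member_xy) < 3:
        raise ValidationError("TLS area undefined for fewer than 3 member cells")
    hull = ConvexHull(member_xy)
    area = hull.volume / 1e6  # 2-D hull: .volume is the area, um^2 -> mm^2
    if area <= 0:
        raise ValidationError("TLS area is zero")
    return area


def tls_density(
    cells: CellTable,
    phenotypes,
    disk_radius_um: float | None = None,
    roi_area_mm2: float | None = None,
) -> pd.DataFrame:
    """Per-TLS densities (cells/mm^2) of the given phenotypes.

    TLS membership comes from the ``tls_id`` column. Area is the convex
    hull of the member cells unless ``disk_radius_um`` overrides it. When
    ``roi_area_mm2`` is given, an ``outside`` row per ROI reports the
    complement densities (phenotype counts outside every TLS divided by the
    ROI area minus the summed TLS areas).
    """
    phenotypes = _as_tuple(phenotypes)
    df = cells.df
    if "tls_id" not in df.columns:
        raise ValidationError("cell table has no tls_id column")
    rows = []
    tls_area_total: dict = {}
    for (roi, tid), grp in df[df["tls_id"].notna()].groupby(["roi_id", "tls_id"]):
        area = tls_area_mm2(grp[["x_um", "y_um"]].to_numpy(), disk_radius_um)
        tls_area_total[roi] = tls_area_total.get(roi, 0.0) + area
        row = dict(roi_id=roi, tls_id=tid, area_mm2=area, n_cells=len(grp))
        for ph in phenotypes:
            n = int((grp["phenotype"] == ph).sum())
            row[f"count_{ph}"] = n
            row[f"density_{ph}"] = n / area
        rows.append(row)
    if roi_area_mm2 is not None:
        for roi, grp in df.groupby("roi_id"):
            outside = grp[grp["tls_id"].isna()]
            area = roi_area_mm2 - tls_area_total.get(roi, 0.0)
            if area <= 0:
                raise ValidationError(f"non-positive outside-TLS area in ROI {roi!r}")
            row = dict(roi_id=roi, tls_id="outside", area_mm2=area, n_cells=len(outside))
            for ph in phenotypes:
                n = int((outside["phenotype"] == ph).sum())
                row[f"count_{ph}"] = n
                row[f"density_{ph}"] = n / area
            rows.append(row)
    return pd.DataFrame(rows)


def activation_exhaustion_ratio(
    tls_densities: pd.DataFrame,
    activated: str,
    exhausted: str,
) -> pd.Series:
    """Activated / exhausted density ratio per TLS.

    A TLS with zero exhausted-cell density yields a missing value (NaN),
    flagged with a warning, rather than infinity.
    """
    act = tls_densities[f"density_{activated}"]
    exh = tls_densities[f"density_{exhausted}"]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(exh > 0, act / exh, np.nan)
    if np.isnan(ratio).any():
        warnings.warn("TLS with zero exhausted-cell density: ratio undefined (NaN)")
    idx = tls_densities["tls_id"] if "tls_id" in tls_densities else tls_densities.index
    return pd.Series(ratio, index=idx, name=f"{activated}/{exhausted}")
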