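"""B cell - endothelial cell - T cell (BET) triad detection.

An endothelial cell (EC) is "in contact" with a lymphocyte when their
centroid distance is at most ``boundary_multiplier`` times the EC's major
axis length (the longest cell diameter; default multiplier 2, boundary
inclusive). An EC anchors a BET triad when at least one B cell *and* at
least one T cell are simultaneously in contact with it; ECs with contacts
of a single class or none are discarded. The EC-centric triad count is the
primary statistic; the number of distinct (B, T) contact pairs per triad EC
is reported alongside.

BET triads were proposed as an imaging proxy for high-endothelial-venule
mediated lymphocyte recruitment inside tertiary lymphoid structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ValidationError
from .io import CellTable

DEFAULT_EC_CLASSES = ("EC",)
DEFAULT_B_CLASSES = ("B",)
DEFAULT_T_CLASSES = ("CD4T", "CD8T", "CD4T_act", "CD4T_exh", "CD8T_act", "CD8T_exh", "Treg")


def classify_contacts(
    cells: CellTable,
    ec_classes=DEFAULT_EC_CLASSES,
    b_classes=DEFAULT_B_CLASSES,
    t_classes=DEFAULT_T_CLASSES,
    boundary_multiplier: float = 2.0,
) -> pd.DataFrame:
    """All (EC, lymphocyte) contact records.

    Returns a DataFrame with columns ``roi_id, ec_id, lymphocyte_id,
    lymphocyte_class (B|T), distance_um, boundary_um``; only pairs within
    the boundary (inclusive) are kept. Every EC row must carry a major axis
    length.
    """
    df = cells.df
    ecs = df[df["phenotype"].isin(ec_classes)]
    if "major_axis_um" not in df.columns or ecs["major_axis_um"].isna().any():
        bad = (
            ecs["cell_id"][ecs["major_axis_um"].isna()].tolist()
            if "major_axis_um" in df.columns
            else ecs["cell_id"].tolist()
        )
        raise ValidationError(f"EC rows missing major_axis_um: {bad[:10]}")
    records = []
    for roi, roi_df in df.groupby("roi_id", sort=False):
        ec = roi_df[roi_df["phenotype"].isin(ec_classes)]
        lymph = roi_df[roi_df["phenotype"].isin(tuple(b_classes) + tuple(t_classes))]
        if ec.empty or lymph.empty:
            continue
        tree = cKDTree(lymph[["x_um", "y_um"]].to_numpy())
        l_ids = lymph["cell_id"].to_numpy()
        l_class = np.where(lymph["phenotype"].isin(b_classes), "B", "T")
        l_xy = lymph[["x_um", "y_um"]].to_numpy()
        ec_xy = ec[["x_um", "y_um"]].to_numpy()
        bounds = boundary_multiplier * ec["major_axis_um"].to_numpy()
        hits = tree.query_ball_point(ec_xy, r=bounds)
        for k, (eid, b) in enumerate(zip(ec["cell_id"], bounds)):
            for idx in hits[k]:
                d = float(np.hypot(*(l_xy[idx] - ec_xy[k])))
                if d <= b:  # query_ball_point is inclusive; keep the check explicit
                    records.append(
                        dict(roi_id=roi, ec_id=eid, lymphocyte_id=l_ids[idx],
                             lymphocyte_class=l_class[idx], distance_um=d,
                             boundary_um=float(b))
                    )
    return pd.DataFrame(
        records,
        columns=["roi_id", "ec_id", "lymphocyte_id", "lymphocyte_class",
                 "distance_um", "boundary_um"],
    )


@dataclass
class TriadResult:
    """Per-ROI triad detection summary."""

    per_roi: pd.DataFrame  # roi_id, n_triads, n_triples
    triad_ec_ids: dict  # roi_id -> list of EC ids anchoring a triad


def detect_triads(contacts: pd.DataFrame) -> TriadResult:
    """EC-centric triad detection from contact records.

    An EC with >= 1 B contact and >= 1 T contact anchors one triad;
    single-class and contact-free ECs are dropped. ``n_triples`` counts
    distinct (B, T) pairs per triad EC, summed over triad ECs.
    """
    rows, ec_ids = [], {}
    if contacts.empty:
        return TriadResult(pd.DataFrame(columns=["roi_id", "n_triads", "n_triples"]), {})
    for roi, grp in contacts.groupby("roi_id", sort=False):
        tab = (
            grp.groupby("ec_id")["lymphocyte_class"]
            .value_counts()
            .unstack(fill_value=0)
            .reindex(columns=["B", "T"], fill_value=0)
        )
        triad = tab[(tab["B"] > 0) & (tab["T"] > 0)]
        rows.append(dict(roi_id=roi, n_triads=len(triad),
                         n_triples=int((triad["B"] * triad["T"]).sum())))
        ec_ids[roi] = sorted(triad.index)
    return TriadResult(pd.DataFrame(rows), ec_ids)


def triad_rate(result: TriadResult, roi_area_mm2) -> pd.DataFrame:
    """Triads per mm^2 of ROI area.

    ``roi_area_mm2`` is a scalar (same area for every ROI) or a mapping
    roi_id -> area.
    """
    out = result.per_roi.copy()
    if out.empty:
        out["area_mm2"] = pd.Series(dtype=float)
        out["triads_per_mm2"] = pd.Series(dtype=float)
        return out
    if np.isscalar(roi_area_mm2):
        out["area_mm2"] = float(roi_area_mm2)
    else:
        out["area_mm2"] = out["roi_id"].map(roi_area_mm2)
    if (out["area_mm2"] <= 0).any():
        raise ValidationError("ROI areas must be > 0")
    out["triads_per_mm2"] = out["n_triads"] / out["area_mm2"]
    return out
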