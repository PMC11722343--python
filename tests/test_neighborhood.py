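"""Proximity graph, anchored densities, TLS densities and ratios."""

import numpy as np
import pandas as pd
import pytest

import tmequant as tq
from tmequant.errors import ParameterError, ValidationError
from tmequant.neighborhood import tls_area_mm2


def test_edges_inclusive_at_exact_radius(make_cells):
    cells = make_cells(
        [("a", 0.0, 0.0, "Tumor"), ("b", 100.0, 0.0, "CD8T"), ("c", 0.0, 150.0, "CD8T")]
    )
    g = tq.build_neighbor_graph(cells, radius_um=100.0)
    assert g.has_edge("a", "b")  # exactly 100 um: edge (inclusive)
    assert not g.has_edge("a", "c")  # 150 um: no edge
    assert g.edges["a", "b"]["distance"] == pytest.approx(100.0)


def test_graph_matches_brute_force(make_cells):
    rng = np.random.default_rng(7)
    pts = rng.uniform(0, 400, size=(50, 2))
    cells = make_cells(
        [(f"c{i}", x, y, "Tumor") for i, (x, y) in enumerate(pts)]
    )
    g = tq.build_neighbor_graph(cells, radius_um=100.0)
    expected = {
        tuple(sorted((f"c{i}", f"c{j}")))
        for i in range(50)
        for j in range(i + 1, 50)
        if np.hypot(*(pts[i] - pts[j])) <= 100.0
    }
    assert {tuple(sorted(e)) for e in g.edges} == expected


def test_graph_rejects_bad_radius_and_multi_roi(make_cells):
    cells = make_cells([("a", 0, 0, "Tumor")])
    with pytest.raises(ParameterError):
        tq.build_neighbor_graph(cells, radius_um=0)
    two = pd.concat([cells.df, cells.df.assign(roi_id="R2")], ignore_index=True)
    with pytest.raises(ValidationError):
        tq.build_neighbor_graph(tq.CellTable(two))


def test_density_direct_arithmetic(make_cells):
    """3 targets inside r=100 um -> 3 / (pi * 0.01 mm^2) ~= 95.49 / mm^2."""
    cells = make_cells(
        [
            ("anchor", 0.0, 0.0, "Tumor"),
            ("t1", 10.0, 0.0, "CD8T"),
            ("t2", 0.0, 50.0, "CD8T"),
            ("t3", 70.0, 70.0, "CD8T"),  # ~99 um
            ("far", 200.0, 0.0, "CD8T"),
        ]
    )
    res = tq.density_around(cells, "Tumor", "CD8T", radius_um=100.0)
    assert res.per_anchor["count"].tolist() == [3]
    assert res.per_anchor["density_per_mm2"].iloc[0] == pytest.approx(95.49, abs=0.01)


def test_density_no_targets_zero(make_cells):
    cells = make_cells([("anchor", 0.0, 0.0, "Tumor")])
    res = tq.density_around(cells, "Tumor", "CD8T")
    assert res.per_anchor["density_per_mm2"].tolist() == [0.0]


def test_density_excludes_anchor_itself(make_cells):
    cells = make_cells([("a", 0.0, 0.0, "Tumor"), ("b", 10.0, 0.0, "Tumor")])
    res = tq.density_around(cells, "Tumor", "Tumor", radius_um=100.0)
    assert res.per_anchor["count"].tolist() == [1, 1]


def test_density_matches_brute_force_oracle(make_cells):
    rng = np.random.default_rng(11)
    rows = []
    pts = {}
    for i in range(120):
        ph = rng.choice(["Tumor", "CD8T_exh", "other"])
        x, y = rng.uniform(0, 500, 2)
        rows.append((f"c{i}", x, y, ph))
        pts[f"c{i}"] = (x, y, ph)
    cells = make_cells(rows)
    res = tq.density_around(cells, "Tumor", "CD8T_exh", radius_um=100.0)
    for rec in res.per_anchor.itertuples():
        ax, ay, _ = pts[rec.anchor_id]
        expected = sum(
            1
            for cid, (x, y, ph) in pts.items()
            if ph == "CD8T_exh" and cid != rec.anchor_id
            and np.hypot(x - ax, y - ay) <= 100.0
        )
        assert rec.count == expected


def test_density_no_anchor_roi_omitted_with_warning(make_cells):
    cells = make_cells([("a", 0, 0, "other")])
    with pytest.warns(UserWarning, match="no anchor"):
        res = tq.density_around(cells, "Tumor", "CD8T")
    assert res.per_roi.empty


def test_density_constant_under_radius_doubling(make_cells):
    """Uniform targets: expected density is radius-free; check within noise."""
    rng = np.random.default_rng(3)
    rows = [("anchor", 500.0, 500.0, "Tumor")]
    rows += [
        (f"t{i}", x, y, "CD8T") for i, (x, y) in
        enumerate(rng.uniform(0, 1000, size=(2000, 2)))
    ]
    cells = make_cells(rows)
    d1 = tq.density_around(cells, "Tumor", "CD8T", radius_um=100).per_anchor
    d2 = tq.density_around(cells, "Tumor", "CD8T", radius_um=200).per_anchor
    assert d2["density_per_mm2"].iloc[0] == pytest.approx(
        d1["density_per_mm2"].iloc[0], rel=0.25
    )


def test_tls_density_disk_arithmetic():
    """10 cells of a phenotype in a 0.05 mm^2 TLS -> 200 / mm^2."""
    # disk of radius sqrt(0.05/pi) mm = 126.16 um
    r_um = np.sqrt(0.05 / np.pi) * 1000
    rows = []
    for i in range(10):
        rows.append(dict(roi_id="R1", cell_id=f"b{i}", x_um=float(i), y_um=0.0,
                         phenotype="CD4T_act", major_axis_um=np.nan,
                         compartment="NS", tls_id="TLS1", patient_id="P1"))
    cells = tq.CellTable(pd.DataFrame(rows))
    out = tq.tls_density(cells, ("CD4T_act",), disk_radius_um=r_um)
    assert out["density_CD4T_act"].iloc[0] == pytest.approx(200.0, rel=1e-6)


def test_tls_inside_outside_partition():
    cfg = tq.SimConfig(seed=19)
    cells, truth = tq.simulate_roi(cfg)
    out = tq.tls_density(
        cells, ("CD8T_act",), disk_radius_um=cfg.tls_radius_um,
        roi_area_mm2=truth["roi_area_mm2"],
    )
    total = int((cells.df["phenotype"] == "CD8T_act").sum())
    assert out["count_CD8T_act"].sum() == total


def test_tls_empty_densities_zero():
    rows = [
        dict(roi_id="R1", cell_id=f"o{i}", x_um=float(i * 20), y_um=float(i * 13),
             phenotype="other", major_axis_um=np.nan, compartment="NS",
             tls_id="TLS1", patient_id="P1")
        for i in range(5)
    ]
    cells = tq.CellTable(pd.DataFrame(rows))
    out = tq.tls_density(cells, ("CD4T_act", "CD8T_exh"), disk_radius_um=100.0)
    assert (out[["density_CD4T_act", "density_CD8T_exh"]] == 0).all().all()


def test_tls_hull_area_requires_three_cells():
    with pytest.raises(ValidationError):
        tls_area_mm2(np.array([[0.0, 0.0], [1.0, 1.0]]))


@pytest.mark.parametrize(
    "act, exh, expected",
    [(2.0, 2.0, 1.0), (4.0, 2.0, 2.0)],
)
def test_activation_exhaustion_ratio(act, exh, expected):
    dens = pd.DataFrame(
        {"tls_id": ["TLS1"], "density_A": [act], "density_E": [exh]}
    )
    r = tq.activation_exhaustion_ratio(dens, "A", "E")
    assert r.iloc[0] == pytest.approx(expected)


def test_ratio_zero_exhausted_is_missing_not_inf():
    dens = pd.DataFrame({"tls_id": ["TLS1"], "density_A": [3.0], "density_E": [0.0]})
    with pytest.warns(UserWarning, match="undefined"):
        r = tq.activation_exhaustion_ratio(dens, "A", "E")
    assert np.isnan(r.iloc[0])


def test_geometry_invariant_under_rigid_motion(make_cells):
    rng = np.random.default_rng(23)
    pts = rng.uniform(0, 300, size=(60, 2))
    phenos = rng.choice(["Tumor", "CD8T"], size=60)
    cells = make_cells([(f"c{i}", x, y, p) for i, ((x, y), p) in enumerate(zip(pts, phenos))])
    base = tq.density_around(cells, "Tumor", "CD8T").per_anchor["count"].tolist()
    theta = rng.uniform(0, 2 * np.pi)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    moved = pts @ rot.T + np.array([1000.0, -400.0])
    cells2 = make_cells(
        [(f"c{i}", x, y, p) for i, ((x, y), p) in enumerate(zip(moved, phenos))]
    )
    assert tq.density_around(cells2, "Tumor", "CD8T").per_anchor["count"].tolist() == base
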