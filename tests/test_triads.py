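"""BET triad contact classification and detection."""

import numpy as np
import pandas as pd
import pytest

import tmequant as tq
from tmequant.errors import ValidationError


def brute_force_triads(df, boundary_multiplier=2.0):
    """O(n^2) oracle: per EC, scan every lymphocyte pairwise."""
    from tmequant.triads import DEFAULT_B_CLASSES, DEFAULT_T_CLASSES

    out = {}
    for roi, grp in df.groupby("roi_id"):
        ecs = grp[grp["phenotype"] == "EC"]
        triads = []
        triples = 0
        for ec in ecs.itertuples():
            bound = boundary_multiplier * ec.major_axis_um
            n_b = n_t = 0
            for cell in grp.itertuples():
                d = np.hypot(cell.x_um - ec.x_um, cell.y_um - ec.y_um)
                if d <= bound:
                    if cell.phenotype in DEFAULT_B_CLASSES:
                        n_b += 1
                    elif cell.phenotype in DEFAULT_T_CLASSES:
                        n_t += 1
            if n_b > 0 and n_t > 0:
                triads.append(ec.cell_id)
                triples += n_b * n_t
        out[roi] = (sorted(triads), triples)
    return out


def test_contact_boundary_arithmetic(make_cells):
    """EC axis 10 um: B at 15 um is contact, B at 25 um is not, 20 um is (inclusive)."""
    cells = make_cells(
        [
            ("ec", 0.0, 0.0, "EC", 10.0),
            ("b_in", 0.0, 15.0, "B"),
            ("b_out", 0.0, 25.0, "B"),
            ("b_edge", 20.0, 0.0, "B"),
        ]
    )
    contacts = tq.classify_contacts(cells)
    assert sorted(contacts["lymphocyte_id"]) == ["b_edge", "b_in"]
    assert (contacts["boundary_um"] == 20.0).all()


def test_no_lymphocytes_empty_contacts(make_cells):
    cells = make_cells([("ec", 0.0, 0.0, "EC", 10.0), ("t", 5.0, 5.0, "Tumor")])
    assert tq.classify_contacts(cells).empty


def test_ec_missing_axis_raises(make_cells):
    cells = make_cells([("ec", 0.0, 0.0, "EC"), ("b", 5.0, 0.0, "B")])
    with pytest.raises(ValidationError, match="ec"):
        tq.classify_contacts(cells)


def test_triad_requires_both_classes_on_same_ec(make_cells):
    cells = make_cells(
        [
            ("ec1", 0.0, 0.0, "EC", 10.0),
            ("ec2", 500.0, 500.0, "EC", 10.0),
            ("b", 10.0, 0.0, "B"),          # contacts ec1 only
            ("t", 510.0, 500.0, "CD8T"),    # contacts ec2 only
        ]
    )
    res = tq.detect_triads(tq.classify_contacts(cells))
    assert res.per_roi["n_triads"].sum() == 0


def test_single_triad_single_triple(make_cells):
    cells = make_cells(
        [
            ("ec", 0.0, 0.0, "EC", 10.0),
            ("b", 0.0, 15.0, "B"),
            ("t", 12.0, 0.0, "CD4T"),
        ]
    )
    res = tq.detect_triads(tq.classify_contacts(cells))
    assert res.per_roi.iloc[0]["n_triads"] == 1
    assert res.per_roi.iloc[0]["n_triples"] == 1
    assert res.triad_ec_ids["R1"] == ["ec"]


def test_triple_count_is_b_times_t(make_cells):
    cells = make_cells(
        [
            ("ec", 0.0, 0.0, "EC", 10.0),
            ("b1", 0.0, 15.0, "B"),
            ("b2", 0.0, -15.0, "B"),
            ("t1", 12.0, 0.0, "CD4T"),
            ("t2", -12.0, 0.0, "CD8T"),
            ("t3", 0.0, 18.0, "Treg"),
        ]
    )
    res = tq.detect_triads(tq.classify_contacts(cells))
    assert res.per_roi.iloc[0]["n_triads"] == 1
    assert res.per_roi.iloc[0]["n_triples"] == 2 * 3


def test_matches_brute_force_on_random_fixtures(make_cells):
    rng = np.random.default_rng(5)
    for rep in range(20):
        n = rng.integers(30, 120)
        rows = []
        for i in range(n):
            ph = rng.choice(["EC", "B", "CD4T", "CD8T", "Tumor", "other"])
            axis = float(rng.uniform(5, 20)) if ph == "EC" else np.nan
            rows.append((f"c{i}", *rng.uniform(0, 300, 2), ph, axis))
        cells = make_cells(rows)
        res = tq.detect_triads(tq.classify_contacts(cells))
        oracle = brute_force_triads(cells.df)
        got = res.triad_ec_ids.get("R1", [])
        exp_ids, exp_triples = oracle.get("R1", ([], 0))
        assert got == exp_ids
        got_triples = (
            int(res.per_roi["n_triples"].iloc[0]) if len(res.per_roi) else 0
        )
        assert got_triples == exp_triples


def test_boundary_multiplier_flag(make_cells):
    cells = make_cells(
        [("ec", 0.0, 0.0, "EC", 10.0), ("b", 0.0, 15.0, "B"), ("t", 12.0, 0.0, "CD4T")]
    )
    # 1x multiplier: boundary 10 um, neither lymphocyte reaches it
    contacts = tq.classify_contacts(cells, boundary_multiplier=1.0)
    assert contacts.empty


def test_triad_rate_proportional_to_area(make_cells):
    cells = make_cells(
        [("ec", 0.0, 0.0, "EC", 10.0), ("b", 0.0, 15.0, "B"), ("t", 12.0, 0.0, "CD4T")]
    )
    res = tq.detect_triads(tq.classify_contacts(cells))
    r2 = tq.triad_rate(res, 2.0)
    r1 = tq.triad_rate(res, 1.0)
    assert r2["triads_per_mm2"].iloc[0] == pytest.approx(0.5)
    assert r1["triads_per_mm2"].iloc[0] == pytest.approx(2 * r2["triads_per_mm2"].iloc[0])
    assert tq.triad_rate(tq.TriadResult(pd.DataFrame(columns=["roi_id", "n_triads", "n_triples"]), {}), 2.0).empty


def test_detection_invariant_under_rigid_motion(make_cells):
    rng = np.random.default_rng(41)
    cfg = tq.SimConfig(seed=41)
    cells, truth = tq.simulate_roi(cfg)
    base = tq.detect_triads(tq.classify_contacts(cells)).triad_ec_ids["ROI1"]
    theta = rng.uniform(0, 2 * np.pi)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    df = cells.df.copy()
    xy = df[["x_um", "y_um"]].to_numpy() @ rot.T + np.array([123.0, -77.0])
    df[["x_um", "y_um"]] = xy
    moved = tq.CellTable(df)
    assert tq.detect_triads(tq.classify_contacts(moved)).triad_ec_ids["ROI1"] == base


def test_permutation_null_destroys_planted_excess():
    """Random lymphocyte relocation drops triad counts below the planted count.

    Background B/T densities are zeroed so the only lymphocytes are the
    planted legs and TLS members; with them shuffled uniformly, chance
    contacts with the ~hundred ECs are rare and the planted excess vanishes.
    """
    dens = dict(tq.synthetic.DEFAULT_DENSITIES)
    for ph in tq.synthetic.B_PHENOTYPES + tq.synthetic.T_PHENOTYPES:
        dens[ph] = 0.0
    cfg = tq.SimConfig(seed=8, densities=dens)
    cells, truth = tq.simulate_roi(cfg)
    planted = len(truth["triad_ec_ids"])
    rng = np.random.default_rng(0)
    df = cells.df
    lymph_mask = df["phenotype"].isin(
        tq.synthetic.B_PHENOTYPES + tq.synthetic.T_PHENOTYPES
    )
    width, height = cfg.roi_size_um
    null_counts = []
    for _ in range(50):
        shuffled = df.copy()
        shuffled.loc[lymph_mask, "x_um"] = rng.uniform(0, width, lymph_mask.sum())
        shuffled.loc[lymph_mask, "y_um"] = rng.uniform(0, height, lymph_mask.sum())
        res = tq.detect_triads(tq.classify_contacts(tq.CellTable(shuffled)))
        null_counts.append(res.per_roi["n_triads"].sum() if len(res.per_roi) else 0)
    assert planted > np.percentile(null_counts, 95)
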