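"""Synthetic data with known ground truth for every analysis stage.

The generators emulate the four substrates the pipeline consumes:

* IMC-like ROIs: homogeneous Poisson point patterns per phenotype with
  planted endothelial-cell (EC) triads, single-contact distractor ECs and
  tertiary-lymphoid-structure (TLS) disks;
* scRNA-seq-like count matrices: negative-binomial (Gamma-Poisson) counts
  with lognormal library sizes, planted AT2/club expression programs,
  mitochondrial fractions and marker-co-expressing doublets;
* per-cell CNV matrices: Gaussian noise around neutral with additive
  chromosome-arm shifts in tumor cells;
* Visium-like spot grids: Poisson counts with planted spatially variable
  genes on a smooth gradient and a planted positively correlated cell-type
  pair.

Every generator is deterministic given ``SimConfig.seed`` and returns a
``truth`` record sufficient to score the downstream detector (precision and
recall are computable without re-deriving anything).

Planted geometry is kept *certifiable*: background B/T lymphocytes are
rejection-sampled out of a 4x-major-axis exclusion disk around every EC, and
planted ECs are mutually separated, so the planted triad set is provably the
complete triad set of the ROI. Real tissue has no such exclusion zones; see
the methods note for what this does and does not test.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CapacityError, ParameterError, ValidationError
from .io import CellTable, ExpressionMatrix, GeneSignature, SpotTable

import anndata as ad


DEFAULT_DENSITIES = {
    # cells / mm^2, loosely scaled to lung IMC ROIs
    "Tumor": 600.0,
    "EC": 60.0,
    "B": 80.0,
    "CD4T": 120.0,
    "CD8T": 100.0,
    "CD4T_act": 40.0,
    "CD4T_exh": 30.0,
    "CD8T_act": 40.0,
    "CD8T_exh": 30.0,
    "Treg": 30.0,
    "M1": 40.0,
    "M2": 50.0,
    "DC": 20.0,
    "other": 200.0,
}

#: lymphocyte phenotypes that can satisfy the B or T leg of a triad
B_PHENOTYPES = ("B",)
T_PHENOTYPES = ("CD4T", "CD8T", "CD4T_act", "CD4T_exh", "CD8T_act", "CD8T_exh", "Treg")


@dataclass
class SimConfig:
    """Parameters of all generators; one seed fixes every output bit-for-bit."""

    seed: int = 0
    roi_size_um: tuple = (1500.0, 1500.0)
    densities: dict = field(default_factory=lambda: dict(DEFAULT_DENSITIES))
    # triad planting
    n_triads_planted: int = 7
    n_distractors: int = 5
    ec_axis_median_um: float = 10.0
    ec_axis_sigma: float = 0.25
    # TLS disks
    n_tls: int = 2
    tls_radius_um: float = 150.0
    tls_n_cells: int = 200
    tls_b_fraction: float = 0.5
    tls_t_fraction: float = 0.4
    tls_b_core_fraction: float = 0.6  # B cells confined to this radius fraction
    # expression programs
    program_delta: float = 1.0  # mean log-expression shift on signature genes
    program_fraction: float = 0.5  # fraction of cells carrying the first program
    n_signature_genes: int = 10
    # base mean counts of the AT2 and club gene blocks; distinct strata keep
    # the two programs in different expression bins during scoring
    program_base_means: tuple = (20.0, 8.0)
    nb_dispersion: float = 10.0  # Gamma shape; larger = closer to Poisson
    library_sigma: float = 0.25  # lognormal sd of per-cell library factor
    doublet_rate: float = 0.0
    mito_beta: tuple = (2.0, 38.0)  # per-cell mito fraction ~ Beta(a, b)
    n_patients: int = 4
    # None: programs i.i.d. per cell; a float p: patients alternate a dominant
    # program (AT2, club, AT2, ...) and each cell follows it with probability p
    patient_program_purity: float | None = None
    # CNV
    cnv_noise_sd: float = 0.05
    cnv_shifts: dict = field(default_factory=lambda: {"1q": 0.5})
    cnv_tumor_fraction: float = 0.5
    # spots
    n_sv_genes: int = 5
    sv_amplitude: float = 2.0  # log-scale amplitude of the planted gradient
    spot_base_mean: float = 5.0
    n_cell_types: int = 6
    coexist_shared_rate: float = 20.0  # shared latent count driving the planted pair

    def __post_init__(self):
        if any(d < 0 for d in self.densities.values()):
            raise ParameterError("densities must be >= 0")
        for frac in (
            self.tls_b_fraction,
            self.tls_t_fraction,
            self.tls_b_core_fraction,
            self.program_fraction,
            self.doublet_rate,
            self.cnv_tumor_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ParameterError(f"fractions must lie in [0, 1]; got {frac}")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# IMC-like ROI
# ---------------------------------------------------------------------------

def _sample_positions(rng, n, width, height):
    return np.column_stack([rng.uniform(0, width, n), rng.uniform(0, height, n)])


def _resample_outside(rng, pts, centers, radii, width, height, max_tries=2000):
    """Rejection-sample points until none lies inside any exclusion disk."""
    if len(centers) == 0 or len(pts) == 0:
        return pts
    centers = np.asarray(centers)
    radii = np.asarray(radii)
    pts = pts.copy()
    for _ in range(max_tries):
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        inside = (d2 <= (radii[None, :] ** 2)).any(axis=1)
        if not inside.any():
            return pts
        pts[inside] = _sample_positions(rng, int(inside.sum()), width, height)
    raise CapacityError("could not place background cells outside exclusion zones")


def simulate_roi(config: SimConfig, roi_id: str = "ROI1", compartment: str = "NS",
                 patient_id: str = "P1"):
    """Simulate one ROI; returns ``(CellTable, truth)``.

    ``truth`` records the planted triad EC ids, distractor EC ids, TLS
    membership (disk centers/radii and member cell ids) and the ROI area.
    """
    rng = np.random.default_rng(config.seed)
    width, height = config.roi_size_um
    area_mm2 = width * height / 1e6

    rows: list[dict] = []
    next_id = [0]

    def add(phenotype, x, y, axis=np.nan, tls=pd.NA):
        next_id[0] += 1
        cid = f"c{next_id[0]:05d}"
        rows.append(
            dict(roi_id=roi_id, cell_id=cid, x_um=float(x), y_um=float(y),
                 phenotype=phenotype, major_axis_um=axis, compartment=compartment,
                 tls_id=tls, patient_id=patient_id)
        )
        return cid

    def ec_axis(n):
        return np.exp(rng.normal(np.log(config.ec_axis_median_um), config.ec_axis_sigma, n))

    # --- TLS disk centers first (fewest placement constraints) -------------
    n_planted = config.n_triads_planted + config.n_distractors
    axes = ec_axis(n_planted)
    max_axis = axes.max(initial=config.ec_axis_median_um)
    tls_margin = config.tls_radius_um
    tls_centers_arr: list[np.ndarray] = []
    for _ in range(config.n_tls):
        if width <= 2 * tls_margin or height <= 2 * tls_margin:
            raise CapacityError("ROI too small for requested TLS disks")
        for _try in range(5000):
            c = np.array([rng.uniform(tls_margin, width - tls_margin),
                          rng.uniform(tls_margin, height - tls_margin)])
            if all(np.linalg.norm(c - q) > 2.2 * config.tls_radius_um
                   for q in tls_centers_arr):
                tls_centers_arr.append(c)
                break
        else:
            raise CapacityError("could not place non-overlapping TLS disks")

    # --- planted ECs (triads + distractors), separated and outside TLS -----
    margin = 4.0 * max_axis if n_planted else 0.0
    if n_planted and (width <= 2 * margin or height <= 2 * margin):
        raise CapacityError("ROI too small for requested planted ECs")
    sep = 8.0 * axes.max(initial=0.0)
    # TLS lymphocytes sit within tls_radius of the center; keeping ECs
    # 4 axes further out guarantees they stay beyond the 2x-axis contact range
    tls_clear = config.tls_radius_um + 4.0 * max_axis
    centers: list[np.ndarray] = []
    for _ in range(n_planted):
        for _try in range(5000):
            p = np.array([rng.uniform(margin, width - margin),
                          rng.uniform(margin, height - margin)])
            if (all(np.linalg.norm(p - q) > sep for q in centers)
                    and all(np.linalg.norm(p - c) > tls_clear for c in tls_centers_arr)):
                centers.append(p)
                break
        else:
            raise CapacityError(
                f"could not place {n_planted} separated ECs in a "
                f"{width}x{height} um ROI"
            )

    def place_lymph(center, axis, lo_mult, hi_mult, phenotype):
        # radius uniform in (lo, hi] x axis, angle uniform
        r = axis * (lo_mult + (hi_mult - lo_mult) * (1.0 - rng.uniform()))
        theta = rng.uniform(0, 2 * np.pi)
        return add(phenotype, center[0] + r * np.cos(theta), center[1] + r * np.sin(theta))

    triad_ec_ids, distractor_ec_ids = [], []
    for i in range(n_planted):
        c, a = centers[i], axes[i]
        ecid = add("EC", c[0], c[1], axis=a)
        if i < config.n_triads_planted:
            triad_ec_ids.append(ecid)
            place_lymph(c, a, 0.0, 2.0, "B")
            place_lymph(c, a, 0.0, 2.0, rng.choice(["CD4T", "CD8T"]))
        else:
            distractor_ec_ids.append(ecid)
            # single-contact EC plus an out-of-reach lymphocyte of the other class
            if rng.uniform() < 0.5:
                place_lymph(c, a, 0.0, 2.0, "B")
                place_lymph(c, a, 2.0, 4.0, rng.choice(["CD4T", "CD8T"]))
            else:
                place_lymph(c, a, 0.0, 2.0, rng.choice(["CD4T", "CD8T"]))
                place_lymph(c, a, 2.0, 4.0, "B")

    # --- populate TLS disks -------------------------------------------------
    tls_truth = {}
    for t, c in enumerate(tls_centers_arr):
        tid = f"TLS{t + 1}"
        members = []
        n_b = int(round(config.tls_n_cells * config.tls_b_fraction))
        n_t = int(round(config.tls_n_cells * config.tls_t_fraction))
        n_o = config.tls_n_cells - n_b - n_t
        core = config.tls_b_core_fraction * config.tls_radius_um
        for phenotype, n, rmax, rmin in (
            ("B", n_b, core, 0.0),
            # T cells occupy the ring around the B core
            ("T_RING", n_t, config.tls_radius_um, core),
            ("other", n_o, config.tls_radius_um, 0.0),
        ):
            for _ in range(n):
                r = np.sqrt(rng.uniform(rmin ** 2, rmax ** 2))
                th = rng.uniform(0, 2 * np.pi)
                ph = phenotype
                if ph == "T_RING":
                    ph = rng.choice(["CD4T_act", "CD4T_exh", "CD8T_act", "CD8T_exh"])
                members.append(add(ph, c[0] + r * np.cos(th), c[1] + r * np.sin(th), tls=tid))
        tls_truth[tid] = {"center": c, "radius_um": config.tls_radius_um,
                          "member_ids": members}

    # --- background ---------------------------------------------------------
    # ECs are placed before lymphocytes so the lymphocyte exclusion disks can
    # cover every EC (planted and background) when they are sampled.
    tls_centers = [v["center"] for v in tls_truth.values()]
    order = sorted(config.densities.items(), key=lambda kv: kv[0] != "EC")
    for phenotype, dens in order:
        n = rng.poisson(dens * area_mm2)
        if n == 0:
            continue
        pts = _sample_positions(rng, n, width, height)
        if phenotype == "EC":
            axes_bg = ec_axis(n)
            # stay out of TLS disks, clear of other ECs and clear of every
            # lymphocyte already placed (the planted triad/distractor legs)
            ec_pts = [np.array([r["x_um"], r["y_um"]]) for r in rows
                      if r["phenotype"] == "EC"]
            ec_rad = [8.0 * r["major_axis_um"] for r in rows if r["phenotype"] == "EC"]
            lymph = [np.array([r["x_um"], r["y_um"]]) for r in rows
                     if r["phenotype"] in B_PHENOTYPES + T_PHENOTYPES]
            ctr = ec_pts + tls_centers + lymph
            rad = (ec_rad
                   + [config.tls_radius_um + 4.0 * axes_bg.max()] * len(tls_centers)
                   + [4.0 * axes_bg.max()] * len(lymph))
            pts = _resample_outside(rng, pts, ctr, rad, width, height)
            for (x, y), a in zip(pts, axes_bg):
                add("EC", x, y, axis=a)
            continue
        if phenotype in B_PHENOTYPES or phenotype in T_PHENOTYPES:
            # keep background lymphocytes certifiably away from every EC
            excl_centers = [np.array([r["x_um"], r["y_um"]]) for r in rows
                            if r["phenotype"] == "EC"]
            excl_radii = [4.0 * r["major_axis_um"] for r in rows
                          if r["phenotype"] == "EC"]
            pts = _resample_outside(rng, pts, excl_centers, excl_radii, width, height)
        for x, y in pts:
            add(phenotype, x, y)

    df = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["roi_id", "cell_id", "x_um", "y_um", "phenotype",
                 "major_axis_um", "compartment", "tls_id", "patient_id"])
    truth = {
        "triad_ec_ids": triad_ec_ids,
        "distractor_ec_ids": distractor_ec_ids,
        "tls": tls_truth,
        "roi_area_mm2": area_mm2,
    }
    return CellTable(df), truth


# ---------------------------------------------------------------------------
# scRNA-seq-like counts
# ---------------------------------------------------------------------------

LINEAGE_MARKERS = {
    "epithelial": ("SFTPC", "SCGB3A1"),
    "T": ("CD3D",),
    "B_plasma": ("CD79A", "JCHAIN", "MZB1"),
    "myeloid": ("MARCO", "CD163"),
}
PAN_IMMUNE_MARKERS = ("PTPRC",)
N_MITO_GENES = 10


def _gene_names(n_background: int) -> list:
    markers = [g for gs in LINEAGE_MARKERS.values() for g in gs] + list(PAN_IMMUNE_MARKERS)
    mito = [f"MT-G{i + 1}" for i in range(N_MITO_GENES)]
    bg = [f"G{i + 1:05d}" for i in range(n_background)]
    return bg + markers + mito


def simulate_expression(config: SimConfig, n_cells: int = 1000, n_genes: int = 1000):
    """Simulate a count matrix with two planted programs; returns
    ``(ExpressionMatrix, truth)``.

    The first ``n_signature_genes`` background genes form the AT2 program,
    the next block the club program. Cells in a program group have the
    log-mean of their program's genes shifted by ``program_delta``. Lineage
    marker genes and mitochondrial genes are appended after the background
    block. ``truth`` carries per-cell program labels, doublet flags, target
    mitochondrial fractions and the two planted signatures.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_signature_genes
    if n_genes < 2 * k + 20:
        raise ParameterError("n_genes too small for the planted programs")
    names = _gene_names(n_genes)
    n_total = len(names)

    at2_genes = names[:k]
    club_genes = names[k: 2 * k]
    sig_at2 = GeneSignature("AT2", tuple(at2_genes), role="AT2")
    sig_club = GeneSignature("club", tuple(club_genes), role="club")

    # gene-wise base means: mostly low lognormal background plus a block of
    # high-expression housekeeping-like genes spanning the upper decades, so
    # the two program blocks (placed at different base levels) fall into
    # different mean-expression bins and do not contaminate each other's
    # control pools during scoring
    mu = np.exp(rng.normal(np.log(0.3), 1.0, n_total))
    n_hk = min(200, max(0, n_genes - 2 * k - 50))
    mu[2 * k: 2 * k + n_hk] = np.exp(rng.normal(np.log(10.0), 1.0, n_hk))
    mu[:k] = config.program_base_means[0]  # AT2 program stratum
    mu[k: 2 * k] = config.program_base_means[1]  # club program stratum
    marker_idx = slice(n_genes, n_genes + 8)  # lineage + pan-immune markers
    mu[marker_idx] = 0.0  # markers off by default; doublets switch them on
    mito_idx = slice(n_total - N_MITO_GENES, n_total)

    patient_idx = np.arange(n_cells) % config.n_patients
    if config.patient_program_purity is None:
        groups = np.where(rng.uniform(size=n_cells) < config.program_fraction, "AT2", "club")
    else:
        dominant = np.where(patient_idx % 2 == 0, "AT2", "club")
        follow = rng.uniform(size=n_cells) < config.patient_program_purity
        other = np.where(dominant == "AT2", "club", "AT2")
        groups = np.where(follow, dominant, other)
    shift = np.ones((n_cells, n_total))
    shift[groups == "AT2", : k] = np.exp(config.program_delta)
    shift[groups == "club", k: 2 * k] = np.exp(config.program_delta)

    # per-cell mito target fraction determines mito gene means
    mito_frac = rng.beta(*config.mito_beta, size=n_cells)
    base_total = mu.sum()
    mito_mu = mito_frac / (1.0 - mito_frac) * base_total / N_MITO_GENES

    lib = np.exp(rng.normal(0.0, config.library_sigma, n_cells))
    mean = shift * mu[None, :] * lib[:, None]
    mean[:, mito_idx] = mito_mu[:, None] * lib[:, None]

    theta = config.nb_dispersion
    lam = mean * rng.gamma(theta, 1.0 / theta, size=mean.shape)
    counts = rng.poisson(lam).astype(np.float64)

    # planted doublets co-express two random lineage marker sets
    doublet = rng.uniform(size=n_cells) < config.doublet_rate
    lineages = list(LINEAGE_MARKERS)
    pair_record = {}
    gene_pos = {g: i for i, g in enumerate(names)}
    for ci in np.flatnonzero(doublet):
        pair = rng.choice(len(lineages), size=2, replace=False)
        pair_names = (lineages[pair[0]], lineages[pair[1]])
        for lin in pair_names:
            for g in LINEAGE_MARKERS[lin]:
                counts[ci, gene_pos[g]] = rng.poisson(5) + 1
        pair_record[f"cell{ci + 1:05d}"] = pair_names

    cell_ids = [f"cell{i + 1:05d}" for i in range(n_cells)]
    patients = [f"P{1 + i % config.n_patients}" for i in range(n_cells)]
    obs = pd.DataFrame(
        {
            "patient_id": patients,
            "compartment": [("NS", "S")[i % 2] for i in range(n_cells)],
            "cluster": ["tumor"] * n_cells,
        },
        index=cell_ids,
    )
    var = pd.DataFrame(
        {"mito": [i >= n_total - N_MITO_GENES for i in range(n_total)]}, index=names
    )
    expr = ExpressionMatrix(ad.AnnData(X=counts, obs=obs, var=var))
    truth = {
        "program": pd.Series(groups, index=cell_ids),
        "doublet": pd.Series(doublet, index=cell_ids),
        "doublet_lineages": pair_record,
        "mito_fraction": pd.Series(mito_frac, index=cell_ids),
        "signatures": {"AT2": sig_at2, "club": sig_club},
    }
    return expr, truth


# ---------------------------------------------------------------------------
# CNV matrix
# ---------------------------------------------------------------------------

def simulate_cnv(config: SimConfig, n_cells: int = 500, arm_map: pd.Series | None = None):
    """Simulate a cells x genes CNV matrix; returns ``(DataFrame, truth)``.

    Reference cells carry pure Normal(0, ``cnv_noise_sd``) values; a
    ``cnv_tumor_fraction`` of cells additionally receives the additive arm
    shifts of ``cnv_shifts``. ``truth`` has the per-cell tumor flag and the
    arm map used.
    """
    rng = np.random.default_rng(config.seed)
    if arm_map is None:
        arms = ["1p", "1q", "2p", "2q", "3p", "3q", "4p", "4q", "5p", "5q"]
        genes_per_arm = 10
        arm_map = pd.Series(
            {f"g_{a}_{i + 1}": a for a in arms for i in range(genes_per_arm)}
        )
    genes = list(arm_map.index)
    vals = rng.normal(0.0, config.cnv_noise_sd, size=(n_cells, len(genes)))
    tumor = rng.uniform(size=n_cells) < config.cnv_tumor_fraction
    for arm, amp in config.cnv_shifts.items():
        cols = np.flatnonzero(arm_map.to_numpy() == arm)
        if cols.size == 0:
            raise ValidationError(f"cnv_shifts names arm {arm!r} absent from the arm map")
        vals[np.ix_(tumor, cols)] += amp
    cell_ids = [f"cell{i + 1:05d}" for i in range(n_cells)]
    cnv = pd.DataFrame(vals, index=cell_ids, columns=genes)
    truth = {"tumor": pd.Series(tumor, index=cell_ids), "arm_map": arm_map}
    return cnv, truth


# ---------------------------------------------------------------------------
# Spot grid
# ---------------------------------------------------------------------------

def simulate_spots(config: SimConfig, grid: tuple = (20, 20), n_genes: int = 200):
    """Simulate a spot grid; returns ``(SpotTable, truth)``.

    Most genes are spatially flat Poisson; the first ``n_sv_genes`` genes
    follow a smooth linear gradient of log-amplitude ``sv_amplitude`` in a
    random direction. Per-spot cell-type counts include one planted
    positively correlated pair (types 0 and 1) driven by a shared latent
    Poisson count. ``truth`` lists the spatially variable genes and the pair.
    """
    rng = np.random.default_rng(config.seed)
    nx_, ny_ = grid
    xs, ys = np.meshgrid(np.arange(nx_), np.arange(ny_), indexing="ij")
    coords = pd.DataFrame(
        {"x": xs.ravel(), "y": ys.ravel()},
        index=[f"spot{i + 1:04d}" for i in range(nx_ * ny_)],
    )
    n_spots = len(coords)
    genes = [f"SV{i + 1}" for i in range(config.n_sv_genes)] + [
        f"FLAT{i + 1}" for i in range(n_genes - config.n_sv_genes)
    ]
    theta = rng.uniform(0, 2 * np.pi)
    proj = (coords["x"] * np.cos(theta) + coords["y"] * np.sin(theta)).to_numpy()
    s = (proj - proj.min()) / max(proj.max() - proj.min(), 1e-12)  # in [0, 1]

    mean = np.full((n_spots, n_genes), config.spot_base_mean)
    for j in range(config.n_sv_genes):
        mean[:, j] = config.spot_base_mean * np.exp(config.sv_amplitude * (s - 0.5))
    depth = np.exp(rng.normal(0.0, 0.15, n_spots))
    counts = rng.poisson(mean * depth[:, None]).astype(float)
    expr = pd.DataFrame(counts, index=coords.index, columns=genes)

    types = [f"type{k + 1}" for k in range(config.n_cell_types)]
    shared = rng.poisson(config.coexist_shared_rate, n_spots)
    tc = rng.poisson(10.0, size=(n_spots, config.n_cell_types)).astype(float)
    tc[:, 0] += shared
    tc[:, 1] += shared
    cell_counts = pd.DataFrame(tc, index=coords.index, columns=types)

    spots = SpotTable(expr, coords, cell_counts)
    truth = {
        "sv_genes": genes[: config.n_sv_genes],
        "correlated_pair": (types[0], types[1]),
        "gradient": pd.Series(s, index=coords.index),
    }
    return spots, truth
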