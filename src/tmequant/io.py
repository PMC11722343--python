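"""Domain types and readers/writers for the tabular and matrix substrates.

Five substrates flow through the package:

* :class:`CellTable` — segmented cells from multiplexed imaging, one row per
  cell with centroid coordinates in micrometers (image convention: origin
  top-left, y increasing downward; all downstream geometry uses distances
  only, so the convention never enters a computation).
* :class:`ExpressionMatrix` — cells x genes counts (an :class:`anndata.AnnData`
  under the hood) for QC and signature scoring.
* :class:`GeneSignature` — a named gene list.
* CNV matrices — plain cells x genes :class:`pandas.DataFrame` of copy-number
  deviations from neutral (0-centered), plus a gene -> chromosome-arm map.
* :class:`SpotTable` — spot-based spatial transcriptomics counts with spot
  grid coordinates and optional per-spot cell-type counts.

File formats are deliberately boring: CSV for cell tables, MatrixMarket +
TSV sidecars for expression, TSV for everything else.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import FormatError, SchemaError, ValidationError

COMPARTMENTS = ("NL", "NS", "S")
"""Tissue compartments: adjacent normal lung, non-solid (preinvasive) and
solid (invasive) components of a part-solid nodule."""

CELL_TABLE_REQUIRED = (
    "roi_id",
    "cell_id",
    "x_um",
    "y_um",
    "phenotype",
    "compartment",
    "patient_id",
)
CELL_TABLE_OPTIONAL = ("major_axis_um", "tls_id")


# ---------------------------------------------------------------------------
# CellTable
# ---------------------------------------------------------------------------

@dataclass
class CellTable:
    """Validated table of segmented cells from one or more imaging ROIs.

    ``df`` holds one row per cell with at least the columns in
    :data:`CELL_TABLE_REQUIRED`; ``major_axis_um`` (longest cell diameter,
    required downstream for endothelial cells) and ``tls_id`` (tertiary
    lymphoid structure membership, NA = outside any TLS) are optional.
    Unknown extra columns are preserved untouched.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = validate_cell_table(self.df)

    @property
    def n_cells(self) -> int:
        return len(self.df)

    def rois(self) -> list:
        return list(self.df["roi_id"].unique())

    def subset_roi(self, roi_id) -> "CellTable":
        return CellTable(self.df[self.df["roi_id"] == roi_id].copy())


def validate_cell_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check CellTable invariants, raising with offending row indices."""
    missing = [c for c in CELL_TABLE_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"cell table is missing mandatory column(s): {missing}")
    for col in ("x_um", "y_um"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[~np.isfinite(vals)].tolist()
        if bad:
            raise ValidationError(f"non-finite or non-numeric {col} at rows {bad[:10]}")
        df = df.assign(**{col: vals.astype(float)})
    if "major_axis_um" in df.columns:
        axis = pd.to_numeric(df["major_axis_um"], errors="coerce")
        present = df["major_axis_um"].notna()
        bad = df.index[present & ~(axis > 0)].tolist()
        if bad:
            raise ValidationError(f"major_axis_um must be > 0 where present; rows {bad[:10]}")
        df = df.assign(major_axis_um=axis)
    dup = df.duplicated(subset=["roi_id", "cell_id"])
    if dup.any():
        raise ValidationError(
            f"(roi_id, cell_id) must be unique; duplicated rows {df.index[dup].tolist()[:10]}"
        )
    bad_comp = ~df["compartment"].isin(COMPARTMENTS)
    if bad_comp.any():
        raise ValidationError(
            f"compartment must be one of {COMPARTMENTS}; rows {df.index[bad_comp].tolist()[:10]}"
        )
    return df


def read_cell_table(path) -> CellTable:
    """Read a segmented-cell CSV (UTF-8, comma separated, header mandatory)."""
    df = pd.read_csv(path)
    return CellTable(df)


def write_cell_table(cells: CellTable, path) -> None:
    cells.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------

class ExpressionMatrix:
    """Cells x genes count matrix with per-cell and per-gene metadata.

    Thin wrapper over :class:`anndata.AnnData`: ``X`` holds non-negative
    counts (cells as rows), ``obs`` per-cell metadata (``patient_id``,
    ``compartment``, ``cluster`` when available) and ``var`` per-gene
    metadata including the boolean ``mito`` flag used by QC.
    """

    def __init__(self, adata: ad.AnnData):
        if adata.n_obs and adata.n_vars:
            x = adata.X
            mn = x.min() if not scipy.sparse.issparse(x) else x.data.min(initial=0)
            if mn < 0:
                raise ValidationError("expression counts must be non-negative")
        if adata.var_names.has_duplicates:
            raise ValidationError("gene ids must be unique")
        if "mito" not in adata.var.columns:
            adata.var["mito"] = adata.var_names.str.upper().str.startswith(("MT-", "MT."))
        self.adata = adata

    @property
    def n_cells(self) -> int:
        return self.adata.n_obs

    @property
    def n_genes(self) -> int:
        return self.adata.n_vars

    @property
    def cell_ids(self) -> pd.Index:
        return self.adata.obs_names

    @property
    def gene_ids(self) -> pd.Index:
        return self.adata.var_names

    def counts(self) -> np.ndarray:
        """Dense cells x genes count array."""
        x = self.adata.X
        return np.asarray(x.todense()) if scipy.sparse.issparse(x) else np.asarray(x)

    def genes_detected(self) -> pd.Series:
        """Number of genes with count > 0 per cell."""
        return pd.Series((self.counts() > 0).sum(axis=1), index=self.cell_ids)

    def mito_fraction(self) -> pd.Series:
        """Fraction of counts coming from mitochondrial genes, per cell."""
        x = self.counts()
        total = x.sum(axis=1)
        mito = x[:, self.adata.var["mito"].to_numpy(dtype=bool)].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
        return pd.Series(frac, index=self.cell_ids)


def read_expression(mtx_path, genes_path, cells_path) -> ExpressionMatrix:
    """Read counts from MatrixMarket plus TSV sidecars.

    The matrix is cells x genes (rows = cells). The genes sidecar has one
    gene per row (columns ``gene_id`` and optional ``mito``); the cells
    sidecar one cell per row (``cell_id`` plus metadata columns).
    """
    x = scipy.io.mmread(str(mtx_path)).tocsr()
    genes = pd.read_csv(genes_path, sep="\t")
    cells = pd.read_csv(cells_path, sep="\t")
    if x.shape[1] != len(genes):
        raise FormatError(
            f"matrix has {x.shape[1]} gene columns but genes file has {len(genes)} rows"
        )
    if x.shape[0] != len(cells):
        raise FormatError(
            f"matrix has {x.shape[0]} cell rows but cells file has {len(cells)} rows"
        )
    var = genes.set_index("gene_id")
    obs = cells.set_index("cell_id")
    var.index = var.index.astype(str)
    obs.index = obs.index.astype(str)
    if "mito" in var.columns:
        var["mito"] = var["mito"].astype(bool)
    adata = ad.AnnData(X=x.astype(np.float64), obs=obs, var=var)
    return ExpressionMatrix(adata)


def write_expression(expr: ExpressionMatrix, mtx_path, genes_path, cells_path) -> None:
    x = expr.adata.X
    if not scipy.sparse.issparse(x):
        x = scipy.sparse.csr_matrix(x)
    scipy.io.mmwrite(str(mtx_path), x)
    expr.adata.var.rename_axis("gene_id").reset_index().to_csv(genes_path, sep="\t", index=False)
    expr.adata.obs.rename_axis("cell_id").reset_index().to_csv(cells_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GeneSignature
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSignature:
    """A named, non-redundant gene list used for module/enrichment scoring."""

    name: str
    genes: tuple
    role: str = ""

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(self.genes))
        if not self.genes:
            raise ValidationError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"signature {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


#: Inhibitory-receptor program scored per spatial-transcriptomics spot.
EXHAUSTED_T_SIGNATURE = GeneSignature(
    "exhausted_T",
    ("LAG3", "PDCD1", "CTLA4", "HAVCR2", "TIGIT", "TOX", "LAYN", "CXCL13"),
    role="exhaustion",
)

#: B-cell identity program scored per spot.
B_CELL_SIGNATURE = GeneSignature(
    "B_cell", ("CD19", "MS4A1", "CD79A", "CD79B"), role="B-cell"
)


def read_signatures(path) -> dict:
    """Read signatures from a two-column TSV (signature, gene) or a plain
    one-gene-per-line file (signature named after the file stem)."""
    path = Path(path)
    first = path.read_text().strip().splitlines()
    if first and "\t" in first[0]:
        df = pd.read_csv(path, sep="\t", header=None, names=["signature", "gene"], comment="#")
        if len(df) and list(df.iloc[0]) == ["signature", "gene"]:
            df = df.iloc[1:]
        out = {}
        for name, grp in df.groupby("signature", sort=False):
            out[str(name)] = GeneSignature(str(name), tuple(grp["gene"].astype(str)))
        return out
    genes = tuple(line.strip() for line in first if line.strip() and not line.startswith("#"))
    return {path.stem: GeneSignature(path.stem, genes)}


def write_signatures(signatures: Mapping[str, GeneSignature], path) -> None:
    rows = [(s.name, g) for s in signatures.values() for g in s.genes]
    pd.DataFrame(rows, columns=["signature", "gene"]).to_csv(
        path, sep="\t", index=False, header=False
    )


# ---------------------------------------------------------------------------
# CNV matrix and arm map
# ---------------------------------------------------------------------------

def read_cnv_matrix(path, center: bool = False) -> pd.DataFrame:
    """Read a cells x genes CNV-value TSV (index = cell ids).

    Values are deviations from neutral (0-centered). ``center=True``
    subtracts 1 for matrices supplied on a 1-centered scale.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not np.isfinite(df.to_numpy()).all():
        raise ValidationError("CNV matrix contains non-finite values")
    if center:
        df = df - 1.0
    return df


def write_cnv_matrix(cnv: pd.DataFrame, path) -> None:
    cnv.to_csv(path, sep="\t")


def read_arm_map(path) -> pd.Series:
    """Read a two-column TSV (gene, arm) into a gene -> chromosome-arm Series."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "arm"], comment="#")
    if len(df) and list(df.iloc[0]) == ["gene", "arm"]:
        df = df.iloc[1:]
    ser = df.set_index("gene")["arm"].astype(str)
    if ser.index.has_duplicates:
        dup = ser.index[ser.index.duplicated()].unique().tolist()
        raise ValidationError(f"genes mapped to more than one arm: {dup[:10]}")
    return ser


def write_arm_map(arm_map: pd.Series, path) -> None:
    arm_map.rename("arm").rename_axis("gene").reset_index().to_csv(
        path, sep="\t", index=False, header=False
    )


# ---------------------------------------------------------------------------
# SpotTable
# ---------------------------------------------------------------------------

@dataclass
class SpotTable:
    """Spot-based spatial transcriptomics sample.

    ``expr`` is spots x genes (raw counts or normalized, always finite and
    >= 0), indexed by spot id; ``coords`` has columns ``x``/``y`` (grid
    units) on the same index; ``cell_type_counts`` (optional) holds
    deconvolved per-spot cell-type counts, spots x types.
    """

    expr: pd.DataFrame
    coords: pd.DataFrame
    cell_type_counts: pd.DataFrame | None = None

    def __post_init__(self):
        if self.expr.index.has_duplicates:
            raise ValidationError("spot ids must be unique")
        vals = self.expr.to_numpy()
        if vals.size and (not np.isfinite(vals).all() or (vals < 0).any()):
            raise ValidationError("spot expression must be finite and >= 0")
        if not self.coords.index.equals(self.expr.index):
            raise FormatError("spot coordinates index does not match expression index")

    @property
    def n_spots(self) -> int:
        return len(self.expr)

    @property
    def genes(self) -> pd.Index:
        return self.expr.columns


def read_spot_table(expr_path, coords_path, cell_counts_path=None) -> SpotTable:
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    coords = pd.read_csv(coords_path, sep="\t", index_col=0)
    counts = pd.read_csv(cell_counts_path, sep="\t", index_col=0) if cell_counts_path else None
    return SpotTable(expr, coords, counts)


def write_spot_table(spots: SpotTable, expr_path, coords_path, cell_counts_path=None) -> None:
    spots.expr.to_csv(expr_path, sep="\t")
    spots.coords.to_csv(coords_path, sep="\t")
    if cell_counts_path and spots.cell_type_counts is not None:
        spots.cell_type_counts.to_csv(cell_counts_path, sep="\t")


# ---------------------------------------------------------------------------
# CohortTable
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Per-category level counts describing a patient cohort.

    ``counts`` maps a categorical attribute (e.g. ``"sex"``) to a mapping of
    level -> patient count.
    """

    counts: Mapping[str, Mapping[str, int]] = field(default_factory=dict)

    def __post_init__(self):
        for cat, levels in self.counts.items():
            for lev, n in levels.items():
                if n < 0:
                    raise ValidationError(f"negative count for {cat}/{lev}")


def _round_half_up(x: float, ndigits: int = 1) -> float:
    return float(
        decimal.Decimal(repr(x)).quantize(
            decimal.Decimal("1." + "0" * ndigits), rounding=decimal.ROUND_HALF_UP
        )
    )


def summarize_cohort(cohort: CohortTable, category: str) -> pd.DataFrame:
    """Tabulate (level, count, percent) for one categorical attribute.

    Percentages are 100*count/total rounded half-up to one decimal; levels
    are ordered by count descending (ties by level name). A zero total
    yields an empty table rather than a division error.
    """
    levels = cohort.counts.get(category, {})
    total = sum(levels.values())
    if total == 0:
        return pd.DataFrame(columns=["level", "count", "percent"])
    rows = [
        (lev, n, _round_half_up(100.0 * n / total))
        for lev, n in sorted(levels.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["level", "count", "percent"])
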