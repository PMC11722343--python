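import anndata as ad
import numpy as np
import pandas as pd
import pytest

from tmequant.io import CellTable, ExpressionMatrix


@pytest.fixture
def make_expr():
    """Build an ExpressionMatrix from a dense array and gene names."""

    def _make(counts, genes, mito_flags=None, obs=None):
        counts = np.asarray(counts, dtype=float)
        cell_ids = [f"c{i + 1}" for i in range(counts.shape[0])]
        var = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
        if mito_flags is not None:
            var["mito"] = list(mito_flags)
        obs_df = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
        if obs:
            for k, v in obs.items():
                obs_df[k] = v
        return ExpressionMatrix(ad.AnnData(X=counts, obs=obs_df, var=var))

    return _make


@pytest.fixture
def make_cells():
    """Build a CellTable from (cell_id, x, y, phenotype[, major_axis]) tuples."""

    def _make(rows, roi_id="R1", compartment="NS", patient_id="P1"):
        recs = []
        for row in rows:
            cid, x, y, ph = row[:4]
            axis = row[4] if len(row) > 4 else np.nan
            recs.append(
                dict(roi_id=roi_id, cell_id=cid, x_um=x, y_um=y, phenotype=ph,
                     major_axis_um=axis, compartment=compartment,
                     tls_id=pd.NA, patient_id=patient_id)
            )
        return CellTable(pd.DataFrame(recs))

    return _make
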