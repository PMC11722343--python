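"""Spot-level spatial transcriptomics statistics.

Four operations on spot-based expression:

* spatial significance — the across-spot standard deviation (ddof=1) of each
  gene's normalized expression; spatially patterned genes vary more across
  spots than flat ones, so the s.d. ranks them;
* candidate-gene selection — the top-n genes per sample by that score and
  their cross-sample intersection;
* rank-recovery score — per spot, an AUCell-style area under the recovery
  curve of a gene signature within the top fraction of the spot's
  expression ranking, normalized to [0, 1];
* coexistence — the Pearson correlation matrix across spots of deconvolved
  per-spot cell-type counts.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .io import GeneSignature, SpotTable


def normalize_spots(spots: SpotTable, target_sum: float = 1e4) -> pd.DataFrame:
    """log1p of spot-depth-scaled counts (spots x genes)."""
    x = spots.expr.to_numpy(dtype=float)
    depth = x.sum(axis=1, keepdims=True)
    depth[depth == 0] = 1.0
    return pd.DataFrame(
        np.log1p(x / depth * target_sum), index=spots.expr.index, columns=spots.expr.columns
    )


def spatial_significance(spots, normalize: bool = True) -> pd.DataFrame:
    """Across-spot standard deviation of each gene, with ranks.

    ``spots`` is a :class:`SpotTable` (normalized internally unless
    ``normalize=False``) or an already-normalized spots x genes DataFrame.
    Returns a DataFrame indexed by gene with columns ``score`` (unbiased,
    n-1 denominator, standard deviation; 0 for a constant gene) and
    ``rank`` (1 = most variable; ties broken by gene id).
    """
    if isinstance(spots, SpotTable):
        X = normalize_spots(spots) if normalize else spots.expr.astype(float)
    else:
        X = spots
    score = X.std(axis=0, ddof=1)
    order = sorted(score.index, key=lambda g: (-score[g], g))
    rank = pd.Series(range(1, len(order) + 1), index=order)
    return pd.DataFrame({"score": score, "rank": rank.reindex(score.index)})


def select_candidate_genes(scores_per_sample: dict, n_top: int = 5000):
    """Top-``n_top`` genes by spatial score per sample and their intersection.

    ``scores_per_sample`` maps sample id to a :func:`spatial_significance`
    result (or a gene-indexed score Series). Ties at the cutoff break by
    gene id (lexicographic) so selections are deterministic. Returns
    ``(per_sample_sets, intersection_set)``.
    """
    per_sample = {}
    for sample, sc in scores_per_sample.items():
        ser = sc["score"] if isinstance(sc, pd.DataFrame) else sc
        order = sorted(ser.index, key=lambda g: (-ser[g], g))
        per_sample[sample] = set(order[:n_top])
    inter = set.intersection(*per_sample.values()) if per_sample else set()
    return per_sample, inter


def rank_recovery_score(
    spots,
    signature: GeneSignature,
    top_fraction: float = 0.05,
) -> pd.Series:
    """Per-spot signature enrichment as normalized area under the recovery curve.

    Per spot, genes are ranked by expression descending (ties by gene id
    ascending, so scores are bit-stable). Over the top
    ``ceil(top_fraction * n_genes)`` ranks, the recovery curve counts how
    many signature genes have appeared by each rank; the score is the area
    under that curve divided by the maximal achievable area (all signature
    genes packed at the top). Depends on the within-spot ranking only, so it
    is invariant to monotone transforms of a spot's expression.
    """
    if not 0 < top_fraction <= 1:
        raise ParameterError("top_fraction must lie in (0, 1]")
    X = spots.expr if isinstance(spots, SpotTable) else spots
    genes = list(X.columns)
    sig = [g for g in signature.genes if g in genes]
    if not sig:
        raise ValidationError(
            f"no gene of signature {signature.name!r} present in the spot matrix"
        )
    n = len(genes)
    window = math.ceil(top_fraction * n)
    s = min(len(sig), window)
    max_area = sum(min(k, s) for k in range(1, window + 1))
    # deterministic ranking: sort by (-expression, gene id)
    gene_order = np.array(genes)
    lex = np.argsort(gene_order)  # secondary key
    vals = X.to_numpy(dtype=float)[:, lex]
    sig_mask = np.isin(gene_order[lex], sig)
    scores = np.empty(len(X))
    for i in range(len(X)):
        order = np.argsort(-vals[i], kind="stable")  # stable keeps gene-id order in ties
        positions = np.flatnonzero(sig_mask[order]) + 1  # 1-based ranks of sig genes
        inside = positions[positions <= window]
        scores[i] = (window - inside + 1).sum() / max_area
    return pd.Series(scores, index=X.index, name=signature.name)


def coexistence_matrix(cell_type_counts: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation across spots for each cell-type pair.

    Diagonal entries are 1; a type with zero variance across spots yields
    missing (NaN) entries and a warning.
    """
    counts = cell_type_counts.astype(float)
    var = counts.var(axis=0, ddof=1)
    corr = counts.corr(method="pearson")
    zero = var.index[var == 0].tolist()
    if zero:
        warnings.warn(f"cell type(s) with zero variance across spots: {zero}")
        corr.loc[zero, :] = np.nan
        corr.loc[:, zero] = np.nan
    pos = var.index[var > 0]
    for t in pos:
        corr.loc[t, t] = 1.0
    return corr
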