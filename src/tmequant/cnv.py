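"""Arm-level squared-CNV cell scores and tumor-cluster calling.

The per-cell score of a chromosome arm is the mean of the squared CNV
values of the genes on that arm; the overall cell score is the unweighted
arithmetic mean of the arm scores. Squaring makes gains and losses count
alike, so the score measures total copy-number deviation from neutral:
for i.i.d. Normal(0, sigma) noise its expectation is sigma^2, and a single
arm shifted by ``a`` among ``k`` arms (no noise) scores exactly a^2/k.

Clusters are called tumor when their mean cell score exceeds the mean of a
reference (normal-tissue) population by ``k_sigma`` reference standard
deviations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ValidationError


def arm_scores(cnv: pd.DataFrame, arm_map: pd.Series) -> pd.DataFrame:
    """Per-cell per-arm mean squared CNV value (cells x arms).

    Genes absent from ``arm_map`` are dropped with a warning; arms that map
    no gene of the matrix are omitted with a warning.
    """
    mapped = [g for g in cnv.columns if g in arm_map.index]
    unmapped = [g for g in cnv.columns if g not in arm_map.index]
    if unmapped:
        warnings.warn(f"{len(unmapped)} gene(s) missing from the arm map were dropped")
    if not mapped:
        raise ValidationError("no gene of the CNV matrix is mapped to an arm")
    empty = set(arm_map.unique()) - set(arm_map.loc[mapped].unique())
    if empty:
        warnings.warn(f"arm(s) with no mapped gene omitted: {sorted(empty)}")
    sq = cnv[mapped] ** 2
    return sq.T.groupby(arm_map.loc[mapped]).mean().T


def cell_cnv_score(arm_score_table: pd.DataFrame) -> pd.Series:
    """Unweighted mean over arms present; one score per cell."""
    return arm_score_table.mean(axis=1).rename("cnv_score")


def cluster_mean_scores(scores: pd.Series, clusters: pd.Series) -> pd.Series:
    """Mean per-cell score within each cluster (per-cell first, then mean)."""
    return scores.groupby(clusters).mean()


def call_tumor_clusters(
    scores: pd.Series,
    clusters: pd.Series,
    reference: pd.Series,
    k_sigma: float = 2.0,
) -> pd.DataFrame:
    """Flag clusters whose mean score is elevated over the reference baseline.

    ``reference`` is a boolean Series (aligned with ``scores``) marking
    normal-tissue cells; a cluster is flagged tumor when its mean score
    exceeds ``reference mean + k_sigma * reference s.d.``. Fewer than 10
    reference cells make the baseline unreliable and raise.
    """
    reference = reference.reindex(scores.index).fillna(False).astype(bool)
    ref_scores = scores[reference]
    if len(ref_scores) < 10:
        raise ValidationError(
            f"only {len(ref_scores)} reference cells; >= 10 required for a baseline"
        )
    mu, sd = float(ref_scores.mean()), float(ref_scores.std(ddof=1))
    threshold = mu + k_sigma * sd
    means = cluster_mean_scores(scores, clusters)
    out = pd.DataFrame({"mean_score": means})
    out["threshold"] = threshold
    with np.errstate(invalid="ignore"):
        out["tumor"] = means > threshold
    return out
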