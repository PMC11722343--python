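"""End-to-end orchestration on synthetic inputs.

``run_pipeline`` executes simulate -> QC -> module scoring / origin calls ->
CNV scoring -> neighborhood densities -> TLS ratios -> BET triads -> spot
statistics -> paired compartment comparison, writing per-stage TSVs, a JSON
summary and a timestamped log. Everything is deterministic given the
configuration's single seed: each stage derives its own child seed from it.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cnv as cnv_mod
from . import neighborhood, qc, scoring, spots as spots_mod, stats, synthetic, triads
from .errors import ValidationError

log = logging.getLogger("tmequant.pipeline")


@dataclass
class PipelineConfig:
    """Seed, sizes and module parameter blocks for the synthetic pipeline."""

    seed: int = 0
    outdir: str = "tmequant_run"
    n_patients: int = 6  # patients with paired NS/S ROIs
    sim: synthetic.SimConfig = field(default_factory=synthetic.SimConfig)
    n_cells: int = 1000
    n_genes: int = 1000
    n_cnv_cells: int = 500
    spot_grid: tuple = (20, 20)
    n_spot_genes: int = 200
    module_params: scoring.ModuleScoreParams = field(
        default_factory=scoring.ModuleScoreParams
    )
    qc_thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = synthetic.SimConfig(**raw.pop("sim", {}))
        mp = scoring.ModuleScoreParams(**raw.pop("module_params", {}))
        th = qc.QCThresholds(**raw.pop("qc_thresholds", {}))
        cfg = cls(sim=sim, module_params=mp, qc_thresholds=th, **raw)
        return cfg

    def validate(self) -> None:
        if self.n_patients < 3:
            raise ValidationError(
                "paired compartment comparison needs >= 3 patients with complete pairs"
            )


def _child_seed(seed: int, stage: int, extra: int = 0) -> int:
    return int(np.random.SeedSequence([seed, stage, extra]).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on synthetic data; returns the summary dict.

    Outputs under ``config.outdir``: per-stage TSVs, ``summary.json`` and
    ``pipeline.log``. Any stage failure aborts with the stage name.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict = {"seed": config.seed}
    t0 = time.time()

    stage = "simulate_rois"
    try:
        # one NS and one S ROI per patient, for the paired comparison
        roi_tables, roi_truths, roi_meta = [], {}, []
        for p in range(config.n_patients):
            for comp in ("NS", "S"):
                seed = _child_seed(config.seed, 1, 2 * p + (comp == "S"))
                sim = config.sim.replace(
                    seed=seed,
                    # progression: fewer triads in the solid component
                    n_triads_planted=config.sim.n_triads_planted
                    if comp == "NS"
                    else max(config.sim.n_triads_planted - 4, 0),
                )
                roi_id = f"P{p + 1}_{comp}"
                table, truth = synthetic.simulate_roi(
                    sim, roi_id=roi_id, compartment=comp, patient_id=f"P{p + 1}"
                )
                roi_tables.append(table.df)
                roi_truths[roi_id] = truth
                roi_meta.append((roi_id, comp, f"P{p + 1}"))
        cells = synthetic.CellTable(pd.concat(roi_tables, ignore_index=True))
        cells.df.to_csv(outdir / "cells.csv", index=False)
        log.info("simulated %d cells in %d ROIs", cells.n_cells, len(roi_meta))

        stage = "triads"
        contacts = triads.classify_contacts(cells)
        tri = triads.detect_triads(contacts)
        area = {rid: t["roi_area_mm2"] for rid, t in roi_truths.items()}
        rates = triads.triad_rate(tri, area)
        rates.to_csv(outdir / "triads.tsv", sep="\t", index=False)
        summary["triads"] = {
            "n_triads_total": int(rates["n_triads"].sum()),
            "per_roi": rates.set_index("roi_id")["n_triads"].to_dict(),
        }

        stage = "densities"
        dens = neighborhood.density_around(cells, anchors="Tumor",
                                           targets=("CD8T_exh", "CD4T_exh"))
        dens.per_roi.to_csv(outdir / "density_tumor_exhausted.tsv", sep="\t", index=False)
        summary["density_exhausted_around_tumor_per_mm2"] = {
            r.roi_id: r.mean_density_per_mm2 for r in dens.per_roi.itertuples()
        }

        stage = "tls"
        tls = neighborhood.tls_density(
            cells, ("CD4T_act", "CD4T_exh", "CD8T_act", "CD8T_exh"),
            disk_radius_um=config.sim.tls_radius_um,
        )
        tls.to_csv(outdir / "tls_density.tsv", sep="\t", index=False)
        ratios = pd.DataFrame(
            {
                "cd4_act_exh_ratio": neighborhood.activation_exhaustion_ratio(
                    tls, "CD4T_act", "CD4T_exh").to_numpy(),
                "cd8_act_exh_ratio": neighborhood.activation_exhaustion_ratio(
                    tls, "CD8T_act", "CD8T_exh").to_numpy(),
            },
            index=tls["tls_id"] + "@" + tls["roi_id"],
        )
        ratios.to_csv(outdir / "tls_ratios.tsv", sep="\t")
        summary["tls_mean_cd8_act_exh_ratio"] = float(
            np.nanmean(ratios["cd8_act_exh_ratio"])
        )

        stage = "paired_comparison"
        by_patient = rates.assign(
            patient=[r.split("_")[0] for r in rates["roi_id"]],
            comp=[r.split("_")[1] for r in rates["roi_id"]],
        ).pivot(index="patient", columns="comp", values="triads_per_mm2")
        cmp_res = stats.paired_signed_rank(
            by_patient["NS"], by_patient["S"], groups=("NS", "S")
        )
        summary["triad_rate_ns_vs_s"] = {
            "statistic": cmp_res.statistic, "p_value": cmp_res.p_value,
            "stars": cmp_res.stars, "n_pairs": int(len(by_patient)),
        }

        stage = "expression"
        expr_seed = _child_seed(config.seed, 2)
        expr, expr_truth = synthetic.simulate_expression(
            config.sim.replace(seed=expr_seed, patient_program_purity=0.9),
            n_cells=config.n_cells, n_genes=config.n_genes,
        )
        kept, report = qc.qc_filter(expr, config.qc_thresholds)
        report.to_csv(outdir / "qc_report.tsv", sep="\t")
        doublets = qc.flag_marker_doublets(kept, config.qc_thresholds)
        summary["qc"] = {
            "n_input": expr.n_cells, "n_kept": kept.n_cells,
            "n_removed": expr.n_cells - kept.n_cells,
            "n_marker_doublets": len(doublets),
        }

        stage = "scoring"
        sig_at2 = expr_truth["signatures"]["AT2"]
        sig_club = expr_truth["signatures"]["club"]
        calls = scoring.classify_tumor_cells(kept, sig_at2, sig_club, config.module_params)
        calls.to_csv(outdir / "cell_origin_scores.tsv", sep="\t")
        origins = scoring.assign_origin_by_patient(
            calls, kept.adata.obs["patient_id"]
        )
        origins.to_csv(outdir / "patient_origin.tsv", sep="\t", index=False)
        truth_kept = expr_truth["program"].reindex(calls.index)
        agreement = float(
            (calls["label"].str.replace("-like", "") == truth_kept).mean()
        )
        summary["origin"] = {
            "per_cell_recovery": agreement,
            "patient_labels": origins.set_index("patient_id")["label"].to_dict(),
        }

        stage = "cnv"
        cnv_seed = _child_seed(config.seed, 3)
        cnv_vals, cnv_truth = synthetic.simulate_cnv(
            config.sim.replace(seed=cnv_seed), n_cells=config.n_cnv_cells
        )
        arms = cnv_mod.arm_scores(cnv_vals, cnv_truth["arm_map"])
        score = cnv_mod.cell_cnv_score(arms)
        clusters = cnv_truth["tumor"].map({True: "tumor_like", False: "reference"})
        called = cnv_mod.call_tumor_clusters(score, clusters, ~cnv_truth["tumor"])
        called.to_csv(outdir / "cnv_clusters.tsv", sep="\t")
        summary["cnv"] = {
            "mean_score_reference": float(score[~cnv_truth["tumor"]].mean()),
            "mean_score_tumor": float(score[cnv_truth["tumor"]].mean()),
            "tumor_cluster_called": bool(called.loc["tumor_like", "tumor"]),
        }

        stage = "spots"
        spot_seed = _child_seed(config.seed, 4)
        spot_tab, spot_truth = synthetic.simulate_spots(
            config.sim.replace(seed=spot_seed), grid=config.spot_grid,
            n_genes=config.n_spot_genes,
        )
        sig_scores = spots_mod.spatial_significance(spot_tab)
        sig_scores.to_csv(outdir / "spatial_scores.tsv", sep="\t")
        top = set(sig_scores.sort_values("rank").index[: config.sim.n_sv_genes * 4])
        recovered = len(top & set(spot_truth["sv_genes"]))
        coexist = spots_mod.coexistence_matrix(spot_tab.cell_type_counts)
        coexist.to_csv(outdir / "coexistence.tsv", sep="\t")
        pair = spot_truth["correlated_pair"]
        summary["spots"] = {
            "sv_genes_recovered": recovered,
            "sv_genes_planted": len(spot_truth["sv_genes"]),
            "planted_pair_correlation": float(coexist.loc[pair[0], pair[1]]),
        }
    except Exception:
        log.exception("stage %s failed (seed=%d)", stage, config.seed)
        raise RuntimeError(f"pipeline stage {stage!r} failed") from None
    finally:
        log.removeHandler(handler)
        handler.close()

    summary["runtime_s"] = round(time.time() - t0, 2)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
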