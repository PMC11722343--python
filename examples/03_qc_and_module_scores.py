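"""Single-cell QC, bin-matched module scores and cell-of-origin calls.

Simulates a count matrix with a planted AT2 program (log-shift delta = 1),
filters cells by gene count and mitochondrial fraction, scores each cell
with the AT2 and club signatures and aggregates per-patient origin calls.
"""

import tmequant as tq

cfg = tq.SimConfig(seed=3, program_delta=1.0, patient_program_purity=0.9,
                   doublet_rate=0.02)
expr, truth = tq.simulate_expression(cfg, n_cells=1000, n_genes=1000)

kept, report = tq.qc_filter(expr)
doublets = tq.flag_marker_doublets(kept)
print(f"QC: kept {kept.n_cells}/{expr.n_cells} cells "
      f"(removed: {report['primary_reason'].value_counts().to_dict()}); "
      f"{len(doublets)} marker-co-expression doublets flagged")

sig_at2 = truth["signatures"]["AT2"]
sig_club = truth["signatures"]["club"]
calls = tq.classify_tumor_cells(kept, sig_at2, sig_club)
prog = truth["program"].reindex(calls.index)
diff = (calls.loc[(prog == "AT2").to_numpy(), "score_AT2"].mean()
        - calls.loc[(prog == "club").to_numpy(), "score_AT2"].mean())
print(f"AT2 module score: program-vs-background difference = {diff:.3f} "
      f"(planted shift 1.0)")

origins = tq.assign_origin_by_patient(calls, kept.adata.obs["patient_id"])
print(origins.to_string(index=False))
# Patients dominated by one program are called AT2-like or club-like; mixed
# or sparsely sampled patients stay unassigned.
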