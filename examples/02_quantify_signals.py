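"""Quantify raw intensities into one activity value per substrate/sample.

Each spot's signal is the background-corrected slope of intensity vs. camera
exposure (robust to detector saturation), summarized as the end-level over
the final cycles and averaged across technical replicates, with QC flags.
"""

import kinomechip as kc

amap = kc.build_default_annotation(seed=0)
design = kc.AssayDesign(cycles_per_chip={"PTK": 20, "STK": 24}, exposure_times=(10, 50, 200))
cohort = kc.CohortDesign(patients=(("HCC-M-1", "M"), ("HCC-F-2", "F")))
panel = kc.DrugPanel()
truth = kc.default_ground_truth(amap, cohort, panel, seed=0)
raw = kc.simulate_signals(design, amap, truth, cohort, panel, seed=7)

matrix = kc.quantify(raw, design, kc.QuantifyParams(window=10))
print(f"matrix: {matrix.values.shape[0]} substrates × {matrix.values.shape[1]} sample-conditions "
      f"(AU/ms, {matrix.n_replicates} replicates collapsed)")
print("QC flags:", matrix.flag_counts())

cell = matrix.values.loc["PTK_001", ("HCC-M-1", "tumor", "vehicle")]
print(f"\nexample cell PTK_001 / HCC-M-1 tumor vehicle: {cell:.3f} AU/ms")
print("A cell is the phosphorylation velocity of that peptide in that lysate;")
print("'low_signal' marks cells below the detection floor, 'saturated' cells")
print("where too few unsaturated exposures survived for a slope fit.")

filtered, report = kc.qc_filter(matrix, policy="mask_cell")
print("\nafter mask_cell policy:", report)
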