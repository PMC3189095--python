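"""Compute a vector datasheet from generated characterization data.

A seeded plate run (triplicate dose series, reads every 570 s for 20.5 h)
is reduced to the 18-hour dose response and a Hill fit; a seeded qPCR run
(seven four-fold dilutions per target) yields plasmid copy number per
chromosomal equivalent via per-target standard curves.
"""

from bglbrick import synthdata as sd
from bglbrick.datasheet import (
    copy_number_from_table,
    dose_response,
    fit_hill,
    render_datasheet,
    specific_fluorescence,
)

plate, truth = sd.gen_plate(
    sd.GrowthModel(),
    sd.ExpressionModel(noise_sd=0.05, k_half=50.0, hill_n=2.0),
    doses=[0, 5, 10, 25, 50, 100, 250, 500],
    seed=42,
)
df = specific_fluorescence(plate)
summary = dose_response(df, control_mask=plate.well.str.startswith("control"))
hill = fit_hill(summary.doses, summary.mean_sf)

qpcr, qtruth = sd.gen_qpcr(sd.QpcrModel(copy_number=60.0, ct_sd=0.1), seed=42)
copy = copy_number_from_table(qpcr)

doc, text = render_datasheet("pBbE5a-RFP", dose=summary, hill=hill, copy=copy)
print(text)
print()
print(f"generator truth: K = {truth['hill']['K']} uM, n = {truth['hill']['n']}, "
      f"copy number = {qtruth['copy_number']}")
# The fitted K/n and the recovered copy number should match the planted
# values up to the simulated noise (5% fluorescence CV, Ct sd 0.1).
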