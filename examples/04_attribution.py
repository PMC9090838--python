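"""First-difference attribution with stepwise regression.

Generates a yield-climate panel in which year-over-year yield change is
driven only by the radiation change (2.34 kg/ha per MJ/m2) plus noise, and
shows that bidirectional stepwise regression selects exactly that driver
and recovers its coefficient. Pearson correlations of every candidate are
printed alongside.
"""

import chingke as ck
from chingke.attribution import pearson_matrix, stepwise_mlr

panel, truth = ck.gen_yield_panel(
    ck.PanelGenConfig(seed=3, n_rows=500, coefficients={"dRA": 2.34},
                      noise_sigma=50.0)
)
print(f"generated {len(panel)} first-difference rows, truth: {truth['coefficients']}")

print("\nPearson correlations with dYp:")
print(pearson_matrix(panel).to_string(index=False))

res = stepwise_mlr(panel, zone="demo")
print(f"\nstepwise selection: {res.equation()}")
print(f"F = {res.f_statistic:.1f}, R2 = {res.r2:.2f}, RMSE = {res.rmse:.1f} kg/ha")
print("the radiation coefficient should sit within a few percent of 2.34")
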