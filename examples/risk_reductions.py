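"""10-year CVD risk reductions and their cost consequences.

For each cardiovascular outcome and sex, the absolute risk reduction (ARR)
is the comparator risk minus the intervention risk, in percentage points;
dividing the incremental annual cost by the ARR gives the cost per 1%
absolute risk reduction.  CHD reductions are severalfold cheaper than
stroke reductions.
"""

from capicea import datasets
from capicea.costing import compare_costs
from capicea.io import risk_report_frame
from capicea.risk_effects import risk_source

models = datasets.load_cost_models()
cmp = compare_costs(models["intervention"], models["comparator"])
grid = risk_source(datasets.fixture_risk_engine)
frame = risk_report_frame(grid, cmp)
print(frame.round(3).to_string(index=False))
row = frame.query("outcome == 'fatal_CHD' and sex == 'male'").iloc[0]
print(
    f"\nFatal CHD, males: ARR {row.arr_pct_points:.2f} points -> "
    f"ZAR {row.cost_per_pct_arr_zar:.2f} per 1% risk reduction; "
    f"mortality ratio rr_m = {row.rr_m:.3f} feeds the life tables."
)
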