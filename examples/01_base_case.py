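"""Deterministic base case: run the four-state cohort model for both
management strategies and compare them at the willingness-to-pay threshold.

The printed totals are discounted lifetime (8-year) costs and QALYs per
patient; the ICER is the extra cost per QALY gained by IoT-based
management over standard management of home noninvasive ventilation.
"""

from nppvcea import ArmTotals, ModelConfig, compare, load_default_parameters
from nppvcea.markov import build_arm_models, run_cohort

params = load_default_parameters()
config = ModelConfig()  # 8 annual cycles, 5% discounting, WTP ¥70,100/QALY

models = build_arm_models(params)
traces = {arm: run_cohort(model, config) for arm, model in models.items()}

for arm, trace in traces.items():
    print(f"{arm:>8s}: cost ¥{trace.total_cost:>10,.2f}   "
          f"QALYs {trace.total_qalys:.4f}")

result = compare(
    ArmTotals("iot", traces["iot"].total_cost, traces["iot"].total_qalys),
    ArmTotals("standard", traces["standard"].total_cost,
              traces["standard"].total_qalys),
    config.wtp,
)
print(f"ΔC = ¥{result.delta_cost:,.2f}, ΔE = {result.delta_effect:.4f} QALYs")
print(f"ICER = ¥{result.icer:,.2f}/QALY "
      f"({'below' if result.cost_effective else 'not below'} "
      f"WTP ¥{config.wtp:,.0f}/QALY)")
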