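"""When is the blood T1 optimal after a gadolinium injection?

Using a population vascular input function, the planner converts blood
gadolinium concentration to blood T1 through the relaxivity relation
R1_post = R1_pre + r1*cb and reports when the recovering T1 passes the
optimal 0.8 s for each fractional dose.
"""

import numpy as np

from ceasl import dose_plan, parker_vif, t1b_post

vif = parker_vif(np.linspace(0, 250, 5001))  # full dose 0.1 mmol/kg
print(f"peak blood concentration: {vif.cb.max():.1f} mM "
      f"-> blood T1 {float(t1b_post(vif.cb.max())):.3f} s at first pass")

plan = dose_plan(vif, fractions=(0.25, 0.5, 0.75, 1.0), target_t1=0.8)
print("\ndose fraction   minutes until blood T1 recovers to 0.8 s")
for _, row in plan.iterrows():
    print(f"   {row['dose_fraction']:4.2f}          "
          f"{row['minutes_to_target']:6.1f}")

print("\nSmaller doses reach the optimal window sooner; larger doses "
      "keep the\nblood T1 below optimum for much longer — convenient "
      "when piggybacking\non a dynamic contrast-enhanced protocol.")
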