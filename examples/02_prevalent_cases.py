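"""Prevalent cases of PTSD and major depression, and their comorbidity split.

Age-standardised prevalences (12.9% PTSD, 7.6% depression) are spread over
a unimodal age curve peaking in young adults, multiplied by the population,
and partitioned assuming 50% of PTSD cases are comorbid with depression.
"""

import numpy as np

import mhplan

fx = mhplan.syria_fixture()

for d in ("ptsd", "depression"):
    std = mhplan.age_standardise(fx.curves[d].schedule, fx.population)
    print(f"{d:12s} age-standardised prevalence {std:.3f}, "
          f"cases {fx.cases[d].total / 1e6:.2f} million")

for g in ("ptsd_only", "depression_only", "comorbid", "combined"):
    print(f"{g:16s} {fx.cases[g].total / 1e6:5.2f} million")

peak = int(np.argmax(fx.cases["combined"].cases))
print(f"most prevalent cases at age {peak}")
# The combined total stays near the PTSD total because half of the PTSD
# cases also meet criteria for depression.
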