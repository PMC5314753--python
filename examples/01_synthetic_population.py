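"""Build the synthetic Syria-like study population and inspect its shape.

The pyramid is a quasi-stable age structure (young, growing population) and
the all-cause mortality hazard is Gompertz-Makeham, calibrated to a life
expectancy at birth around 70 years.
"""

import mhplan
from mhplan.synthetic import life_expectancy

fx = mhplan.syria_fixture()
pop = fx.population

print(f"total population:        {pop.total:,.0f}")
print(f"share aged under 15:     {pop.band(0, 14) / pop.total:.1%}")
print(f"women aged 15-44:        {pop.women(15, 44):,.0f}")
print(f"life expectancy at birth:{life_expectancy(fx.mortality):6.1f} years")

# A young pyramid is what drives the concentration of prevalent cases in
# adolescents and young adults downstream.
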