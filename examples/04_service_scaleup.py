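"""15-year scale-up of mhGAP-style care packages: visits, beds and staff.

Moderate-severe cases aged 15+ (plus a perinatal depression group) receive
packages of care whose coverage ramps from 1% to package-specific targets;
visits and bed-days convert to full-time-equivalent staff by provider type.
"""

import mhplan

cfg = mhplan.load_config()
fx = mhplan.syria_fixture()
model = mhplan.build_service_model(cfg, fx)

plan = mhplan.run_scaleup(model, mode="linear")
cols = ["year", "primary_care_visits", "ancillary_visits", "outpatient_visits",
        "inpatient_days", "beds", "fte_total", "fte_per_100k"]
print(plan[cols].iloc[[0, 7, 14]].round(1).to_string(index=False))

final = plan.iloc[-1]
print("\n2029 workforce by provider type (FTE):")
for p in cfg.staffing.providers:
    print(f"  {p:18s} {final[f'fte_{p}']:6.0f}")
# Baseline needs ~0.3 FTE per 100,000; the target year needs ~7.6, with the
# large majority of the workforce being non-specialist providers.
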