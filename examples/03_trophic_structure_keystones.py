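"""Trophic structure of a balanced web: levels, omnivory, keystone groups.

Trophic levels come from the linear system TL_i = 1 + sum_j DC_ji * TL_j
(producers and detritus at 1). The mixed trophic impact (MTI) matrix
propagates direct and indirect effects of a marginal biomass increase of
each group; keystoneness combines a group's overall MTI effect with its
(low) share of biomass, so small groups with web-wide influence rank
first.
"""

import numpy as np

import shelfweb as sw

web = sw.generate_foodweb(sw.WebGenConfig(seed=7))
model = sw.solve_balance(web.inputs)
report = sw.trophic_report(model)

frame = report.to_frame()
print("top of the web by trophic level:")
print(frame.sort_values("trophic_level", ascending=False).head(6)
      .to_string(float_format=lambda v: f"{v:8.3f}"))

print("\nkeystone ranking (rank 1 = most keystone):")
living = frame[frame["keystone_rank"] > 0]  # detritus carries no rank
print(living.sort_values("keystone_rank").head(5)
      .to_string(float_format=lambda v: f"{v:8.3f}"))

if report.mean_tl_catch is not None:
    print(f"\nmean trophic level of the catch: {report.mean_tl_catch:.3f}")

# MTI columns show who a group's biomass increase helps (+) or hurts (-).
m = sw.mixed_trophic_impact(model)
i = int(np.nanargmax(np.where(np.isnan(report.ks), -np.inf, report.ks)))
impacts = sorted(zip(model.names, m[i]), key=lambda kv: kv[1])
print(f"\nstrongest impacts of '{model.names[i]}':")
for name, val in impacts[:3] + impacts[-3:]:
    print(f"  {name:<16} {val:+.3f}")
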