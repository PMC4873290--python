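"""Compare system attributes of two parameterizations of a shelf fishery.

The bundled dataset describes a 25-group tropical shelf food web with two
basic parameter tables for the same group list: one science-based ("sc",
literature rates) and one built from fishers' expert knowledge ("fk").
Only the basic table (B, P/B, Q/B) is bundled; the published diet matrices
are not, so a clearly labelled SYNTHETIC stand-in diet supplies the web
structure. Attributes that depend only on the basic table — net primary
production, total production, biomass and their ratios — are exact;
flow-structure attributes (throughput, ascendency, cycling) reflect the
stand-in diet and are illustrative only.
"""

import shelfweb as sw
from shelfweb.datasets import baia_formosa_inputs
from shelfweb.fileio import compare_models
from shelfweb.network import attribute_report

reports = {}
for which in ("fk", "sc"):
    model = sw.solve_balance(baia_formosa_inputs(which))
    net = sw.build_flow_network(model)
    reports[which] = attribute_report(model, net)

table = compare_models(reports["fk"], reports["sc"], "fk", "sc")
print(table.to_string(float_format=lambda v: f"{v:10.2f}"))

sc = reports["sc"]
print(f"\nnet primary production (sc): {sc.total_net_pp:.2f} t/km2/yr")
print(f"PP / total biomass (sc):     {sc.pp_over_biomass:.2f} /yr")
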