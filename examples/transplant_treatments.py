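"""MSC-transplant strategies for the established atrophic non-union.

At post-osteotomy week 3 (when the gap has started to revascularize),
1 ml of MSCs at 1e6 cells/ml is delivered either directly into the
callus (central or excentral disc footprint) or in a carrier adjacent
to, but outside, the callus.  Prints week-16 outcomes against the
untreated non-union.
"""

import callussim as cs
from callussim.scenarios import TreatmentEvent

runs = {"untreated": cs.make_nonunion_scenario()}
for site, label in (("central", "central"), ("excentral", "excentral"),
                    ("external_carrier", "carrier")):
    runs[label] = cs.make_nonunion_scenario(
        treatments=[TreatmentEvent(time=21.0, site=site)], label=label
    )

print("treatment   bone(POW16)  fibrous(POW16)  injected cells")
for label, sc in runs.items():
    traj, grid, params, ledgers = cs.run_scenario(sc)
    bone, cart, fib = cs.tissue_fractions(traj.at(112.0), grid)
    cells = f"{ledgers[0]['nominal_cells']:.0f}" if ledgers else "-"
    print(f"{label:10s}  {bone:.3f}        {fib:.3f}           {cells}")

print(
    "\nDirect central injection rescues the non-union (bone up, fibrous down)."
    "\nExcentral injection bridges the injection side first and leaves"
    "\ncartilage still ossifying on the opposite side at week 16."
    "\nCarrier delivery outside the callus forms a bone layer next to the"
    "\nsource: the slowly migrating cells differentiate before they reach"
    "\nthe centre, which stays fibrous."
)
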