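"""Cellular signatures: post-inhibitory rebound vs rebound bursting.

Applies a hyperpolarize-and-release protocol to isolated random neurons and
labels each cell's response: PIR (transient spiking after release), RB
(a genuine high-frequency rebound burst), HIB (sustained bursting while
hyperpolarized).  Removing the slow activation kinetics preserves PIR but
destroys RB - the two phenomena have different mechanisms even though both
involve T-type channels.
"""

from slowswitch.experiments import run_single_cell_protocols

for mode in ("slow", "instantaneous"):
    df = run_single_cell_protocols(n=25, seed=3, cat_mode=mode)
    counts = df.label.value_counts().to_dict()
    print(f"{mode:>13} activation: {counts}")

print(
    "\nPIR needs only T-type deinactivation and survives the kinetics ablation;\n"
    "rebound bursting needs the slow activation itself and does not."
)
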