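"""Spatially localized control of the network state.

A 40-cell network whose GABA_B synapses decay with distance (Gaussian
clustering, spread 0.8 cell indices) is divided into 4 modulatory pathways.
Hyperpolarizing a single pathway switches on a rhythm only in the spatially
corresponding excitatory cluster, even though AMPA and GABA_A stay
all-to-all.
"""

from slowswitch.experiments import PathwayScheduleEntry, run_pathway_modulation
from slowswitch.lfp import band_power_ratio

out = run_pathway_modulation(
    n_E=20,
    n_I=20,
    n_pathways=4,
    clustered=("GABA_B",),
    schedule=[PathwayScheduleEntry(pathway=0, t_on=2000.0, t_off=10000.0)],
    t_end=10000.0,
    seed=0,
)

during, active_ref = (3000.0, 10000.0), (500.0, 2000.0)
print("pathway 0 hyperpolarized; slow-band LFP power vs the active state:")
for c, data in out["clusters"].items():
    ratio = band_power_ratio(data["lfp"], during, active_ref)
    state = "oscillatory" if ratio >= 10 else "active"
    print(f"  E-cluster {c}: power ratio {ratio:8.1f}  -> {state}")

print(
    "\nOnly the cluster wired to the modulated pathway switches state: spatial\n"
    "structure in GABA_B alone converts a global cellular mechanism into a\n"
    "spatially addressable one."
)
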