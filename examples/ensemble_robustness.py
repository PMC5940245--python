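"""Robustness of the network switch across random circuits.

Draws an ensemble of two-cell circuits with every maximal conductance and
synaptic weight randomized, applies the hyperpolarizing step, and counts how
many circuits switch - with slow and with instantaneous T-type activation.
A modest ensemble (n = 60) keeps this example quick; the acceptance script
runs the full 1000.
"""

from slowswitch.experiments import run_ensemble_switch

N = 60
for mode in ("slow", "instantaneous"):
    table = run_ensemble_switch(n=N, seed=7, cat_mode=mode)
    n_switch = int(table.switched.sum())
    n_sync = int(table.sync_during.sum())
    print(f"{mode:>13}: {n_switch}/{N} circuits switch; "
          f"{n_sync}/{N} burst synchronously during hyperpolarization")
    if mode == "slow" and n_sync:
        sub = table[table.sync_during]
        print(f"               bursting period {sub.PER.mean():.0f} +/- {sub.PER.std():.0f} ms, "
              f"intraburst {sub.IBF.mean():.0f} Hz, duty cycle {sub.DC.mean():.2f}")

print(
    "\nHeterogeneity in every conductance tunes each circuit's rhythm over a\n"
    "broad range, yet the switch itself survives in nearly all of them -\n"
    "unless the slow T-type activation is removed, which abolishes it entirely."
)
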