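"""Mean-field convergence: the network rhythm sharpens with population size.

Simulates ensembles of random networks of 10 and 40 cells under the switch
protocol and compares the spread of the dominant LFP frequency during
hyperpolarization.  Small networks wear their heterogeneity on their sleeve;
larger ones average it into a reproducible mean-field rhythm.
"""

from slowswitch.experiments import run_size_scaling

df = run_size_scaling(sizes=(10, 40), n_networks=10, seed=1)
for size, sub in df.groupby("size"):
    v = sub.peak_freq_hz.dropna()
    print(
        f"{size:3d}-cell networks: peak LFP frequency "
        f"{v.mean():.2f} +/- {v.std():.2f} Hz  (range {v.min():.1f}-{v.max():.1f})"
    )

print(
    "\nEvery network oscillates near the same frequency, but the spread across\n"
    "random networks shrinks as the population grows - the rhythmic network\n"
    "state is a mean-field property, not a finely synchronized one."
)
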