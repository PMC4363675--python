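"""Quantify how particle size perturbs each spectral region.

Computes the relative standard deviation (RSD) of mean log(1/R) across
the four mesh classes per wavenumber, summarised over the SCOT / FCOT /
CR regions, and labels each region's granularity sensitivity. Also shows
the Kubelka-Munk transform that motivates the analysis.
"""

import numpy as np

import granupls as g

cfg = g.SimulationConfig(grid=g.WavenumberGrid(step=7.712), n_samples=30,
                         seed=2)
avg = g.average_replicates(g.generate_dataset(cfg))
profile = g.region_rsd(g.class_mean_spectra(avg))
labels = g.classify_sensitivity(profile)

print("region   mean RSD   label")
for name, row in profile.region_summary.iterrows():
    print(f"{name:5s}    {row['mean']:.4f}     {labels[name]}")

R = np.array([0.9, 0.5, 0.2])
print("\nKubelka-Munk F(R) for R =", R, "->", np.round(g.kubelka_munk(R), 4))
# CR (5000-4000 cm^-1) is the most granularity-sensitive region (RSD >
# 0.035, 'high'), FCOT intermediate, SCOT nearly immune (< 0.015, 'low') —
# the wavelength dependence that motivates granularity-aware calibration.
# F(R) grows as reflectance drops: absorption relative to scatter increases.
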