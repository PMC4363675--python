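"""Generate a synthetic granularity study and export it as CSV.

Ninety powder samples, each sieved to four finenesses (40/65/80/100 mesh)
and measured in triplicate on the 10000-4000 cm^-1 grid. The analyte
concentration distribution targets a mean of 3.695 and SD of 1.452 mg/g
within [1.476, 8.162] mg/g.
"""

import numpy as np

import granupls as g

cfg = g.SimulationConfig(seed=1)  # full instrument grid, 90 samples
data = g.generate_dataset(cfg)
avg = g.average_replicates(data)

print(f"raw spectra:      {len(data)} rows "
      f"({cfg.n_samples} samples x 4 mesh classes x {cfg.replicates} replicates)")
print(f"averaged spectra: {len(avg)} rows on {data.grid.n_points} grid points")
c = avg.concentrations[avg.mesh == 65]
print(f"concentrations:   mean {c.mean():.3f}, SD {c.std(ddof=1):.3f}, "
      f"range [{c.min():.3f}, {c.max():.3f}] mg/g")

g.write_csv(avg, "synthetic_averaged.csv")
print("wrote synthetic_averaged.csv")
# The mean/SD sit near the configured 3.695 / 1.452 mg/g (truncation to the
# range shifts the realised mean slightly upward); every sample keeps the
# same concentration across its four mesh fractions.
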