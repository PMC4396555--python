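"""Why spatial weighting matters: the pixel-shuffle thought experiment.

A band and a pixel-shuffled copy of it have *identical* histograms, so any
marginal-histogram statistic calls them the same image.  SMI weights each
joint-histogram cell by the level difference of the co-occurring pixels:
a band against itself scores exactly 0, while against its shuffled copy
the mass lands off-diagonal and the score is positive.
"""

import numpy as np

import smiband as sb

rng = np.random.default_rng(0)
band = np.zeros((32, 32))
band[:, 16:] = 1.0                      # a structured, half-dark/half-bright band
band += rng.normal(0, 0.1, band.shape)
shuffled = rng.permutation(band.ravel()).reshape(band.shape)

q = sb.quantize(band, 64)
qs = sb.quantize(shuffled, 64, q.source_min, q.source_max)

hist_equal = np.array_equal(sb.marginal_histogram(q).counts,
                            sb.marginal_histogram(qs).counts)
mi_self = sb.mutual_information(sb.joint_histogram(q, q))
mi_cross = sb.mutual_information(sb.joint_histogram(q, qs))
smi_self = sb.spatial_mutual_information(sb.joint_histogram(q, q))
smi_cross = sb.spatial_mutual_information(sb.joint_histogram(q, qs))

print(f"marginal histograms identical:     {hist_equal}")
print(f"MI  band vs itself / vs shuffled:  {mi_self:.3f} / {mi_cross:.3f} bits")
print(f"SMI band vs itself / vs shuffled:  {smi_self:.3f} / {smi_cross:.3f}")
# MI drops for the shuffled pair but cannot flag which band is spatially
# degenerate; SMI pins the self-comparison at exactly 0 and scores the
# shuffled impostor strictly above it — the separation band clustering uses.
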