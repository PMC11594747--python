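"""Round-trip the signal chain: simulate a recording, extract kernels,
measure regional response amplitude densities (RAD).

A noise-free multifocal recording is generated with a known trough density
of 25 nV/deg^2 in every element; first-order kernel extraction followed by
baseline-to-trough measurement must give back exactly that density in every
ring and sector.
"""

import numpy as np

import mfphnr as m
from mfphnr.kernel import first_order_kernel

elements = m.build_dartboard()
params = m.WaveformParams(p1_amp=40.0, trough_amp=25.0, trough_time=70.0)
mseq = m.generate_mseq(8)  # 255 steps keeps the example fast
trace_set = m.simulate_trace_set(elements, mseq, params, noise_sd=0.0, seed=0)

kernels = first_order_kernel(trace_set)
pre = trace_set.pre_samples
template = m.element_response_template(params, elements[0].area)
err = np.abs(kernels.kernels[0][pre:] - template).max() / np.abs(template).max()
print(f"kernel vs generating template, max relative error: {err:.2e}")

rads = m.element_rads(kernels, elements)
rings = m.aggregate_rings(rads, elements)
sectors = m.aggregate_sectors(rads, elements)
print("ring RAD (nV/deg^2):", {k: round(v, 3) for k, v in rings.items()})
print("sector RAD (nV/deg^2):", {k: round(v, 3) for k, v in sectors.items()})
# All values equal the generating 25 nV/deg^2: the chain is unbiased and the
# area normalisation cancels element size exactly.
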