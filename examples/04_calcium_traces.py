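"""Calcium-trace analysis: bleach correction, events, alignment.

Simulates a bleaching fluorescence trace coupled to a known spike
train, corrects the bleach with an order-10 polynomial, extracts
calcium events, and aligns them with the underlying electrophysiology
spike train using a known acquisition-start offset.
"""

import numpy as np

from measort import (
    GroundTruth,
    SpikeTrain,
    align_traces,
    bleach_correct,
    delta_f_over_f,
    detect_calcium_spikes,
    simulate_calcium_trace,
)

rng = np.random.default_rng(0)
spike_s = 5.0 + np.arange(15) * 15.0 + rng.uniform(0, 4, 15)
truth = GroundTruth((spike_s * 20000).astype(np.int64),
                    np.zeros(15, dtype=np.int64), 1)
trace = simulate_calcium_trace(truth, frame_interval=0.0125, kernel_tau=0.4,
                               bleach_coeffs=(120.0, -0.1, 1.5e-4),
                               noise_sd=0.1, rng_seed=1, n_frames=20000)
print(f"trace: {len(trace.intensities)} frames, {trace.duration:.0f} s")

corrected = bleach_correct(trace, order=10)
spikes = detect_calcium_spikes(corrected, prominence_mult=4.0)
print(f"{len(spikes)} calcium events detected (injected: {len(spike_s)})")

dff = delta_f_over_f(trace)
print(f"peak dF/F = {dff.max():.3f} (event amplitude over baseline fluorescence)")

# imaging started 0.6 s after the electrophysiology clock: calcium event
# times sit 0.6 s early on the ephys axis until the offset is applied
ephys = SpikeTrain(spike_s + 0.6, duration=250.0)
table, n_co = align_traces(ephys, spikes, offset=-0.6, tolerance=1.0)
print(f"co-occurring events within +/-1 s: {n_co} of {len(spikes)}")
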