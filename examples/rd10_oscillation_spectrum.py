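"""Low-frequency oscillations in a degenerated-retina recording.

rd10 retinae exhibit pathologic 3-7 Hz oscillations with phase-locked
spike bursts.  This script generates a 10 s rd10-mode recording whose
oscillatory LFP components sit at 3.3 and 7 Hz, low-pass filters at
100 Hz, and reads the peaks off the single-sided amplitude spectrum.
"""

from retroprobe import ephys as E
from retroprobe import synthetic as syn

block, truth = syn.gen_recording(
    syn.InsertionProtocol(n_steps=2),  # 2 x 5 s at 20 kHz
    syn.RecordingScenario(mode="rd10", seed=42),
)
_, lfp = E.split_bands(block)
spec = E.amplitude_spectrum(lfp[-1], block.fs_hz, peak_band_hz=(1.0, 20.0))

print(f"generated oscillation frequencies: {truth.oscillation_freqs_hz} Hz")
print(f"spectral resolution: {block.fs_hz / block.traces_uv.shape[1]:.2f} Hz")
print("detected low-band peaks (frequency, amplitude):")
for f, a in spec.peaks[:2]:
    print(f"  {f:.1f} Hz   {a:.1f} uV")
print(
    "\nThe dominant peak matches the generated slow oscillation; the "
    "secondary peak is the weaker 7 Hz component."
)
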