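"""Parse an MSP spectrum, preprocess it, and bin it into a model input.

Builds a two-entry MSP text in memory, runs the scale -> filter -> bin
chain, and prints the surviving peak list and the nonzero bins.
"""

from specfid import BinningSpec, bin_spectrum, filter_spectrum, parse_msp

MSP = """\
Name: demo_glucose
InChIKey: WQZGKKKJIJFFOK-GASJEMHNSA-N
Precursor_type: [M+H]+
PrecursorMZ: 181.0707
ExactMass: 180.0634
Ion_mode: P
Instrument_type: Orbitrap
Collision_energy: 35 eV
Num Peaks: 6
59.0128 12
71.0128 30
85.0285 100
97.0285 45
127.039 22
163.060 8
"""

records = parse_msp(MSP)
print(f"parsed {len(records)} record(s); first has {len(records[0].peaks)} peaks")

filtered = filter_spectrum(records[0])
print("after filtering (scaled to base peak = 100):")
for p in filtered.peaks:
    print(f"  m/z {p.mz:9.4f}  intensity {p.intensity:6.1f}")

binned = bin_spectrum(filtered.peaks, BinningSpec())
nonzero = {i + 1: float(v) for i, v in enumerate(binned.values) if v > 0}
print(f"binned vector length {binned.values.shape[0]}; nonzero bins: {nonzero}")
# Each key is an integer m/z bin [b, b+1); its value is the accumulated
# scaled intensity — the feature the fingerprint predictor consumes.
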