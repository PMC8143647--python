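"""Analyze broth-microdilution plates: inhibition curves, MIC, dose trend.

Simulates duplicate OD600 readings for two substances on the reference
two-fold dilution series (1 mg/ml down to 31.25 ug/ml): one with partial
efficacy (Emax 0.75) and one nearly fully inhibitory (Emax 0.95).
"""

import glandscreen as gs

series = [float(c) for c in gs.dilution_series(1000.0, factor=2.0,
                                               floor=31.0)]
print("dilution series (ug/ml):", series)

for emax, name in [(0.75, "partial-efficacy peptide"),
                   (0.95, "strong peptide")]:
    spec = gs.SimulationSpec(dose_ec50=125.0, dose_hill=2.0,
                             od_noise_sd=0.01, seed=7)
    plate = gs.simulate_plate(spec, series, emax=emax, peptide_id=name)
    curve = gs.analyze_plate(plate, mic_threshold=90.0)
    mic = "none" if curve.mic is None else f"{curve.mic:g} ug/ml"
    print(f"\n{name}:")
    for conc, inhib in zip(curve.concentrations, curve.inhibition_percent):
        print(f"  {conc:7.2f} ug/ml -> {inhib:5.1f}% inhibition")
    print(f"  max inhibition {curve.max_inhibition:.1f}%, MIC {mic}, "
          f"dose dependent: {curve.dose_dependent} "
          f"(rho={curve.spearman_rho:.2f}, p={curve.spearman_p:.3g})")
# The Emax=0.75 substance plateaus near 75% and never reaches the 90%
# MIC threshold (MIC none); the Emax=0.95 one crosses it within the
# tested series.  Both show a significant monotone dose trend.
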