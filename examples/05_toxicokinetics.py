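"""Convert applied oral doses into serum Cmax and TWA for a 28-day
daily-gavage study with a one-compartment model."""

from ttraop.tk import DoseRegimen, TKParameters, convert_doses

# PFOA-like parameters in the male rat
params = TKParameters(half_life=24 * 7, volume_of_distribution=0.2,
                      molecular_weight=414.07, absorption_rate_ka=1.0)
regimen = DoseRegimen(dose=0.0, interval=24.0, duration=28.0)

table = convert_doses([0.3, 1.0, 3.0, 10.0], params, regimen)
print(table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
# Cmax is the peak serum concentration over the study; TWA the trapezoidal
# time-weighted average. Both scale linearly with dose, and the week-long
# half-life produces substantial accumulation over 28 daily doses.
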