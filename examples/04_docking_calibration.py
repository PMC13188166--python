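"""Calibrate docking scores against measured pEC50 on C4-C8 carboxylates
and estimate binding for two replacement PFAS from their scores."""

from ttraop.docking import fit_calibration, predict_pec50, select_calibration_subset
from ttraop.synth import ADONA_SCORE, GENX_SCORE, make_docking_fixture

subset = select_calibration_subset(make_docking_fixture())
cal = fit_calibration(subset)
print(f"calibration on {cal.n_used} C4-C8 carboxylates: "
      f"pEC50 = {cal.slope:.3f}*score + {cal.intercept:.3f}, R2 = {cal.r2:.2f}")

for name, score in (("ADONA-like", ADONA_SCORE), ("GenX-like", GENX_SCORE)):
    p = predict_pec50(cal, score)
    print(f"{name}: score {score:.3f} kcal/mol -> pEC50 {p['pec50']:.2f} "
          f"({p['binder_class']}, extrapolated={p['extrapolated']})")
# More negative scores mean stronger predicted binding; the linear map is
# trusted only inside the carboxylate chemical class it was fit on.
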