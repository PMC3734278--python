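"""Allocating a fixed yearly treatment supply: few large or many small pulses?

Holding the dose rate C = kappa*nu fixed, the exact master-equation MFPT is
computed across kappa.  Because the number treated per pulse is the integer
part of kappa*I, very small pulses stop acting once few individuals remain
infected, so large rare pulses eradicate faster than small frequent ones.
Rounding up instead (ceil) removes that floor effect.
"""

import math

from sispulse import EpidemicParams
from sispulse.experiments import fixed_dose_sweep

params = EpidemicParams(beta=2.0, gamma=0.8, mu=0.2, N_bar=500)
df, _ = fixed_dose_sweep(params, dose_constant=0.2,
                         kappa_grid=[0.02, 0.05, 0.1, 0.2, 0.4],
                         methods=("master_eq",))

print("fixed dose rate C = kappa*nu = 0.2 per year, N = 500")
print(f"{'kappa':>6} {'nu':>6} {'ln MTE (floor)':>15} {'ln MTE (ceil)':>14}")
fl = df[df.rounding == "floor"].set_index("kappa")
ce = df[df.rounding == "ceil"].set_index("kappa")
for k in sorted(fl.index):
    print(f"{k:6.2f} {0.2 / k:6.1f} {fl.loc[k, 'log_mte']:15.2f} "
          f"{ce.loc[k, 'log_mte']:14.2f}")
print()
print("Under floor rounding the mean extinction time falls steeply with")
print("kappa at fixed supply: treating a larger pool less often wins.")
print("Ceil rounding keeps tiny pulses active down to the last infecteds,")
print("so its extinction times are never slower than floor's.")
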