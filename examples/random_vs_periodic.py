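"""Random (Poisson) versus strictly periodic treatment schedules.

Same mean pulse frequency and pulse fraction, matched simulation budgets.
In the endemic regime the Poisson schedule extinguishes the disease sooner:
occasional clumps of closely spaced pulses drive the infection down before
it can relax back, a route the rigid periodic schedule never takes.
"""

from sispulse import EpidemicParams, TreatmentPolicy
from sispulse.experiments import schedule_comparison

params = EpidemicParams(beta=2.0, gamma=0.8, mu=0.2, N_bar=60)
df, _ = schedule_comparison(params, kappa_grid=[0.1, 0.2], nu_set=[2.0, 4.0],
                            n_realizations=1000, seed=3, t_max=1e6)

print(f"{'kappa':>6} {'nu':>4} {'poisson':>10} {'periodic':>10} {'diff':>9} {'z':>6}")
for _, r in df.iterrows():
    z = r["diff"] / r.se_diff
    print(f"{r.kappa:6.2f} {r.nu:4.0f} {r.mte_poisson:10.1f} "
          f"{r.mte_periodic:10.1f} {r['diff']:+9.1f} {z:+6.1f}")
print()
print("Negative differences mean the random schedule reaches extinction")
print("sooner; z is the paired difference in units of its standard error.")
print("(Once the dose kappa*nu exceeds beta - gamma - mu the endemic state")
print("is gone and the ordering can invert: there the risk is long Poisson")
print("pulse gaps, not missing pulse clumps.)")
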