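"""The extinction prehistory density follows the WKB optimal path.

Simulates the full (S, I) model to extinction many times and histograms the
last five years before each extinction.  The ridge of that occupancy density
is compared with the optimal path computed from the Hamiltonian: the most
probable route to extinction in the simulations is the theory's heteroclinic
trajectory.
"""

from sispulse import EpidemicParams, TreatmentPolicy
from sispulse.experiments import prehistory_vs_path

params = EpidemicParams(beta=2.0, gamma=0.8, mu=0.2, N_bar=500)
policy = TreatmentPolicy(kappa=0.18, nu=4.0)

summary, ridge = prehistory_vs_path(params, policy, n_realizations=1000,
                                    seed=11, window=5.0, bins=40, t_max=1e6)

print(f"extinct realizations : {summary['n_extinct']}")
print(f"optimal-path action  : {summary['action']:.5f}")
print(f"ridge-to-path mean distance: "
      f"{summary['mean_ridge_distance_bins']:.2f} histogram bin widths")
print()
print("sample of ridge vs path (susceptible fraction at given infected fraction):")
print(ridge.iloc[::6][["x", "ridge_y", "path_y", "dist_bins"]].to_string(index=False))
print()
print("A mean distance well under 2 bin widths means the simulated")
print("pre-extinction flow concentrates on the predicted optimal path.")
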