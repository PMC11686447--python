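"""Simulate N-glycan processing through four Golgi cisternae.

Builds a CHO-like enzyme parameter set, pushes 10,000 glycans through the
stochastic simulator, and prints the resulting glycoform profile next to
the exact distribution from the matrix-exponential of the underlying
continuous-time Markov chain.  The two columns agree to Monte-Carlo
accuracy — the simulator is an exact sampler of the model.
"""

from glygolgi.ctmc_reference import terminal_distribution
from glygolgi.golgi_ssa import flux_localization, simulate_profile
from glygolgi.synthetic_data import cho_baseline_parameters

params = cho_baseline_parameters()
result = simulate_profile(params, n_glycans=10_000, seed=7)
exact = terminal_distribution(params)

print(f"{'glycoform':<12}{'simulated':>10}{'exact':>10}")
for name, frac in sorted(result.profile.items(), key=lambda kv: -kv[1]):
    if frac >= 0.01:
        print(f"{name:<12}{frac:>10.3f}{exact.get(name, 0.0):>10.3f}")

print("\nMgat1 flux by cisterna (fraction of firings in cis..TGN):")
print("  " + "  ".join(f"{f:.2f}" for f in flux_localization(result, "Mgat1")))
print(
    "\nThe profile is G0F-dominant, as for a typical IgG; the flux vector"
    "\nshows where in the Golgi Mgat1 does its work under these activities."
)
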