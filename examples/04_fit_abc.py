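"""Infer enzyme activities from a glycan profile by ABC-MCMC.

Simulates an observed profile at known parameters with GalT (the
galactosyltransferase) raised four-fold, fits both the baseline and the
perturbed profile with parallel ABC-MCMC chains, and prints the
per-enzyme posterior-median log-ratio with Mann-Whitney p-values — the
cluster-versus-cluster comparison readout.  Takes a couple of minutes.
"""

from glygolgi.abc_fit import AbcConfig, compare_clusters
from glygolgi.synthetic_data import abc_recovery_parameters, make_abc_target

base = abc_recovery_parameters()
obs_a, _, _ = make_abc_target(base, None, n_glycans=10_000, seed=41)
obs_b, _, _ = make_abc_target(base, {"GalT": 4.0}, n_glycans=10_000, seed=42)

config = AbcConfig(seed=7, chain_length=1200, n_chains=4, n_glycans=3000)
comparison = compare_clusters(obs_a, obs_b, config)
cols = ["enzyme", "median_log_ratio", "p", "p_adj", "rhat_a", "rhat_b", "significant"]
print(comparison.table[cols].round(3).to_string(index=False))
print(
    "\nGalT was raised 4-fold when generating profile B, so its"
    "\nmedian_log_ratio should be near ln 4 = 1.39 and the largest in"
    "\nmagnitude; parameters with R-hat > 1.2 are excluded from claims."
    "\nAt this demo chain length some R-hats stay above the gate —"
    "\nlengthen chain_length for a production comparison."
)
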