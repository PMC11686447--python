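"""Cluster synthetic glycan profiles and characterize the clusters.

Generates the two-cluster project preset (Man5-dominant vs G0F-dominant
samples, measured in duplicate), averages replicates, picks the cluster
count from the largest relative drop of the within-cluster sum of squares
(the elbow), and reports each cluster's dominant glycoforms.
"""

from sklearn.metrics import adjusted_rand_score

from glygolgi.profile_clustering import (
    characterize_clusters,
    choose_k,
    elbow_curve,
    kmeans_profiles,
)
from glygolgi.synthetic_data import make_profiles, project_a_spec

profiles, true_labels = make_profiles(project_a_spec(seed=7))
avg = profiles.averaged_replicates()

curve = elbow_curve(avg, k_max=6, seed=0)
print("k    WCSS")
for k, w in curve:
    print(f"{k}    {w:.4f}")
k = choose_k(curve)
print(f"elbow -> k = {k}")

assignment = kmeans_profiles(avg, k, seed=0)
ari = adjusted_rand_score(true_labels.loc[assignment.labels.index], assignment.labels)
print(f"adjusted Rand index vs planted labels: {ari:.3f}")
print(characterize_clusters(assignment, avg)[["n_samples", "dominant_species"]])
print(
    "\nWCSS collapses between k=1 and k=2 and flattens after — the planted"
    "\ntwo-cluster structure; ARI 1.0 means k-means recovered it exactly."
)
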