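"""Habitat enrichment: where do carriers of a gene family live?

Simulates a habitat-preference score matrix with a planted enrichment of
family carriers in one environment and recovers it as the difference of
group mean scores per environment.
"""

import numpy as np

import convfuse as cf

rng = np.random.default_rng(3)
presence = {f"s{i}": int(rng.random() < 0.3) for i in range(400)}
environments = ["activated_sludge", "freshwater", "human_gut", "hot_spring",
                "marine", "marine_sediment", "soil"]

habitat = cf.simulate_habitat_matrix(
    presence, environments, focal_environment="marine_sediment",
    effect_size=0.35, noise_sd=0.1, seed=3)

report = cf.enrichment_score(habitat, presence)
top, bottom, _ = cf.rank_environments(report, top_n=3)

print(f"carriers: {report.n_with}, non-carriers: {report.n_without}")
print("\ntop environments (enrichment score = carrier mean - non-carrier mean):")
for env, score in top:
    print(f"  {env:<18} {score:+.3f}")
print("bottom environments:")
for env, score in bottom:
    print(f"  {env:<18} {score:+.3f}")
print("\nThe planted environment tops the ranking at roughly the planted")
print("effect size (0.35); the other scores scatter around zero.")
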