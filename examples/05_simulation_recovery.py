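"""Ground-truth recovery of the scoring pipeline under ordinal noise.

Simulates evidence tables whose true burden category per nutrient is known,
then measures how often the end-to-end pipeline recovers the true rating as
the misclassification probability epsilon grows.
"""

from nutrigap import Nutrient, SimulationSpec, recovery_experiment

print("epsilon  recovery  high-certainty")
for eps in (0.0, 0.1, 0.2, 0.3, 0.4):
    spec = SimulationSpec(
        seed=42, epsilon=eps, n_points_per_nutrient=3,
        guarantee_strong_point=False,
        true_codes={Nutrient.IRON: 3, Nutrient.VITAMIN_A: 2, Nutrient.ZINC: 1},
    )
    s = recovery_experiment(spec, n_replicates=60)
    print(f"  {eps:.2f}   {s.rating_recovery:7.2%}   {s.high_certainty_fraction:7.2%}")
print()
print("With epsilon = 0 every point's estimate falls in its true category's")
print("threshold interval, so ratings are recovered exactly; as epsilon grows,")
print("points slip into adjacent categories and both recovery and the share")
print("of high-certainty assessments fall.")
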