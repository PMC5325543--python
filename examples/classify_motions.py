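"""Motion-type classification: who rotates, tumbles, circles, or ignores light.

Classifies ground-truth tracks over the 3rd blue-light pulse of a cycle-1
experiment A and prints the proportions of the four photophobic motions.
"""

from phototrace.pipeline import run_experiment

res = run_experiment("A", cycle=1, n_cells=100, seed=10, classify_pulse=3,
                     duration=466.0)

print("motion type proportions during the 3rd pulse (cycle 1):")
for name, frac in res["proportions"].items():
    print(f"  {name:12s} {frac*100:5.1f}%")
excluded = (res["labels"]["label"] == "irregular_excluded").mean()
print(f"  excluded as irregular: {excluded*100:.1f}%")
print()
print("A naive autotrophic population responds almost uniformly with on-site")
print("rotation (~90%); run/tumble, circular and straightforward swimming")
print("take over as the population adapts across cycles.")
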