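"""Fixation probabilities of the two-choice learning process, three ways.

The predator/prey choice model applies g₁(x) = (1−a₁)x + a₁ with
probability x (success reinforces) and g₂(x) = (1−a₂)x otherwise.  The
probability f(x) of ultimately fixating on the reinforced response solves
f(x) = x f(g₁(x)) + (1−x) f(g₂(x)) with f(0)=0, f(1)=1.  This script
solves that equation on a grid and cross-checks it with Monte-Carlo
simulation of the process itself; the z column is |difference|/SE, so
values below 3 mean the solver and the simulator agree statistically.
"""

from fractions import Fraction

import operanteq as oq

# equal rates: the state is a martingale, so f(x) = x in closed form
model = oq.preset_model("lyubich_shapiro", {"a1": Fraction(3, 10)})
df = oq.compare_to_solution(model, [0.25, 0.5, 0.75], n_reps=4000, seed=7)
print("equal rates a1 = a2 = 0.3 (closed form f(x) = x):")
print(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

model2 = oq.preset_model("lyubich_shapiro", {"a1": Fraction(3, 10), "a2": Fraction(6, 10)})
df2 = oq.compare_to_solution(model2, [0.25, 0.5, 0.75], n_reps=4000, seed=8)
print("\nunequal rates a1 = 0.3, a2 = 0.6 (reinforcement asymmetry pulls f below x):")
print(df2.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
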