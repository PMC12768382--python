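"""Exact Picard iteration for the two-choice pigeon-style model.

Builds the model Γ(x) = ∫₀ˣ t Γ((t+1)/4) + (1−t) Γ((t+2)/5) dt, runs three
exact symbolic Picard steps from Γ₀(x) = x, and prints each iterate's
rational coefficients.  The coefficients are exact: each iterate is a
polynomial, and the sup-norm deltas shrinking toward 0 show the sequence
contracting onto the equation's unique fixed point in the space of
continuous functions vanishing at 0.
"""

import operanteq as oq

model = oq.preset_model("example1", {})
trace = oq.picard_iterates(model, n=3)

for n, poly in enumerate(trace.iterates):
    print(f"Gamma{n}(x) = {poly}")
print("sup-norm deltas per step:", [f"{d:.4f}" for d in trace.sup_norm_deltas])
print("Gamma1(1) =", oq.evaluate_poly(trace.iterates[1], 1), "(exact rational)")
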