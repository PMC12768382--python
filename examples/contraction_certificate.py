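"""Contraction certificates for the built-in models.

For each model the report lists the exact Lipschitz constant κ of every
response operator, the aggregate k = Σκ, and whether the strict condition
k < 1 holds — the certificate that Picard iteration converges to a unique
solution.  The a-priori bound then says how many iterations guarantee a
given sup-norm accuracy from the first observed delta.
"""

import operanteq as oq

for preset in ("example1", "example2"):
    model = oq.preset_model(preset, {})
    rep = oq.contraction_report(model)
    print(f"{preset}: kappas = {[str(k) for _, k, _ in rep.per_operator_kappa]}, "
          f"aggregate k = {rep.aggregate_k}, "
          f"sum<1 {'satisfied' if rep.sum_condition_satisfied else 'violated'}, "
          f"certified={rep.certified}")

# how many iterations until the a-priori error bound k^n d1/(1-k) <= 1e-6?
trace = oq.picard_iterates(oq.preset_model("example1", {}), n=1)
d1 = trace.sup_norm_deltas[0]
n = oq.a_priori_iterations(9 / 20, d1, 1e-6)
print(f"first delta d1 = {d1:.4f}; iterations for 1e-6 accuracy: {n}")
print("comparison-function decay:", [f"{v:.4f}" for v in oq.phi_iterate(9 / 20, 1.0, 4)[0]])
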