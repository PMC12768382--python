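"""Contraction certificates for the integral operator.

The existence/uniqueness certificate for the Volterra-form model is that
every response operator ℰᵢ is a contraction with coefficient κᵢ and the
aggregate k = Σκᵢ is strictly below 1; the associated comparison function
is the linear map φ(t) = k·t, whose iterates φⁿ(t) = kⁿ t vanish.  A
two-operator corollary uses the (order-free) condition 2·max(κᵢ) < 1.
Affine operators have exact rational κ = |slope|; generic operators get a
grid-based estimate that never yields a certificate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .model import IntegralModel, ResponseOperator

__all__ = [
    "ContractionReport",
    "lipschitz_constant",
    "contraction_report",
    "phi_iterate",
    "a_priori_iterations",
]


@dataclass
class ContractionReport:
    """Per-operator Lipschitz constants and theorem-style certificate flags.

    ``certified`` is True only when every κ is exact (all operators affine);
    estimated constants make the flags heuristic, never a certificate.
    """

    per_operator_kappa: list[tuple[int, Fraction | float, str]]
    aggregate_k: Fraction | float
    sum_condition_satisfied: bool
    max_condition_satisfied: bool
    certified: bool

    @property
    def phi_description(self) -> str:
        return f"phi(t) = {self.aggregate_k} * t"

    def to_dict(self) -> dict:
        def num(v):
            return {"exact": str(v), "float": float(v)}

        return {
            "operators": [
                {"id": i, "kappa": num(k), "method": m}
                for i, k, m in self.per_operator_kappa
            ],
            "aggregate_k": num(self.aggregate_k),
            "sum_condition_satisfied": self.sum_condition_satisfied,
            "max_condition_satisfied": self.max_condition_satisfied,
            "phi": self.phi_description,
            "certified": self.certified,
        }


def lipschitz_constant(
    op: ResponseOperator, method: str = "exact", n_grid: int = 1000
) -> tuple[Fraction | float, str]:
    """κ for a response operator.

    Affine operators give the exact |slope| regardless of ``method``.
    ``method="grid"`` estimates κ for generic operators as the maximum
    absolute difference quotient over adjacent nodes of an n_grid-point
    uniform grid; the estimate never exceeds the true constant and is
    flagged ``"estimated"``.
    """
    if op.is_affine:
        return op.lipschitz(), "exact"
    if method == "exact":
        raise ValueError("exact Lipschitz constant unavailable for generic operators")
    if n_grid < 100:
        raise ValueError("grid Lipschitz estimation needs n_grid >= 100")
    t = np.linspace(0.0, 1.0, n_grid)
    y = np.asarray([op(float(v)) for v in t], dtype=float)
    quotients = np.abs(np.diff(y)) / np.diff(t)
    return float(quotients.max()), "estimated"


def contraction_report(model: IntegralModel, n_grid: int = 1000) -> ContractionReport:
    """Aggregate the κᵢ over all terms and evaluate both certificate flags.

    sum_condition_satisfied ⇔ Σκᵢ < 1 (strict; the m-operator extension of the
    two-term condition); max_condition_satisfied ⇔ 2·max(κᵢ) < 1.
    """
    kappas: list[tuple[int, Fraction | float, str]] = []
    for i, op in enumerate(model.operators):
        k, how = lipschitz_constant(op, method="exact" if op.is_affine else "grid", n_grid=n_grid)
        kappas.append((i, k, how))
    certified = all(how == "exact" for _, _, how in kappas)
    values = [k for _, k, _ in kappas]
    aggregate = sum(values, Fraction(0)) if certified else float(sum(map(float, values)))
    kmax = max(values)
    return ContractionReport(
        per_operator_kappa=kappas,
        aggregate_k=aggregate,
        sum_condition_satisfied=aggregate < 1,
        max_condition_satisfied=2 * kmax < 1,
        certified=certified,
    )


def phi_iterate(k: float, t0: float, n: int) -> tuple[list[float], bool]:
    """Iterates [t0, k·t0, …, kⁿ·t0] of the linear comparison function.

    Returns ``(values, is_comparison)`` where ``is_comparison`` is False
    when φ(t) < t fails for t > 0 (i.e. k ≥ 1), so the sequence need not
    decay.
    """
    if k < 0 or t0 < 0:
        raise ValueError("k and t0 must be >= 0")
    values = [t0 * k**i for i in range(n + 1)]
    return values, (k < 1)


def a_priori_iterations(k: float, d1: float, eps: float) -> int:
    """Smallest n with kⁿ·d1/(1−k) ≤ eps (linear-φ a-priori error bound).

    d1 is the first successive-difference norm ‖Γ₁ − Γ₀‖∞; requires a
    strict certificate 0 < k < 1.
    """
    if not (0 < k < 1):
        raise ValueError("a-priori bound requires a certificate 0 < k < 1")
    if d1 <= 0 or eps <= 0:
        raise ValueError("d1 and eps must be > 0")
    bound = d1 / (1 - k)
    if bound <= eps:
        return 0
    # ceil of log(eps/bound)/log(k), guarded against float edge cases
    n = max(0, math.ceil(math.log(eps / bound) / math.log(k)))
    while k**n * bound > eps:
        n += 1
    while n > 0 and k ** (n - 1) * bound <= eps:
        n -= 1
    return n
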