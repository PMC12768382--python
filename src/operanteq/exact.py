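"""Exact symbolic Picard iteration in arbitrary-precision rational arithmetic.

Each Picard iterate of an integral model with polynomial weights and affine
response operators is itself a polynomial with rational coefficients, so
the iteration

    Γₙ₊₁(x) = ∫₀ˣ Σᵢ wᵢ(x, t) Γₙ(ℰᵢ(t)) dt

can be carried out exactly: compose Γₙ with each affine ℰᵢ (binomial
expansion), multiply by the weight polynomial, integrate term-wise in t
from 0 to the variable upper limit x, and collect powers of x.  Every
iterate vanishes at 0 by construction, and the degree grows by
1 + deg_t(w) per step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import IntegralModel, ResponseOperator, RationalLike, _frac

__all__ = [
    "RationalPolynomial",
    "PicardTrace",
    "poly_compose_affine",
    "picard_step_exact",
    "picard_iterates",
    "coefficient_query",
    "evaluate_poly",
]

# degree/coefficient size grow per step; the cap is a config knob, not a
# mathematical limit
MAX_ITERATIONS = 25
SUP_NORM_GRID = 10001


@dataclass(frozen=True)
class RationalPolynomial:
    """Univariate polynomial with exact Fraction coefficients.

    Coefficients are stored sparsely as ``{degree: Fraction}`` with no zero
    entries; the empty map is the zero polynomial.  Fractions are always in
    lowest terms with positive denominator (the Fraction type guarantees
    this), matching how coefficients are printed in worked examples.
    """

    coeffs: Mapping[int, Fraction] = field(default_factory=dict)
    var: str = "x"

    def __post_init__(self):
        clean = {int(k): _frac(v) for k, v in self.coeffs.items() if v != 0}
        object.__setattr__(self, "coeffs", clean)

    @classmethod
    def identity(cls, var: str = "x") -> "RationalPolynomial":
        return cls({1: Fraction(1)}, var=var)

    @classmethod
    def zero(cls, var: str = "x") -> "RationalPolynomial":
        return cls({}, var=var)

    @property
    def degree(self) -> int:
        """Degree; −1 for the zero polynomial."""
        return max(self.coeffs, default=-1)

    def coefficient(self, k: int) -> Fraction:
        return self.coeffs.get(k, Fraction(0))

    def __add__(self, other: "RationalPolynomial") -> "RationalPolynomial":
        out = dict(self.coeffs)
        for k, v in other.coeffs.items():
            out[k] = out.get(k, Fraction(0)) + v
        return RationalPolynomial(out, var=self.var)

    def __sub__(self, other: "RationalPolynomial") -> "RationalPolynomial":
        return self + other.scale(Fraction(-1))

    def scale(self, a: RationalLike) -> "RationalPolynomial":
        a = _frac(a)
        return RationalPolynomial({k: a * v for k, v in self.coeffs.items()}, var=self.var)

    def shift_degree(self, j: int) -> "RationalPolynomial":
        """Multiply by var**j."""
        return RationalPolynomial({k + j: v for k, v in self.coeffs.items()}, var=self.var)

    def __call__(self, x):
        return self.eval_float(x)

    def eval_exact(self, x: RationalLike) -> Fraction:
        """Exact Horner evaluation at a rational point."""
        x = _frac(x)
        acc = Fraction(0)
        for k in range(self.degree, -1, -1):
            acc = acc * x + self.coeffs.get(k, Fraction(0))
        return acc

    def eval_float(self, x):
        """Horner evaluation at a float or numpy array."""
        acc = np.zeros_like(np.asarray(x, dtype=float))
        for k in range(self.degree, -1, -1):
            acc = acc * x + float(self.coeffs.get(k, 0))
        if np.ndim(x) == 0:
            return float(acc)
        return acc

    def sup_norm(self, n_grid: int = SUP_NORM_GRID) -> float:
        """Numeric sup norm on [0, 1] on a dense grid (diagnostic accuracy)."""
        xs = np.linspace(0.0, 1.0, n_grid)
        return float(np.abs(self.eval_float(xs)).max())

    def to_coefficient_records(self) -> list[dict]:
        """JSON-friendly exact listing, ascending degree."""
        return [
            {"degree": k, "numerator": v.numerator, "denominator": v.denominator}
            for k, v in sorted(self.coeffs.items())
        ]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        if not self.coeffs:
            return "0"
        parts = [f"({v})*{self.var}^{k}" for k, v in sorted(self.coeffs.items(), reverse=True)]
        return " + ".join(parts)


def poly_compose_affine(poly: RationalPolynomial, op: ResponseOperator) -> RationalPolynomial:
    """Exact composition poly(slope·t + intercept) by binomial expansion."""
    if not op.is_affine:
        raise ValueError("exact composition requires an affine operator")
    s, c = op.slope, op.intercept
    out: dict[int, Fraction] = {}
    for k, a in poly.coeffs.items():
        # (s t + c)^k = Σ_j C(k, j) s^j c^(k-j) t^j
        for j in range(k + 1):
            coef = a * math.comb(k, j) * s**j * c ** (k - j)
            if coef:
                out[j] = out.get(j, Fraction(0)) + coef
    return RationalPolynomial(out, var=poly.var)


def picard_step_exact(model: IntegralModel, poly: RationalPolynomial) -> RationalPolynomial:
    """One exact application of the integral operator T.

    For each term: compose the iterate with the affine operator, multiply by
    the bivariate weight w(x, t), integrate term-wise in t over [0, x]
    (monomial x^i t^j contributes x^(i+j+1)/(j+1)), and collect in x.  The
    result always vanishes at x = 0.
    """
    if not model.is_exactly_solvable:
        raise ValueError(
            "exact Picard step requires polynomial weights and affine operators"
        )
    out: dict[int, Fraction] = {}
    for w, op in model.terms:
        q = poly_compose_affine(poly, op)  # polynomial in t
        for (i, j), wc in w.coeffs.items():
            for k, qc in q.coeffs.items():
                # ∫₀ˣ x^i t^(j+k) dt = x^(i+j+k+1) / (j+k+1)
                deg = i + j + k + 1
                out[deg] = out.get(deg, Fraction(0)) + wc * qc / (j + k + 1)
    return RationalPolynomial(out, var=poly.var)


@dataclass
class PicardTrace:
    """Successive exact iterates Γ₀ … Γₙ with sup-norm successive differences.

    ``sup_norm_deltas[i] = ‖Γᵢ₊₁ − Γᵢ‖∞`` computed numerically on a dense
    grid (grid-resolution-limited; exact maximization of high-degree
    polynomials is unnecessary for diagnostics).
    """

    iterates: list[RationalPolynomial]
    sup_norm_deltas: list[float]
    model: IntegralModel

    def __len__(self) -> int:
        return len(self.iterates)

    @property
    def final(self) -> RationalPolynomial:
        return self.iterates[-1]


def picard_iterates(
    model: IntegralModel,
    gamma0: RationalPolynomial | None = None,
    n: int = 3,
) -> PicardTrace:
    """Run n exact Picard steps from Γ₀ (default Γ₀(x) = x).

    Returns the trace of n + 1 iterates.  Degree grows by
    1 + max t-degree of the weights per step.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n > MAX_ITERATIONS:
        raise ValueError(
            f"n={n} exceeds the iteration cap {MAX_ITERATIONS} "
            "(coefficient size grows rapidly); raise MAX_ITERATIONS deliberately"
        )
    gamma = RationalPolynomial.identity() if gamma0 is None else gamma0
    iterates = [gamma]
    deltas: list[float] = []
    for _ in range(n):
        nxt = picard_step_exact(model, gamma)
        deltas.append((nxt - gamma).sup_norm())
        iterates.append(nxt)
        gamma = nxt
    return PicardTrace(iterates=iterates, sup_norm_deltas=deltas, model=model)


def coefficient_query(poly: RationalPolynomial, k: int) -> tuple[int, int]:
    """Lowest-terms (numerator, denominator) of the degree-k coefficient;
    (0, 1) for absent degrees."""
    if k < 0:
        raise ValueError("degree must be >= 0")
    c = poly.coefficient(k)
    return (c.numerator, c.denominator)


def evaluate_poly(poly: RationalPolynomial, x: RationalLike) -> Fraction:
    """Exact Horner evaluation at a rational point."""
    return poly.eval_exact(x)
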