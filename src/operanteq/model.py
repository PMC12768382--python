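"""Model types for operant-learning functional equations.

Two families of models are represented here.

*Integral form.*  The unknown probability-evolution map ``Γ`` on ``[0, 1]``
with ``Γ(0) = 0`` satisfies a Volterra-type equation

    Γ(x) = ∫₀ˣ Σᵢ wᵢ(x, t) Γ(ℰᵢ(t)) dt,

where the weights ``wᵢ`` are non-negative, sum to one on the triangle
``0 ≤ t ≤ x ≤ 1``, and each response operator ``ℰᵢ`` maps ``[0, 1]`` into
itself.  The two-choice case has weights ``t`` and ``1 − t`` (a pigeon
pecking / not pecking a target); the four-outcome case has weights
``pt, (1−p)t, p(1−t), (1−p)(1−t)`` for a reward-predictability experiment.

*Discrete form.*  The classical two-choice learning equation

    f(x) = x f(g₁(x)) + (1 − x) f(g₂(x)),   f(0) = 0, f(1) = 1,

whose solution is the fixation (absorption) probability of the Markov
process that applies ``g₁`` with probability ``x`` and ``g₂`` otherwise.
The predator/prey choice model uses ``g₁(x) = (1−a₁)x + a₁`` and
``g₂(x) = (1−a₂)x``.

All preset operators are affine with exact rational coefficients, so the
exact Picard engine can reproduce closed-form iterate coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Mapping, Sequence

__all__ = [
    "ResponseOperator",
    "WeightFunction",
    "IntegralModel",
    "DiscreteModel",
    "ValidationReport",
    "make_affine_operator",
    "validate_integral_model",
    "preset_model",
    "reduce_to_discrete",
    "PRESET_NAMES",
]

RationalLike = Fraction | int | str


def _frac(value: RationalLike) -> Fraction:
    """Coerce ints, ``"num/den"`` strings and Fractions to Fraction."""
    if isinstance(value, Fraction):
        return value
    return Fraction(value)


@dataclass(frozen=True)
class ResponseOperator:
    """A response operator ℰ (or transition operator g) on [0, 1].

    ``affine`` operators ``t ↦ slope·t + intercept`` carry exact rational
    coefficients and an exact Lipschitz constant ``|slope|``; ``generic``
    operators wrap an arbitrary continuous self-map of [0, 1].
    """

    kind: str  # "affine" | "generic"
    slope: Fraction | None = None
    intercept: Fraction | None = None
    func: Callable[[float], float] | None = None
    label: str = ""

    def __call__(self, t):
        if self.kind == "affine":
            # works for floats, numpy arrays and Fractions alike
            if isinstance(t, Fraction):
                return self.slope * t + self.intercept
            return float(self.slope) * t + float(self.intercept)
        return self.func(t)

    @property
    def is_affine(self) -> bool:
        return self.kind == "affine"

    def lipschitz(self) -> Fraction:
        """Exact Lipschitz constant; defined only for affine operators."""
        if not self.is_affine:
            raise ValueError("exact Lipschitz constant requires an affine operator")
        return abs(self.slope)

    def image(self) -> tuple[Fraction, Fraction]:
        """Exact image interval of [0, 1] under an affine operator."""
        if not self.is_affine:
            raise ValueError("exact image requires an affine operator")
        ends = (self.intercept, self.slope + self.intercept)
        return min(ends), max(ends)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        if self.is_affine:
            return f"ResponseOperator({self.slope}*t + {self.intercept})"
        return f"ResponseOperator(generic {self.label or self.func!r})"


def make_affine_operator(slope: RationalLike, intercept: RationalLike) -> ResponseOperator:
    """Build ``t ↦ slope·t + intercept`` and check it maps [0, 1] into [0, 1].

    Raises ``ValueError`` naming the offending endpoint if the image of
    [0, 1] leaves [0, 1].  The contraction coefficient κ = |slope| is exact.
    """
    s, c = _frac(slope), _frac(intercept)
    for endpoint, value in (("0", c), ("1", s + c)):
        if not (0 <= value <= 1):
            raise ValueError(
                f"affine operator {s}*t + {c} maps endpoint t={endpoint} "
                f"to {value}, outside [0, 1]"
            )
    return ResponseOperator(kind="affine", slope=s, intercept=c)


def make_generic_operator(func: Callable[[float], float], label: str = "") -> ResponseOperator:
    """Wrap an arbitrary continuous self-map of [0, 1] (numeric engine only)."""
    return ResponseOperator(kind="generic", func=func, label=label)


@dataclass(frozen=True)
class WeightFunction:
    """A weight w(x, t), either an exact bivariate polynomial or a callable.

    Polynomial coefficients are stored as ``{(i, j): Fraction}`` for the
    monomial ``x^i t^j``.  All built-in presets use polynomials constant
    in x (weights in ``t`` only) or constant in t (weights ``x``, ``1 − x``).
    """

    coeffs: Mapping[tuple[int, int], Fraction] | None = None
    func: Callable[[float, float], float] | None = None
    label: str = ""

    def __post_init__(self):
        if (self.coeffs is None) == (self.func is None):
            raise ValueError("supply exactly one of coeffs or func")
        if self.coeffs is not None:
            clean = {
                (int(i), int(j)): _frac(c)
                for (i, j), c in self.coeffs.items()
                if c != 0
            }
            object.__setattr__(self, "coeffs", clean)

    @classmethod
    def from_poly_t(cls, coeffs_t: Mapping[int, RationalLike], label: str = "") -> "WeightFunction":
        """Polynomial in t alone: {degree: coefficient}."""
        return cls(coeffs={(0, j): _frac(c) for j, c in coeffs_t.items()}, label=label)

    @classmethod
    def from_poly_x(cls, coeffs_x: Mapping[int, RationalLike], label: str = "") -> "WeightFunction":
        """Polynomial in x alone: {degree: coefficient}."""
        return cls(coeffs={(i, 0): _frac(c) for i, c in coeffs_x.items()}, label=label)

    @property
    def is_polynomial(self) -> bool:
        return self.coeffs is not None

    @property
    def depends_on_x(self) -> bool:
        """Whether w varies with x (callables are conservatively assumed to)."""
        if self.is_polynomial:
            return any(i > 0 for (i, _) in self.coeffs)
        return True

    def t_degree(self) -> int:
        if not self.is_polynomial:
            raise ValueError("degree undefined for callable weights")
        return max((j for (_, j) in self.coeffs), default=0)

    def __call__(self, x, t):
        if self.is_polynomial:
            total = 0.0
            for (i, j), c in self.coeffs.items():
                total = total + float(c) * x**i * t**j
            return total
        return self.func(x, t)

    def eval_exact(self, x: Fraction, t: Fraction) -> Fraction:
        if not self.is_polynomial:
            raise ValueError("exact evaluation requires polynomial weights")
        return sum((c * x**i * t**j for (i, j), c in self.coeffs.items()), Fraction(0))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        if self.label:
            return f"WeightFunction({self.label})"
        if self.is_polynomial:
            return f"WeightFunction(poly {dict(self.coeffs)})"
        return "WeightFunction(callable)"


@dataclass(frozen=True)
class IntegralModel:
    """Volterra-form model: ordered (weight, operator) terms, m ≥ 2.

    The initial condition Γ(0) = 0 is implicit (it holds automatically for
    the integral operator).  ``p`` records the outcome-probability parameter
    of four-outcome models, purely as metadata: the iterates themselves are
    p-independent because the four weights sum to one.
    """

    terms: tuple[tuple[WeightFunction, ResponseOperator], ...]
    p: Fraction | None = None
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))
        if len(self.terms) < 2:
            raise ValueError("an integral model needs at least two terms")

    @property
    def operators(self) -> tuple[ResponseOperator, ...]:
        return tuple(op for _, op in self.terms)

    @property
    def weights(self) -> tuple[WeightFunction, ...]:
        return tuple(w for w, _ in self.terms)

    @property
    def is_exactly_solvable(self) -> bool:
        return all(w.is_polynomial for w in self.weights) and all(
            op.is_affine for op in self.operators
        )


@dataclass(frozen=True)
class DiscreteModel:
    """Classical two-choice learning equation f(x) = x f(g₁(x)) + (1−x) f(g₂(x)).

    Carries the boundary conditions f(0) = 0 and f(1) = 1 implicitly — the
    homogeneous fixed-point operator otherwise admits only the zero function.
    A model is *classical* when g₁(1) = 1 and g₂(0) = 0, which makes the
    states 0 and 1 absorbing for the underlying Markov process.
    """

    g1: ResponseOperator
    g2: ResponseOperator
    name: str = ""

    @property
    def is_classical(self) -> bool:
        try:
            return self.g1(Fraction(1)) == 1 and self.g2(Fraction(0)) == 0
        except TypeError:
            return abs(self.g1(1.0) - 1.0) < 1e-12 and abs(self.g2(0.0)) < 1e-12


@dataclass
class ValidationReport:
    """Outcome of model validation: ``valid`` iff ``violations`` is empty."""

    violations: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations

    def add(self, rule: str, location: str, magnitude: float) -> None:
        self.violations.append((rule, location, float(magnitude)))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        if self.valid:
            return "ValidationReport(valid)"
        return f"ValidationReport({len(self.violations)} violations)"


# callables are checked on a triangular grid; exact checks are impossible
# for black boxes, so a tolerance absorbs roundoff
_VALIDATION_GRID = 201
_VALIDATION_TOL = 1e-12


def validate_integral_model(model: IntegralModel) -> ValidationReport:
    """Check weight-sum ≡ 1 and non-negativity on 0 ≤ t ≤ x ≤ 1, and that
    every operator maps [0, 1] into [0, 1].  Violations are reported, never
    raised."""
    report = ValidationReport()

    if all(w.is_polynomial for w in model.weights):
        total: dict[tuple[int, int], Fraction] = {}
        for w in model.weights:
            for key, c in w.coeffs.items():
                total[key] = total.get(key, Fraction(0)) + c
        total = {k: c for k, c in total.items() if c != 0}
        if total != {(0, 0): Fraction(1)}:
            report.add("weight-sum", "symbolic sum != 1", 1.0)
        # non-negativity sampled exactly on a rational triangular grid
        n = 21
        for w_idx, w in enumerate(model.weights):
            worst = Fraction(0)
            for a in range(n + 1):
                x = Fraction(a, n)
                for b in range(a + 1):
                    t = Fraction(b, n)
                    v = w.eval_exact(x, t)
                    if v < worst:
                        worst = v
            if worst < 0:
                report.add("weight-negativity", f"term {w_idx}", float(-worst))
    else:
        import numpy as np

        xs = np.linspace(0.0, 1.0, _VALIDATION_GRID)
        worst_sum = 0.0
        worst_neg = [0.0] * len(model.weights)
        for x in xs:
            ts = np.linspace(0.0, x, _VALIDATION_GRID)
            s = np.zeros_like(ts)
            for w_idx, w in enumerate(model.weights):
                vals = np.asarray(w(x, ts), dtype=float)
                s = s + vals
                neg = float(-vals.min())
                if neg > worst_neg[w_idx]:
                    worst_neg[w_idx] = neg
            dev = float(np.abs(s - 1.0).max())
            if dev > worst_sum:
                worst_sum = dev
        if worst_sum > _VALIDATION_TOL:
            report.add("weight-sum", "grid max |sum-1|", worst_sum)
        for w_idx, neg in enumerate(worst_neg):
            if neg > _VALIDATION_TOL:
                report.add("weight-negativity", f"term {w_idx}", neg)

    for op_idx, op in enumerate(model.operators):
        if op.is_affine:
            lo, hi = op.image()
            if lo < 0 or hi > 1:
                report.add("operator-range", f"operator {op_idx}", float(max(-lo, hi - 1)))
        else:
            import numpy as np

            ts = np.linspace(0.0, 1.0, _VALIDATION_GRID)
            vals = np.asarray([op(float(t)) for t in ts], dtype=float)
            excess = max(float(-vals.min()), float(vals.max() - 1.0))
            if excess > _VALIDATION_TOL:
                report.add("operator-range", f"operator {op_idx}", excess)
    return report


PRESET_NAMES = (
    "example1",
    "example2",
    "pigeon",
    "four_outcome",
    "lyubich_shapiro",
    "berinde_khan",
)

_W_T = WeightFunction.from_poly_t({1: 1}, label="t")
_W_1MT = WeightFunction.from_poly_t({0: 1, 1: -1}, label="1-t")


def _four_outcome_weights(p: Fraction) -> tuple[WeightFunction, ...]:
    q = 1 - p
    return (
        WeightFunction.from_poly_t({1: p}, label="p*t"),
        WeightFunction.from_poly_t({1: q}, label="(1-p)*t"),
        WeightFunction.from_poly_t({0: p, 1: -p}, label="p*(1-t)"),
        WeightFunction.from_poly_t({0: q, 1: -q}, label="(1-p)*(1-t)"),
    )


def preset_model(name: str, params: Mapping[str, object] | None = None):
    """Construct a named preset model.

    =================  ==========================================================
    name               model
    =================  ==========================================================
    example1           integral: weights t, 1−t; ℰ₁(t)=(t+1)/4, ℰ₂(t)=(t+2)/5
    example2           integral, four outcomes, all ℰᵢ(t)=(t+1)/5; param p
    pigeon             integral: weights t, 1−t; operators from params
                       (``e1``/``e2`` as (slope, intercept); defaults = example1)
    four_outcome       integral: four-outcome weights with param p and four
                       operators from params (defaults = example2 operators)
    lyubich_shapiro    discrete: g₁(x)=(1−a₁)x+a₁, g₂(x)=(1−a₂)x; 0<a₁≤a₂<1
    berinde_khan       integral with weights x, 1−x around supplied g₁, g₂
                       (reduces to the discrete form via ``reduce_to_discrete``)
    =================  ==========================================================
    """
    params = dict(params or {})

    def pop_op(key: str, default: tuple[str, str]) -> ResponseOperator:
        value = params.pop(key, default)
        if isinstance(value, ResponseOperator):
            return value
        slope, intercept = value
        return make_affine_operator(slope, intercept)

    if name == "example1":
        e1 = make_affine_operator(Fraction(1, 4), Fraction(1, 4))
        e2 = make_affine_operator(Fraction(1, 5), Fraction(2, 5))
        model = IntegralModel(terms=((_W_T, e1), (_W_1MT, e2)), name=name)
    elif name in ("example2", "four_outcome"):
        p = _frac(params.pop("p", Fraction(1, 2)))
        if not (0 <= p <= 1):
            raise ValueError(f"p={p} outside [0, 1]")
        if name == "example2":
            ops = tuple(
                make_affine_operator(Fraction(1, 5), Fraction(1, 5)) for _ in range(4)
            )
        else:
            default = ("1/5", "1/5")
            ops = tuple(pop_op(f"e{i}", default) for i in (1, 2, 3, 4))
        model = IntegralModel(
            terms=tuple(zip(_four_outcome_weights(p), ops)), p=p, name=name
        )
    elif name == "pigeon":
        e1 = pop_op("e1", ("1/4", "1/4"))
        e2 = pop_op("e2", ("1/5", "2/5"))
        model = IntegralModel(terms=((_W_T, e1), (_W_1MT, e2)), name=name)
    elif name == "lyubich_shapiro":
        a1 = _frac(params.pop("a1", Fraction(3, 10)))
        a2 = _frac(params.pop("a2", a1))
        if not (0 < a1 <= a2 < 1):
            raise ValueError(f"lyubich_shapiro requires 0 < a1 <= a2 < 1, got {a1}, {a2}")
        g1 = make_affine_operator(1 - a1, a1)
        g2 = make_affine_operator(1 - a2, Fraction(0))
        model = DiscreteModel(g1=g1, g2=g2, name=name)
    elif name == "berinde_khan":
        g1 = pop_op("g1", ("7/10", "3/10"))
        g2 = pop_op("g2", ("2/5", "0"))
        w_x = WeightFunction.from_poly_x({1: 1}, label="x")
        w_1mx = WeightFunction.from_poly_x({0: 1, 1: -1}, label="1-x")
        model = IntegralModel(terms=((w_x, g1), (w_1mx, g2)), name=name)
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")

    if params:
        raise ValueError(f"unused parameters for preset {name!r}: {sorted(params)}")
    if isinstance(model, IntegralModel):
        report = validate_integral_model(model)
        if not report.valid:
            raise ValueError(f"preset {name!r} failed validation: {report.violations}")
    return model


def reduce_to_discrete(model: IntegralModel) -> DiscreteModel:
    """Reduce an integral model with weights x and 1 − x to the discrete form.

    Evaluating the integrand at t = x turns
    ``Γ(x) = ∫₀ˣ x Γ(ℰ₁(t)) + (1−x) Γ(ℰ₂(t)) dt`` into the classical
    ``f(x) = x f(g₁(x)) + (1−x) f(g₂(x))``; only weights of exactly that
    form (constant in t) admit the reduction.
    """
    if len(model.terms) != 2:
        raise ValueError("reduction requires exactly two terms")
    w1, w2 = model.weights
    want1 = {(1, 0): Fraction(1)}
    want2 = {(0, 0): Fraction(1), (1, 0): Fraction(-1)}
    if not (w1.is_polynomial and w2.is_polynomial):
        raise ValueError("reduction requires polynomial weights x and 1-x")
    if dict(w1.coeffs) != want1 or dict(w2.coeffs) != want2:
        raise ValueError(
            "reduction requires weights x and 1-x (constant in t); "
            f"got {w1!r}, {w2!r}"
        )
    op1, op2 = model.operators
    return DiscreteModel(g1=op1, g2=op2, name=model.name or "reduced")
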