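"""Normalized Hill functions, continuous logic gates, and the ODE right-hand side.

The model class is a *logic-based differential equation* (LDE): each species
activity y_i relaxes, with time constant tau_i, toward a target that is a
logical composition of sigmoid responses to its regulators,

    dy_i/dt = (ymax_i * F_i(y) - y_i) / tau_i,

where F_i OR-combines the activities of all reactions producing species i.
A reaction's activity is its weight times the product (continuous AND) of a
normalized Hill term per regulator; an input reaction (no regulators) has
activity equal to its weight.

The *normalized* Hill activation is the unique scaled Hill curve through the
three anchor points f(0) = 0, f(ec50) = 0.5, f(1) = 1:

    f(x) = B * x^n / (K^n + x^n),   B = (ec50^n - 1) / (2*ec50^n - 1),
                                    K^n = B - 1.

When 2*ec50^n = 1 the expression for B is singular; the constrained limit is
f(x) = x^n, which still satisfies all three anchors.  The implementation
clears the singular denominators algebraically, so the limit is taken
automatically and f is continuous in (n, ec50) everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt

from .model import NetworkModel, ReactionDef

__all__ = [
    "ActivityState",
    "CompiledNetwork",
    "apply_overrides",
    "fixed_point",
    "hill_activation",
    "hill_inhibition",
    "or_fold",
    "reaction_activity",
    "rhs",
]

SPECIES_PARAMS = ("tau", "ymax", "yinit")
REACTION_PARAMS = ("weight", "n", "ec50")


@dataclass
class ActivityState:
    """Activities of every species at one instant (model species order)."""

    t: float
    y: npt.NDArray[np.float64]


def _check_hill_params(n: float, ec50: float) -> None:
    if n <= 0:
        raise ValueError(f"Hill coefficient n must be > 0 (got {n})")
    if not 0.0 < ec50 < 1.0:
        raise ValueError(f"ec50 must be in the open interval (0, 1) (got {ec50})")


def hill_activation(x, n: float = 1.4, ec50: float = 0.5):
    """Normalized Hill activation; scalar in, scalar out (arrays broadcast).

    Monotone non-decreasing on [0, 1] with f(0)=0, f(ec50)=0.5, f(1)=1.
    Inputs above 1 are evaluated by the same closed form; the normalization
    guarantees hold only on [0, 1].
    """
    _check_hill_params(n, ec50)
    x_arr = np.asarray(x, dtype=float)
    xn = np.power(x_arr, n)
    e = ec50**n
    # Algebraically identical to B*x^n/(K^n + x^n) after eliminating B (clear
    # the 2*e - 1 denominators).  This form is exact at the anchors x=ec50 and
    # x=1 in floating point and passes continuously through the singular
    # locus 2*ec50^n = 1, where it reduces to x^n.
    result = (e - 1.0) * xn / ((2.0 * e - 1.0) * xn - e)
    if np.isscalar(x) or x_arr.ndim == 0:
        return float(result)
    return result


def hill_inhibition(x, n: float = 1.4, ec50: float = 0.5):
    """Complementary inhibition: 1 at x=0, 0.5 at ec50, 0 at x=1."""
    return 1.0 - hill_activation(x, n, ec50)


def or_fold(activities) -> float:
    """Continuous OR: fold of OR(a, b) = a + b - a*b over the inputs.

    Commutative, associative, with 0 as identity and 1 absorbing.  An empty
    fold is 0: a species with no incoming reactions has no drive and decays.
    Algebraically equal to ``1 - prod(1 - a_i)``.
    """
    acc = 0.0
    for a in activities:
        acc = acc + a - acc * a
    return acc


def reaction_activity(reaction: ReactionDef, activities) -> float:
    """Weight times the continuous-AND product of per-regulator Hill terms.

    *activities* maps species id to current activity.  The empty product is
    1, so an input reaction returns its weight.
    """
    value = reaction.weight
    for reg in reaction.regulators:
        x = activities[reg.species_id]
        term = hill_activation(x, reaction.n, reaction.ec50)
        if reg.is_inhibitor:
            term = 1.0 - term
        value *= term
    return value


# ---------------------------------------------------------------------------
# Parameter overrides and network compilation
# ---------------------------------------------------------------------------

def apply_overrides(model: NetworkModel, overrides: dict[str, float] | None) -> NetworkModel:
    """Return a deep-enough copy of *model* with overrides applied.

    Keys are ``"<target>.<param>"`` where target is a species id (params
    tau, ymax, yinit) or a reaction id (weight, n, ec50).  Unknown targets
    or parameters raise ``KeyError``.
    """
    species = {s.id: s for s in model.species}
    reactions = {r.id: r for r in model.reactions}
    new_species = {sid: [s.tau, s.ymax, s.yinit] for sid, s in species.items()}
    new_reactions = {rid: [r.weight, r.n, r.ec50] for rid, r in reactions.items()}
    for key, value in (overrides or {}).items():
        target, _, param = key.partition(".")
        if not param:
            raise KeyError(f"override {key!r} is not of the form target.param")
        param = param.lower()
        if target in species:
            if param not in SPECIES_PARAMS:
                raise KeyError(
                    f"{key!r}: species parameter must be one of {SPECIES_PARAMS}"
                )
            new_species[target][SPECIES_PARAMS.index(param)] = float(value)
        elif target in reactions:
            if param not in REACTION_PARAMS:
                raise KeyError(
                    f"{key!r}: reaction parameter must be one of {REACTION_PARAMS}"
                )
            new_reactions[target][REACTION_PARAMS.index(param)] = float(value)
        else:
            raise KeyError(f"override target {target!r} is not a species or reaction id")

    from dataclasses import replace

    out_species = [
        replace(s, tau=new_species[s.id][0], ymax=new_species[s.id][1], yinit=new_species[s.id][2])
        for s in model.species
    ]
    out_reactions = [
        replace(
            r,
            weight=new_reactions[r.id][0],
            n=new_reactions[r.id][1],
            ec50=new_reactions[r.id][2],
            regulators=list(r.regulators),
        )
        for r in model.reactions
    ]
    return NetworkModel(out_species, out_reactions, dict(model.metadata))


class CompiledNetwork:
    """Index-based form of a model for fast repeated RHS evaluation."""

    def __init__(self, model: NetworkModel, overrides: dict[str, float] | None = None):
        effective = apply_overrides(model, overrides)
        self.species_ids = effective.species_ids()
        index = effective.species_index()
        self.tau = np.array([s.tau for s in effective.species], dtype=float)
        self.ymax = np.array([s.ymax for s in effective.species], dtype=float)
        self.yinit = np.array([s.yinit for s in effective.species], dtype=float)
        # per reaction: (product index, weight, n, ec50, [(reg index, inhibitor?)...])
        self.reactions = [
            (
                index[r.product],
                r.weight,
                r.n,
                r.ec50,
                [(index[reg.species_id], reg.is_inhibitor) for reg in r.regulators],
            )
            for r in effective.reactions
        ]
        self.n_species = len(self.species_ids)

    def drive(self, y: npt.NDArray[np.float64]) -> npt.NDArray[np.float64]:
        """F_i(y): OR-combined reaction activities per species."""
        per_species: list[list[float]] = [[] for _ in range(self.n_species)]
        for prod, weight, n, ec50, regs in self.reactions:
            act = weight
            for idx, inhib in regs:
                term = hill_activation(max(y[idx], 0.0), n, ec50)
                act *= (1.0 - term) if inhib else term
            per_species[prod].append(act)
        return np.array([or_fold(acts) for acts in per_species])

    def rhs(self, t: float, y: npt.NDArray[np.float64]) -> npt.NDArray[np.float64]:
        return (self.ymax * self.drive(y) - y) / self.tau


def rhs(
    model: NetworkModel,
    state: ActivityState,
    overrides: dict[str, float] | None = None,
) -> npt.NDArray[np.float64]:
    """Time derivative dy/dt = (ymax * F(y) - y) / tau at *state*."""
    return CompiledNetwork(model, overrides).rhs(state.t, np.asarray(state.y, dtype=float))


def fixed_point(
    model: NetworkModel,
    overrides: dict[str, float] | None = None,
    damping: float = 0.5,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> tuple[npt.NDArray[np.float64], bool]:
    """Damped iteration of the steady-state map y <- ymax * F(y).

    Returns ``(y, converged)``.  This is an integration-free route to the
    same fixed points the ODE settles into and serves as an independent
    cross-check for long-time integration.
    """
    net = CompiledNetwork(model, overrides)
    y = net.yinit.astype(float).copy()
    for _ in range(max_iter):
        target = net.ymax * net.drive(y)
        new = (1.0 - damping) * y + damping * target
        if np.max(np.abs(new - y)) < tol:
            return new, True
        y = new
    return y, False
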