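"""Domain types for logic-based network models.

A model is a list of *species* (network nodes with a continuous activity in
[0, ymax]) and a list of *reactions* (directed influence rules mapping zero
or more signed regulators onto one product species).  These are plain
in-memory dataclasses; file I/O lives in :mod:`hillnet.model_io` and the
mathematics in :mod:`hillnet.dynamics`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any, Iterator, Literal

__all__ = [
    "DEFAULTS",
    "Defaults",
    "Diagnostic",
    "NetworkModel",
    "ReactionDef",
    "Regulator",
    "SpeciesDef",
    "is_valid_token",
    "validate_model",
]

# Tokens appear inside rule strings, so they must not collide with the rule
# grammar ("=>" separator, "&" conjunction, "!" negation) or contain blanks.
_TOKEN_RE = re.compile(r"[^\s&!=>|]+")

SIGN_ACTIVATOR: Literal["activator"] = "activator"
SIGN_INHIBITOR: Literal["inhibitor"] = "inhibitor"


def is_valid_token(token: str) -> bool:
    """True if *token* is usable as a species/reaction id in rule strings."""
    return bool(token) and _TOKEN_RE.fullmatch(token) is not None


@dataclass(frozen=True)
class Defaults:
    """Default parameter values applied where a model table leaves a cell blank.

    ``weight`` deliberately has no default: it encodes the on/off state of
    stimuli, so a blank weight cell is a validation error rather than a
    silent assumption.
    """

    tau: float = 1.0
    yinit: float = 0.0
    ymax: float = 1.0
    n: float = 1.4
    ec50: float = 0.5


DEFAULTS = Defaults()


@dataclass
class SpeciesDef:
    """One network node.

    Parameters
    ----------
    id:
        Short unique token (valid in the rule grammar).
    name:
        Free-text label.
    yinit:
        Initial activity (dimensionless, normally in ``[0, ymax]``).
    ymax:
        Maximal attainable activity.  ``ymax = 0`` is legal and encodes a
        gene knockout.
    tau:
        Time constant governing how fast the species relaxes toward its
        driven target activity (arbitrary time units, > 0).
    """

    id: str
    name: str = ""
    yinit: float = DEFAULTS.yinit
    ymax: float = DEFAULTS.ymax
    tau: float = DEFAULTS.tau


@dataclass(frozen=True)
class Regulator:
    """A signed reference from a reaction to one of its source species."""

    species_id: str
    sign: str  # "activator" | "inhibitor"

    @property
    def is_inhibitor(self) -> bool:
        return self.sign == SIGN_INHIBITOR


@dataclass
class ReactionDef:
    """One directed influence rule.

    An empty ``regulators`` list makes this an *input reaction*: an
    environmental stimulus whose activity equals its weight.  A single
    ``(n, ec50)`` pair applies to every regulator of the reaction.
    """

    id: str
    regulators: list[Regulator]
    product: str
    weight: float
    module: str = ""
    n: float = DEFAULTS.n
    ec50: float = DEFAULTS.ec50

    @property
    def is_input(self) -> bool:
        return not self.regulators


@dataclass
class NetworkModel:
    """A validated collection of species and reactions.

    ``metadata`` carries pass-through annotations (citation columns etc.)
    keyed by table kind, e.g. ``metadata["species_columns"]["ref"]["A"]``.
    """

    species: list[SpeciesDef] = field(default_factory=list)
    reactions: list[ReactionDef] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)

    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def species_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    def get_species(self, species_id: str) -> SpeciesDef:
        for s in self.species:
            if s.id == species_id:
                return s
        raise KeyError(species_id)

    def get_reaction(self, reaction_id: str) -> ReactionDef:
        for r in self.reactions:
            if r.id == reaction_id:
                return r
        raise KeyError(reaction_id)

    def reactions_by_product(self) -> dict[str, list[ReactionDef]]:
        out: dict[str, list[ReactionDef]] = {s.id: [] for s in self.species}
        for r in self.reactions:
            out.setdefault(r.product, []).append(r)
        return out


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding.  ``level`` is ``"error"`` or ``"warning"``."""

    level: str
    element: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - formatting only
        return f"{self.level}: {self.element}: {self.message}"


def _iter_diagnostics(model: NetworkModel) -> Iterator[Diagnostic]:
    seen_species: set[str] = set()
    for s in model.species:
        if not is_valid_token(s.id):
            yield Diagnostic("error", f"species {s.id!r}", "id is not a valid token")
        if s.id in seen_species:
            yield Diagnostic("error", f"species {s.id!r}", "duplicate species id")
        seen_species.add(s.id)
        if s.tau <= 0:
            yield Diagnostic("error", f"species {s.id!r}", f"tau must be > 0 (got {s.tau})")
        if s.ymax < 0:
            yield Diagnostic("error", f"species {s.id!r}", f"ymax must be >= 0 (got {s.ymax})")
        if s.yinit < 0:
            yield Diagnostic("error", f"species {s.id!r}", f"yinit must be >= 0 (got {s.yinit})")
        elif s.yinit > s.ymax:
            # Legal (the knockout protocol creates it transiently) but worth
            # flagging: the species will decay toward the reachable range.
            yield Diagnostic(
                "warning",
                f"species {s.id!r}",
                f"yinit ({s.yinit}) exceeds ymax ({s.ymax}); activity will decay",
            )

    declared = {s.id for s in model.species}
    seen_reactions: set[str] = set()
    for r in model.reactions:
        tag = f"reaction {r.id!r}"
        if not is_valid_token(r.id):
            yield Diagnostic("error", tag, "id is not a valid token")
        if r.id in seen_reactions:
            yield Diagnostic("error", tag, "duplicate reaction id")
        seen_reactions.add(r.id)
        if r.product not in declared:
            yield Diagnostic("error", tag, f"product {r.product!r} is not a declared species")
        for reg in r.regulators:
            if reg.species_id not in declared:
                yield Diagnostic(
                    "error", tag, f"regulator {reg.species_id!r} is not a declared species"
                )
            if reg.sign not in (SIGN_ACTIVATOR, SIGN_INHIBITOR):
                yield Diagnostic("error", tag, f"unknown regulator sign {reg.sign!r}")
        if r.weight is None:
            yield Diagnostic("error", tag, "weight is missing (no default exists)")
        elif not 0.0 <= r.weight <= 1.0:
            yield Diagnostic("error", tag, f"weight must be in [0, 1] (got {r.weight})")
        if r.n <= 0:
            yield Diagnostic("error", tag, f"Hill coefficient n must be > 0 (got {r.n})")
        if not 0.0 < r.ec50 < 1.0:
            yield Diagnostic("error", tag, f"ec50 must be in (0, 1) (got {r.ec50})")


def validate_model(model: NetworkModel) -> list[Diagnostic]:
    """Check all structural invariants; returns diagnostics, never raises.

    An empty list means the model is fully valid.  Warning-level diagnostics
    flag legal-but-odd configurations (currently: ``yinit > ymax``); a model
    whose only diagnostics are warnings is still simulatable.  The model is
    never mutated.
    """
    return list(_iter_diagnostics(model))


def validation_errors(model: NetworkModel) -> list[Diagnostic]:
    """Error-level diagnostics only (warnings do not block simulation)."""
    return [d for d in validate_model(model) if d.level == "error"]
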