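"""Built-in network models and scenario scripts.

Two small models ship with the package, fully specified in code (and as CSV
table pairs under ``hillnet/data/``):

* **ExampleNet** — five generic species A–E with two switchable stimulus
  inputs, a coherent cascade, an incoherent AND gate (``C & !D => E``) and a
  positive feedback loop (``E => C``).  Good for demonstrating stimulation /
  washout dynamics and latching.
* **CardiacDevNet** — a five-transcription-factor gene-regulatory circuit of
  early heart development (GATA6, NKX2-5, TBX1, ISL1, PITX2).  ISL1 starts
  high (yinit = 1) because it is constitutively expressed until NKX2-5
  represses it; knocking out NKX2-5 (ymax = 0) de-represses ISL1.

A seeded random-model generator supports property testing, and
:class:`ScenarioScript` packages the canonical stimulation/washout and
knockout protocols together with their expected qualitative outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .model import NetworkModel, ReactionDef, Regulator, SpeciesDef
from .simulation import ProtocolStep, Trajectory, run_protocol

__all__ = [
    "SCENARIOS",
    "OutcomeCheck",
    "ScenarioScript",
    "build_cardiacdevnet",
    "build_examplenet",
    "data_dir",
    "random_model",
]


def data_dir() -> Path:
    """Directory holding the fixture models as CSV table pairs."""
    return Path(__file__).parent / "data"


def build_examplenet() -> NetworkModel:
    """Five species A–E, six reactions, two switchable inputs (off by default)."""
    species = [SpeciesDef(id=s, name=f"Species {s}") for s in "ABCDE"]
    reactions = [
        ReactionDef("r1", [], "A", weight=0.0),
        ReactionDef("r2", [], "B", weight=0.0),
        ReactionDef("r3", [Regulator("A", "activator")], "C", weight=1.0),
        ReactionDef("r4", [Regulator("B", "activator")], "D", weight=1.0),
        ReactionDef(
            "r5",
            [Regulator("C", "activator"), Regulator("D", "inhibitor")],
            "E",
            weight=1.0,
        ),
        ReactionDef("r6", [Regulator("E", "activator")], "C", weight=1.0),
    ]
    return NetworkModel(species, reactions)


def build_cardiacdevnet() -> NetworkModel:
    """Cardiac-development gene regulatory circuit; ISL1 starts fully on."""
    species = [
        SpeciesDef("GATA6", "GATA6"),
        SpeciesDef("NKX25", "NKX2-5"),
        SpeciesDef("TBX1", "TBX1"),
        SpeciesDef("ISL1", "ISL1", yinit=1.0),
        SpeciesDef("PITX2", "PITX2"),
    ]
    act = lambda s: [Regulator(s, "activator")]  # noqa: E731
    reactions = [
        ReactionDef("r1", [], "GATA6", weight=0.0),
        ReactionDef("r2", act("GATA6"), "NKX25", weight=1.0),
        ReactionDef("r3", act("GATA6"), "TBX1", weight=1.0),
        ReactionDef("r4", act("NKX25"), "TBX1", weight=1.0),
        ReactionDef("r5", act("TBX1"), "PITX2", weight=1.0),
        ReactionDef("r6", act("NKX25"), "PITX2", weight=1.0),
        ReactionDef("r7", [Regulator("NKX25", "inhibitor")], "ISL1", weight=1.0),
    ]
    return NetworkModel(species, reactions)


def random_model(n_species: int, edge_density: float, seed: int) -> NetworkModel:
    """Reproducible random model for property tests.

    Each species gets an input reaction with probability *edge_density*
    (weight drawn from {0, 1}); each ordered species pair gets a one-regulator
    reaction with the same probability (activator with probability 0.8).
    tau ~ U[0.1, 10], ec50 ~ U[0.2, 0.8], n ~ U[1, 4], yinit ~ U[0, ymax=1].
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if not 0.0 <= edge_density <= 1.0:
        raise ValueError("edge_density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    species = [
        SpeciesDef(
            id=f"S{i + 1}",
            name=f"Species {i + 1}",
            yinit=float(rng.uniform(0.0, 1.0)),
            ymax=1.0,
            tau=float(rng.uniform(0.1, 10.0)),
        )
        for i in range(n_species)
    ]
    reactions: list[ReactionDef] = []
    counter = 0
    for s in species:
        if rng.uniform() < edge_density:
            counter += 1
            reactions.append(
                ReactionDef(
                    f"r{counter}",
                    [],
                    s.id,
                    weight=float(rng.integers(0, 2)),
                    n=float(rng.uniform(1.0, 4.0)),
                    ec50=float(rng.uniform(0.2, 0.8)),
                )
            )
    for src in species:
        for dst in species:
            if rng.uniform() < edge_density:
                counter += 1
                sign = "activator" if rng.uniform() < 0.8 else "inhibitor"
                reactions.append(
                    ReactionDef(
                        f"r{counter}",
                        [Regulator(src.id, sign)],
                        dst.id,
                        weight=float(rng.integers(0, 2)),
                        n=float(rng.uniform(1.0, 4.0)),
                        ec50=float(rng.uniform(0.2, 0.8)),
                    )
                )
    return NetworkModel(species, reactions)


# ---------------------------------------------------------------------------
# Scenario scripts: canonical protocols plus expected qualitative outcomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeCheck:
    """One qualitative expectation evaluated against a trajectory.

    ``kind``:
      * ``at_end_ge`` / ``at_end_le`` — activity at time ``at`` (defaults to
        the final time) compared against ``threshold``.
      * ``max_le`` — maximum over the whole trajectory.
      * ``increasing`` / ``decreasing`` — monotone (within ``slack``) over
        the final segment.
    """

    species: str
    kind: str
    threshold: float = 0.0
    at: float | None = None
    slack: float = 1e-6

    def evaluate(self, traj: Trajectory) -> tuple[bool, float]:
        col = traj.column(self.species)
        if self.kind in ("at_end_ge", "at_end_le"):
            value = (
                float(traj.at_time(self.at)[self.species])
                if self.at is not None
                else float(col[-1])
            )
            ok = value >= self.threshold if self.kind == "at_end_ge" else value <= self.threshold
            return ok, value
        if self.kind == "max_le":
            value = float(np.max(col))
            return value <= self.threshold, value
        if self.kind in ("increasing", "decreasing"):
            start = traj.segment_marks[-1] if traj.segment_marks else traj.times[0]
            tail = col[traj.times >= start]
            diffs = np.diff(tail)
            ok = bool(
                np.all(diffs >= -self.slack)
                if self.kind == "increasing"
                else np.all(diffs <= self.slack)
            )
            return ok, float(tail[-1])
        raise ValueError(f"unknown outcome kind {self.kind!r}")

    def describe(self) -> str:
        if self.kind in ("at_end_ge", "at_end_le"):
            op = ">=" if self.kind == "at_end_ge" else "<="
            when = f"at t={self.at}" if self.at is not None else "at end"
            return f"{self.species} {when} {op} {self.threshold}"
        if self.kind == "max_le":
            return f"max {self.species} <= {self.threshold}"
        return f"{self.species} {self.kind} over final segment"


@dataclass(frozen=True)
class ScenarioScript:
    """A named protocol on a built-in model, with expected outcomes."""

    name: str
    build: Callable[[], NetworkModel]
    steps: tuple[ProtocolStep, ...]
    checks: tuple[OutcomeCheck, ...] = field(default_factory=tuple)

    def run(self) -> Trajectory:
        return run_protocol(self.build(), list(self.steps))

    def report(self, traj: Trajectory) -> list[tuple[str, bool, float]]:
        return [(c.describe(), *c.evaluate(traj)) for c in self.checks]


def _examplenet_stim() -> ScenarioScript:
    # Six ten-unit segments: quiescent; +A; washout A; +B; washout B; +A and +B.
    steps = (
        ProtocolStep(10.0, {}),
        ProtocolStep(10.0, {"r1.weight": 1.0}),
        ProtocolStep(10.0, {"r1.weight": 0.0}),
        ProtocolStep(10.0, {"r2.weight": 1.0}),
        ProtocolStep(10.0, {"r2.weight": 0.0}),
        ProtocolStep(10.0, {"r1.weight": 1.0, "r2.weight": 1.0}),
    )
    # "reaches activity 1" is asserted at two-decimal resolution (>= 0.995):
    # E trails the A->C->E cascade and sits ~1.3e-3 below 1 at t=20.
    checks = (
        OutcomeCheck("A", "at_end_ge", 0.995, at=20.0),
        OutcomeCheck("C", "at_end_ge", 0.995, at=20.0),
        OutcomeCheck("E", "at_end_ge", 0.995, at=20.0),
        OutcomeCheck("B", "at_end_le", 1e-6, at=20.0),
        OutcomeCheck("D", "at_end_le", 1e-6, at=20.0),
        # stimulation with B drives D up and the D-inhibited AND gate shuts E
        OutcomeCheck("D", "at_end_ge", 0.999, at=40.0),
        OutcomeCheck("E", "at_end_le", 0.1, at=40.0),
    )
    return ScenarioScript("examplenet-stim", build_examplenet, steps, checks)


def _cardiacdev_baseline() -> ScenarioScript:
    steps = (
        ProtocolStep(2.0, {}),
        ProtocolStep(8.0, {"r1.weight": 1.0}),
    )
    checks = (
        OutcomeCheck("NKX25", "at_end_ge", 0.9),
        OutcomeCheck("TBX1", "at_end_ge", 0.9),
        OutcomeCheck("PITX2", "at_end_ge", 0.9),
        OutcomeCheck("ISL1", "at_end_le", 0.1),
        OutcomeCheck("NKX25", "increasing"),
        OutcomeCheck("TBX1", "increasing"),
        OutcomeCheck("PITX2", "increasing"),
        OutcomeCheck("ISL1", "decreasing"),
    )
    return ScenarioScript("cardiacdev-baseline", build_cardiacdevnet, steps, checks)


def _cardiacdev_ko() -> ScenarioScript:
    steps = (
        ProtocolStep(2.0, {"NKX25.ymax": 0.0}),
        ProtocolStep(8.0, {"r1.weight": 1.0}),
    )
    checks = (
        OutcomeCheck("NKX25", "max_le", 0.0),
        OutcomeCheck("ISL1", "at_end_ge", 0.99),  # de-repressed: stays on
    )
    return ScenarioScript("cardiacdev-ko", build_cardiacdevnet, steps, checks)


SCENARIOS: dict[str, ScenarioScript] = {
    s.name: s for s in (_examplenet_stim(), _cardiacdev_baseline(), _cardiacdev_ko())
}
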