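"""Reading and writing network-model tables, rule parsing, and edge export.

Two on-disk dialects are supported:

* ``workbook`` — one ``.xlsx`` file with a ``species`` sheet
  (``ID, name, Yinit, Ymax, tau``) and a ``reactions`` sheet
  (``module, ID, Rule, Weight, n, EC50``); sheet and column names are
  matched case-insensitively and unrecognized columns (citations, notes)
  ride along in ``NetworkModel.metadata``.
* ``csv`` — a directory holding ``species.csv`` and ``reactions.csv`` with
  the same headers.

Reaction rules use a small grammar: ``"A & !B => C"`` means A activates and
B inhibits product C; ``"=> C"`` is an input reaction (an environmental
stimulus).  OR logic is expressed structurally, by several reactions sharing
a product — never inside one rule string.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from .model import (
    DEFAULTS,
    NetworkModel,
    ReactionDef,
    Regulator,
    SpeciesDef,
    is_valid_token,
    validation_errors,
)

__all__ = [
    "EdgeRecord",
    "ModelIOError",
    "RuleParseError",
    "export_edges",
    "load_model",
    "parse_rule",
    "render_rule",
    "write_model",
]

Dialect = Literal["workbook", "csv"]

SPECIES_COLUMNS = ["ID", "name", "Yinit", "Ymax", "tau"]
REACTION_COLUMNS = ["module", "ID", "Rule", "Weight", "n", "EC50"]


class RuleParseError(ValueError):
    """A reaction rule string does not match the grammar."""


class ModelIOError(ValueError):
    """A model file is unreadable, structurally wrong, or fails validation."""


# ---------------------------------------------------------------------------
# Rule grammar
# ---------------------------------------------------------------------------

def parse_rule(text: str) -> tuple[list[Regulator], str]:
    """Parse ``"[!]R1 [& [!]R2 ...] => P"`` into (regulators, product).

    A single leading apostrophe is stripped (spreadsheet text-guard: a quote
    typed before ``=`` so the cell is not read as a formula), as is
    surrounding whitespace.  Regulator order is preserved.
    """
    raw = text.strip()
    if raw.startswith("'"):
        raw = raw[1:].strip()
    if not raw:
        raise RuleParseError("empty rule")
    if "|" in raw:
        raise RuleParseError(
            f"{text!r}: '|' is not part of the rule grammar; OR logic is expressed "
            "by separate reactions sharing a product"
        )
    if raw.count("=>") != 1:
        raise RuleParseError(f"{text!r}: a rule must contain exactly one '=>'")
    lhs, rhs = raw.split("=>")
    product = rhs.strip()
    if not product:
        raise RuleParseError(f"{text!r}: missing product after '=>'")
    if not is_valid_token(product):
        raise RuleParseError(f"{text!r}: product {product!r} is not a single valid token")

    regulators: list[Regulator] = []
    lhs = lhs.strip()
    if lhs:
        for fragment in lhs.split("&"):
            token = fragment.strip()
            if not token:
                raise RuleParseError(f"{text!r}: empty regulator between '&'s")
            sign = "activator"
            if token.startswith("!"):
                sign = "inhibitor"
                token = token[1:].strip()
                if not token:
                    raise RuleParseError(f"{text!r}: '!' with no regulator token")
            if not is_valid_token(token):
                raise RuleParseError(f"{text!r}: {token!r} is not a valid regulator token")
            regulators.append(Regulator(token, sign))
    return regulators, product


def render_rule(regulators: Iterable[Regulator], product: str) -> str:
    """Canonical rule string; inverse of :func:`parse_rule` on its output."""
    lhs = " & ".join(
        ("!" if reg.is_inhibitor else "") + reg.species_id for reg in regulators
    )
    return f"{lhs} => {product}" if lhs else f"=> {product}"


# ---------------------------------------------------------------------------
# Table loading
# ---------------------------------------------------------------------------

def _is_blank(value: object) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and not value.strip()


def _norm(header: object) -> str:
    return str(header).strip().lower()


def _find_frame(frames: dict[str, pd.DataFrame], wanted: str, where: str) -> pd.DataFrame:
    for key, frame in frames.items():
        if _norm(key) == wanted:
            return frame
    raise ModelIOError(f"{where}: no {wanted!r} table found (have: {sorted(frames)})")


def _column_map(frame: pd.DataFrame, known: list[str]) -> tuple[dict[str, str], list[str]]:
    """Map normalized known header -> actual header; remaining headers are extras."""
    known_norm = {_norm(k): k for k in known}
    mapping: dict[str, str] = {}
    extras: list[str] = []
    for col in frame.columns:
        norm = _norm(col)
        if norm in known_norm:
            mapping[known_norm[norm]] = col
        elif not norm.startswith("unnamed:"):
            extras.append(col)
    return mapping, extras


def _cell(row: pd.Series, colmap: dict[str, str], key: str) -> object:
    actual = colmap.get(key)
    return row[actual] if actual is not None else None


def _float_cell(
    row: pd.Series, colmap: dict[str, str], key: str, default: float | None, where: str
) -> float:
    value = _cell(row, colmap, key)
    if _is_blank(value):
        if default is None:
            raise ModelIOError(f"{where}: {key} is blank and has no default")
        return default
    try:
        return float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError) as exc:
        raise ModelIOError(f"{where}: {key} value {value!r} is not a number") from exc


def _parse_species(frame: pd.DataFrame, sheet: str) -> tuple[list[SpeciesDef], dict]:
    colmap, extras = _column_map(frame, SPECIES_COLUMNS)
    if "ID" not in colmap:
        raise ModelIOError(f"sheet {sheet!r}: required column 'ID' not found")
    species: list[SpeciesDef] = []
    extra_values: dict[str, dict[str, object]] = {c: {} for c in extras}
    for pos, (_, row) in enumerate(frame.iterrows()):
        where = f"sheet {sheet!r}, row {pos + 2}"  # +2: 1-based plus header row
        sid = _cell(row, colmap, "ID")
        if _is_blank(sid):
            continue  # spreadsheets routinely carry trailing blank rows
        sid = str(sid).strip()
        name = _cell(row, colmap, "name")
        species.append(
            SpeciesDef(
                id=sid,
                name="" if _is_blank(name) else str(name).strip(),
                yinit=_float_cell(row, colmap, "Yinit", DEFAULTS.yinit, where),
                ymax=_float_cell(row, colmap, "Ymax", DEFAULTS.ymax, where),
                tau=_float_cell(row, colmap, "tau", DEFAULTS.tau, where),
            )
        )
        for col in extras:
            if not _is_blank(row[col]):
                extra_values[col][sid] = row[col]
    if not species:
        raise ModelIOError(f"sheet {sheet!r} declares no species")
    return species, {c: v for c, v in extra_values.items() if v}


def _parse_reactions(frame: pd.DataFrame, sheet: str) -> tuple[list[ReactionDef], dict]:
    colmap, extras = _column_map(frame, REACTION_COLUMNS)
    for required in ("ID", "Rule"):
        if required not in colmap:
            raise ModelIOError(f"sheet {sheet!r}: required column {required!r} not found")
    reactions: list[ReactionDef] = []
    extra_values: dict[str, dict[str, object]] = {c: {} for c in extras}
    for pos, (_, row) in enumerate(frame.iterrows()):
        where = f"sheet {sheet!r}, row {pos + 2}"
        rid = _cell(row, colmap, "ID")
        rule = _cell(row, colmap, "Rule")
        if _is_blank(rid) and _is_blank(rule):
            continue
        if _is_blank(rid):
            raise ModelIOError(f"{where}: reaction has a Rule but no ID")
        rid = str(rid).strip()
        if _is_blank(rule):
            raise ModelIOError(f"{where}: reaction {rid!r} has no Rule")
        try:
            regulators, product = parse_rule(str(rule))
        except RuleParseError as exc:
            raise ModelIOError(f"{where}: {exc}") from exc
        module = _cell(row, colmap, "module")
        reactions.append(
            ReactionDef(
                id=rid,
                regulators=regulators,
                product=product,
                module="" if _is_blank(module) else str(module).strip(),
                weight=_float_cell(row, colmap, "Weight", None, where),
                n=_float_cell(row, colmap, "n", DEFAULTS.n, where),
                ec50=_float_cell(row, colmap, "EC50", DEFAULTS.ec50, where),
            )
        )
        for col in extras:
            if not _is_blank(row[col]):
                extra_values[col][rid] = row[col]
    return reactions, {c: v for c, v in extra_values.items() if v}


def _infer_dialect(path: Path) -> Dialect:
    if path.is_dir():
        return "csv"
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        return "workbook"
    raise ModelIOError(
        f"{path}: cannot infer dialect (expected a .xlsx workbook or a directory "
        "with species.csv/reactions.csv); pass dialect= explicitly"
    )


def load_model(path: str | Path, dialect: Dialect | None = None) -> NetworkModel:
    """Load and validate a model from *path*.

    Blank parameter cells are filled from :data:`hillnet.model.DEFAULTS`
    except ``Weight``, which must be explicit.  Raises :class:`ModelIOError`
    with sheet/row coordinates on any structural or validation failure.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = _infer_dialect(path)

    if dialect == "workbook":
        try:
            frames = pd.read_excel(path, sheet_name=None)
        except Exception as exc:
            raise ModelIOError(f"{path}: unreadable workbook ({exc})") from exc
        species_frame = _find_frame(frames, "species", str(path))
        reaction_frame = _find_frame(frames, "reactions", str(path))
    elif dialect == "csv":
        frames = {}
        for stem in ("species", "reactions"):
            csv_path = path / f"{stem}.csv"
            if not csv_path.exists():
                raise ModelIOError(f"{path}: missing {stem}.csv")
            frames[stem] = pd.read_csv(csv_path)
        species_frame, reaction_frame = frames["species"], frames["reactions"]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    species, species_extras = _parse_species(species_frame, "species")
    reactions, reaction_extras = _parse_reactions(reaction_frame, "reactions")
    metadata: dict = {}
    if species_extras:
        metadata["species_columns"] = species_extras
    if reaction_extras:
        metadata["reactions_columns"] = reaction_extras
    model = NetworkModel(species=species, reactions=reactions, metadata=metadata)

    errors = validation_errors(model)
    if errors:
        listing = "; ".join(str(d) for d in errors)
        raise ModelIOError(f"{path}: model failed validation: {listing}")
    return model


# ---------------------------------------------------------------------------
# Table writing
# ---------------------------------------------------------------------------

def _species_frame(model: NetworkModel) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "ID": [s.id for s in model.species],
            "name": [s.name for s in model.species],
            "Yinit": [s.yinit for s in model.species],
            "Ymax": [s.ymax for s in model.species],
            "tau": [s.tau for s in model.species],
        }
    )
    for col, values in model.metadata.get("species_columns", {}).items():
        frame[col] = [values.get(s.id) for s in model.species]
    return frame


def _guarded_rule(reaction: ReactionDef) -> str:
    # input-reaction rules start with "=", which spreadsheet tools read as a
    # formula; the conventional leading apostrophe keeps the cell as text and
    # parse_rule strips it on the way back in
    text = render_rule(reaction.regulators, reaction.product)
    return "'" + text if text.startswith("=") else text


def _reactions_frame(model: NetworkModel) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "module": [r.module for r in model.reactions],
            "ID": [r.id for r in model.reactions],
            "Rule": [_guarded_rule(r) for r in model.reactions],
            "Weight": [r.weight for r in model.reactions],
            "n": [r.n for r in model.reactions],
            "EC50": [r.ec50 for r in model.reactions],
        }
    )
    for col, values in model.metadata.get("reactions_columns", {}).items():
        frame[col] = [values.get(r.id) for r in model.reactions]
    return frame


def write_model(model: NetworkModel, path: str | Path, dialect: Dialect | None = None) -> None:
    """Write *model* so that :func:`load_model` reads back an equal model."""
    path = Path(path)
    if dialect is None:
        dialect = "workbook" if path.suffix.lower() in (".xlsx", ".xlsm") else "csv"
    species, reactions = _species_frame(model), _reactions_frame(model)
    if dialect == "workbook":
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            species.to_excel(writer, sheet_name="species", index=False)
            reactions.to_excel(writer, sheet_name="reactions", index=False)
    elif dialect == "csv":
        path.mkdir(parents=True, exist_ok=True)
        species.to_csv(path / "species.csv", index=False)
        reactions.to_csv(path / "reactions.csv", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Edge export (Cytoscape-compatible)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeRecord:
    """One edge of the interaction graph, with reaction provenance."""

    source: str
    interaction: str  # "activates" | "inhibits" | "input"
    target: str
    reaction_id: str


def iter_edges(model: NetworkModel) -> Iterable[EdgeRecord]:
    """One edge per (reaction, regulator) pair, in deterministic model order.

    Input reactions emit a pseudo-source node ``INPUT_<product>`` so stimuli
    remain visible in graph tools.
    """
    for r in model.reactions:
        if r.is_input:
            yield EdgeRecord(f"INPUT_{r.product}", "input", r.product, r.id)
        else:
            for reg in r.regulators:
                kind = "inhibits" if reg.is_inhibitor else "activates"
                yield EdgeRecord(reg.species_id, kind, r.product, r.id)


def export_edges(model: NetworkModel, format: str = "sif") -> str:
    """Render the edge table as SIF (``source<TAB>interaction<TAB>target``)
    or as TSV with a header and a reaction-id provenance column."""
    edges = list(iter_edges(model))
    if format == "sif":
        lines = [f"{e.source}\t{e.interaction}\t{e.target}" for e in edges]
    elif format == "tsv":
        lines = ["source\tinteraction\ttarget\treaction_id"]
        lines += [f"{e.source}\t{e.interaction}\t{e.target}\t{e.reaction_id}" for e in edges]
    else:
        raise ValueError(f"unknown edge format {format!r}")
    return "\n".join(lines) + "\n"
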