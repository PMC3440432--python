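"""Reaction-network representation of the coagulation model.

The network (extrinsic cascade plus a protein C pathway module) is data, not
code: it is parsed from three plain-text TSV tables (species, reactions, rate
constants) shipped with the package under :mod:`thrombogen.data`.  Every
reversible row is expanded into an explicit association/dissociation pair of
irreversible mass-action reactions, and the transcription is validated for
referential integrity, molecularity/unit consistency and conservation of the
elementary protein moieties.

Concentrations are nanomolar throughout; bimolecular rate constants are stored
as ``per_nanomolar_per_second``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "ModelError",
    "SpeciesDef",
    "RateConstant",
    "ReactionDef",
    "ModelDefinition",
    "ConservationReport",
    "load_model",
    "load_default_model",
    "serialize_model",
    "stoichiometry_matrix",
    "check_conservation",
    "select_submodel",
]

BASE_EXTRINSIC = "base_extrinsic"
PC_PATHWAY = "pc_pathway"
SUBMODELS = (BASE_EXTRINSIC, PC_PATHWAY)

PER_SECOND = "per_second"
PER_NANOMOLAR_PER_SECOND = "per_nanomolar_per_second"
RATE_UNITS = (PER_SECOND, PER_NANOMOLAR_PER_SECOND)


class ModelError(ValueError):
    """Raised when a model transcription fails validation."""


@dataclass(frozen=True)
class SpeciesDef:
    """A chemical species: elementary protein, active enzyme, complex or fragment."""

    symbol: str
    display_name: str
    moieties: tuple[tuple[str, int], ...]
    submodel: str

    def moiety_map(self) -> dict[str, int]:
        return dict(self.moieties)

    def __post_init__(self) -> None:
        if self.submodel not in SUBMODELS:
            raise ModelError(f"species {self.symbol!r}: unknown submodel {self.submodel!r}")
        counts = dict(self.moieties)
        if any(c < 0 for c in counts.values()):
            raise ModelError(f"species {self.symbol!r}: negative moiety count")
        if not any(counts.values()):
            raise ModelError(f"species {self.symbol!r}: moiety map is all zero")


@dataclass(frozen=True)
class RateConstant:
    id: str
    value: float
    units: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ModelError(f"rate constant {self.id!r}: value must be > 0")
        if self.units not in RATE_UNITS:
            raise ModelError(f"rate constant {self.id!r}: unknown units {self.units!r}")


@dataclass(frozen=True)
class ReactionDef:
    """One irreversible mass-action reaction."""

    id: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_constant_id: str
    submodel: str
    reversible_pair_id: str | None = None

    @property
    def order(self) -> int:
        return sum(c for _, c in self.reactants)

    def __post_init__(self) -> None:
        if self.order > 2:
            raise ModelError(f"reaction {self.id!r}: more than 2 reactant molecules")
        if self.order < 0 or not self.reactants:
            raise ModelError(f"reaction {self.id!r}: no reactants")


@dataclass(frozen=True)
class ConservationReport:
    """Result of the moiety-conservation audit."""

    moieties: tuple[str, ...]
    violations: tuple[tuple[str, str], ...]  # (moiety, reaction id)

    @property
    def ok(self) -> bool:
        return not self.violations


@dataclass(frozen=True)
class ModelDefinition:
    name: str
    version: str
    species: tuple[SpeciesDef, ...]
    reactions: tuple[ReactionDef, ...]
    rate_constants: Mapping[str, RateConstant]

    @property
    def species_symbols(self) -> tuple[str, ...]:
        return tuple(s.symbol for s in self.species)

    def species_index(self) -> dict[str, int]:
        return {s.symbol: i for i, s in enumerate(self.species)}

    def moiety_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.species:
            for m, _ in s.moieties:
                seen.setdefault(m)
        return tuple(seen)

    def moiety_matrix(self) -> np.ndarray:
        """Moiety x species integer count matrix."""
        moieties = self.moiety_names()
        mi = {m: i for i, m in enumerate(moieties)}
        out = np.zeros((len(moieties), len(self.species)), dtype=int)
        for j, s in enumerate(self.species):
            for m, c in s.moieties:
                out[mi[m], j] = c
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModelDefinition):
            return NotImplemented
        return (
            self.name == other.name
            and self.version == other.version
            and self.species == other.species
            and self.reactions == other.reactions
            and dict(self.rate_constants) == dict(other.rate_constants)
        )


# ---------------------------------------------------------------------------
# parsing

_COEF_TOKEN = re.compile(r"^(?:(\d+)\s+)?(\S.*)$")


def _parse_side(expr: str, rid: str) -> tuple[tuple[str, int], ...]:
    terms: list[tuple[str, int]] = []
    for raw in expr.split("+"):
        token = raw.strip()
        if not token:
            raise ModelError(f"reaction {rid!r}: empty species token in {expr!r}")
        m = _COEF_TOKEN.match(token)
        assert m is not None
        coef = int(m.group(1)) if m.group(1) else 1
        terms.append((m.group(2), coef))
    # merge duplicate symbols (e.g. "A + A" == "2 A")
    merged: dict[str, int] = {}
    for sym, c in terms:
        merged[sym] = merged.get(sym, 0) + c
    return tuple(merged.items())


def _read_tsv(path: Path | str, expected_cols: Iterable[str]) -> list[dict[str, str]]:
    expected = list(expected_cols)
    rows: list[dict[str, str]] = []
    header: list[str] | None = None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            missing = [c for c in expected if c not in header]
            if missing:
                raise ModelError(f"{path}: missing columns {missing}")
            continue
        fields += [""] * (len(header) - len(fields))
        rows.append(dict(zip(header, (f.strip() for f in fields))))
    if header is None:
        raise ModelError(f"{path}: empty table")
    return rows


def _parse_moieties(text: str, symbol: str) -> tuple[tuple[str, int], ...]:
    out: list[tuple[str, int]] = []
    for item in text.split(";"):
        item = item.strip()
        if not item:
            continue
        try:
            name, count = item.split(":")
            out.append((name.strip(), int(count)))
        except ValueError as exc:
            raise ModelError(f"species {symbol!r}: bad moiety entry {item!r}") from exc
    return tuple(out)


def load_model(
    reaction_table_path: Path | str,
    rate_table_path: Path | str,
    species_table_path: Path | str | None = None,
    *,
    name: str = "tf_thrombin_pc",
    version: str = "1.0",
) -> ModelDefinition:
    """Parse and validate the three-table plain-text model transcription.

    ``species_table_path`` defaults to ``species.tsv`` next to the reaction
    table.  Reversible rows (arrow ``<->``) are expanded into a forward
    (association) reaction carrying ``k_fwd_id`` and a reverse (dissociation)
    reaction carrying ``k_rev_id``, linked by a shared ``reversible_pair_id``.
    """
    reaction_table_path = Path(reaction_table_path)
    if species_table_path is None:
        species_table_path = reaction_table_path.with_name("species.tsv")

    species: list[SpeciesDef] = []
    seen_symbols: set[str] = set()
    for row in _read_tsv(species_table_path, ("symbol", "display_name", "moieties", "submodel")):
        sym = row["symbol"]
        if sym in seen_symbols:
            raise ModelError(f"duplicate species symbol {sym!r}")
        seen_symbols.add(sym)
        species.append(
            SpeciesDef(sym, row["display_name"], _parse_moieties(row["moieties"], sym), row["submodel"])
        )
    by_symbol = {s.symbol: s for s in species}

    # complex symbols whose "="-separated components all resolve must carry
    # exactly the component-sum moiety map
    for s in species:
        parts = s.symbol.split("=")
        if len(parts) > 1 and all(p in by_symbol for p in parts):
            expected: dict[str, int] = {}
            for p in parts:
                for m, c in by_symbol[p].moieties:
                    expected[m] = expected.get(m, 0) + c
            if expected != s.moiety_map():
                raise ModelError(
                    f"species {s.symbol!r}: moiety map {s.moiety_map()} != component sum {expected}"
                )

    rate_constants: dict[str, RateConstant] = {}
    for row in _read_tsv(rate_table_path, ("k_id", "value", "units", "source_note")):
        kid = row["k_id"]
        if kid in rate_constants:
            raise ModelError(f"duplicate rate constant id {kid!r}")
        rate_constants[kid] = RateConstant(kid, float(row["value"]), row["units"], row["source_note"])

    reactions: list[ReactionDef] = []
    seen_rids: set[str] = set()
    for row in _read_tsv(
        reaction_table_path,
        ("reaction_id", "lhs", "arrow", "rhs", "k_fwd_id", "k_rev_id", "submodel"),
    ):
        rid = row["reaction_id"]
        if rid in seen_rids:
            raise ModelError(f"duplicate reaction id {rid!r}")
        seen_rids.add(rid)
        if row["arrow"] not in ("->", "<->"):
            raise ModelError(f"reaction {rid!r}: bad arrow {row['arrow']!r}")
        lhs = _parse_side(row["lhs"], rid)
        rhs = _parse_side(row["rhs"], rid)
        submodel = row["submodel"]
        if submodel not in SUBMODELS:
            raise ModelError(f"reaction {rid!r}: unknown submodel {submodel!r}")
        if row["arrow"] == "<->":
            if not row["k_rev_id"]:
                raise ModelError(f"reaction {rid!r}: reversible row missing k_rev_id")
            reactions.append(ReactionDef(rid + ":f", lhs, rhs, row["k_fwd_id"], submodel, rid))
            reactions.append(ReactionDef(rid + ":r", rhs, lhs, row["k_rev_id"], submodel, rid))
        else:
            if row["k_rev_id"]:
                raise ModelError(f"reaction {rid!r}: irreversible row has k_rev_id")
            reactions.append(ReactionDef(rid, lhs, rhs, row["k_fwd_id"], submodel, None))

    model = ModelDefinition(name, version, tuple(species), tuple(reactions), rate_constants)
    _validate(model)
    return model


def _validate(model: ModelDefinition) -> None:
    by_symbol = {s.symbol: s for s in model.species}
    for rxn in model.reactions:
        for sym, _ in rxn.reactants + rxn.products:
            if sym not in by_symbol:
                raise ModelError(f"reaction {rxn.id!r}: unresolved species symbol {sym!r}")
        k = model.rate_constants.get(rxn.rate_constant_id)
        if k is None:
            raise ModelError(f"reaction {rxn.id!r}: unknown rate constant {rxn.rate_constant_id!r}")
        expected_units = PER_SECOND if rxn.order == 1 else PER_NANOMOLAR_PER_SECOND
        if k.units != expected_units:
            raise ModelError(
                f"reaction {rxn.id!r}: order {rxn.order} requires {expected_units}, "
                f"but {k.id!r} has {k.units}"
            )
        balance: dict[str, int] = {}
        for side, sign in ((rxn.reactants, -1), (rxn.products, +1)):
            for sym, coef in side:
                for m, c in by_symbol[sym].moieties:
                    balance[m] = balance.get(m, 0) + sign * coef * c
        bad = {m: v for m, v in balance.items() if v != 0}
        if bad:
            raise ModelError(f"reaction {rxn.id!r}: moiety conservation violated: {bad}")


def load_default_model() -> ModelDefinition:
    """Load the transcription shipped with the package."""
    root = resources.files("thrombogen") / "data"
    return load_model(
        Path(str(root / "reactions.tsv")),
        Path(str(root / "rates.tsv")),
        Path(str(root / "species.tsv")),
    )


# ---------------------------------------------------------------------------
# serialization (round-trip support)


def _format_side(terms: tuple[tuple[str, int], ...]) -> str:
    return " + ".join(sym if c == 1 else f"{c} {sym}" for sym, c in terms)


def serialize_model(model: ModelDefinition, out_dir: Path | str) -> dict[str, Path]:
    """Write species/reactions/rates TSVs; ``load_model`` on them reproduces the model."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "species": out / "species.tsv",
        "reactions": out / "reactions.tsv",
        "rates": out / "rates.tsv",
    }
    lines = ["symbol\tdisplay_name\tmoieties\tsubmodel"]
    for s in model.species:
        moieties = ";".join(f"{m}:{c}" for m, c in s.moieties)
        lines.append(f"{s.symbol}\t{s.display_name}\t{moieties}\t{s.submodel}")
    paths["species"].write_text("\n".join(lines) + "\n")

    lines = ["k_id\tvalue\tunits\tsource_note"]
    for k in model.rate_constants.values():
        lines.append(f"{k.id}\t{k.value!r}\t{k.units}\t{k.note}")
    paths["rates"].write_text("\n".join(lines) + "\n")

    lines = ["reaction_id\tlhs\tarrow\trhs\tk_fwd_id\tk_rev_id\tsubmodel"]
    skip: set[str] = set()
    for rxn in model.reactions:
        if rxn.id in skip:
            continue
        if rxn.reversible_pair_id is not None:
            pair = next(
                r
                for r in model.reactions
                if r.reversible_pair_id == rxn.reversible_pair_id and r.id != rxn.id
            )
            skip.add(pair.id)
            lines.append(
                f"{rxn.reversible_pair_id}\t{_format_side(rxn.reactants)}\t<->\t"
                f"{_format_side(rxn.products)}\t{rxn.rate_constant_id}\t{pair.rate_constant_id}\t{rxn.submodel}"
            )
        else:
            lines.append(
                f"{rxn.id}\t{_format_side(rxn.reactants)}\t->\t"
                f"{_format_side(rxn.products)}\t{rxn.rate_constant_id}\t\t{rxn.submodel}"
            )
    paths["reactions"].write_text("\n".join(lines) + "\n")
    return paths


# ---------------------------------------------------------------------------
# derived structure


def stoichiometry_matrix(model: ModelDefinition) -> np.ndarray:
    """Species x reactions integer matrix of net stoichiometric changes."""
    idx = model.species_index()
    N = np.zeros((len(model.species), len(model.reactions)), dtype=int)
    for j, rxn in enumerate(model.reactions):
        for sym, coef in rxn.reactants:
            N[idx[sym], j] -= coef
        for sym, coef in rxn.products:
            N[idx[sym], j] += coef
    return N


def check_conservation(model: ModelDefinition) -> ConservationReport:
    """Verify every moiety count vector lies in the left null space of N."""
    N = stoichiometry_matrix(model)
    M = model.moiety_matrix()
    prod = M @ N  # moieties x reactions
    moieties = model.moiety_names()
    violations = [
        (moieties[i], model.reactions[j].id)
        for i, j in zip(*np.nonzero(prod))
    ]
    return ConservationReport(moieties, tuple(violations))


def select_submodel(model: ModelDefinition, include_pc: bool) -> ModelDefinition:
    """Return the model with or without the protein C pathway module.

    ``include_pc=True`` is the identity.  ``include_pc=False`` drops all
    ``pc_pathway`` reactions plus every species that appears only in them,
    and prunes rate constants no longer cited.
    """
    if include_pc:
        return model
    reactions = tuple(r for r in model.reactions if r.submodel != PC_PATHWAY)
    used = {sym for r in reactions for sym, _ in r.reactants + r.products}
    species = tuple(s for s in model.species if s.submodel == BASE_EXTRINSIC)
    kept_symbols = {s.symbol for s in species}
    dangling = used - kept_symbols
    if dangling:
        raise ModelError(f"submodel tagging error: base reactions reference {sorted(dangling)}")
    kept_k = {r.rate_constant_id for r in reactions}
    rate_constants = {kid: k for kid, k in model.rate_constants.items() if kid in kept_k}
    sub = ModelDefinition(model.name, model.version, species, reactions, rate_constants)
    _validate(sub)
    return sub
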