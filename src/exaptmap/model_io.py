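"""Reaction universe, metabolic genotypes, and growth environments.

The central object is a :class:`ReactionUniverse`: a fixed, ordered set of
candidate *internal* reactions together with always-present transport and
exchange reactions and a biomass reaction.  A metabolic genotype is a
presence/absence bit vector over the internal reactions, in the order fixed
by the universe; bit *i* of a :class:`Genotype` corresponds to the *i*-th
internal reaction.

The bundled model is the central carbon metabolism of *E. coli*: 51 internal
reactions (glycolysis/gluconeogenesis, pentose-phosphate pathway, TCA cycle,
anaplerosis, glyoxylate shunt, oxidative phosphorylation and a handful of
fermentative reactions), 20 transport reactions assumed present in every
genotype, and a biomass reaction that drains 13 well-known biomass
precursors.  It derives from the published *E. coli* core reconstruction
with the four ethanol-metabolism reactions removed and the two aconitase
half-reactions merged into a single cit <-> icit conversion.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

__all__ = [
    "Metabolite",
    "Reaction",
    "ReactionUniverse",
    "Genotype",
    "Environment",
    "ModelFormatError",
    "ValidationError",
    "load_universe",
    "save_universe",
    "load_environments",
    "load_bundled_model",
    "make_genotype",
    "full_genotype",
    "empty_genotype",
    "genotype_from_bits",
    "save_genotypes",
    "load_genotypes",
]

REACTION_KINDS = ("internal", "transport", "exchange", "biomass")


class ModelFormatError(ValueError):
    """Raised when a model file cannot be parsed or violates the format."""


class ValidationError(ValueError):
    """Raised when a parsed model violates a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    external: bool = False
    is_biomass_precursor: bool = False
    carbon_atoms: int = 0


@dataclass(frozen=True)
class Reaction:
    """A (pseudo-)reaction with signed stoichiometry.

    ``lower_bound``/``upper_bound`` are the flux bounds *when the reaction is
    present*; an absent reaction is constrained to zero flux.  ``reversible``
    is equivalent to ``lower_bound < 0``.
    """

    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float
    upper_bound: float
    kind: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in REACTION_KINDS:
            raise ValidationError(f"reaction {self.id}: unknown kind {self.kind!r}")
        if not self.stoichiometry:
            raise ValidationError(f"reaction {self.id}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ValidationError(f"reaction {self.id}: lower bound exceeds upper bound")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def substrates(self) -> Tuple[str, ...]:
        return tuple(m for m, c in self.stoichiometry.items() if c < 0)

    def products(self) -> Tuple[str, ...]:
        return tuple(m for m, c in self.stoichiometry.items() if c > 0)


@dataclass(frozen=True)
class Environment:
    """A minimal aerobic growth environment with a sole carbon source.

    ``uptake_bounds`` maps external metabolite ids to maximal uptake fluxes;
    every external metabolite not listed can only be excreted.
    """

    name: str
    carbon_source: str
    fixed_nutrients: Tuple[str, ...]
    uptake_bounds: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.carbon_source not in self.uptake_bounds:
            raise ValidationError(
                f"environment {self.name}: carbon source {self.carbon_source} has no uptake bound"
            )


class ReactionUniverse:
    """Ordered reaction universe; internal-reaction order fixes genotype bits."""

    def __init__(
        self,
        internal_reactions: Sequence[Reaction],
        transport_reactions: Sequence[Reaction],
        exchange_reactions: Sequence[Reaction],
        biomass_reaction: Reaction,
        metabolites: Sequence[Metabolite],
    ) -> None:
        self.internal_reactions = list(internal_reactions)
        self.transport_reactions = list(transport_reactions)
        self.exchange_reactions = list(exchange_reactions)
        self.biomass_reaction = biomass_reaction
        self.metabolites = list(metabolites)
        self._validate()
        self.metabolite_index: Dict[str, Metabolite] = {m.id: m for m in self.metabolites}
        self.internal_index: Dict[str, int] = {
            r.id: i for i, r in enumerate(self.internal_reactions)
        }
        # exchange reaction per external metabolite (unique by validation)
        self.exchange_by_metabolite: Dict[str, Reaction] = {
            next(iter(r.stoichiometry)): r for r in self.exchange_reactions
        }

    # -- invariants ---------------------------------------------------------
    def _validate(self) -> None:
        ids = [r.id for r in self.all_reactions()]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ModelFormatError(f"duplicate reaction ids: {dupes}")
        mids = [m.id for m in self.metabolites]
        if len(set(mids)) != len(mids):
            raise ModelFormatError("duplicate metabolite ids")
        known = set(mids)
        for r in self.all_reactions():
            missing = set(r.stoichiometry) - known
            if missing:
                raise ValidationError(
                    f"reaction {r.id} references unknown metabolites {sorted(missing)}"
                )
        # internal reactions must not move carbon across the boundary; they
        # may touch extracellular protons (proton-translocating reactions of
        # oxidative phosphorylation are internal, not transport)
        met_by_id = {m.id: m for m in self.metabolites}
        for r in self.internal_reactions:
            for mid in r.stoichiometry:
                m = met_by_id[mid]
                if m.external and m.carbon_atoms > 0:
                    raise ValidationError(
                        f"internal reaction {r.id} moves carbon across the boundary"
                    )
        for r in self.exchange_reactions:
            if len(r.stoichiometry) != 1:
                raise ValidationError(f"exchange reaction {r.id} must involve one metabolite")
        for m in self.metabolites:
            if m.is_biomass_precursor and m.external:
                raise ValidationError(f"biomass precursor {m.id} must be intracellular")

    # -- views --------------------------------------------------------------
    @property
    def n_internal(self) -> int:
        return len(self.internal_reactions)

    @property
    def internal_ids(self) -> List[str]:
        return [r.id for r in self.internal_reactions]

    def all_reactions(self) -> List[Reaction]:
        return (
            self.internal_reactions
            + self.transport_reactions
            + self.exchange_reactions
            + [self.biomass_reaction]
        )

    @property
    def biomass_precursors(self) -> List[str]:
        return [m.id for m in self.metabolites if m.is_biomass_precursor]

    def reaction(self, rid: str) -> Reaction:
        for r in self.all_reactions():
            if r.id == rid:
                return r
        raise KeyError(rid)

    def content_hash(self) -> str:
        """Stable hash of the model content, for cache invalidation."""
        blob = json.dumps(_universe_to_dict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ReactionUniverse(N={self.n_internal}, "
            f"transport={len(self.transport_reactions)}, "
            f"exchange={len(self.exchange_reactions)}, "
            f"metabolites={len(self.metabolites)})"
        )


@dataclass(frozen=True)
class Genotype:
    """Presence/absence bit vector over the internal reactions of a universe.

    ``bits`` is an integer bit mask; bit *i* set means internal reaction *i*
    is present.  ``n`` is the universe size the mask refers to.
    """

    bits: int
    n: int

    def __post_init__(self) -> None:
        if self.bits < 0 or self.bits >> self.n:
            raise ValidationError("genotype bits exceed universe size")

    @property
    def size(self) -> int:
        return self.bits.bit_count()

    def reaction_ids(self, universe: ReactionUniverse) -> List[str]:
        if universe.n_internal != self.n:
            raise ValidationError("genotype length does not match universe")
        return [universe.internal_ids[i] for i in range(self.n) if (self.bits >> i) & 1]

    def contains(self, other: "Genotype") -> bool:
        return (self.bits | other.bits) == self.bits

    def bitstring(self) -> str:
        """'0'/'1' string; character *i* is internal reaction *i*."""
        return format(self.bits, f"0{self.n}b")[::-1]

    def __iter__(self):
        return (i for i in range(self.n) if (self.bits >> i) & 1)


def make_genotype(universe: ReactionUniverse, reaction_ids: Iterable[str]) -> Genotype:
    """Genotype with exactly the given internal reactions present.

    Transport, exchange and biomass reactions are not genotype-encoded;
    passing one of their ids is an error.
    """
    bits = 0
    for rid in reaction_ids:
        idx = universe.internal_index.get(rid)
        if idx is None:
            if any(r.id == rid for r in universe.all_reactions()):
                raise ValidationError(f"{rid} is not an internal reaction")
            raise KeyError(f"unknown reaction id {rid!r}")
        bits |= 1 << idx
    return Genotype(bits, universe.n_internal)


def full_genotype(universe: ReactionUniverse) -> Genotype:
    return Genotype((1 << universe.n_internal) - 1, universe.n_internal)


def empty_genotype(universe: ReactionUniverse) -> Genotype:
    return Genotype(0, universe.n_internal)


def genotype_from_bits(bits: int, universe: ReactionUniverse) -> Genotype:
    return Genotype(bits, universe.n_internal)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _parse_stoichiometry(text: str) -> Dict[str, float]:
    out: Dict[str, float] = {}
    for part in text.split(";"):
        if not part:
            continue
        try:
            met, coef = part.rsplit(":", 1)
            out[met] = float(coef)
        except ValueError as exc:
            raise ModelFormatError(f"bad stoichiometry entry {part!r}") from exc
    return out


def _format_stoichiometry(st: Mapping[str, float]) -> str:
    return ";".join(f"{m}:{c:g}" for m, c in sorted(st.items()))


def _universe_to_dict(u: ReactionUniverse) -> dict:
    return {
        "reactions": [
            {
                "id": r.id,
                "kind": r.kind,
                "stoichiometry": dict(sorted(r.stoichiometry.items())),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "name": r.name,
            }
            for r in u.all_reactions()
        ],
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "external": m.external,
                "biomass_precursor": m.is_biomass_precursor,
                "carbon_atoms": m.carbon_atoms,
            }
            for m in u.metabolites
        ],
    }


def _universe_from_records(reactions: List[dict], metabolites: List[dict]) -> ReactionUniverse:
    mets = [
        Metabolite(
            id=m["id"],
            name=m.get("name", ""),
            external=bool(int(m["external"])),
            is_biomass_precursor=bool(int(m["biomass_precursor"])),
            carbon_atoms=int(m.get("carbon_atoms", 0)),
        )
        for m in metabolites
    ]
    groups: Dict[str, List[Reaction]] = {k: [] for k in REACTION_KINDS}
    for r in reactions:
        st = r["stoichiometry"]
        if isinstance(st, str):
            st = _parse_stoichiometry(st)
        rx = Reaction(
            id=r["id"],
            stoichiometry=st,
            lower_bound=float(r["lower_bound"]),
            upper_bound=float(r["upper_bound"]),
            kind=r["kind"],
            name=r.get("name", ""),
        )
        groups[rx.kind].append(rx)
    if len(groups["biomass"]) != 1:
        raise ValidationError("model must define exactly one biomass reaction")
    return ReactionUniverse(
        internal_reactions=groups["internal"],
        transport_reactions=groups["transport"],
        exchange_reactions=groups["exchange"],
        biomass_reaction=groups["biomass"][0],
        metabolites=mets,
    )


def _read_tsv(path: Path) -> List[dict]:
    rows: List[dict] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            vals = line.rstrip("\n").split("\t")
            if len(vals) != len(header):
                raise ModelFormatError(f"{path}: ragged row {vals!r}")
            rows.append(dict(zip(header, vals)))
    return rows


def load_universe(path: str | Path, format: Optional[str] = None) -> ReactionUniverse:
    """Load a reaction universe from TSV (directory or reactions file), JSON or SBML.

    For the TSV format, ``path`` may be either the directory containing
    ``reactions.tsv`` and ``metabolites.tsv`` or the reactions file itself
    (with the metabolites file next to it).
    """
    path = Path(path)
    if format is None:
        if path.is_dir() or path.suffix == ".tsv":
            format = "tsv"
        elif path.suffix == ".json":
            format = "json"
        elif path.suffix in (".xml", ".sbml"):
            format = "sbml"
        else:
            raise ModelFormatError(f"cannot infer model format from {path}")
    if format == "tsv":
        rdir = path if path.is_dir() else path.parent
        rfile = rdir / "reactions.tsv" if path.is_dir() else path
        mfile = rdir / "metabolites.tsv"
        return _universe_from_records(_read_tsv(rfile), _read_tsv(mfile))
    if format == "json":
        with open(path) as fh:
            data = json.load(fh)
        for m in data["metabolites"]:
            m["external"] = int(m["external"])
            m["biomass_precursor"] = int(m["biomass_precursor"])
        return _universe_from_records(data["reactions"], data["metabolites"])
    if format == "sbml":
        return _universe_from_sbml(path)
    raise ModelFormatError(f"unsupported format {format!r}")


def save_universe(universe: ReactionUniverse, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        path.mkdir(parents=True, exist_ok=True)
        with open(path / "reactions.tsv", "w") as fh:
            fh.write("id\tkind\tstoichiometry\tlower_bound\tupper_bound\tname\n")
            for r in universe.all_reactions():
                fh.write(
                    f"{r.id}\t{r.kind}\t{_format_stoichiometry(r.stoichiometry)}"
                    f"\t{r.lower_bound:g}\t{r.upper_bound:g}\t{r.name}\n"
                )
        with open(path / "metabolites.tsv", "w") as fh:
            fh.write("id\tname\texternal\tbiomass_precursor\tcarbon_atoms\n")
            for m in universe.metabolites:
                fh.write(
                    f"{m.id}\t{m.name}\t{int(m.external)}"
                    f"\t{int(m.is_biomass_precursor)}\t{m.carbon_atoms}\n"
                )
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(_universe_to_dict(universe), fh, indent=1)
    else:
        raise ModelFormatError(f"unsupported format {format!r}")


def _universe_from_sbml(path: Path) -> ReactionUniverse:
    """Optional SBML import through cobrapy; transport/exchange classified
    by compartment spanning and the conventional ``EX_`` prefix."""
    try:
        import cobra.io
    except ImportError as exc:  # pragma: no cover - cobra is an optional extra
        raise ModelFormatError("SBML import requires the 'cobra' package") from exc
    model = cobra.io.read_sbml_model(str(path))
    reactions = []
    for r in model.reactions:
        if r.id.startswith("EX_"):
            kind = "exchange"
        elif "biomass" in r.id.lower():
            kind = "biomass"
        elif len({met.compartment for met in r.metabolites}) > 1:
            kind = "transport"
        else:
            kind = "internal"
        reactions.append(
            {
                "id": r.id,
                "kind": kind,
                "stoichiometry": {met.id: c for met, c in r.metabolites.items()},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "name": r.name or "",
            }
        )
    mets = [
        {
            "id": m.id,
            "name": m.name or "",
            "external": int(m.compartment == "e"),
            "biomass_precursor": 0,
            "carbon_atoms": m.elements.get("C", 0) if m.formula else 0,
        }
        for m in model.metabolites
    ]
    return _universe_from_records(reactions, mets)


# ---------------------------------------------------------------------------
# environments
# ---------------------------------------------------------------------------

def load_environments(path: str | Path) -> Dict[str, Environment]:
    """Load environments from JSON; returned dict follows the canonical
    (alphabetical) carbon-source order used for phenotype vectors."""
    with open(path) as fh:
        data = json.load(fh)
    nutrient_bound = float(data.get("nutrient_bound", 1000.0))
    carbon_bound = float(data.get("carbon_uptake_bound", 10.0))
    fixed = tuple(data["fixed_nutrients"])
    envs: Dict[str, Environment] = {}
    for name in sorted(data["sources"]):
        met = data["sources"][name]
        uptake = {m: nutrient_bound for m in fixed}
        uptake[met] = carbon_bound
        envs[name] = Environment(
            name=name, carbon_source=met, fixed_nutrients=fixed, uptake_bounds=uptake
        )
    return envs


def load_bundled_model() -> Tuple[ReactionUniverse, Dict[str, Environment]]:
    """The bundled 51-reaction central carbon metabolism model and its ten
    minimal aerobic environments."""
    data = resources.files("exaptmap") / "data"
    with resources.as_file(data) as p:
        universe = load_universe(p)
        envs = load_environments(p / "environments.json")
    if universe.n_internal != 51:
        raise ValidationError(f"bundled model must have 51 internal reactions, got {universe.n_internal}")
    if len(universe.transport_reactions) != 20:
        raise ValidationError("bundled model must have 20 transport reactions")
    if len(universe.biomass_precursors) != 13:
        raise ValidationError("bundled model must have 13 biomass precursors")
    if len(envs) != 10:
        raise ValidationError("bundled model must define ten carbon sources")
    return universe, envs


# ---------------------------------------------------------------------------
# genotype sets
# ---------------------------------------------------------------------------

def _open_maybe_gzip(path: Path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def save_genotypes(
    genotypes: Iterable[Genotype],
    path: str | Path,
    universe: Optional[ReactionUniverse] = None,
    as_ids: bool = False,
) -> None:
    """One genotype per line, as a bitstring or as comma-separated reaction ids."""
    path = Path(path)
    with _open_maybe_gzip(path, "w") as fh:
        for g in genotypes:
            if as_ids:
                if universe is None:
                    raise ValueError("as_ids=True requires the universe")
                fh.write(",".join(g.reaction_ids(universe)) + "\n")
            else:
                fh.write(g.bitstring() + "\n")


def load_genotypes(path: str | Path, universe: ReactionUniverse) -> List[Genotype]:
    path = Path(path)
    out: List[Genotype] = []
    with _open_maybe_gzip(path, "r") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if set(line) <= {"0", "1"}:
                if len(line) != universe.n_internal:
                    raise ModelFormatError("bitstring length does not match universe")
                out.append(Genotype(int(line[::-1], 2), universe.n_internal))
            else:
                out.append(make_genotype(universe, line.split(",")))
    return out
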