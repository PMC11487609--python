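"""Read, write and generate genome-scale metabolic models (GSMMs).

Supports the SBML Level 3 + FBC v2 subset emitted by automated
reconstruction tools: species with compartments and boundary flags,
reactions with stoichiometry, flux bounds, and a linear objective.
Everything else in SBML (events, rules, kinetic laws) is ignored with a
logged warning.

The module also ships deterministic toy-model and random-model generators
so that the whole pipeline is testable without any model downloads.
"""

from __future__ import annotations

import io
import logging
import re
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import libsbml
import numpy as np

from .errors import ArchiveLayoutError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Default flux bounds (mmol/gDW/h) used when a file omits them.
DEFAULT_LOWER_BOUND = -1000.0
DEFAULT_UPPER_BOUND = 1000.0

#: Single-letter compartment codes recognised by the default id
#: normalization rule (BiGG-style suffixes such as ``_c`` / ``_e``).
DEFAULT_COMPARTMENT_CODES = frozenset(
    ["c", "e", "p", "m", "x", "h", "v", "g", "n", "r", "u", "l", "i", "f", "s", "w", "y"]
)

#: Maximum number of models the reference platform accepts; exceeding it
#: here only triggers a warning (the cap is a platform policy, not a
#: method constraint).
PLATFORM_MODEL_LIMIT = 300


def normalize_metabolite_id(full_id: str, rule: str = "strip") -> str:
    """Return the base id of a metabolite.

    rule="strip" (default): remove a trailing single-token compartment
    suffix after the last underscore when it is a known compartment code
    (``glc__D_e`` -> ``glc__D``). rule="identity": return the id as-is.
    Unrecognised suffixes fall back to identity.
    """
    if not full_id:
        raise ValidationError("empty metabolite id")
    if rule == "identity":
        return full_id
    if rule != "strip":
        raise ValidationError(f"unknown normalization rule {rule!r}")
    base, sep, suffix = full_id.rpartition("_")
    if sep and base and suffix in DEFAULT_COMPARTMENT_CODES:
        return base
    return full_id


def _compartment_of(full_id: str) -> str:
    base, sep, suffix = full_id.rpartition("_")
    if sep and base and suffix in DEFAULT_COMPARTMENT_CODES:
        return suffix
    return ""


@dataclass(frozen=True)
class Metabolite:
    """A model species. ``base_id`` is the id with its compartment suffix
    stripped under the default normalization rule."""

    full_id: str
    name: str = ""
    boundary: bool = False

    def __post_init__(self) -> None:
        if not self.full_id:
            raise ValidationError("metabolite with empty id")

    @property
    def base_id(self) -> str:
        return normalize_metabolite_id(self.full_id)

    @property
    def compartment(self) -> str:
        return _compartment_of(self.full_id)


@dataclass
class Reaction:
    """A stoichiometric reaction. Negative coefficients are substrates,
    positive are products; zero coefficients are never stored."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_UPPER_BOUND
    name: str = ""
    objective_coefficient: float = 0.0

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("reaction with empty id")
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        self.stoichiometry = {
            m: float(c) for m, c in self.stoichiometry.items() if c != 0
        }

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 and self.upper_bound > 0

    @property
    def is_exchange(self) -> bool:
        """Single-metabolite stoichiometry: crosses the system boundary."""
        return len(self.stoichiometry) == 1

    def substrates(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c < 0]

    def products(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c > 0]


_MODEL_ID_RE = re.compile(r"^\S+$")


@dataclass
class GSMM:
    """A genome-scale metabolic model: metabolites plus bounded reactions
    with an optional linear objective."""

    model_id: str
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.model_id or not _MODEL_ID_RE.match(self.model_id):
            raise ValidationError(
                f"model_id {self.model_id!r} must be non-empty without whitespace"
            )
        for rid, rxn in self.reactions.items():
            if rid != rxn.id:
                raise ValidationError(f"reaction key {rid} != reaction id {rxn.id}")
            for met in rxn.stoichiometry:
                if met not in self.metabolites:
                    raise ValidationError(
                        f"reaction {rid} references unknown metabolite {met}"
                    )

    @property
    def objective_reactions(self) -> dict[str, float]:
        return {
            rid: r.objective_coefficient
            for rid, r in self.reactions.items()
            if r.objective_coefficient != 0
        }

    def internal_metabolites(self) -> list[str]:
        """Full ids of species not flagged as boundary, in model order."""
        return [m for m, sp in self.metabolites.items() if not sp.boundary]

    def metabolite_names(self, rule: str = "strip") -> dict[str, str]:
        """base_id -> first non-empty species name (model order)."""
        out: dict[str, str] = {}
        for sp in self.metabolites.values():
            key = normalize_metabolite_id(sp.full_id, rule)
            if sp.name and not out.get(key):
                out[key] = sp.name
        return out


# ---------------------------------------------------------------------------
# SBML reading / writing
# ---------------------------------------------------------------------------

_SBML_MET_PREFIX = "M_"
_SBML_RXN_PREFIX = "R_"


def _strip_prefix(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _doc_has_fatal_errors(doc: libsbml.SBMLDocument) -> bool:
    for i in range(doc.getNumErrors()):
        if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            return True
    return False


def _parse_document(doc: libsbml.SBMLDocument, model_id: str, source: str) -> GSMM:
    if _doc_has_fatal_errors(doc) or doc.getModel() is None:
        raise FormatError(f"cannot parse SBML from {source}")
    sbml_model = doc.getModel()

    if sbml_model.getNumRules() or sbml_model.getNumEvents():
        logger.warning(
            "%s: SBML rules/events present and ignored (FBC subset only)", source
        )

    metabolites: dict[str, Metabolite] = {}
    for sp in sbml_model.getListOfSpecies():
        full_id = _strip_prefix(sp.getId(), _SBML_MET_PREFIX)
        metabolites[full_id] = Metabolite(
            full_id=full_id,
            name=sp.getName() or "",
            boundary=bool(sp.getBoundaryCondition()),
        )

    fbc_model = sbml_model.getPlugin("fbc")
    objective_coefs: dict[str, float] = {}
    if fbc_model is not None:
        active = fbc_model.getActiveObjective()
        if active is None and fbc_model.getNumObjectives() > 0:
            active = fbc_model.getObjective(0)
        if active is not None:
            for fo in active.getListOfFluxObjectives():
                rid = _strip_prefix(fo.getReaction(), _SBML_RXN_PREFIX)
                objective_coefs[rid] = fo.getCoefficient()

    def _param_value(pid: str) -> float | None:
        if not pid:
            return None
        par = sbml_model.getParameter(pid)
        return par.getValue() if par is not None else None

    reactions: dict[str, Reaction] = {}
    for rxn in sbml_model.getListOfReactions():
        rid = _strip_prefix(rxn.getId(), _SBML_RXN_PREFIX)
        stoich: dict[str, float] = {}
        for sr in rxn.getListOfReactants():
            met = _strip_prefix(sr.getSpecies(), _SBML_MET_PREFIX)
            stoich[met] = stoich.get(met, 0.0) - sr.getStoichiometry()
        for sr in rxn.getListOfProducts():
            met = _strip_prefix(sr.getSpecies(), _SBML_MET_PREFIX)
            stoich[met] = stoich.get(met, 0.0) + sr.getStoichiometry()

        lb = ub = None
        fbc_rxn = rxn.getPlugin("fbc")
        if fbc_rxn is not None:
            lb = _param_value(fbc_rxn.getLowerFluxBound())
            ub = _param_value(fbc_rxn.getUpperFluxBound())
        if lb is None:
            lb = DEFAULT_LOWER_BOUND if rxn.getReversible() else 0.0
        if ub is None:
            ub = DEFAULT_UPPER_BOUND

        reactions[rid] = Reaction(
            id=rid,
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            name=rxn.getName() or "",
            objective_coefficient=objective_coefs.get(rid, 0.0),
        )

    if not reactions:
        raise ValidationError(f"{source}: model has zero reactions")
    return GSMM(model_id=model_id, metabolites=metabolites, reactions=reactions)


def read_sbml(path: str | Path, model_id: str | None = None) -> GSMM:
    """Load a GSMM from an SBML Level 3 (+FBC v2) file.

    Missing flux bounds default to (-1000, 1000) for reversible and
    (0, 1000) for irreversible reactions. ``model_id`` defaults to the
    filename stem.
    """
    path = Path(path)
    if not path.is_file():
        raise FormatError(f"no such file: {path}")
    doc = libsbml.readSBMLFromFile(str(path))
    return _parse_document(doc, model_id or path.stem, str(path))


def read_sbml_string(text: str, model_id: str, source: str = "<string>") -> GSMM:
    doc = libsbml.readSBMLFromString(text)
    return _parse_document(doc, model_id, source)


def write_sbml(model: GSMM, path: str | Path) -> Path:
    """Serialise a GSMM as SBML Level 3 Version 1 with FBC v2 bounds and
    objective. ``read_sbml(write_sbml(m))`` restores ``m`` up to ordering."""
    model.validate()
    path = Path(path)

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(model.model_id)
    fbc_model = sbml_model.getPlugin("fbc")
    fbc_model.setStrict(False)

    compartments = sorted({m.compartment or "d" for m in model.metabolites.values()})
    for comp in compartments:
        c = sbml_model.createCompartment()
        c.setId(comp)
        c.setConstant(True)

    for met in model.metabolites.values():
        sp = sbml_model.createSpecies()
        sp.setId(_SBML_MET_PREFIX + met.full_id)
        if met.name:
            sp.setName(met.name)
        sp.setCompartment(met.compartment or "d")
        sp.setBoundaryCondition(met.boundary)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)

    bound_params: dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"bound_{len(bound_params)}"
            par = sbml_model.createParameter()
            par.setId(pid)
            par.setValue(float(value))
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    objective = fbc_model.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    fbc_model.setActiveObjectiveId("obj")

    for rxn in model.reactions.values():
        r = sbml_model.createReaction()
        r.setId(_SBML_RXN_PREFIX + rxn.id)
        if rxn.name:
            r.setName(rxn.name)
        r.setReversible(rxn.lower_bound < 0)
        r.setFast(False)
        for met, coef in rxn.stoichiometry.items():
            sr = r.createReactant() if coef < 0 else r.createProduct()
            sr.setSpecies(_SBML_MET_PREFIX + met)
            sr.setStoichiometry(abs(coef))
            sr.setConstant(True)
        fbc_rxn = r.getPlugin("fbc")
        fbc_rxn.setLowerFluxBound(_bound_param(rxn.lower_bound))
        fbc_rxn.setUpperFluxBound(_bound_param(rxn.upper_bound))
        if rxn.objective_coefficient != 0:
            fo = objective.createFluxObjective()
            fo.setReaction(_SBML_RXN_PREFIX + rxn.id)
            fo.setCoefficient(rxn.objective_coefficient)

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise OSError(f"cannot write SBML to {path}")
    return path


def sbml_to_string(model: GSMM) -> str:
    """In-memory SBML serialisation (used for archive building in tests)."""
    import tempfile

    with tempfile.NamedTemporaryFile("r", suffix=".xml", delete=False) as fh:
        tmp = fh.name
    try:
        write_sbml(model, tmp)
        return Path(tmp).read_text()
    finally:
        Path(tmp).unlink(missing_ok=True)


def read_model_archive(path: str | Path) -> list[GSMM]:
    """Load every model from a zip archive of SBML files.

    Files must sit at the archive's top level (not inside folders); the
    returned list is sorted lexicographically by model_id (= file stem).
    """
    path = Path(path)
    try:
        archive = zipfile.ZipFile(path)
    except (OSError, zipfile.BadZipFile) as exc:
        raise FormatError(f"cannot open archive {path}: {exc}") from exc

    with archive:
        names = [n for n in archive.namelist() if not n.endswith("/")]
        if any("/" in n or "\\" in n for n in names) or any(
            n.endswith("/") for n in archive.namelist()
        ):
            raise ArchiveLayoutError(
                f"{path}: the archive contains a folder; make sure all model "
                "files are directly zipped"
            )
        if len(names) > PLATFORM_MODEL_LIMIT:
            warnings.warn(
                f"{path}: {len(names)} models exceeds the reference platform "
                f"limit of {PLATFORM_MODEL_LIMIT}; proceeding anyway",
                stacklevel=2,
            )
        stems = [Path(n).stem for n in names]
        dupes = {s for s in stems if stems.count(s) > 1}
        if dupes:
            raise ValidationError(
                f"{path}: duplicate model stems {sorted(dupes)}"
            )
        models = []
        for name in sorted(names, key=lambda n: Path(n).stem):
            text = archive.read(name).decode("utf-8")
            models.append(read_sbml_string(text, Path(name).stem, f"{path}:{name}"))
    return models


def read_model_dir(path: str | Path) -> list[GSMM]:
    """Load every ``*.xml``/``*.sbml`` model from a directory."""
    path = Path(path)
    files = sorted(
        [p for p in path.iterdir() if p.suffix.lower() in (".xml", ".sbml")],
        key=lambda p: p.stem,
    )
    if not files:
        raise FormatError(f"no SBML files in {path}")
    return [read_sbml(p) for p in files]


# ---------------------------------------------------------------------------
# Model generators
# ---------------------------------------------------------------------------

_ARROWS = ("<->", "<=>", "->", "=>")
_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$")


def _parse_side(side: str, sign: float, stoich: dict[str, float]) -> None:
    side = side.strip()
    if not side:
        return
    for term in side.split("+"):
        term = term.strip()
        if not term:
            raise ValidationError(f"empty term in reaction side {side!r}")
        m = _TERM_RE.match(term)
        if m is None:
            raise ValidationError(f"cannot parse reaction term {term!r}")
        coef = float(m.group(1)) if m.group(1) else 1.0
        met = m.group(2)
        stoich[met] = stoich.get(met, 0.0) + sign * coef


def parse_reaction_string(equation: str) -> tuple[dict[str, float], bool]:
    """Parse ``"a + 2 b -> c"`` into (stoichiometry, reversible)."""
    for arrow in _ARROWS:
        if arrow in equation:
            lhs, rhs = equation.split(arrow, 1)
            reversible = arrow in ("<->", "<=>")
            break
    else:
        raise ValidationError(f"reaction string {equation!r} has no arrow")
    stoich: dict[str, float] = {}
    _parse_side(lhs, -1.0, stoich)
    _parse_side(rhs, +1.0, stoich)
    stoich = {m: c for m, c in stoich.items() if c != 0}
    if not stoich:
        raise ValidationError(f"reaction string {equation!r} has no net conversion")
    return stoich, reversible


ReactionSpec = "str | tuple"


def make_toy_model(
    reactions: Sequence[str | tuple],
    model_id: str = "toy",
    objective: str | None = None,
) -> GSMM:
    """Build a GSMM from declarative reaction strings.

    Each entry is either an equation string (``"a + b -> c"``, auto id
    ``R1..Rn``) or a tuple ``(rxn_id, equation)`` optionally extended with
    explicit ``(rxn_id, equation, lb, ub)`` bounds. ``<->`` yields default
    reversible bounds (-1000, 1000); ``->`` yields (0, 1000). An empty
    side denotes a boundary exchange (``"g ->"``). ``objective`` names the
    reaction given coefficient 1.
    """
    if not reactions:
        raise ValidationError("toy model needs at least one reaction")
    rxns: dict[str, Reaction] = {}
    mets: dict[str, Metabolite] = {}
    for i, entry in enumerate(reactions, start=1):
        lb = ub = None
        if isinstance(entry, str):
            rid, equation = f"R{i}", entry
        elif len(entry) == 2:
            rid, equation = entry
        elif len(entry) == 4:
            rid, equation, lb, ub = entry
        else:
            raise ValidationError(f"bad reaction spec {entry!r}")
        stoich, reversible = parse_reaction_string(equation)
        if lb is None:
            lb = DEFAULT_LOWER_BOUND if reversible else 0.0
        if ub is None:
            ub = DEFAULT_UPPER_BOUND
        if rid in rxns:
            raise ValidationError(f"duplicate reaction id {rid}")
        for met in stoich:
            mets.setdefault(met, Metabolite(full_id=met))
        rxns[rid] = Reaction(
            id=rid,
            stoichiometry=stoich,
            lower_bound=float(lb),
            upper_bound=float(ub),
            objective_coefficient=1.0 if rid == objective else 0.0,
        )
    if objective is not None and objective not in rxns:
        raise ValidationError(f"objective reaction {objective!r} not in spec")
    return GSMM(model_id=model_id, metabolites=mets, reactions=rxns)


def make_random_model(
    n_metabolites: int,
    n_reactions: int,
    seed: int,
    reversibility_prob: float = 0.3,
    model_id: str | None = None,
) -> GSMM:
    """Reproducible random GSMM (metabolite graph testing; not guaranteed
    to be connected or to carry an objective)."""
    if n_metabolites < 2:
        raise ValidationError("need at least 2 metabolites")
    rng = np.random.default_rng(seed)
    width = len(str(n_metabolites - 1))
    met_ids = [f"m{idx:0{width}d}" for idx in range(n_metabolites)]
    mets = {m: Metabolite(full_id=m) for m in met_ids}
    rxns: dict[str, Reaction] = {}
    for k in range(1, n_reactions + 1):
        n_sub = int(rng.integers(1, 3))
        n_prod = int(rng.integers(1, 3))
        chosen = rng.choice(n_metabolites, size=min(n_sub + n_prod, n_metabolites),
                            replace=False)
        subs = chosen[:n_sub]
        prods = chosen[n_sub:]
        if len(prods) == 0:
            continue
        stoich = {met_ids[int(s)]: -1.0 for s in subs}
        stoich.update({met_ids[int(p)]: 1.0 for p in prods})
        reversible = bool(rng.random() < reversibility_prob)
        rxns[f"R{k}"] = Reaction(
            id=f"R{k}",
            stoichiometry=stoich,
            lower_bound=DEFAULT_LOWER_BOUND if reversible else 0.0,
            upper_bound=DEFAULT_UPPER_BOUND,
        )
    if not rxns:  # extremely unlikely; force one reaction
        rxns["R1"] = Reaction(
            id="R1", stoichiometry={met_ids[0]: -1.0, met_ids[1]: 1.0}
        )
    return GSMM(
        model_id=model_id or f"random_{seed}",
        metabolites=mets,
        reactions=rxns,
    )


def make_random_growth_model(
    seed: int,
    n_nutrients: int = 2,
    n_intermediates: int = 3,
    model_id: str | None = None,
) -> GSMM:
    """Random model guaranteed to grow: nutrient uptakes feed a random
    acyclic conversion chain ending in a biomass ("Growth") reaction."""
    rng = np.random.default_rng(seed)
    nutrients = [f"n{i}" for i in range(n_nutrients)]
    inters = [f"x{i}" for i in range(n_intermediates)]
    specs: list[tuple] = []
    for i, nut in enumerate(nutrients):
        uptake = float(rng.integers(1, 11))
        specs.append((f"EX_{nut}", f"{nut} ->", -uptake, DEFAULT_UPPER_BOUND))
    pool = list(nutrients)
    for i, x in enumerate(inters):
        src = pool[int(rng.integers(0, len(pool)))]
        specs.append((f"C{i}", f"{src} -> {x}", 0.0, DEFAULT_UPPER_BOUND))
        pool.append(x)
    k = int(rng.integers(1, n_intermediates + 1))
    chosen = sorted(rng.choice(n_intermediates, size=k, replace=False).tolist())
    lhs = " + ".join(inters[j] for j in chosen)
    specs.append(("Growth", f"{lhs} ->", 0.0, DEFAULT_UPPER_BOUND))
    return make_toy_model(
        specs, model_id=model_id or f"growth_{seed}", objective="Growth"
    )


def make_demo_models() -> list[GSMM]:
    """Seven small interlocking models used by the integration demo.

    Each grows on its own nutrient uptake, and the models share / complement
    metabolites so that seed sets, PTMs and flux distances are all
    non-trivial.
    """
    shared = [
        ("d1", [("EX_g", "g ->", -10.0, 1000.0), ("P1", "g -> x"),
                ("P2", "x -> y"), ("Growth", "y ->", 0.0, 1000.0)]),
        ("d2", [("EX_g", "g ->", -6.0, 1000.0), ("P1", "g -> a"),
                ("P2", "a -> x"), ("P3", "x -> y"),
                ("Growth", "y ->", 0.0, 1000.0)]),
        ("d3", [("EX_a", "a ->", -8.0, 1000.0), ("P1", "a -> b"),
                ("P2", "b <-> c"), ("P3", "c -> y"),
                ("Growth", "y ->", 0.0, 1000.0)]),
        ("d4", [("EX_c", "c ->", -5.0, 1000.0), ("P1", "c -> w"),
                ("P2", "w -> y"), ("P3", "g -> y"),
                ("Growth", "y ->", 0.0, 1000.0)]),
        ("d5", [("EX_g", "g ->", -4.0, 1000.0), ("EX_b", "b ->", -3.0, 1000.0),
                ("P1", "g + b -> x"), ("P2", "x -> y"),
                ("Growth", "y ->", 0.0, 1000.0)]),
        ("d6", [("EX_w", "w ->", -7.0, 1000.0), ("P1", "w -> a"),
                ("P2", "a -> b"), ("P3", "b -> y"),
                ("Growth", "y ->", 0.0, 1000.0)]),
        ("d7", [("EX_g", "g ->", -9.0, 1000.0), ("P1", "g -> c"),
                ("P2", "c -> x"), ("P3", "x <-> w"), ("P4", "w -> y"),
                ("Growth", "y ->", 0.0, 1000.0)]),
    ]
    return [make_toy_model(spec, model_id=mid, objective="Growth")
            for mid, spec in shared]


def write_demo_models(outdir: str | Path) -> list[Path]:
    """Write the demo model set as SBML files into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for model in make_demo_models():
        paths.append(write_sbml(model, outdir / f"{model.model_id}.xml"))
    return paths
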