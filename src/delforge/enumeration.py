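"""Scaffold definition, reaction transforms, and combinatorial library
enumeration.

The scaffold is a benzene core carrying an aromatic azide, a benzylic
(CH2) azide, and a carboxamide cap standing in for the DNA attachment.
Four two-step schemes (A-D) consume both azide handles:

====== ==========================  ==========================  =========================================
scheme step 1 (aromatic azide)     step 2 (benzylic azide)     building-block classes (BB1, BB2)
====== ==========================  ==========================  =========================================
A      enolate [3+2] cycloaddition CuAAC                       active methylene, terminal alkyne
B      enolate [3+2] cycloaddition reduction + amidation       active methylene, carboxylic acid
C      reduction + amidation       CuAAC                       carboxylic acid,  terminal alkyne
D      reduction + amidation       reduction + amidation       carboxylic acid,  carboxylic acid
====== ==========================  ==========================  =========================================

The aromatic azide is the more reactive handle and must always be
consumed first; aliphatic-site transforms refuse to run while it is
still present (:class:`~delforge.errors.ReactivityOrderError`).

Fixed monoisotopic mass deltas per scheme (product minus scaffold + BB1 +
BB2): condensations lose one H2O (18.010565) each, azide reductions lose
N2 and gain 2 H (net -25.990483); CuAAC conserves atoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors

from .curation import BBClass, BuildingBlock, CLASS_PATTERNS
from .errors import (
    AmbiguousBuildingBlockError,
    ContractViolationError,
    IncompatibleBuildingBlockError,
    ParseError,
    ReactivityOrderError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Scaffold",
    "SchemeName",
    "LibraryScheme",
    "SCHEMES",
    "Warhead",
    "EnumerationResult",
    "enolate_cycloaddition",
    "cuaac",
    "reduce_azide",
    "amidate",
    "apply_scheme",
    "enumerate_library",
    "scheme_mass_delta",
]

# diazide acid with the attachment point capped as an N-methyl amide
DEFAULT_SCAFFOLD_SMILES = "CNC(=O)c1cc(N=[N+]=[N-])cc(CN=[N+]=[N-])c1"
# the uncapped parent acid, formula C8H6N6O2
UNCAPPED_ACID_SMILES = "OC(=O)c1cc(N=[N+]=[N-])cc(CN=[N+]=[N-])c1"

H2O_MONO = 18.010565
# lose N2 (28.006148), gain 2 H (2 * 1.00782503)
AZIDE_REDUCTION_DELTA = -28.006148 + 2 * 1.00782503

_AROMATIC_AZIDE = Chem.MolFromSmarts("[c][NX2]=[NX2+]=[NX1-]")
_ALIPHATIC_AZIDE = Chem.MolFromSmarts("[CX4][NX2]=[NX2+]=[NX1-]")
_ANY_AZIDE = Chem.MolFromSmarts("[NX2]~[NX2]~[NX1,NX2]")
_AMIDE = Chem.MolFromSmarts("[NX3][CX3]=[OX1]")
_CARBOXYLIC_ACID = Chem.MolFromSmarts("[CX3](=[OX1])[OX2H1]")
_TERMINAL_ALKYNE = Chem.MolFromSmarts("[CX2]#[CX2H1]")

# --- reaction transforms (products written in Kekule form; azide charges
# are reset explicitly because mapped atoms keep their reactant charge) ---

# aryl azide + active methylene -> 1-aryl-1,4,5-trisubstituted triazole:
# the former methylene carbon becomes C4, the consumed carbonyl carbon C5.
# Tier 1 consumes a ketone carbonyl (carbon substituent), tier 2 any
# carbonyl (ester/amide) -- so for keto-esters the ester survives at C4.
_ACTIVATED = "$([CX3]=[OX1]),$([SX4](=[OX1])=[OX1]),$([CX2]#[NX1]),$(c)"
_RXN_ENOLATE = [
    AllChem.ReactionFromSmarts(
        "[c:1][NX2:2]=[NX2+:3]=[NX1-:4]."
        f"[#6;!$([#6]=[OX1]):6][CX3:5](=[OX1])[CH2X4:7][{_ACTIVATED}:8]"
        ">>[c:1][N+0:2]1[N+0:3]=[N+0:4][C:7]([*:8])=[C:5]1[*:6]"
    ),
    AllChem.ReactionFromSmarts(
        "[c:1][NX2:2]=[NX2+:3]=[NX1-:4]."
        f"[*:6][CX3:5](=[OX1])[CH2X4:7][{_ACTIVATED}:8]"
        ">>[c:1][N+0:2]1[N+0:3]=[N+0:4][C:7]([*:8])=[C:5]1[*:6]"
    ),
]

# benzylic azide + terminal alkyne -> 1,4-disubstituted triazole
_RXN_CUAAC = AllChem.ReactionFromSmarts(
    "[CX4:1][NX2:2]=[NX2+:3]=[NX1-:4].[CX2H1:6]#[CX2:5]"
    ">>[CX4:1][N+0:2]1[CH1:6]=[C:5][N+0:4]=[N+0:3]1"
)

_RXN_REDUCE = {
    "aromatic": AllChem.ReactionFromSmarts(
        "[c:1][NX2:2]=[NX2+]=[NX1-]>>[c:1][NH2+0:2]"),
    "aliphatic": AllChem.ReactionFromSmarts(
        "[CX4:1][NX2:2]=[NX2+]=[NX1-]>>[CX4:1][NH2+0:2]"),
}

_RXN_AMIDATE = {
    "aromatic": AllChem.ReactionFromSmarts(
        "[c:1][NX3H2:2].[CX3:3](=[OX1:4])[OX2H1]"
        ">>[c:1][NH1:2][C:3]=[O:4]"),
    "aliphatic": AllChem.ReactionFromSmarts(
        "[CX4:1][NX3H2:2].[CX3:3](=[OX1:4])[OX2H1]"
        ">>[CX4:1][NH1:2][C:3]=[O:4]"),
}


@dataclass(frozen=True)
class Scaffold:
    """The diazide core with a capped attachment point.

    Validated to contain exactly one aromatic azide, exactly one benzylic
    CH2 azide, and at least one carboxamide (the cap).
    """

    smiles: str = DEFAULT_SCAFFOLD_SMILES

    def __post_init__(self):
        mol = self.mol
        n_ar = len(mol.GetSubstructMatches(_AROMATIC_AZIDE))
        n_al = len(mol.GetSubstructMatches(_ALIPHATIC_AZIDE))
        if n_ar != 1 or n_al != 1:
            raise ValueError(
                f"scaffold must carry exactly one aromatic and one "
                f"aliphatic azide (found {n_ar}/{n_al})")
        if not mol.HasSubstructMatch(_AMIDE):
            raise ValueError("scaffold must carry the carboxamide cap")

    @property
    def mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise ParseError(f"unparsable scaffold SMILES: {self.smiles!r}")
        return mol


class SchemeName(str, Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"


@dataclass(frozen=True)
class LibraryScheme:
    name: SchemeName
    step1: str  # transform at the aromatic azide
    step2: str  # transform at the aliphatic (benzylic) site
    bb1_class: BBClass
    bb2_class: BBClass


SCHEMES: dict[SchemeName, LibraryScheme] = {
    SchemeName.A: LibraryScheme(
        SchemeName.A, "enolate_cycloaddition", "cuaac",
        BBClass.ACTIVE_METHYLENE, BBClass.TERMINAL_ALKYNE),
    SchemeName.B: LibraryScheme(
        SchemeName.B, "enolate_cycloaddition", "reduce_amidate",
        BBClass.ACTIVE_METHYLENE, BBClass.CARBOXYLIC_ACID),
    SchemeName.C: LibraryScheme(
        SchemeName.C, "reduce_amidate", "cuaac",
        BBClass.CARBOXYLIC_ACID, BBClass.TERMINAL_ALKYNE),
    SchemeName.D: LibraryScheme(
        SchemeName.D, "reduce_amidate", "reduce_amidate",
        BBClass.CARBOXYLIC_ACID, BBClass.CARBOXYLIC_ACID),
}


def scheme_mass_delta(name: SchemeName | str) -> float:
    """Fixed monoisotopic mass delta of a scheme: product minus
    (scaffold + bb1 + bb2)."""
    name = SchemeName(name)
    step = {"enolate_cycloaddition": -H2O_MONO,
            "cuaac": 0.0,
            "reduce_amidate": AZIDE_REDUCTION_DELTA - H2O_MONO}
    scheme = SCHEMES[name]
    return step[scheme.step1] + step[scheme.step2]


@dataclass(frozen=True)
class Warhead:
    smiles: str
    scheme: SchemeName
    bb1_id: str
    bb2_id: str
    mw: float
    duplicate: bool = False


@dataclass
class EnumerationResult:
    scheme: SchemeName
    warheads: list[Warhead]
    failures: list[tuple[str, str, str]]  # (bb1_id, bb2_id, reason)

    def __len__(self) -> int:
        return len(self.warheads)


def _as_mol(structure: str | Chem.Mol) -> Chem.Mol:
    if isinstance(structure, Chem.Mol):
        return structure
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ParseError(f"unparsable SMILES: {structure!r}")
    return mol


def _bb_mol(bb: BuildingBlock | str | Chem.Mol) -> Chem.Mol:
    if isinstance(bb, BuildingBlock):
        return _as_mol(bb.smiles)
    return _as_mol(bb)


def _run(rxn, reactants: tuple) -> list[str]:
    """Run a reaction, sanitize products, return sorted unique SMILES."""
    out = set()
    for prods in rxn.RunReactants(reactants):
        mol = prods[0]
        try:
            Chem.SanitizeMol(mol)
        except Exception:  # pragma: no cover - malformed intermediate
            continue
        out.add(Chem.MolToSmiles(mol))
    return sorted(out)


def _pick(products: list[str]) -> Chem.Mol:
    # deterministic site choice: lowest canonical SMILES
    if len(products) > 1:
        logger.debug("ambiguous transform site: %d products, picking %s",
                     len(products), products[0])
    return Chem.MolFromSmiles(products[0])


def _require_no_aromatic_azide(mol: Chem.Mol, transform: str) -> None:
    if mol.HasSubstructMatch(_AROMATIC_AZIDE):
        raise ReactivityOrderError(
            f"{transform} targets the aliphatic site but the aromatic "
            "azide is still unreacted; consume the aromatic site first")


def enolate_cycloaddition(structure: str | Chem.Mol,
                          bb: BuildingBlock | str | Chem.Mol) -> Chem.Mol:
    """Aryl azide + active methylene -> 1-aryl triazole, losing one H2O.

    The former methylene carbon becomes C4 (keeping its second activating
    substituent); the consumed carbonyl carbon becomes C5.  When two
    carbonyls compete, a ketone carbonyl is consumed in preference to an
    ester/amide, then the lowest-canonical product is taken.
    """
    mol = _as_mol(structure)
    bb_mol = _bb_mol(bb)
    if not mol.HasSubstructMatch(_AROMATIC_AZIDE):
        raise ContractViolationError("no aromatic azide on substrate")
    if not bb_mol.HasSubstructMatch(CLASS_PATTERNS[BBClass.ACTIVE_METHYLENE]):
        raise IncompatibleBuildingBlockError(
            "incompatible_bb: not an active methylene compound")
    for rxn in _RXN_ENOLATE:
        products = _run(rxn, (mol, bb_mol))
        if products:
            return _pick(products)
    raise IncompatibleBuildingBlockError(
        "incompatible_bb: active methylene lacks a reactive carbonyl")


def cuaac(structure: str | Chem.Mol,
          bb: BuildingBlock | str | Chem.Mol) -> Chem.Mol:
    """Benzylic azide + terminal alkyne -> 1,4-disubstituted triazole.

    Atom-conserving.  The building block must carry exactly one terminal
    alkyne.
    """
    mol = _as_mol(structure)
    bb_mol = _bb_mol(bb)
    _require_no_aromatic_azide(mol, "cuaac")
    if not mol.HasSubstructMatch(_ALIPHATIC_AZIDE):
        raise ContractViolationError("no aliphatic azide on substrate")
    n_alkyne = len(bb_mol.GetSubstructMatches(_TERMINAL_ALKYNE))
    if n_alkyne == 0:
        raise IncompatibleBuildingBlockError(
            "incompatible_bb: no terminal alkyne")
    if n_alkyne > 1:
        raise IncompatibleBuildingBlockError(
            "incompatible_bb: more than one terminal alkyne")
    products = _run(_RXN_CUAAC, (mol, bb_mol))
    if not products:
        raise IncompatibleBuildingBlockError("incompatible_bb: cuaac failed")
    return _pick(products)


def reduce_azide(structure: str | Chem.Mol, site: str = "aromatic") -> Chem.Mol:
    """Replace the azide at ``site`` ('aromatic' or 'aliphatic') by -NH2."""
    mol = _as_mol(structure)
    if site not in _RXN_REDUCE:
        raise ValueError(f"unknown site {site!r}")
    pattern = _AROMATIC_AZIDE if site == "aromatic" else _ALIPHATIC_AZIDE
    if site == "aliphatic":
        _require_no_aromatic_azide(mol, "reduce_azide(aliphatic)")
    if not mol.HasSubstructMatch(pattern):
        raise ContractViolationError(f"no {site} azide to reduce")
    return _pick(_run(_RXN_REDUCE[site], (mol,)))


def amidate(structure: str | Chem.Mol, bb: BuildingBlock | str | Chem.Mol,
            site: str = "aromatic") -> Chem.Mol:
    """Couple a primary amine at ``site`` with a mono-carboxylic acid,
    losing one H2O."""
    mol = _as_mol(structure)
    bb_mol = _bb_mol(bb)
    if site not in _RXN_AMIDATE:
        raise ValueError(f"unknown site {site!r}")
    n_acid = len(bb_mol.GetSubstructMatches(_CARBOXYLIC_ACID))
    if n_acid == 0:
        raise IncompatibleBuildingBlockError(
            "incompatible_bb: no carboxylic acid")
    if n_acid > 1:
        raise AmbiguousBuildingBlockError(
            "ambiguous_bb: more than one carboxylic acid")
    products = _run(_RXN_AMIDATE[site], (mol, bb_mol))
    if not products:
        raise ContractViolationError(f"no primary {site} amine on substrate")
    return _pick(products)


def _apply_step(mol: Chem.Mol, transform: str, bb, site: str) -> Chem.Mol:
    if transform == "enolate_cycloaddition":
        return enolate_cycloaddition(mol, bb)
    if transform == "cuaac":
        return cuaac(mol, bb)
    if transform == "reduce_amidate":
        mol = reduce_azide(mol, site=site)
        return amidate(mol, bb, site=site)
    raise ValueError(f"unknown transform {transform!r}")


def apply_scheme(scheme: LibraryScheme | SchemeName | str,
                 bb1, bb2, scaffold: Scaffold | None = None) -> Chem.Mol:
    """Apply a scheme's step 1 (aromatic site) then step 2 (aliphatic
    site) to the scaffold."""
    if not isinstance(scheme, LibraryScheme):
        scheme = SCHEMES[SchemeName(scheme)]
    scaffold = scaffold or Scaffold()
    mol = _apply_step(scaffold.mol, scheme.step1, bb1, "aromatic")
    return _apply_step(mol, scheme.step2, bb2, "aliphatic")


def _step1_intermediate(scheme: LibraryScheme, scaffold: Scaffold, bb1,
                        prereduce_step2: bool) -> Chem.Mol:
    mol = _apply_step(scaffold.mol, scheme.step1, bb1, "aromatic")
    if prereduce_step2:
        mol = reduce_azide(mol, site="aliphatic")
    return mol


def enumerate_library(
    scheme: LibraryScheme | SchemeName | str,
    bb1_set: list[BuildingBlock],
    bb2_set: list[BuildingBlock],
    scaffold: Scaffold | None = None,
) -> EnumerationResult:
    """Enumerate one warhead per (bb1, bb2) pair in bb1-major order.

    Per-pair transform failures are recorded with provenance and
    enumeration continues.  Duplicate product structures (from distinct
    pairs) are retained and flagged.
    """
    if not isinstance(scheme, LibraryScheme):
        scheme = SCHEMES[SchemeName(scheme)]
    scaffold = scaffold or Scaffold()
    for bb, want, pos in ((bb1_set, scheme.bb1_class, "bb1"),
                          (bb2_set, scheme.bb2_class, "bb2")):
        bad = [b.bb_id for b in bb
               if isinstance(b, BuildingBlock) and b.bb_class is not want]
        if bad:
            raise ContractViolationError(
                f"{pos} class mismatch for scheme {scheme.name.value}: "
                f"{bad[:5]} (expected {want.value})")

    # step 2 amidation needs the benzylic azide reduced once per bb1, not
    # once per pair
    prereduce = scheme.step2 == "reduce_amidate"
    step2_bbs = [(b.bb_id, _bb_mol(b)) for b in bb2_set]

    warheads: list[Warhead] = []
    failures: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    for bb1 in bb1_set:
        try:
            inter = _step1_intermediate(scheme, scaffold, bb1, prereduce)
        except Exception as exc:
            for bb2_id, _ in step2_bbs:
                failures.append((bb1.bb_id, bb2_id, f"step1: {exc}"))
            continue
        for bb2_id, bb2_mol in step2_bbs:
            try:
                if scheme.step2 == "cuaac":
                    prod = cuaac(inter, bb2_mol)
                else:
                    prod = amidate(inter, bb2_mol, site="aliphatic")
            except Exception as exc:
                failures.append((bb1.bb_id, bb2_id, f"step2: {exc}"))
                continue
            smi = Chem.MolToSmiles(prod)
            warheads.append(Warhead(
                smiles=smi, scheme=scheme.name, bb1_id=bb1.bb_id,
                bb2_id=bb2_id, mw=Descriptors.MolWt(prod),
                duplicate=smi in seen))
            seen.add(smi)
    return EnumerationResult(scheme=scheme.name, warheads=warheads,
                             failures=failures)
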