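"""Seeded generators for every input the pipeline needs.

Two generators produce drop-in replacements for real catalog data:

* :func:`gen_bbs` — class-valid building-block candidates (active
  methylenes, terminal alkynes, carboxylic acids) assembled from SMILES
  templates, with a controllable fraction failing the rule-of-2 filter.
* :func:`gen_reference` — an approved-drug-like reference population: a
  majority of decorated small-molecule scaffolds plus a heavy, peptide-like
  low-QED tail of linear oligo-amides.

Everything is deterministic under the spec seed, and generated molecules
satisfy the enumeration preconditions by construction (no azides anywhere,
no di-acids, no stray terminal alkynes in acid/methylene candidates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .curation import BBClass, RawCandidate, matches_class, ro2_profile
from .errors import CapacityError

__all__ = ["BBGenSpec", "ReferenceGenSpec", "gen_bbs", "gen_reference"]

# substituent grammar: a few "middle" tokens followed by one terminal
# token; all concatenations are valid linear SMILES.  Middle tokens ending
# in an ether oxygen must be followed by a carbon-initial terminal.
_MIDDLE = ["C", "CC", "C(C)", "CO", "CCO", "CC(C)"]
_END_SMALL = ["C", "CC", "CCC", "O", "OC", "F", "Cl", "N(C)C", "C1CC1",
              "C1CCC1", "C1CCOC1", "C(F)(F)F", "c1ccccc1", "c1ccncc1",
              "c1ccco1", "C1CCN(C)C1"]
_CARBON_END = [e for e in _END_SMALL if e[0] in "Cc" and e != "C(F)(F)F"]
# heavy terminals guarantee MW >= 200 and/or clogP >= 2
_END_HEAVY = ["CCCCCCCCCCCC", "CCCCCCCCCCCCCC", "CCCCCCCCc1ccccc1",
              "c1ccc(-c2ccccc2)cc1", "CCCCCCCCCCCCCCCC"]

# acyl groups are built as prefix + carbon chain so the string always ends
# in a carbon before the carbonyl
_ACYL_PREFIX = ["", "C", "CC", "CCC", "OC", "OCC", "COC", "CCOC",
                "FC(F)(F)", "ClC", "FC", "CN(C)", "c1ccccc1",
                "c1ccc(F)cc1", "c1ccc(C)cc1", "c1ccncc1", "c1ccco1",
                "C1CC1", "C1CCC1", "C1CCCC1", "N#C"]
_ACYL_CHAIN = ["C", "CC", "C(C)", "CCC"]
_ESTER_TAIL = ["C", "CC", "C(C)C", "C(C)(C)C", "CCC"]
_AMIDE_TAIL = ["N(C)C", "NC", "N(C)CC", "N1CCCC1", "N1CCOCC1"]
_SULFONYL_TAIL = ["C", "CC", "c1ccccc1"]
_PARA_SUB = ["C", "CC", "F", "Cl", "OC", "C(C)C", "O", "C(F)(F)F",
             "N(C)C", "CCC", "OCC", "C1CC1"]


def _substituent(rng: np.random.Generator, heavy: bool) -> str:
    n_mid = int(rng.integers(0, 4))
    mid = "".join(rng.choice(_MIDDLE) for _ in range(n_mid))
    if heavy:
        end = rng.choice(_END_HEAVY)
    elif mid.endswith("O"):
        end = rng.choice(_CARBON_END)
    else:
        end = rng.choice(_END_SMALL)
    return mid + str(end)


def _am_candidate(rng: np.random.Generator, heavy: bool) -> str:
    acyl = str(rng.choice(_ACYL_PREFIX)) + str(rng.choice(_ACYL_CHAIN))
    ester = str(rng.choice(_ESTER_TAIL))
    if heavy:
        # a heavy chain in one slot pushes MW/clogP over the Ro2 thresholds
        h = str(rng.choice(_END_HEAVY))
        if rng.integers(0, 2):
            acyl = h
        else:
            ester = h
    kind = int(rng.integers(0, 8))
    if kind == 0:  # beta-keto ester
        return f"{acyl}C(=O)CC(=O)O{ester}"
    if kind == 1:  # beta-keto nitrile
        return f"{acyl}C(=O)CC#N"
    if kind == 2:  # beta-keto amide
        return f"{acyl}C(=O)CC(=O){rng.choice(_AMIDE_TAIL)}"
    if kind == 3:  # beta-keto sulfone
        return f"{acyl}C(=O)CS(=O)(=O){rng.choice(_SULFONYL_TAIL)}"
    ring = str(rng.choice(["c1ccc({s})cc1", "c1ccc({s})cn1",
                           "c1cc({s})ccc1F"])).format(
                               s=rng.choice(_PARA_SUB))
    if kind == 4:  # malonate diester
        return f"{ester}OC(=O)CC(=O)O{rng.choice(_ESTER_TAIL)}"
    if kind == 5:  # aryl-acetate ester (ester + aryl activation)
        return f"{ester}OC(=O)C{ring}"
    if kind == 6:  # cyanoacetate ester
        return f"{ester}OC(=O)CC#N"
    # (hetero)aryl-activated methylene ketone with a ring substituent
    return f"{acyl}C(=O)C{ring}"


def _alkyne_candidate(rng: np.random.Generator, heavy: bool) -> str:
    return f"C#C{_substituent(rng, heavy)}"


def _acid_candidate(rng: np.random.Generator, heavy: bool) -> str:
    return f"OC(=O){_substituent(rng, heavy)}"


_BUILDERS = {
    BBClass.ACTIVE_METHYLENE: _am_candidate,
    BBClass.TERMINAL_ALKYNE: _alkyne_candidate,
    BBClass.CARBOXYLIC_ACID: _acid_candidate,
}

_ALKYNE_PAT = Chem.MolFromSmarts("[CX2]#[CX2H1]")
_ACID_PAT = Chem.MolFromSmarts("[CX3](=[OX1])[OX2H1]")


@dataclass(frozen=True)
class BBGenSpec:
    bb_class: BBClass
    n: int
    seed: int = 0
    fraction_ro2_fail: float = 0.0


@dataclass(frozen=True)
class ReferenceGenSpec:
    n: int
    seed: int = 0
    fraction_heavy_tail: float = 0.152


def _valid_for_class(smiles: str, bb_class: BBClass) -> str | None:
    """Canonicalize and vet one candidate; None if it must be resampled."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    if not matches_class(mol, bb_class):
        return None
    if bb_class is BBClass.TERMINAL_ALKYNE:
        if len(mol.GetSubstructMatches(_ALKYNE_PAT)) != 1:
            return None
    else:
        # enumeration preconditions: one acid max, no stray alkynes
        if mol.HasSubstructMatch(_ALKYNE_PAT):
            return None
    if len(mol.GetSubstructMatches(_ACID_PAT)) > (
            1 if bb_class is BBClass.CARBOXYLIC_ACID else 0):
        return None
    return Chem.MolToSmiles(mol)


def gen_bbs(spec: BBGenSpec) -> list[RawCandidate]:
    """Generate ``spec.n`` unique class-valid candidate SMILES.

    ``fraction_ro2_fail`` of them are built with heavy decorations and
    verified to fail the Ro2 filter; the rest are verified to pass.
    Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    builder = _BUILDERS[spec.bb_class]
    n_fail = int(round(spec.fraction_ro2_fail * spec.n))
    quotas = [(spec.n - n_fail, False), (n_fail, True)]
    out: list[str] = []
    seen: set[str] = set()
    for quota, heavy in quotas:
        found = 0
        attempts = 0
        stall = 0
        max_attempts = 400 * max(quota, 1)
        while found < quota:
            attempts += 1
            stall += 1
            if attempts > max_attempts or stall > 20000:
                raise CapacityError(spec.n, len(seen))
            smi = _valid_for_class(builder(rng, heavy), spec.bb_class)
            if smi is None or smi in seen:
                continue
            if ro2_profile(smi).passes == heavy:
                continue  # wrong side of the boundary for this quota
            seen.add(smi)
            out.append(smi)
            found += 1
            stall = 0
    order = rng.permutation(len(out))
    prefix = {BBClass.ACTIVE_METHYLENE: "am", BBClass.TERMINAL_ALKYNE: "ta",
              BBClass.CARBOXYLIC_ACID: "ca"}[spec.bb_class]
    return [RawCandidate(source_id=f"syn-{prefix}-{i:05d}",
                         smiles=out[j]) for i, j in enumerate(order)]


# --- reference population -------------------------------------------------

# substitution-ready cores: format slots for one decoration and one
# linker+tail arm
_CORES = ["{d}c1ccc({a})cc1", "{d}c1ccc({a})cn1", "{d}c1ccc2cc({a})ccc2c1",
          "{d}c1cc({a})ccc1O", "{d}c1cc({a})ccc1F", "{d}c1ccc({a})nc1C",
          "{d}c1cnc({a})cn1", "{d}c1cc({a})cc(C)c1"]
_LINKERS = ["C(=O)N(C)", "S(=O)(=O)N(C)", "C(=O)N", "OCC(=O)N", "NC(=O)",
            "CN(C)C(=O)", "C(=O)N(CC)", "CNC(=O)", "OCC(=O)N(C)",
            "S(=O)(=O)N"]
_TAILS = ["C1CCCCC1", "C1CCNC1", "C1CCOC1", "CC(C)C", "c1ccccc1",
          "c1ccc(F)cc1", "c1ccc(C)cc1", "c1ccc(OC)cc1", "c1ccncc1",
          "C1CCN(C)CC1", "CCO", "C1CCNCC1", "CC1CCCCC1", "C1CCOCC1",
          "CCN(C)C", "C1CC1"]
_DECOR = ["C", "F", "Cl", "OC", "C(C)C", "CC", "O", "OCC", "C(F)(F)F",
          "N(C)C", "CCC", "C#N"]

# oligo-amide residues for the peptide-like heavy tail
_RESIDUES = ["NCC(=O)", "NC(C)C(=O)", "NC(CO)C(=O)", "NC(C(C)C)C(=O)",
             "NC(CC(C)C)C(=O)", "NC(Cc1ccccc1)C(=O)"]
_HEAVY_MIN_RES, _HEAVY_MAX_RES = 28, 60


def _smallmol(rng: np.random.Generator) -> str:
    core = str(rng.choice(_CORES))
    arm = str(rng.choice(_LINKERS)) + str(rng.choice(_TAILS))
    return core.format(d=rng.choice(_DECOR), a=arm)


def _heavy(rng: np.random.Generator) -> str:
    length = int(rng.integers(_HEAVY_MIN_RES, _HEAVY_MAX_RES + 1))
    chain = "".join(str(rng.choice(_RESIDUES)) for _ in range(length))
    return chain + "O"


def gen_reference(spec: ReferenceGenSpec) -> list[RawCandidate]:
    """Generate an approved-drug-like mixture population.

    ``fraction_heavy_tail`` of the records are long linear oligo-amides
    (MW > 1500, QED well below 0.2); the rest are decorated small-molecule
    scaffolds.  Deterministic under ``spec.seed``.
    """
    if spec.n < 100:
        raise ValueError("reference population needs n >= 100")
    rng = np.random.default_rng(spec.seed)
    n_heavy = int(round(spec.fraction_heavy_tail * spec.n))
    out: list[str] = []
    seen: set[str] = set()
    for quota, builder in ((spec.n - n_heavy, _smallmol), (n_heavy, _heavy)):
        found = 0
        attempts = 0
        stall = 0
        max_attempts = 400 * max(quota, 1)
        while found < quota:
            attempts += 1
            stall += 1
            if attempts > max_attempts or stall > 20000:
                raise CapacityError(spec.n, len(seen))
            mol = Chem.MolFromSmiles(builder(rng))
            if mol is None:
                continue
            smi = Chem.MolToSmiles(mol)
            if smi in seen:
                continue
            seen.add(smi)
            out.append(smi)
            found += 1
            stall = 0
    order = rng.permutation(len(out))
    return [RawCandidate(source_id=f"syn-ref-{i:05d}", smiles=out[j])
            for i, j in enumerate(order)]
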