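"""Building-block curation: desalting, class validation, rule-of-2 filtering
and diversity selection.

The curation pipeline turns raw candidate SMILES into a fixed-size,
class-validated building-block set::

    desalt -> class filter -> Ro2 filter -> fingerprint -> k-means selection

Rule of 2 (Ro2): MW < 200, clogP < 2, HBD <= 2, HBA <= 4.  clogP is the
Crippen atomic-contribution estimate; HBD/HBA are Lipinski counts (N-H/O-H
hydrogens and N+O atoms) so the same profile feeds both the Ro2 and Ro5
filters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdFingerprintGenerator
from sklearn.cluster import KMeans

from .errors import EmptySetError, ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "BBClass",
    "RawCandidate",
    "Ro2Profile",
    "BuildingBlock",
    "ClusterSelection",
    "CurationResult",
    "desalt",
    "ro2_profile",
    "morgan_fp",
    "kmeans_select",
    "curate",
]


class BBClass(str, Enum):
    """Reactive class of a building block."""

    ACTIVE_METHYLENE = "active_methylene"
    TERMINAL_ALKYNE = "terminal_alkyne"
    CARBOXYLIC_ACID = "carboxylic_acid"


# sp3 CH2 flanked by a carbonyl/sulfonyl on one side and a second
# activating group (carbonyl, sulfonyl, nitrile, or aryl) on the other.
_ACTIVE_METHYLENE_SMARTS = (
    "[$([CX3]=[OX1]),$([SX4](=[OX1])=[OX1])]"
    "[CH2X4]"
    "[$([CX3]=[OX1]),$([SX4](=[OX1])=[OX1]),$([CX2]#[NX1]),c]"
)
_TERMINAL_ALKYNE_SMARTS = "[CX2]#[CX2H1]"
_CARBOXYLIC_ACID_SMARTS = "[CX3](=[OX1])[OX2H1]"
_AZIDE_SMARTS = "[NX2]~[NX2]~[NX1,NX2]"

CLASS_PATTERNS = {
    BBClass.ACTIVE_METHYLENE: Chem.MolFromSmarts(_ACTIVE_METHYLENE_SMARTS),
    BBClass.TERMINAL_ALKYNE: Chem.MolFromSmarts(_TERMINAL_ALKYNE_SMARTS),
    BBClass.CARBOXYLIC_ACID: Chem.MolFromSmarts(_CARBOXYLIC_ACID_SMARTS),
}
_AZIDE_PATTERN = Chem.MolFromSmarts(_AZIDE_SMARTS)
_ALKYNE_PATTERN = CLASS_PATTERNS[BBClass.TERMINAL_ALKYNE]

# Atoms whose formal charge can be fixed by adding/removing protons only
# (no counter-ion partner elsewhere in the molecule).
_NEUTRALIZE_PATTERN = Chem.MolFromSmarts(
    "[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]"
)

RO2_MW_MAX = 200.0
RO2_CLOGP_MAX = 2.0
RO2_HBD_MAX = 2
RO2_HBA_MAX = 4


@dataclass(frozen=True)
class RawCandidate:
    """An uncurated input record: free-text id plus structure string."""

    source_id: str
    smiles: str


@dataclass(frozen=True)
class Ro2Profile:
    mw: float
    clogp: float
    hbd: int
    hba: int
    passes: bool
    reject_reasons: tuple[str, ...] = ()


@dataclass(frozen=True)
class BuildingBlock:
    bb_id: str
    smiles: str
    bb_class: BBClass
    ro2: Ro2Profile
    fp: np.ndarray
    source_id: str = ""
    cluster: int = -1

    def __post_init__(self):
        if self.fp.shape != (1024,):
            raise ValueError("fingerprint must have exactly 1024 positions")


@dataclass
class ClusterSelection:
    k: int
    seed: int
    representative_ids: list[str]
    cluster_assignments: dict[str, int]


@dataclass
class CurationResult:
    blocks: list[BuildingBlock]
    selection: ClusterSelection
    report: dict


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparsable SMILES: {smiles!r}")
    return mol


def _neutralize(mol: Chem.Mol) -> Chem.Mol:
    """Neutralize charges fixable by simple proton add/remove."""
    matches = mol.GetSubstructMatches(_NEUTRALIZE_PATTERN)
    if not matches:
        return mol
    mol = Chem.RWMol(mol)
    for (idx,) in matches:
        atom = mol.GetAtomWithIdx(idx)
        charge = atom.GetFormalCharge()
        h = atom.GetTotalNumHs()
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(max(0, h - charge))
        atom.UpdatePropertyCache()
    Chem.SanitizeMol(mol)
    return mol.GetMol()


def desalt(candidate: RawCandidate | str) -> str:
    """Return the canonical SMILES of the largest covalent fragment.

    Ties on heavy-atom count are broken by the lower canonical-SMILES sort
    order, so the result is independent of fragment order in the input.
    Simple protonation-state charges are neutralized.

    Raises
    ------
    ParseError
        If the SMILES does not parse.
    """
    smiles = candidate.smiles if isinstance(candidate, RawCandidate) else candidate
    mol = _mol_from_smiles(smiles)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    ranked = sorted(
        ((f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)) for f in frags),
        key=lambda t: (-t[0], t[1]),
    )
    best = _mol_from_smiles(ranked[0][1])
    best = _neutralize(best)
    return Chem.MolToSmiles(best)


def ro2_profile(structure: str | Chem.Mol) -> Ro2Profile:
    """Compute the rule-of-2 descriptor profile of a (desalted) structure."""
    mol = _mol_from_smiles(structure) if isinstance(structure, str) else structure
    mw = Descriptors.MolWt(mol)
    clogp = Crippen.MolLogP(mol)
    hbd = Lipinski.NHOHCount(mol)
    hba = Lipinski.NOCount(mol)
    reasons = []
    if not mw < RO2_MW_MAX:
        reasons.append("mw")
    if not clogp < RO2_CLOGP_MAX:
        reasons.append("clogp")
    if hbd > RO2_HBD_MAX:
        reasons.append("hbd")
    if hba > RO2_HBA_MAX:
        reasons.append("hba")
    return Ro2Profile(mw, clogp, hbd, hba, passes=not reasons,
                      reject_reasons=tuple(reasons))


def matches_class(structure: str | Chem.Mol, bb_class: BBClass) -> bool:
    """True if the structure carries the class pattern and none of the
    cross-reactive groups excluded for that class.

    Carboxylic-acid candidates that also contain an azide or a terminal
    alkyne are rejected (they would react at both scaffold sites).
    """
    mol = _mol_from_smiles(structure) if isinstance(structure, str) else structure
    if not mol.HasSubstructMatch(CLASS_PATTERNS[bb_class]):
        return False
    if bb_class is BBClass.CARBOXYLIC_ACID:
        if mol.HasSubstructMatch(_AZIDE_PATTERN):
            return False
        if mol.HasSubstructMatch(_ALKYNE_PATTERN):
            return False
    return True


_FP_GENERATORS: dict[tuple[int, int], object] = {}


def _fp_generator(nbits: int, radius: int):
    key = (nbits, radius)
    if key not in _FP_GENERATORS:
        _FP_GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=nbits
        )
    return _FP_GENERATORS[key]


def morgan_fp(structure: str | Chem.Mol, nbits: int = 1024,
              radius: int = 2) -> np.ndarray:
    """Morgan (ECFP-style) fingerprint as a 0/1 uint8 vector."""
    mol = _mol_from_smiles(structure) if isinstance(structure, str) else structure
    fp = _fp_generator(nbits, radius).GetFingerprintAsNumPy(mol)
    return fp.astype(np.uint8)


def kmeans_select(
    fps: Sequence[np.ndarray] | np.ndarray,
    k: int = 200,
    seed: int = 0,
    ids: Sequence[str] | None = None,
) -> ClusterSelection:
    """Diversity-select ``min(k, n)`` representatives by k-means.

    Fingerprints are treated as real-valued 0/1 coordinates and clustered
    with k-means++ (Euclidean, max 300 iterations, tol 1e-4).  Within each
    cluster the representative is the member nearest the centroid; ties are
    broken by the lower id sort order.  Duplicate fingerprints are collapsed
    before clustering (keeping the lowest id), and the input is sorted by id
    before clustering, so the selection is invariant to input order and to
    duplication.
    """
    X = np.asarray(fps, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("need at least one fingerprint")
    n = X.shape[0]
    if ids is None:
        width = len(str(n - 1))
        ids = [f"{i:0{width}d}" for i in range(n)]
    ids = list(ids)
    if len(ids) != n:
        raise ValueError("ids and fps length mismatch")

    # canonical ordering + dedup for permutation/duplication invariance
    order = sorted(range(n), key=lambda i: ids[i])
    seen: dict[bytes, int] = {}
    uniq_idx: list[int] = []
    for i in order:
        key = X[i].tobytes()
        if key not in seen:
            seen[key] = i
            uniq_idx.append(i)
    Xu = X[uniq_idx]
    nu = len(uniq_idx)

    if nu <= k:
        if nu < k:
            warnings.warn(
                f"only {nu} unique inputs for k={k}; every input becomes "
                "its own representative", stacklevel=2)
        cluster_of = {X[i].tobytes(): j for j, i in enumerate(uniq_idx)}
        assignments = {ids[i]: cluster_of[X[i].tobytes()] for i in range(n)}
        reps = [ids[i] for i in uniq_idx]
        return ClusterSelection(k=k, seed=seed, representative_ids=reps,
                                cluster_assignments=assignments)

    km = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=300,
                tol=1e-4, random_state=seed)
    labels = km.fit_predict(Xu)
    centroids = km.cluster_centers_

    reps: list[str] = []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        d = np.linalg.norm(Xu[members] - centroids[c], axis=1)
        best = min(
            zip(d, (ids[uniq_idx[m]] for m in members)),
            key=lambda t: (round(t[0], 12), t[1]),
        )
        reps.append(best[1])

    assignments: dict[str, int] = {}
    label_by_key = {Xu[j].tobytes(): int(labels[j]) for j in range(nu)}
    for i in range(n):
        assignments[ids[i]] = label_by_key[X[i].tobytes()]
    return ClusterSelection(k=k, seed=seed, representative_ids=reps,
                            cluster_assignments=assignments)


def curate(
    candidates: Iterable[RawCandidate],
    bb_class: BBClass,
    k: int = 200,
    seed: int = 0,
    nbits: int = 1024,
    radius: int = 2,
) -> CurationResult:
    """Run the full curation pipeline for one building-block class.

    Returns exactly ``min(k, survivors)`` blocks, with per-stage rejection
    counts in the report.  Raises :class:`EmptySetError` naming the first
    stage that removed every candidate.
    """
    candidates = list(candidates)
    counts = {
        "input": len(candidates),
        "parse_error": 0,
        "class_fail": 0,
        "ro2_fail": 0,
        "duplicate": 0,
    }
    if not candidates:
        raise EmptySetError("input")

    survivors: dict[str, tuple[str, Ro2Profile]] = {}  # canonical -> (src, ro2)
    for cand in candidates:
        try:
            smiles = desalt(cand)
        except ParseError:
            counts["parse_error"] += 1
            logger.info("parse_error: %s (%s)", cand.smiles, cand.source_id)
            continue
        mol = Chem.MolFromSmiles(smiles)
        if not matches_class(mol, bb_class):
            counts["class_fail"] += 1
            continue
        ro2 = ro2_profile(mol)
        if not ro2.passes:
            counts["ro2_fail"] += 1
            continue
        if smiles in survivors:
            counts["duplicate"] += 1
            continue
        survivors[smiles] = (cand.source_id, ro2)

    if counts["parse_error"] == counts["input"]:
        raise EmptySetError("parse")
    if not survivors and counts["class_fail"] > 0 and (
            counts["parse_error"] + counts["class_fail"] == counts["input"]):
        raise EmptySetError("class")
    if not survivors:
        raise EmptySetError("ro2")

    counts["ro2_pass"] = len(survivors)
    smiles_sorted = sorted(survivors)
    fps = np.array([morgan_fp(s, nbits=nbits, radius=radius)
                    for s in smiles_sorted])
    selection = kmeans_select(fps, k=k, seed=seed, ids=smiles_sorted)

    prefix = {
        BBClass.ACTIVE_METHYLENE: "am",
        BBClass.TERMINAL_ALKYNE: "ta",
        BBClass.CARBOXYLIC_ACID: "ca",
    }[bb_class]
    fp_by_smiles = dict(zip(smiles_sorted, fps))
    blocks = []
    for i, smi in enumerate(selection.representative_ids):
        src, ro2 = survivors[smi]
        blocks.append(BuildingBlock(
            bb_id=f"{prefix}{i:04d}",
            smiles=smi,
            bb_class=bb_class,
            ro2=ro2,
            fp=fp_by_smiles[smi],
            source_id=src,
            cluster=selection.cluster_assignments[smi],
        ))
    counts["selected"] = len(blocks)
    report = {
        "bb_class": bb_class.value,
        "k": k,
        "seed": seed,
        "fingerprint": {"nbits": nbits, "radius": radius},
        "counts": counts,
    }
    return CurationResult(blocks=blocks, selection=selection, report=report)
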