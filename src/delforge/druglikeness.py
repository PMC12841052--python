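"""Per-molecule drug-likeness profiling and library-level summaries.

Ro5 violation count (ro5vc) counts how many of the four Lipinski criteria
a molecule exceeds, with strict inequalities: MW > 500, clogP > 5,
HBD > 5, HBA > 10.  QED is the weighted geometric mean of desirability
functions (mean weights), delegated to RDKit's implementation.  MW is the
average (not monoisotopic) molecular weight throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, QED

from .errors import ParseError, UndefinedCorrelationError

logger = logging.getLogger(__name__)

__all__ = ["PropertyProfile", "LibrarySummary", "profile", "profile_many",
           "summarize", "pearson_r"]

RO5_MW_MAX = 500.0
RO5_CLOGP_MAX = 5.0
RO5_HBD_MAX = 5
RO5_HBA_MAX = 10


@dataclass(frozen=True)
class PropertyProfile:
    mw: float
    clogp: float
    hbd: int
    hba: int
    ro5vc: int
    qed: float


@dataclass
class LibrarySummary:
    n: int
    ro5vc_fractions: dict[int, float]
    mean_qed: float
    median_qed: float
    mean_mw: float
    frac_mw_lt_500: float
    qed_histogram: list[int]  # 10 bins of width 0.1 over [0, 1]

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "ro5vc_fractions": {str(k): v
                                for k, v in self.ro5vc_fractions.items()},
            "mean_qed": self.mean_qed,
            "median_qed": self.median_qed,
            "mean_mw": self.mean_mw,
            "frac_mw_lt_500": self.frac_mw_lt_500,
            "qed_histogram": self.qed_histogram,
        }


def ro5_violations(mw: float, clogp: float, hbd: int, hba: int) -> int:
    return sum((mw > RO5_MW_MAX, clogp > RO5_CLOGP_MAX,
                hbd > RO5_HBD_MAX, hba > RO5_HBA_MAX))


def profile(structure: str | Chem.Mol) -> PropertyProfile:
    """Compute the full property profile of one molecule.

    Raises :class:`ParseError` if the structure does not parse/sanitize.
    """
    if isinstance(structure, Chem.Mol):
        mol = structure
    else:
        mol = Chem.MolFromSmiles(structure)
        if mol is None:
            raise ParseError(f"unparsable SMILES: {structure!r}")
    mw = Descriptors.MolWt(mol)
    clogp = Crippen.MolLogP(mol)
    hbd = Lipinski.NHOHCount(mol)
    hba = Lipinski.NOCount(mol)
    return PropertyProfile(
        mw=mw, clogp=clogp, hbd=hbd, hba=hba,
        ro5vc=ro5_violations(mw, clogp, hbd, hba),
        qed=QED.qed(mol),
    )


def profile_many(structures: Iterable[str]) -> list[PropertyProfile]:
    """Profile a collection, skipping (and logging) unparsable records."""
    out = []
    for s in structures:
        try:
            out.append(profile(s))
        except ParseError:
            logger.info("profile skip: %r", s)
    return out


def summarize(profiles: Sequence[PropertyProfile]) -> LibrarySummary:
    """Exact counting statistics over a set of profiles.

    Median uses the lower+upper midpoint convention for even n.
    """
    if not profiles:
        raise ValueError("cannot summarize an empty profile list")
    n = len(profiles)
    vc = np.array([p.ro5vc for p in profiles])
    qed = np.array([p.qed for p in profiles])
    mw = np.array([p.mw for p in profiles])
    fractions = {k: float(np.count_nonzero(vc == k)) / n for k in range(5)}
    # bin width 0.1 over [0, 1]; qed == 1.0 counted in the top bin
    hist = np.bincount(np.minimum((qed / 0.1).astype(int), 9),
                       minlength=10)
    return LibrarySummary(
        n=n,
        ro5vc_fractions=fractions,
        mean_qed=float(qed.mean()),
        median_qed=float(np.median(qed)),
        mean_mw=float(mw.mean()),
        frac_mw_lt_500=float(np.count_nonzero(mw < 500.0)) / n,
        qed_histogram=[int(c) for c in hist],
    )


def pearson_r(xs: Sequence[float], ys: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation, returned as (r, r_squared)."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape:
        raise ValueError("xs and ys must have equal length")
    if x.size < 3:
        raise UndefinedCorrelationError("need at least 3 points")
    if math.isclose(float(np.var(x)), 0.0) or math.isclose(float(np.var(y)), 0.0):
        raise UndefinedCorrelationError("zero variance in one input")
    from scipy.stats import pearsonr

    r = float(pearsonr(x, y).statistic)
    return r, r * r
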