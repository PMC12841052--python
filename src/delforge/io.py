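"""Readers and writers for the pipeline's plain-text interchange formats."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
from rdkit import Chem

from .curation import BuildingBlock, RawCandidate
from .enumeration import Warhead

__all__ = [
    "read_smi", "read_table", "write_smi",
    "write_bb_csv", "read_bb_csv_smiles",
    "write_warheads_csv", "write_warheads_sdf",
    "write_json", "read_json", "write_coords_csv",
]


def read_smi(path: str | Path) -> list[RawCandidate]:
    """Read a .smi file: one SMILES per line, optional whitespace-separated
    id.  Lines without an id get a positional one."""
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        source_id = parts[1].strip() if len(parts) > 1 else f"line{i + 1}"
        out.append(RawCandidate(source_id=source_id, smiles=smiles))
    return out


def read_table(path: str | Path, smiles_col: str = "smiles",
               id_col: str | None = None, sep: str | None = None
               ) -> list[RawCandidate]:
    """Read candidates from a delimited table with a named SMILES column.

    The separator is inferred from the extension (.tsv -> tab) unless
    given explicitly.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if smiles_col not in df.columns:
        raise KeyError(f"no column {smiles_col!r} in {path}")
    ids = (df[id_col].astype(str) if id_col and id_col in df.columns
           else pd.Series([f"row{i}" for i in range(len(df))]))
    return [RawCandidate(source_id=i, smiles=s)
            for i, s in zip(ids, df[smiles_col].astype(str))]


def write_smi(path: str | Path, candidates: Iterable[RawCandidate]) -> None:
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f"{c.smiles}\t{c.source_id}\n")


def write_bb_csv(path: str | Path, blocks: Iterable[BuildingBlock]) -> None:
    rows = [{
        "bb_id": b.bb_id, "smiles": b.smiles, "class": b.bb_class.value,
        "mw": round(b.ro2.mw, 3), "clogp": round(b.ro2.clogp, 3),
        "hbd": b.ro2.hbd, "hba": b.ro2.hba, "cluster": b.cluster,
    } for b in blocks]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_bb_csv_smiles(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_warheads_csv(path: str | Path, warheads: Iterable[Warhead]) -> None:
    rows = [{
        "smiles": w.smiles, "scheme": w.scheme.value, "bb1_id": w.bb1_id,
        "bb2_id": w.bb2_id, "mw": round(w.mw, 3), "duplicate": w.duplicate,
    } for w in warheads]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_warheads_sdf(path: str | Path, warheads: Iterable[Warhead]) -> None:
    """SDF with scheme/BB provenance as record properties."""
    writer = Chem.SDWriter(str(path))
    try:
        for w in warheads:
            mol = Chem.MolFromSmiles(w.smiles)
            if mol is None:
                continue
            mol.SetProp("scheme", w.scheme.value)
            mol.SetProp("bb1_id", w.bb1_id)
            mol.SetProp("bb2_id", w.bb2_id)
            mol.SetProp("mw", f"{w.mw:.3f}")
            writer.write(mol)
    finally:
        writer.close()


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_coords_csv(path: str | Path, coords, set_name: str,
                     ids: Iterable[str] | None = None) -> None:
    import numpy as np

    coords = np.asarray(coords)
    df = pd.DataFrame({
        "id": list(ids) if ids is not None
        else [f"{set_name}-{i}" for i in range(len(coords))],
        "set": set_name,
        "umap1": coords[:, 0] if len(coords) else [],
        "umap2": coords[:, 1] if len(coords) else [],
    })
    df.to_csv(path, index=False)
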