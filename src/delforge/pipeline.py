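"""Full-run orchestration: curate -> enumerate -> profile -> embed ->
occupancy -> report, with every parameter carried in a single config."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import chemspace, io
from .curation import BBClass, RawCandidate, curate
from .druglikeness import pearson_r, profile_many, summarize
from .enumeration import SCHEMES, SchemeName, Scaffold, enumerate_library
from .synthetic import BBGenSpec, ReferenceGenSpec, gen_bbs, gen_reference

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "run_full"]


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained on disk."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Defaults: 200 representatives
    per building-block class, 200 x 200 enumeration for each of the four
    schemes, UMAP with n_neighbors=50 on the jaccard metric fitted on the
    reference only, and a 0.01 KDE density threshold.
    """

    seed: int = 0
    k: int = 200
    schemes: list[str] = field(default_factory=lambda: ["A", "B", "C", "D"])
    scaffold_smiles: str | None = None

    # building-block inputs: either file paths per class or synthetic specs
    bb_files: dict[str, str] = field(default_factory=dict)
    bb_candidates_per_class: int = 400
    bb_fraction_ro2_fail: float = 0.3

    # reference population: file path or synthetic spec
    reference_file: str | None = None
    reference_n: int = 3594
    reference_heavy_tail: float = 0.152

    # embedding / density parameters
    n_neighbors: int = 50
    metric: str = "jaccard"
    umap_seed: int = 42
    kde_resolution: int = 512
    kde_threshold: float = 0.01

    out_dir: str = "delforge_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_candidates(path: str) -> list[RawCandidate]:
    if path.endswith(".smi"):
        return io.read_smi(path)
    return io.read_table(path)


def _bb_inputs(config: RunConfig, bb_class: BBClass) -> list[RawCandidate]:
    if bb_class.value in config.bb_files:
        return _load_candidates(config.bb_files[bb_class.value])
    class_seed = config.seed * 10 + list(BBClass).index(bb_class)
    return gen_bbs(BBGenSpec(
        bb_class=bb_class, n=config.bb_candidates_per_class,
        seed=class_seed, fraction_ro2_fail=config.bb_fraction_ro2_fail))


def run_full(config: RunConfig) -> dict:
    """Execute the whole analysis and write a report bundle to
    ``config.out_dir``; returns the manifest (also written as JSON).

    Idempotent under fixed seeds: rerunning the same config reproduces the
    same manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.as_dict(), "stages": {}}
    scaffold = (Scaffold(config.scaffold_smiles) if config.scaffold_smiles
                else Scaffold())

    # --- curation, one set per class any requested scheme needs ----------
    schemes = [SCHEMES[SchemeName(s)] for s in config.schemes]
    needed = sorted({s.bb1_class for s in schemes}
                    | {s.bb2_class for s in schemes},
                    key=lambda c: c.value)
    curated = {}
    for bb_class in needed:
        try:
            result = curate(_bb_inputs(config, bb_class), bb_class,
                            k=config.k, seed=config.seed)
        except Exception as exc:
            raise StageError(f"curate_{bb_class.value}", exc) from exc
        curated[bb_class] = result.blocks
        io.write_bb_csv(out / f"bbs_{bb_class.value}.csv", result.blocks)
        manifest["stages"][f"curate_{bb_class.value}"] = result.report
        logger.info("curated %s: %d blocks", bb_class.value,
                    len(result.blocks))

    # --- enumeration + profiling per scheme ------------------------------
    summaries = {}
    library_smiles = {}
    for scheme in schemes:
        name = scheme.name.value
        try:
            enum = enumerate_library(scheme, curated[scheme.bb1_class],
                                     curated[scheme.bb2_class],
                                     scaffold=scaffold)
        except Exception as exc:
            raise StageError(f"enumerate_{name}", exc) from exc
        io.write_warheads_csv(out / f"library_{name}.csv", enum.warheads)
        library_smiles[name] = [w.smiles for w in enum.warheads]
        profiles = profile_many(library_smiles[name])
        summary = summarize(profiles)
        summaries[name] = summary
        io.write_json(out / f"summary_{name}.json", summary.as_dict())
        manifest["stages"][f"enumerate_{name}"] = {
            "n_products": len(enum.warheads),
            "n_failures": len(enum.failures),
            "n_duplicates": sum(w.duplicate for w in enum.warheads),
        }
        logger.info("scheme %s: %d products, %d failures", name,
                    len(enum.warheads), len(enum.failures))

    manifest["summaries"] = {k: v.as_dict() for k, v in summaries.items()}

    # Ro5VC=0 fraction vs mean QED across libraries
    if len(summaries) >= 3:
        names = sorted(summaries)
        r, r2 = pearson_r([summaries[n].ro5vc_fractions[0] for n in names],
                          [summaries[n].mean_qed for n in names])
        manifest["ro5vc0_vs_qed"] = {"r": r, "r_squared": r2,
                                     "libraries": names}

    # --- reference population, embedding, occupancy ----------------------
    if config.reference_file:
        reference = [c.smiles for c in _load_candidates(config.reference_file)]
    else:
        reference = [c.smiles for c in gen_reference(ReferenceGenSpec(
            n=config.reference_n, seed=config.seed + 1000,
            fraction_heavy_tail=config.reference_heavy_tail))]
    ref_profiles = profile_many(reference)
    manifest["reference_summary"] = summarize(ref_profiles).as_dict()

    try:
        model = chemspace.fit_embedding(
            reference, n_neighbors=config.n_neighbors,
            metric=config.metric, seed=config.umap_seed)
    except Exception as exc:
        raise StageError("embed", exc) from exc
    io.write_coords_csv(out / "coords_reference.csv",
                        model.reference_coords, "reference")
    coords = {}
    for name, smiles in library_smiles.items():
        coords[name] = chemspace.project(model, smiles)
        io.write_coords_csv(out / f"coords_{name}.csv", coords[name], name)

    grid = chemspace.shared_grid(
        [model.reference_coords, *coords.values()],
        resolution=config.kde_resolution)
    ref_map = chemspace.kde_map(model.reference_coords, grid=grid,
                                threshold=config.kde_threshold)
    reports = {}
    for name in sorted(coords):
        lib_map = chemspace.kde_map(coords[name], grid=grid,
                                    threshold=config.kde_threshold)
        reports[name] = chemspace.occupancy(
            lib_map, ref_map, name=name,
            mean_qed=summaries[name].mean_qed)
    manifest["occupancy"] = {n: r.as_dict() for n, r in reports.items()}
    manifest["reference_kde_area"] = ref_map.area

    if len(reports) >= 3:
        names = sorted(reports)
        r, r2 = pearson_r([reports[n].occupancy_rate for n in names],
                          [reports[n].mean_qed for n in names])
        manifest["occupancy_vs_qed"] = {"r": r, "r_squared": r2,
                                        "libraries": names}

    io.write_json(out / "manifest.json", manifest)
    return manifest
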