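# delforge

Build and profile virtual DNA-encoded libraries (DELs) from a compact
diazide scaffold — 3-azido-5-(azidomethyl)benzoic acid with the DNA
attachment modeled as an amide cap — and quantify how the resulting
libraries occupy chemical space relative to a reference compound
population.

The pipeline has five stages:

1. **Building-block curation** (`delforge.curation`): desalting, class
   validation (active methylenes, terminal alkynes, carboxylic acids),
   rule-of-2 filtering (MW < 200, clogP < 2, HBD ≤ 2, HBA ≤ 4), Morgan
   fingerprints (1024 bits, radius 2), and k-means diversity selection of
   200 representatives per class.
2. **Warhead enumeration** (`delforge.enumeration`): four two-step
   reaction schemes (A–D) combining enolate [3+2] cycloaddition, CuAAC,
   azide reduction, and amidation; all 200 × 200 building-block pairs per
   scheme (40,000 products each), with the aromatic azide always consumed
   first.
3. **Drug-likeness profiling** (`delforge.druglikeness`): Lipinski
   rule-of-5 violation counts, QED, library summaries, and correlations.
4. **Chemical-space analysis** (`delforge.chemspace`): FCFP4-style
   fingerprints, UMAP (n_neighbors = 50, jaccard) fitted on the reference
   population only, Gaussian KDE with Scott's rule on a shared grid, and
   occupied-area / occupancy-rate metrics at a 0.01 density threshold.
5. **Synthetic data** (`delforge.synthetic`): seeded generators for
   class-valid building blocks straddling the Ro2 boundary and an
   approved-drug-like reference mixture with a peptide-like heavy tail —
   every stage is testable without downloads.

## CLI

```bash
# synthetic inputs
delforge simulate bbs --bb-class carboxylic_acid --n 400 --seed 1 -o acids.smi
delforge simulate reference --n 3594 --seed 1 -o reference.smi

# stage by stage
delforge curate acids.smi --bb-class carboxylic_acid --k 200 -o bbs_ca.csv --report report.json
delforge enumerate --scheme D --bb1 bbs_ca.csv --bb2 bbs_ca.csv -o library_D.csv
delforge profile library_D.csv -o profiles.csv --summary summary_D.json
delforge embed --reference reference.smi --library library_D.csv --out-dir coords/
delforge occupancy --reference-coords coords/coords_reference.csv \
    --library-coords coords/coords_library_D.csv -o occupancy.json

# everything at once (config optional)
delforge run-full --config config.yaml --out-dir results/

# adapter for a locally downloaded ChEMBL export (SMILES + max_phase table)
delforge chembl-import chembl_approved.csv -o approved_stats.json
```

A `run-full` config is YAML with the fields of
`delforge.pipeline.RunConfig` (seed, k, schemes, synthetic-generator
sizes or input file paths, UMAP and KDE parameters, output directory).
Every run writes per-library warhead CSVs, summary JSONs, occupancy
reports, and a `manifest.json` carrying the full parameter provenance;
reruns with the same config are byte-identical.

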