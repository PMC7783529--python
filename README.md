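# wormvol

Calibrated cell- and tissue-volume estimation from triangle meshes of a
whole-organism model (young-adult *C. elegans*).

The pipeline:

1. **mesh_io** — reads per-cell triangle meshes (OBJ, PLY ascii/binary,
   STL ascii/binary) organized as `<root>/<tissue>/<cell>.<ext>`, and can
   bake affine transforms into vertex coordinates.
2. **volumetrics** — validates meshes (watertightness, manifoldness,
   orientation), computes divergence-theorem signed volumes with
   compensated summation, and calibrates model units to µm³ against a
   reference object of known size (by convention a cube representing
   100 µm edge ↔ 1,000,000 µm³).
3. **anatomy** — joins measurements with a cell→tissue table carrying
   syncytial nuclei counts and per-nucleus ploidy (C-values); diploid
   genome equivalents are `nuclei × C / 2`. A literature-derived fixture
   table (WormAtlas / WormBase anatomy ontology) is bundled. Regrouping
   rules split e.g. cuticle out of hypodermis collections or
   rachis/germ cells out of gonad collections without touching volumes.
4. **aggregate** — tissue totals, volume/nuclei/genome fractions,
   rankings, volume-per-diploid-genome normalization, size-distribution
   threshold statistics, and extreme-cell ratios.
5. **synthetic** — seeded generator of complete synthetic "worms"
   (meshes with analytically known volumes, calibration cube, anatomy
   CSV, ground-truth manifest) for end-to-end verification.

## CLI

```sh
# generate a synthetic worm with ground truth
wormvol simulate --out worm --seed 42

# validate every mesh (exit 1 with --strict if any is defective)
wormvol validate worm/meshes

# calibrated per-cell volumes (reference object "100um_cube" = 1e6 µm³)
wormvol measure --root worm/meshes --out worm/cell_volumes.csv

# tissue summaries, distribution stats, ranking, extreme ratios
wormvol report --measurements worm/cell_volumes.csv \
    --anatomy worm/anatomy.csv --out-dir worm/report
```

`report` excludes the extracellular cuticle from fraction analyses by
default (`--exclude` to change), toggles the germline pseudo-record with
`--include-germline/--somatic-only`, and uses distribution thresholds of
200 and 1000 µm³ unless overridden. Options can also come from a YAML
config (`--config`), with flags taking precedence. Pass `--no-timestamp`
for byte-stable outputs; `--plots` adds PNG figures.

To analyze a real mesh export instead of a synthetic worm, export each
cell to OBJ/PLY/STL under one directory per tissue, include the
calibration reference object, and supply an anatomy CSV with columns
`cell,tissue,somatic,nuclei,ploidy_c` (see
`src/wormvol/data/anatomy.csv` for the bundled fixture and its
conventions).

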