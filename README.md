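# snapqsar

Image-based QSAR pipeline for agonist/antagonist activity prediction. One
sequential "one-unit" flow turns a SMILES + assay-activity table into a
multi-angle 3D snapshot image dataset, trains an image classifier, and
evaluates it with a full binary-classification metric suite:

1. **assay_prep** — ingest CSV/TSV activity tables, normalize raw well
   readings to % activity (`(Vcompound − Vdmso)/(Vpos − Vdmso) × 100`),
   band scores into inactive / inconclusive / active (0 / 1–39 / 40–100,
   active ⇔ score ≥ 40), deduplicate on canonical SMILES, and split into
   train/valid/test (+ permanently fixed foldout) by largest-remainder
   apportionment of ratio specs like 1:1:1 or 7:1:4, stratified on the label.
2. **conformer3d** — SMILES → one explicit-hydrogen 3D conformer (RDKit
   ETKDGv3 + MMFF/UFF minimization, seeded) with plain-text SDF V2000 I/O.
3. **snapshot_render** — enumerate rotational viewpoints from per-axis angle
   increments (k·θ < 360° per axis, Cartesian product over x/y/z; e.g.
   θ = 195° → 8 images, 176° → 27, 100° → 64) and rasterize deterministic
   256×256 RGB ball-and-stick PNGs with configurable background colors
   (PyMOL-style named palette).
4. **cnn_harness** — seeded NumPy CNN (pure-NumPy conv/backprop/Adam; a
   `googlenet_like` mini-inception variant is included), 30-epoch budget
   with checkpoint selection at minimum validation loss, per-image →
   per-molecule probability pooling, N = 3 replicate averaging, and
   resumable grid sweeps over angle / split ratio / LR / batch size /
   background color.
5. **metrics** — contingency tables, Youden-index cutoff, sensitivity,
   specificity, BAC, Acc, precision, recall, F, MCC, ROC_AUC (Mann–Whitney),
   PR_AUC (average precision).
6. **fixtures** — seedable toy assays whose actives carry a geometry-visible
   polybrominated-aryl marker, so the full pipeline is testable offline.
7. **pipeline** — the orchestrator: prepare → conformers → snapshots →
   train → evaluate from one YAML config, with content-hash stage caching
   and a JSON run record.

## CLI

```bash
snapqsar run-all --config config.yaml          # full pipeline
snapqsar prepare --config config.yaml          # molecules.csv only
snapqsar snapshot --config config.yaml         # + conformers.sdf, images/
snapqsar train --config config.yaml            # + model reports
snapqsar evaluate --config config.yaml --split test
snapqsar sweep --config config.yaml \
    --grid '{"theta": [[195,195,195],[176,176,176]], "ratios": [[1,1,1],[3,1,2]]}'
```

Minimal config (all keys optional; defaults shown in
`snapqsar.pipeline.DEFAULT_CONFIG`):

```yaml
data:
  input_csv: assay.csv      # or: fixture: {n: 60, prevalence: 0.35, seed: 0}
  ratios: [1, 1, 1]
  foldout_fraction: 0.0
  seed: 0
render:
  theta: [195, 195, 195]
  image_size: 256
  background: white         # any PyMOL-style name or [r, g, b] in 0-1
train:
  learning_rate: 0.002
  batch_size: 16
  max_epochs: 30
  replicates: 3
out_dir: run
```

Input tables need a header with a `smiles` column plus either
`activity_score` (0–100) or the raw triple `v_compound,v_dmso,v_pos`.

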