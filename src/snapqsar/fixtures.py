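"""Seedable synthetic assay generators with a known structure-label signal.

Active molecules carry a geometry-visible marker — a polybrominated aryl
ring, rendered as large dark red-brown spheres — so the image channel, not
the SMILES text, carries the learnable signal. Inactives are halogen-free
alkyl/aryl scaffolds. Everything is deterministic per seed and emits the same
CSV/SDF/PNG/manifest formats as the real pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from snapqsar.assay_prep import (
    AssayRecord,
    MoleculeRecord,
    SplitPlan,
    canonicalize_smiles,
    deduplicate,
    prepare_molecules,
    split_dataset,
)

__all__ = [
    "ToyAssay",
    "generate_toy_assay",
    "generate_image_fixture",
    "permute_manifest_labels",
]


@dataclass
class ToyAssay:
    records: list[AssayRecord]
    prevalence: float
    signal_rule: str
    seed: int


# halogen-free substituents shared by actives and inactives
_TAILS = ["C", "CC", "CCC", "CCCC", "CO", "CCO", "C(C)C", "CN", "CCN",
          "C(=O)C", "C(=O)O", "CC(C)C", "CCCO", "C(C)O", "CC(=O)C",
          "CCC(C)C", "COC", "CCOC", "CC(C)O", "CCCN"]
_INACTIVE_CORES = ["c1ccccc1", "C1CCCCC1", "c1ccncc1", "C1CCOCC1",
                   "c1ccc(O)cc1", "C1CCNCC1", "c1ccc(N)cc1", "c1ccco1",
                   "C1CCCC1", "c1ccc(C)cc1"]
# every active carries >= 2 bromines on an aryl ring
_ACTIVE_CORES = ["c1cc(Br)cc(Br)c1", "c1ccc(Br)c(Br)c1",
                 "c1cc(Br)c(Br)cc1Br", "c1c(Br)cc(Br)cc1Br"]


def _unique_smiles(builder, rng, count: int, seen: set[str]) -> list[str]:
    out: list[str] = []
    guard = 0
    while len(out) < count:
        guard += 1
        if guard > 200 * count + 1000:
            raise RuntimeError("could not generate enough unique SMILES")
        smi = builder(rng)
        canonical = canonicalize_smiles(smi)
        if canonical is None or canonical in seen:
            continue
        seen.add(canonical)
        out.append(smi)
    return out


def _build_active(rng) -> str:
    core = _ACTIVE_CORES[rng.integers(len(_ACTIVE_CORES))]
    tail = _TAILS[rng.integers(len(_TAILS))]
    return (tail + core) if rng.random() < 0.85 else core


def _build_inactive(rng) -> str:
    core = _INACTIVE_CORES[rng.integers(len(_INACTIVE_CORES))]
    tail = _TAILS[rng.integers(len(_TAILS))]
    return (tail + core) if rng.random() < 0.85 else core


def generate_toy_assay(n: int, prevalence: float, seed: int) -> ToyAssay:
    """n unique molecules; round(n * prevalence) actives (score >= 40) all
    carrying the bromo-aryl marker, the rest halogen-free with score < 40."""
    if n < 4:
        raise ValueError("n must be >= 4")
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must lie in (0, 1)")
    n_active = int(round(n * prevalence))
    if n_active < 1:
        raise ValueError("infeasible: n * prevalence < 1")

    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    active_smiles = _unique_smiles(_build_active, rng, n_active, seen)
    inactive_smiles = _unique_smiles(_build_inactive, rng, n - n_active, seen)

    records = []
    for i, smi in enumerate(active_smiles):
        score = float(40.0 + 60.0 * rng.random())
        records.append(AssayRecord(compound_id=f"act{i:04d}", smiles=smi,
                                   activity_score=round(score, 2)))
    for i, smi in enumerate(inactive_smiles):
        # mix of flat-zero and inconclusive scores, mirroring the 0 / 1-39 bands
        score = 0.0 if rng.random() < 0.6 else float(1.0 + 38.0 * rng.random())
        records.append(AssayRecord(compound_id=f"ina{i:04d}", smiles=smi,
                                   activity_score=round(score, 2)))
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    return ToyAssay(records=records, prevalence=prevalence,
                    signal_rule="active iff >=2 aryl bromines", seed=seed)


def prepare_toy_molecules(assay: ToyAssay,
                          plan: SplitPlan) -> list[MoleculeRecord]:
    """prepare -> dedupe -> split, as the real pipeline would."""
    return split_dataset(deduplicate(prepare_molecules(assay.records)), plan)


def generate_image_fixture(assay: ToyAssay, theta: Sequence[float], seed: int,
                           out_dir: str | Path,
                           ratios: tuple[int, int, int] = (1, 1, 1),
                           foldout_fraction: float = 0.0,
                           background="white",
                           image_size: int = 256) -> pd.DataFrame:
    """Full prepare -> embed -> render run at toy scale; returns the image
    manifest (len == n_molecules * prod(ceil(360/theta)))."""
    from snapqsar.conformer3d import smiles_to_conformer
    from snapqsar.snapshot_render import SnapshotSpec, generate_snapshots

    plan = SplitPlan(ratios=ratios, foldout_fraction=foldout_fraction,
                     seed=seed, stratified=True)
    molecules = prepare_toy_molecules(assay, plan)
    conformers = [smiles_to_conformer(m.canonical_smiles, embed_seed=seed,
                                      compound_id=m.compound_id)
                  for m in molecules]
    info = {m.compound_id: {"split": m.split, "label": m.label}
            for m in molecules}
    spec = SnapshotSpec(theta=tuple(theta), image_size=image_size,
                        background=background)
    return generate_snapshots(conformers, spec, out_dir,
                              molecule_info=info, overwrite=False)


def permute_manifest_labels(manifest: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Null-control variant: permute labels across molecules (consistently
    for all snapshots of a molecule), preserving prevalence."""
    rng = np.random.default_rng(seed)
    mols = manifest.drop_duplicates("compound_id")[["compound_id", "label"]]
    permuted = mols["label"].to_numpy()[rng.permutation(len(mols))]
    mapping = dict(zip(mols["compound_id"], permuted))
    out = manifest.copy()
    out["label"] = out["compound_id"].map(mapping)
    return out
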