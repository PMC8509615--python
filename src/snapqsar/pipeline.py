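"""Sequential one-unit orchestrator: prepare -> conformers -> snapshots ->
train -> evaluate, driven by a single YAML-able config dict, with
content-hash caching and a JSON run record.

Directory layout under ``out_dir``::

    molecules.csv  conformers.sdf  images/  manifest.csv  reports/
    run_record.json  .stage_hashes.json
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd

from snapqsar import __version__ as _pkg_version
from snapqsar.assay_prep import (
    SplitPlan,
    deduplicate,
    load_assay_table,
    prepare_molecules,
    read_molecules_csv,
    split_dataset,
    write_molecules_csv,
)
from snapqsar.cnn_harness import (
    TrainConfig,
    evaluate_split,
    replicate_average,
    train_model,
)
from snapqsar.conformer3d import (
    EmbeddingError,
    read_sdf,
    smiles_to_conformer,
    write_sdf,
)
from snapqsar.snapshot_render import SnapshotSpec, generate_snapshots

__all__ = ["StageError", "run_all", "DEFAULT_CONFIG", "load_config"]


DEFAULT_CONFIG: dict = {
    "data": {
        "input_csv": None,
        "fixture": None,  # {"n": 60, "prevalence": 0.35}
        "ratios": [1, 1, 1],
        "foldout_fraction": 0.0,
        "stratified": True,
        "seed": 0,
    },
    "render": {
        "theta": [195, 195, 195],
        "image_size": 256,
        "background": "white",
    },
    "train": {
        "learning_rate": 2e-3,
        "batch_size": 16,
        "max_epochs": 30,
        "seed": 0,
        "architecture": "small_cnn",
        "replicates": 3,
        "input_size": 32,
    },
    "eval": {
        "cutoff_policy": "youden_self",
        "aggregate": "mean",
    },
    "out_dir": "run",
}


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: dict) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for section, values in user.items():
        if isinstance(values, dict):
            cfg.setdefault(section, {}).update(values)
        else:
            cfg[section] = values
    return cfg


def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


class _Cache:
    def __init__(self, out_dir: Path):
        self.path = out_dir / ".stage_hashes.json"
        self.hashes = (json.loads(self.path.read_text())
                       if self.path.exists() else {})

    def fresh(self, stage: str, key: str, outputs: list[Path]) -> bool:
        return (self.hashes.get(stage) == key
                and all(p.exists() for p in outputs))

    def store(self, stage: str, key: str) -> None:
        self.hashes[stage] = key
        self.path.write_text(json.dumps(self.hashes, indent=1))


def _stage_prepare(cfg, out_dir, cache):
    data = cfg["data"]
    key = _hash(data)
    out = out_dir / "molecules.csv"
    if cache.fresh("prepare", key, [out]):
        return read_molecules_csv(out), True
    if data.get("input_csv"):
        records = load_assay_table(data["input_csv"])
    elif data.get("fixture"):
        from snapqsar.fixtures import generate_toy_assay

        fx = data["fixture"]
        records = generate_toy_assay(
            int(fx["n"]), float(fx.get("prevalence", 0.35)),
            int(fx.get("seed", data.get("seed", 0)))).records
    else:
        raise StageError("prepare", "config needs data.input_csv or data.fixture")
    plan = SplitPlan(ratios=tuple(data["ratios"]),
                     foldout_fraction=float(data["foldout_fraction"]),
                     seed=int(data["seed"]),
                     stratified=bool(data["stratified"]))
    molecules = split_dataset(deduplicate(prepare_molecules(records)), plan)
    if not molecules:
        raise StageError("prepare", "no valid molecules after preparation")
    write_molecules_csv(molecules, out)
    cache.store("prepare", key)
    return molecules, False


def _stage_conformers(cfg, molecules, out_dir, cache):
    key = _hash([cfg["data"], [m.canonical_smiles for m in molecules]])
    out = out_dir / "conformers.sdf"
    if cache.fresh("conformers", key, [out]):
        return read_sdf(out), True
    conformers, skipped = [], []
    for m in molecules:
        try:
            conformers.append(smiles_to_conformer(
                m.canonical_smiles, embed_seed=int(cfg["data"]["seed"]),
                compound_id=m.compound_id))
        except EmbeddingError:
            skipped.append(m.compound_id)
    if skipped:
        import logging

        logging.getLogger(__name__).warning(
            "embedding skipped %d molecules: %s", len(skipped), skipped[:5])
    if not conformers:
        raise StageError("conformers", "no molecule could be embedded")
    write_sdf(conformers, out)
    cache.store("conformers", key)
    return conformers, False


def _stage_snapshot(cfg, molecules, conformers, out_dir, cache):
    render = cfg["render"]
    key = _hash([render, cfg["data"]])
    manifest_path = out_dir / "manifest.csv"
    if cache.fresh("snapshot", key, [manifest_path]):
        return pd.read_csv(manifest_path), True
    try:
        spec = SnapshotSpec(theta=tuple(render["theta"]),
                            image_size=int(render["image_size"]),
                            background=render["background"])
    except (KeyError, ValueError) as exc:
        raise StageError("render", str(exc)) from exc
    info = {m.compound_id: {"split": m.split, "label": m.label}
            for m in molecules}
    manifest = generate_snapshots(conformers, spec, out_dir / "images",
                                  molecule_info=info, overwrite=False)
    manifest.to_csv(manifest_path, index=False)
    cache.store("snapshot", key)
    return manifest, False


def _stage_train_eval(cfg, manifest, out_dir, cache):
    train, ev = cfg["train"], cfg["eval"]
    key = _hash([train, ev, cfg["render"], cfg["data"]])
    reports_dir = out_dir / "reports"
    summary_path = reports_dir / "summary.json"
    if cache.fresh("train", key, [summary_path]):
        return json.loads(summary_path.read_text()), True
    reports_dir.mkdir(parents=True, exist_ok=True)
    base = TrainConfig(
        learning_rate=float(train["learning_rate"]),
        batch_size=int(train["batch_size"]),
        max_epochs=int(train["max_epochs"]),
        seed=int(train["seed"]),
        architecture=train["architecture"],
        replicate_count=int(train["replicates"]),
        input_size=int(train["input_size"]),
        aggregate=ev["aggregate"],
        cutoff_policy=ev["cutoff_policy"],
    )
    from dataclasses import replace

    splits = [s for s in ("valid", "test", "foldout")
              if (manifest["split"] == s).any()]
    per_split: dict[str, list] = {s: [] for s in splits}
    configs = []
    image_cache: dict = {}
    for r in range(base.replicate_count):
        rcfg = replace(base, seed=base.seed + r)
        run = train_model(manifest, rcfg, image_cache)
        configs.append(rcfg)
        for s in splits:
            per_split[s].append(evaluate_split(run, s))
    summary = {"n_replicates": base.replicate_count, "splits": {}}
    for s in splits:
        avg = replicate_average(per_split[s], configs)
        summary["splits"][s] = avg.to_dict()
        (reports_dir / f"{s}.json").write_text(
            json.dumps(avg.to_dict(), indent=1))
    summary_path.write_text(json.dumps(summary, indent=1))
    cache.store("train", key)
    return summary, False


def run_all(config: dict, out_dir: str | Path | None = None) -> dict:
    """Execute every stage in order; returns the run record (also written to
    ``out_dir/run_record.json``). A stage failure raises StageError."""
    cfg = merge_config(config)
    out_dir = Path(out_dir or cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    cache = _Cache(out_dir)

    record: dict = {
        "config": cfg,
        "config_hash": _hash(cfg),
        "versions": {"snapqsar": _pkg_version},
        "stages": {},
    }
    try:
        import numpy
        import rdkit

        record["versions"]["numpy"] = numpy.__version__
        record["versions"]["rdkit"] = rdkit.__version__
    except Exception:
        pass

    def timed(stage, fn, *args):
        t0 = time.perf_counter()
        try:
            result, cached = fn(*args)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        record["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "cached": cached,
        }
        return result

    molecules = timed("prepare", _stage_prepare, cfg, out_dir, cache)
    conformers = timed("conformers", _stage_conformers, cfg, molecules,
                       out_dir, cache)
    manifest = timed("snapshot", _stage_snapshot, cfg, molecules, conformers,
                     out_dir, cache)
    summary = timed("train", _stage_train_eval, cfg, manifest, out_dir, cache)

    record["outputs"] = {
        "molecules": str(out_dir / "molecules.csv"),
        "conformers": str(out_dir / "conformers.sdf"),
        "manifest": str(out_dir / "manifest.csv"),
        "reports": str(out_dir / "reports"),
    }
    record["metrics"] = summary
    (out_dir / "run_record.json").write_text(
        json.dumps(record, indent=1, default=str))
    return record
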