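"""Activity-table ingestion, normalization, labeling, deduplication and
train/valid/test/foldout splitting.

Raw well readings are normalized to a 0-100 % activity scale:

    % activity = (Vcompound - Vdmso) / (Vpos - Vdmso) * 100

Scores are banded into three classes — 0 (inactive), 1-39 (inconclusive),
40-100 (active) — and binarized with active := score >= 40.
"""

from __future__ import annotations

import csv
import hashlib
import io
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AssayRecord",
    "MoleculeRecord",
    "SplitPlan",
    "DegenerateNormalizationError",
    "percent_activity",
    "classify_activity",
    "canonicalize_smiles",
    "deduplicate",
    "largest_remainder",
    "split_dataset",
    "load_assay_table",
    "prepare_molecules",
    "write_molecules_csv",
    "read_molecules_csv",
]

ACTIVE_THRESHOLD = 40.0

SPLIT_NAMES = ("train", "valid", "test")


class DegenerateNormalizationError(ValueError):
    """Raised when the positive-control and solvent-control medians coincide."""


@dataclass(frozen=True)
class AssayRecord:
    """One row of an ingested activity table.

    Carries either a precomputed ``activity_score`` in [0, 100] or the raw
    well triple (``v_compound``, ``v_dmso``, ``v_pos``).
    """

    compound_id: str
    smiles: str
    v_compound: float | None = None
    v_dmso: float | None = None
    v_pos: float | None = None
    activity_score: float | None = None

    def __post_init__(self) -> None:
        has_raw = None not in (self.v_compound, self.v_dmso, self.v_pos)
        if self.activity_score is None and not has_raw:
            raise ValueError(
                f"{self.compound_id}: need activity_score or the raw "
                "(v_compound, v_dmso, v_pos) triple")
        if self.activity_score is not None and not (
                0.0 <= self.activity_score <= 100.0):
            raise ValueError(
                f"{self.compound_id}: activity_score outside [0, 100]")


@dataclass(frozen=True)
class MoleculeRecord:
    """One deduplicated compound with score, classes and split assignment."""

    compound_id: str
    canonical_smiles: str
    activity_score: float
    ternary_class: str  # inactive | inconclusive | active
    label: int  # 1 iff activity_score >= 40
    split: str = "unassigned"  # train | valid | test | foldout | unassigned
    raw_score: float | None = None  # unclamped value, if computed from wells


@dataclass(frozen=True)
class SplitPlan:
    """Deterministic splitting recipe.

    ``ratios`` are the train:valid:test proportions; ``foldout_fraction``
    of records is carved out first (permanently fixed: its membership is a
    pure function of canonical SMILES, independent of ``seed``).
    """

    ratios: tuple[int, int, int] = (1, 1, 1)
    foldout_fraction: float = 0.0
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if len(self.ratios) != 3 or any(r <= 0 for r in self.ratios):
            raise ValueError("ratios must be three positive integers")
        if not (0.0 <= self.foldout_fraction < 1.0):
            raise ValueError("foldout_fraction must lie in [0, 1)")


def percent_activity(v_compound: float, v_dmso: float, v_pos: float) -> float:
    """Normalize a compound well against DMSO and positive-control medians.

    Returns 100*(v_compound - v_dmso)/(v_pos - v_dmso); the result may fall
    outside [0, 100] (the caller clamps before classing).
    """
    if v_pos == v_dmso:
        raise DegenerateNormalizationError(
            "v_pos equals v_dmso: normalization is degenerate")
    return 100.0 * (v_compound - v_dmso) / (v_pos - v_dmso)


def classify_activity(score: float) -> tuple[str, int]:
    """Map a 0-100 score to (ternary_class, binary label).

    Bands: 0 -> inactive, (0, 40) -> inconclusive, [40, 100] -> active.
    Binary label is 1 iff score >= 40.
    """
    if not (0.0 <= score <= 100.0):
        raise ValueError(f"score {score} outside [0, 100]")
    if score >= ACTIVE_THRESHOLD:
        return "active", 1
    if score == 0.0:
        return "inactive", 0
    return "inconclusive", 0


def canonicalize_smiles(smiles: str) -> str | None:
    """Canonical isomeric SMILES via RDKit, or None if unparseable."""
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol, isomericSmiles=True)


def prepare_molecules(records: Iterable[AssayRecord]) -> list[MoleculeRecord]:
    """Score, classify and canonicalize assay records.

    Records whose SMILES cannot be parsed are rejected with a log line, not
    fatally. Scores computed from raw wells are clamped to [0, 100] for
    classing; the unclamped value is kept in ``raw_score``.
    """
    out: list[MoleculeRecord] = []
    for rec in records:
        canonical = canonicalize_smiles(rec.smiles)
        if canonical is None:
            logger.warning("rejecting %s: unparseable SMILES %r",
                           rec.compound_id, rec.smiles)
            continue
        raw = None
        if rec.activity_score is not None:
            score = float(rec.activity_score)
        else:
            raw = percent_activity(rec.v_compound, rec.v_dmso, rec.v_pos)
            score = float(np.clip(raw, 0.0, 100.0))
        ternary, label = classify_activity(score)
        out.append(MoleculeRecord(
            compound_id=rec.compound_id, canonical_smiles=canonical,
            activity_score=score, ternary_class=ternary, label=label,
            raw_score=raw))
    return out


def deduplicate(records: Sequence[MoleculeRecord]) -> list[MoleculeRecord]:
    """One record per canonical SMILES.

    Conflict policy: keep the record with the maximum activity score
    (conservative toward activity). Output preserves first-occurrence order.
    """
    best: dict[str, MoleculeRecord] = {}
    order: list[str] = []
    for rec in records:
        key = rec.canonical_smiles
        if key not in best:
            best[key] = rec
            order.append(key)
        elif rec.activity_score > best[key].activity_score:
            best[key] = rec
    return [best[k] for k in order]


def largest_remainder(n: int, ratios: Sequence[int]) -> list[int]:
    """Apportion n items to the ratios by the largest-remainder method.

    Ties in the fractional remainders are broken by position order.
    """
    total = sum(ratios)
    quotas = [n * r / total for r in ratios]
    sizes = [int(q) for q in quotas]
    leftover = n - sum(sizes)
    remainders = sorted(range(len(ratios)),
                        key=lambda i: (-(quotas[i] - sizes[i]), i))
    for i in remainders[:leftover]:
        sizes[i] += 1
    return sizes


def _smiles_rank(smiles: str) -> int:
    """Stable, seed-free ordering key used for foldout carving."""
    return int.from_bytes(hashlib.sha256(smiles.encode()).digest()[:8], "big")


def _stratified_sizes(strata_sizes: Sequence[int],
                      ratios: Sequence[int]) -> list[list[int]]:
    """Per-stratum split sizes whose column sums equal the global
    largest-remainder apportionment of the pooled count."""
    n = sum(strata_sizes)
    target = largest_remainder(n, ratios)
    per = [largest_remainder(s, ratios) for s in strata_sizes]
    cols = [sum(p[j] for p in per) for j in range(len(ratios))]
    # transportation fix-up: move single units from over- to under-target splits
    while cols != target:
        j_over = next(j for j in range(len(ratios)) if cols[j] > target[j])
        j_under = next(j for j in range(len(ratios)) if cols[j] < target[j])
        donor = max(range(len(per)),
                    key=lambda i: (per[i][j_over], strata_sizes[i], -i))
        per[donor][j_over] -= 1
        per[donor][j_under] += 1
        cols = [sum(p[j] for p in per) for j in range(len(ratios))]
    return per


def split_dataset(records: Sequence[MoleculeRecord],
                  plan: SplitPlan) -> list[MoleculeRecord]:
    """Assign every record to exactly one of train/valid/test/foldout.

    The foldout subset (``plan.foldout_fraction`` of each label stratum) is
    carved out first by a seed-free hash order on canonical SMILES, so it is
    permanently fixed across reruns and seeds. The remainder is shuffled with
    ``plan.seed`` and apportioned to the ratios by largest remainder,
    stratified on the binary label when ``plan.stratified``.
    """
    records = list(records)
    foldout_keys: set[str] = set()
    if plan.foldout_fraction > 0:
        for label in (0, 1):
            stratum = [r for r in records if r.label == label]
            k = int(round(plan.foldout_fraction * len(stratum)))
            ranked = sorted(stratum,
                            key=lambda r: _smiles_rank(r.canonical_smiles))
            foldout_keys.update(r.canonical_smiles for r in ranked[:k])

    remaining = [r for r in records if r.canonical_smiles not in foldout_keys]
    if plan.stratified:
        strata = [[r for r in remaining if r.label == lab] for lab in (0, 1)]
        strata = [s for s in strata if s]
    else:
        strata = [remaining]
    for s in strata:
        if 0 < len(s) < len(SPLIT_NAMES):
            warnings.warn(
                f"stratum of size {len(s)} is smaller than the number of "
                "splits; best-effort assignment", stacklevel=2)

    rng = np.random.default_rng(plan.seed)
    per_sizes = _stratified_sizes([len(s) for s in strata], plan.ratios)
    assignment: dict[str, str] = {}
    for stratum, sizes in zip(strata, per_sizes):
        idx = rng.permutation(len(stratum))
        pos = 0
        for split_name, size in zip(SPLIT_NAMES, sizes):
            for i in idx[pos:pos + size]:
                assignment[stratum[i].canonical_smiles] = split_name
            pos += size

    out = []
    for rec in records:
        if rec.canonical_smiles in foldout_keys:
            out.append(replace(rec, split="foldout"))
        else:
            out.append(replace(rec, split=assignment[rec.canonical_smiles]))
    return out


# ---------------------------------------------------------------------------
# table I/O


def load_assay_table(path: str | Path) -> list[AssayRecord]:
    """Read a CSV/TSV activity table (delimiter sniffed, header required).

    Required column: ``smiles``. Optional: ``compound_id`` and either
    ``activity_score`` or the triple ``v_compound, v_dmso, v_pos``.
    """
    text = Path(path).read_text()
    try:
        dialect = csv.Sniffer().sniff(text.splitlines()[0], delimiters=",\t;")
    except csv.Error:
        dialect = csv.excel
    reader = csv.DictReader(io.StringIO(text), dialect=dialect)
    if reader.fieldnames is None or "smiles" not in reader.fieldnames:
        raise ValueError(f"{path}: header with a 'smiles' column is required")
    records = []
    for i, row in enumerate(reader):
        cid = row.get("compound_id") or f"cmpd{i:05d}"

        def num(key):
            v = row.get(key)
            return float(v) if v not in (None, "") else None

        records.append(AssayRecord(
            compound_id=cid, smiles=row["smiles"],
            v_compound=num("v_compound"), v_dmso=num("v_dmso"),
            v_pos=num("v_pos"), activity_score=num("activity_score")))
    return records


def write_molecules_csv(records: Sequence[MoleculeRecord],
                        path: str | Path) -> None:
    df = pd.DataFrame([{
        "compound_id": r.compound_id,
        "canonical_smiles": r.canonical_smiles,
        "activity_score": r.activity_score,
        "ternary_class": r.ternary_class,
        "label": r.label,
        "split": r.split,
        "raw_score": "" if r.raw_score is None else r.raw_score,
    } for r in records])
    df.to_csv(path, index=False)


def read_molecules_csv(path: str | Path) -> list[MoleculeRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    return [MoleculeRecord(
        compound_id=str(row.compound_id),
        canonical_smiles=row.canonical_smiles,
        activity_score=float(row.activity_score),
        ternary_class=row.ternary_class,
        label=int(row.label),
        split=row.split,
        raw_score=None if row.raw_score == "" else float(row.raw_score),
    ) for row in df.itertuples()]
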