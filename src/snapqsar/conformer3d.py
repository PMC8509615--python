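"""SMILES -> single explicit-hydrogen 3D conformer, plus SDF V2000 I/O.

Embedding uses RDKit distance geometry (ETKDGv3) with a fixed random seed,
followed by MMFF94 minimization (UFF fallback). One conformer per molecule;
for salts/mixtures the largest covalent fragment is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Conformer3D",
    "InvalidSmilesError",
    "EmbeddingError",
    "SdfFormatError",
    "smiles_to_conformer",
    "write_sdf",
    "read_sdf",
]

DEFAULT_EMBED_SEED = 2021


class InvalidSmilesError(ValueError):
    pass


class EmbeddingError(RuntimeError):
    pass


class SdfFormatError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None
                         else f"line {line}: {message}")


@dataclass
class Conformer3D:
    """One embedded 3D structure: atoms as (element, x, y, z) in Angstrom,
    bonds as (i, j, order) with 0-based indices and integer orders."""

    atoms: list[tuple[str, float, float, float]]
    bonds: list[tuple[int, int, int]]
    source_smiles: str = ""
    embed_seed: int = DEFAULT_EMBED_SEED
    compound_id: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("conformer must have at least one atom")
        n = len(self.atoms)
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise ValueError(f"bond ({i},{j}) indices out of range")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def coords(self) -> np.ndarray:
        return np.array([[x, y, z] for _, x, y, z in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [el for el, *_ in self.atoms]

    def with_coords(self, coords: np.ndarray) -> "Conformer3D":
        atoms = [(el, float(x), float(y), float(z))
                 for (el, *_), (x, y, z) in zip(self.atoms, coords)]
        return Conformer3D(atoms=atoms, bonds=list(self.bonds),
                           source_smiles=self.source_smiles,
                           embed_seed=self.embed_seed,
                           compound_id=self.compound_id)


def smiles_to_conformer(smiles: str, embed_seed: int = DEFAULT_EMBED_SEED,
                        compound_id: str = "") -> Conformer3D:
    """Embed one force-field-relaxed, explicit-hydrogen conformer.

    Deterministic for a fixed (smiles, embed_seed). Salts/mixtures keep the
    largest covalent fragment.
    """
    from rdkit import Chem, RDLogger
    from rdkit.Chem import AllChem

    RDLogger.DisableLog("rdApp.*")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"cannot parse SMILES {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    mol = Chem.AddHs(mol)

    conf_id = -1
    for attempt in range(5):
        params = AllChem.ETKDGv3()
        params.randomSeed = int(embed_seed) + attempt
        params.useRandomCoords = attempt >= 3
        conf_id = AllChem.EmbedMolecule(mol, params)
        if conf_id >= 0:
            break
    if conf_id < 0:
        raise EmbeddingError(f"embedding failed for {smiles!r}")

    try:
        if AllChem.MMFFHasAllMoleculeParams(mol):
            AllChem.MMFFOptimizeMolecule(mol, confId=conf_id)
        else:
            AllChem.UFFOptimizeMolecule(mol, confId=conf_id)
    except Exception:  # minimization failure leaves the raw DG geometry
        pass

    Chem.Kekulize(mol, clearAromaticFlags=True)
    conf = mol.GetConformer(conf_id)
    atoms = []
    for atom in mol.GetAtoms():
        p = conf.GetAtomPosition(atom.GetIdx())
        atoms.append((atom.GetSymbol(), float(p.x), float(p.y), float(p.z)))
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
              int(round(b.GetBondTypeAsDouble())))
             for b in mol.GetBonds()]
    return Conformer3D(atoms=atoms, bonds=bonds, source_smiles=smiles,
                       embed_seed=int(embed_seed), compound_id=compound_id)


# ---------------------------------------------------------------------------
# SDF V2000 serialization (plain text, 4-decimal coordinates)


def _mol_block(c: Conformer3D) -> str:
    lines = [c.compound_id, "  snapqsar", ""]
    lines.append(f"{len(c.atoms):3d}{len(c.bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    for el, x, y, z in c.atoms:
        lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {el:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
    for i, j, order in c.bonds:
        lines.append(f"{i + 1:3d}{j + 1:3d}{order:3d}  0")
    lines.append("M  END")
    return "\n".join(lines)


def write_sdf(conformers: Conformer3D | Sequence[Conformer3D],
              path: str | Path) -> None:
    """Write one or many conformers as an SDF V2000 file."""
    if isinstance(conformers, Conformer3D):
        conformers = [conformers]
    blocks = [_mol_block(c) + "\n$$$$\n" for c in conformers]
    Path(path).write_text("".join(blocks))


def read_sdf(path: str | Path) -> list[Conformer3D]:
    """Parse an SDF V2000 file; malformed blocks raise SdfFormatError with
    the offending 1-based line number."""
    lines = Path(path).read_text().splitlines()
    out: list[Conformer3D] = []
    pos = 0
    while pos < len(lines):
        if all(not ln.strip() for ln in lines[pos:]):
            break
        name = lines[pos].strip()
        counts_at = pos + 3
        if counts_at >= len(lines):
            raise SdfFormatError("truncated header", line=pos + 1)
        counts = lines[counts_at]
        try:
            n_atoms = int(counts[0:3])
            n_bonds = int(counts[3:6])
        except (ValueError, IndexError):
            raise SdfFormatError(f"malformed counts line {counts!r}",
                                 line=counts_at + 1) from None
        atoms = []
        for k in range(n_atoms):
            ln_no = counts_at + 1 + k
            if ln_no >= len(lines):
                raise SdfFormatError("atom block truncated", line=ln_no + 1)
            ln = lines[ln_no]
            try:
                x, y, z = float(ln[0:10]), float(ln[10:20]), float(ln[20:30])
                el = ln[31:34].strip()
                if not el or not el[0].isalpha():
                    raise ValueError
            except ValueError:
                raise SdfFormatError(f"malformed atom line {ln!r}",
                                     line=ln_no + 1) from None
            atoms.append((el, x, y, z))
        bonds = []
        for k in range(n_bonds):
            ln_no = counts_at + 1 + n_atoms + k
            if ln_no >= len(lines):
                raise SdfFormatError("bond block truncated", line=ln_no + 1)
            ln = lines[ln_no]
            try:
                i, j, order = int(ln[0:3]), int(ln[3:6]), int(ln[6:9])
            except (ValueError, IndexError):
                raise SdfFormatError(f"malformed bond line {ln!r}",
                                     line=ln_no + 1) from None
            bonds.append((i - 1, j - 1, order))
        out.append(Conformer3D(atoms=atoms, bonds=bonds, compound_id=name))
        # advance to the record terminator
        pos = counts_at + 1 + n_atoms + n_bonds
        while pos < len(lines) and lines[pos].strip() != "$$$$":
            pos += 1
        pos += 1
    return out
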