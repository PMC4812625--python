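"""Reading, standardizing and deduplicating molecular structures.

Molecules enter the pipeline as SMILES, one per line, optionally followed by
a whitespace-separated identifier.  Standardization is deliberately minimal:
keep the largest fragment, perceive aromaticity, recompute the canonical
SMILES.  Vendor-specific normalizations (neutralization, nitro/azide
rewrites) can be injected through the ``transform`` hook but are off by
default -- the threshold-selection framework itself is agnostic to the
standardization dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

from rdkit import Chem, RDLogger

logger = logging.getLogger(__name__)

# RDKit reports parse failures on its own C++ logger; we log them ourselves.
RDLogger.DisableLog("rdApp.error")

MolTransform = Callable[[Chem.Mol], Chem.Mol]


@dataclass(frozen=True)
class MoleculeRecord:
    """A single molecule with its canonical form and heavy-atom count."""

    id: str
    smiles_raw: str
    smiles_canonical: str
    heavy_atom_count: int


def _parse(smiles: str) -> Chem.Mol | None:
    return Chem.MolFromSmiles(smiles)


def read_smiles(path: str | Path) -> list[MoleculeRecord]:
    """Read a SMILES file into molecule records, preserving file order.

    Each non-empty, non-comment line is ``SMILES[<whitespace>ID]``; missing
    identifiers are auto-assigned from the 0-based line index.  Unparseable
    lines are skipped with a logged warning.
    """
    records: list[MoleculeRecord] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(maxsplit=1)
            smiles = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else str(lineno)
            mol = _parse(smiles)
            if mol is None:
                n_skipped += 1
                logger.warning("line %d: unparseable SMILES %r skipped", lineno, smiles)
                continue
            records.append(
                MoleculeRecord(
                    id=mol_id,
                    smiles_raw=smiles,
                    smiles_canonical=Chem.MolToSmiles(mol),
                    heavy_atom_count=mol.GetNumHeavyAtoms(),
                )
            )
    if n_skipped:
        logger.warning("%d line(s) skipped while reading %s", n_skipped, path)
    return records


def standardize(record: MoleculeRecord, transform: MolTransform | None = None) -> MoleculeRecord:
    """Largest-fragment selection, aromatic perception, canonical SMILES.

    Fragment ties on heavy-atom count are broken toward the lexicographically
    smallest canonical SMILES (and logged).  ``transform`` is an optional
    extra normalization applied to the selected fragment.
    """
    mol = _parse(record.smiles_canonical or record.smiles_raw)
    if mol is None:
        raise ValueError(f"record {record.id!r} does not parse: {record.smiles_raw!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        keyed = sorted(
            frags,
            key=lambda f: (-f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)),
        )
        best = keyed[0]
        if keyed[1].GetNumHeavyAtoms() == best.GetNumHeavyAtoms():
            logger.warning(
                "record %s: fragment-size tie, keeping %s",
                record.id,
                Chem.MolToSmiles(best),
            )
        mol = best
    if transform is not None:
        mol = transform(mol)
    canonical = Chem.MolToSmiles(mol)
    return replace(
        record,
        smiles_canonical=canonical,
        heavy_atom_count=mol.GetNumHeavyAtoms(),
    )


def deduplicate(records: Iterable[MoleculeRecord]) -> list[MoleculeRecord]:
    """One record per distinct canonical SMILES; first occurrence wins."""
    seen: set[str] = set()
    out: list[MoleculeRecord] = []
    for rec in records:
        if rec.smiles_canonical in seen:
            continue
        seen.add(rec.smiles_canonical)
        out.append(rec)
    return out


def load_standardized(path: str | Path, transform: MolTransform | None = None) -> list[MoleculeRecord]:
    """Convenience chain: read -> standardize -> deduplicate."""
    return deduplicate(standardize(r, transform) for r in read_smiles(path))


def write_molecule_table(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    """TSV table of id, canonical SMILES and heavy-atom count."""
    with open(path, "w") as fh:
        fh.write("id\tcanonical_smiles\theavy_atoms\n")
        for rec in records:
            fh.write(f"{rec.id}\t{rec.smiles_canonical}\t{rec.heavy_atom_count}\n")


def write_smiles(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    """Plain ``SMILES<space>ID`` file readable by :func:`read_smiles`."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.smiles_canonical} {rec.id}\n")
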