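"""Molecular fingerprints as feature sets.

All fingerprint flavors are represented uniformly as a set of non-negative
integer features: the indices of bits set to 1 in a virtual bit vector whose
length W is the largest feature value plus one.  This makes the Tanimoto
coefficient a plain set computation regardless of whether the features come
from circular environments (ECFP), hashed linear paths, or structural keys.

Extended connectivity fingerprints of diameter d perform d/2 neighborhood
update iterations; the feature set of a molecule at diameter d is therefore
a superset of its feature set at diameter d-2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chem_io import MoleculeRecord

HASHED_LENGTHS = (1024, 2048, 4096)


@dataclass(frozen=True)
class FeatureFingerprint:
    """Duplicate-free set of hashed substructure identifiers.

    ``kind`` is one of ``ecfp``, ``hashed_binary`` or ``structural_key``;
    ``diameter`` is set for ECFPs (even, number of update iterations is
    diameter/2) and ``length`` for fixed-length fingerprints.
    """

    features: frozenset[int]
    kind: str
    diameter: int | None = None
    length: int | None = None

    @property
    def virtual_length(self) -> int:
        """Length W of the virtual bit vector with exactly |features| bits set."""
        return max(self.features) + 1 if self.features else 0

    def compatible_with(self, other: "FeatureFingerprint") -> bool:
        return (
            self.kind == other.kind
            and self.diameter == other.diameter
            and self.length == other.length
        )


def _as_mol(mol: MoleculeRecord | Chem.Mol) -> Chem.Mol:
    if isinstance(mol, MoleculeRecord):
        parsed = Chem.MolFromSmiles(mol.smiles_canonical)
        if parsed is None:
            raise ValueError(f"record {mol.id!r} does not parse")
        return parsed
    return mol


def ecfp(mol: MoleculeRecord | Chem.Mol, diameter: int = 4) -> FeatureFingerprint:
    """Extended connectivity fingerprint as a sparse feature set.

    ``diameter`` is the diameter of the circular environments (ECFP_4 means
    diameter 4, i.e. radius 2).  Features are 32-bit hashed environment
    identifiers over all atoms and iterations 0..d/2; duplicates collapse.
    """
    if diameter < 0 or diameter % 2:
        raise ValueError(f"ECFP diameter must be even and >= 0, got {diameter}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=diameter // 2)
    bits = gen.GetSparseFingerprint(_as_mol(mol)).GetOnBits()
    return FeatureFingerprint(frozenset(bits), kind="ecfp", diameter=diameter)


def hashed_binary(mol: MoleculeRecord | Chem.Mol, length: int = 2048) -> FeatureFingerprint:
    """Path-based fingerprint hashed into a fixed-length bit vector."""
    if length not in HASHED_LENGTHS:
        raise ValueError(f"unsupported length {length}; choose one of {HASHED_LENGTHS}")
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=length)
    bits = gen.GetFingerprint(_as_mol(mol)).GetOnBits()
    return FeatureFingerprint(frozenset(bits), kind="hashed_binary", length=length)


def structural_keys(
    mol: MoleculeRecord | Chem.Mol, keys: Sequence[tuple[int, str]]
) -> FeatureFingerprint:
    """Structural-key fingerprint from a user-supplied SMARTS key table.

    ``keys`` is a sequence of ``(key_index, smarts)`` pairs; no key set is
    bundled.  A key fires when its SMARTS pattern matches the molecule.
    """
    m = _as_mol(mol)
    on: set[int] = set()
    for idx, smarts in keys:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"key {idx}: invalid SMARTS {smarts!r}")
        if m.HasSubstructMatch(patt):
            on.add(idx)
    length = max(idx for idx, _ in keys) + 1 if keys else 0
    return FeatureFingerprint(frozenset(on), kind="structural_key", length=length)


def load_key_definitions(path: str | Path) -> list[tuple[int, str]]:
    """Read a key table: TSV lines ``index<TAB>SMARTS``, '#' comments."""
    keys: list[tuple[int, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            idx, smarts = line.split("\t")
            keys.append((int(idx), smarts))
    return keys


def fingerprint_molecules(
    records: Sequence[MoleculeRecord],
    kind: str = "ecfp",
    diameter: int = 4,
    length: int = 2048,
) -> dict[str, FeatureFingerprint]:
    """Fingerprint a molecule list into an id -> fingerprint map."""
    if kind == "ecfp":
        return {rec.id: ecfp(rec, diameter) for rec in records}
    if kind == "hashed_binary":
        return {rec.id: hashed_binary(rec, length) for rec in records}
    raise ValueError(f"unknown fingerprint kind {kind!r}")


def write_fingerprints(fps: Mapping[str, FeatureFingerprint], path: str | Path) -> None:
    """TSV: ``molecule_id<TAB>comma-separated sorted feature integers``."""
    items = list(fps.items())
    if not items:
        raise ValueError("no fingerprints to write")
    first = items[0][1]
    with open(path, "w") as fh:
        fh.write(f"# kind={first.kind} diameter={first.diameter} length={first.length}\n")
        for mol_id, fp in items:
            feats = ",".join(str(f) for f in sorted(fp.features))
            fh.write(f"{mol_id}\t{feats}\n")


def read_fingerprints(path: str | Path) -> dict[str, FeatureFingerprint]:
    """Inverse of :func:`write_fingerprints`; round-trips exactly."""
    fps: dict[str, FeatureFingerprint] = {}
    kind, diameter, length = "ecfp", None, None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                fields = dict(tok.split("=", 1) for tok in line[1:].split())
                kind = fields.get("kind", kind)
                diameter = None if fields.get("diameter") in (None, "None") else int(fields["diameter"])
                length = None if fields.get("length") in (None, "None") else int(fields["length"])
                continue
            mol_id, feats = line.split("\t")
            features = frozenset(int(f) for f in feats.split(",")) if feats else frozenset()
            fps[mol_id] = FeatureFingerprint(features, kind=kind, diameter=diameter, length=length)
    return fps
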