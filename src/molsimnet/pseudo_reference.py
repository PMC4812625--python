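"""Pseudo-reference clustering via maximal common edge subgraphs (MCES).

When no expert-curated reference clustering exists, one is generated
automatically in two phases.  Phase one groups molecules around common
subgraphs: molecules are first decomposed into hierarchical ring-system
scaffolds (HierS) so that pairs without any common ring system are screened
out cheaply, then a common edge subgraph is searched for among the
survivors with a size-tiered engine -- an exact search for molecules under
40 heavy atoms, an approximate (time-budgeted, best-so-far) search up to
80, and outright exclusion above 80.  Each MCES defines one cluster,
comprising the molecules that contain it; members differ only in linkers
and R-groups.  Phase two applies the two-fold filter: if any member has
more than twice as many heavy atoms as the cluster's MCES, the whole
cluster (including all members) is eliminated.  The surviving clusters are
disjoint and contain no singletons; note that no Tanimoto constraint is
imposed -- members of a valid cluster may well be less than 0.5 similar.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from rdkit import Chem
from rdkit.Chem import rdFMCS

from .chem_io import MoleculeRecord
from .clustering import Clustering

logger = logging.getLogger(__name__)

EXACT_HEAVY_ATOM_LIMIT = 40
MAX_HEAVY_ATOM_LIMIT = 80
SIZE_FILTER_FACTOR = 2.0

# combination scaffolds are enumerated only up to this many ring systems
_MAX_SYSTEMS_FOR_COMBINATIONS = 8


@dataclass(frozen=True)
class RingSystemSet:
    """Canonical ring-system scaffolds of one molecule (empty if acyclic)."""

    mol_id: str
    ring_systems: frozenset[str]


@dataclass(frozen=True)
class MCESResult:
    """A common edge subgraph found by the engine."""

    smarts: str
    n_heavy_atoms: int
    n_bonds: int
    approximate: bool


@dataclass(frozen=True)
class MCESCluster:
    """One cluster: its defining MCES and the member molecules."""

    mces_smarts: str
    mces_heavy_atoms: int
    members: tuple[MoleculeRecord, ...]


def _fused_ring_systems(mol: Chem.Mol) -> list[set[int]]:
    """Atom-index sets of ring systems (rings sharing an atom are merged)."""
    systems: list[set[int]] = []
    for ring in mol.GetRingInfo().AtomRings():
        ring_atoms = set(ring)
        merged = [s for s in systems if s & ring_atoms]
        for s in merged:
            ring_atoms |= s
            systems.remove(s)
        systems.append(ring_atoms)
    return systems


def _linker_atoms(mol: Chem.Mol, sys_a: set[int], sys_b: set[int]) -> set[int] | None:
    """Atoms of a shortest path joining two ring systems (None if disconnected)."""
    best: tuple[int, ...] | None = None
    for a, b in itertools.product(sys_a, sys_b):
        path = Chem.GetShortestPath(mol, a, b)
        if path and (best is None or len(path) < len(best)):
            best = path
    return set(best) if best else None


def hiers_ring_systems(record: MoleculeRecord) -> RingSystemSet:
    """Hierarchical ring-system scaffolds of a molecule.

    Fused rings count as a single ring system.  For molecules with several
    ring systems the hierarchy also contains every combination of systems
    together with the linkers joining them (e.g. biphenyl yields the phenyl
    system and the biphenyl combination).  Acyclic molecules yield the
    empty set.
    """
    mol = Chem.MolFromSmiles(record.smiles_canonical)
    if mol is None:
        raise ValueError(f"record {record.id!r} does not parse")
    systems = _fused_ring_systems(mol)
    scaffolds: set[str] = set()
    for atoms in systems:
        scaffolds.add(Chem.MolFragmentToSmiles(mol, atomsToUse=sorted(atoms), canonical=True))
    if 1 < len(systems) <= _MAX_SYSTEMS_FOR_COMBINATIONS:
        for r in range(2, len(systems) + 1):
            for combo in itertools.combinations(range(len(systems)), r):
                atoms: set[int] = set()
                connected = True
                for i, j in itertools.combinations(combo, 2):
                    link = _linker_atoms(mol, systems[i], systems[j])
                    if link is None:
                        connected = False
                        break
                    atoms |= link
                if not connected:
                    continue
                for i in combo:
                    atoms |= systems[i]
                scaffolds.add(
                    Chem.MolFragmentToSmiles(mol, atomsToUse=sorted(atoms), canonical=True)
                )
    elif len(systems) > _MAX_SYSTEMS_FOR_COMBINATIONS:
        logger.info(
            "record %s: %d ring systems, skipping combination enumeration",
            record.id,
            len(systems),
        )
    return RingSystemSet(mol_id=record.id, ring_systems=frozenset(scaffolds))


def mces_screen(a: RingSystemSet, b: RingSystemSet) -> bool:
    """True when an MCES search is warranted for the pair.

    Pairs lacking any common ring system are screened out; two acyclic
    molecules are screened in (the screen only rejects on *missing common
    ring systems*, and rejecting acyclic pairs would silently drop acyclic
    chemistry).
    """
    if not a.ring_systems and not b.ring_systems:
        return True
    return bool(a.ring_systems & b.ring_systems)


@dataclass
class FMCSEngine:
    """Maximum-common-substructure engine with exact and approximate tiers.

    Both tiers run the same search (atoms match by element, bonds by order,
    on the aromatic-perceived graph); the approximate tier runs under a
    stricter time budget and returns the best subgraph found so far.
    """

    exact_timeout: int = 60
    approx_timeout: int = 5

    def find(self, mols: Sequence[Chem.Mol], approximate: bool) -> MCESResult | None:
        timeout = self.approx_timeout if approximate else self.exact_timeout
        res = rdFMCS.FindMCS(
            list(mols),
            atomCompare=rdFMCS.AtomCompare.CompareElements,
            bondCompare=rdFMCS.BondCompare.CompareOrder,
            timeout=timeout,
        )
        if res.numAtoms == 0:
            return None
        if res.canceled and not approximate:
            logger.warning("exact MCES search timed out; best-so-far used")
        return MCESResult(
            smarts=res.smartsString,
            n_heavy_atoms=res.numAtoms,
            n_bonds=res.numBonds,
            approximate=approximate or bool(res.canceled),
        )


def build_mces_clusters(
    mols: Sequence[MoleculeRecord],
    engine: FMCSEngine | None = None,
    exact_limit: int = EXACT_HEAVY_ATOM_LIMIT,
    approx_limit: int = MAX_HEAVY_ATOM_LIMIT,
) -> list[MCESCluster]:
    """Greedy seed-and-grow MCES clustering.

    Molecules above ``approx_limit`` heavy atoms are excluded up front.
    Repeatedly: the first unassigned molecule seeds a group with every
    unassigned molecule passing the ring-system screen against it; the
    group's common subgraph is computed jointly (the strictest member's
    size tier selects the exact or approximate engine mode) and the cluster
    is formed from the group members containing it.  Clusters with fewer
    than two members are discarded, so the output contains no singletons.
    """
    engine = engine or FMCSEngine()
    eligible = [m for m in mols if m.heavy_atom_count <= approx_limit]
    n_excluded = len(mols) - len(eligible)
    if n_excluded:
        logger.info("%d molecule(s) above %d heavy atoms excluded", n_excluded, approx_limit)
    ring = {m.id: hiers_ring_systems(m) for m in eligible}
    rdmol = {m.id: Chem.MolFromSmiles(m.smiles_canonical) for m in eligible}
    unassigned = list(eligible)
    clusters: list[MCESCluster] = []
    while unassigned:
        seed = unassigned[0]
        group = [seed] + [
            m for m in unassigned[1:] if mces_screen(ring[seed.id], ring[m.id])
        ]
        if len(group) < 2:
            unassigned.pop(0)
            continue
        approximate = max(m.heavy_atom_count for m in group) >= exact_limit
        result = engine.find([rdmol[m.id] for m in group], approximate=approximate)
        if result is None:
            logger.info("no common MCES for seed %s; molecule dropped", seed.id)
            unassigned.pop(0)
            continue
        query = Chem.MolFromSmarts(result.smarts)
        members = tuple(m for m in group if rdmol[m.id].HasSubstructMatch(query))
        if len(members) < 2:
            unassigned.pop(0)
            continue
        clusters.append(
            MCESCluster(
                mces_smarts=result.smarts,
                mces_heavy_atoms=result.n_heavy_atoms,
                members=members,
            )
        )
        member_ids = {m.id for m in members}
        unassigned = [m for m in unassigned if m.id not in member_ids]
    return clusters


def size_filter(
    clusters: Sequence[MCESCluster], factor: float = SIZE_FILTER_FACTOR
) -> list[MCESCluster]:
    """Two-fold heavy-atom filter.

    A cluster survives iff every member's heavy-atom count is at most
    ``factor`` times the MCES heavy-atom count; exceeding the bound by any
    member eliminates the entire cluster, members included.
    """
    kept: list[MCESCluster] = []
    for cl in clusters:
        if all(m.heavy_atom_count <= factor * cl.mces_heavy_atoms for m in cl.members):
            kept.append(cl)
        else:
            logger.info(
                "cluster (MCES %d atoms, %d members) eliminated by the %gx filter",
                cl.mces_heavy_atoms,
                len(cl.members),
                factor,
            )
    return kept


def generate_pseudo_reference(
    mols: Sequence[MoleculeRecord],
    engine: FMCSEngine | None = None,
    exact_limit: int = EXACT_HEAVY_ATOM_LIMIT,
    approx_limit: int = MAX_HEAVY_ATOM_LIMIT,
    factor: float = SIZE_FILTER_FACTOR,
) -> tuple[Clustering, list[MCESCluster]]:
    """Run both phases and return the clustering plus per-cluster metadata."""
    clusters = size_filter(
        build_mces_clusters(mols, engine, exact_limit, approx_limit), factor
    )
    assignment: dict[str, int] = {}
    for label, cl in enumerate(clusters, start=1):
        for member in cl.members:
            assignment[member.id] = label
    return Clustering(assignment=assignment, method="mces", seed=None), clusters


def write_cluster_metadata(clusters: Sequence[MCESCluster], path: str | Path) -> None:
    """JSON metadata: MCES size and membership per cluster."""
    payload = [
        {
            "mces_smarts": cl.mces_smarts,
            "mces_heavy_atoms": cl.mces_heavy_atoms,
            "n_members": len(cl.members),
            "members": [m.id for m in cl.members],
        }
        for cl in clusters
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
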