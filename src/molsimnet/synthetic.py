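"""Synthetic test inputs with known ground truth.

Three generators cover the framework end to end:

* :func:`generate_combinatorial_libraries` emulates a small expert-curated
  reference set: six combinatorial libraries, each a fixed scaffold
  decorated with sampled R-groups at two attachment points, 157 molecules
  in total, with the defining guarantee of combinatorial reference sets --
  every intra-cluster similarity strictly exceeds every inter-cluster
  similarity (checked on ECFP_4 Tanimoto, resampled on failure).
* :func:`generate_random_network` gives Erdos-Renyi graphs for clustering-
  coefficient oracles.
* :func:`generate_block_matrix` plants a block structure in a similarity
  matrix with a clean similarity gap, so any threshold inside the gap
  recovers exactly the planted blocks.

The six bundled scaffolds are pairwise distinct ring systems (so the
ring-system screen of the pseudo-reference generator also separates them)
with deliberately different local chemistry -- an all-carbon aromatic, an
N/O-rich purinedione, an O-rich and an all-carbon saturated bicyclic, a
sulfone, and an N-rich lactam -- which keeps shared circular-environment
features across libraries scarce.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
from rdkit import Chem

from .chem_io import MoleculeRecord
from .clustering import Clustering
from .fingerprints import ecfp
from .network import SimilarityNetwork
from .similarity import SparseSimilarityMatrix, tanimoto


class SeparationError(RuntimeError):
    """Intra/inter similarity separation unattainable with the given pools."""


# Disubstituted scaffold templates; [*:1] and [*:2] mark attachment points.
DEFAULT_SCAFFOLDS: tuple[str, ...] = (
    "Cc1cc2cc([*:1])ccc2cc1[*:2]",            # methylnaphthalene
    "Cn1c(=O)c2c(nc([*:1])n2C)n([*:2])c1=O",  # dimethylxanthine
    "C1CC([*:1])C2OC([*:2])COC2C1",           # dioxadecalin
    "CC1(C)C2CC([*:1])C1(C)CC2[*:2]",         # bornane
    "O=S1(=O)CC2CC([*:1])CC2C1[*:2]",         # bicyclic sulfone
    "CC1N([*:1])C(=O)C(C)N([*:2])C1=O",       # dimethylpiperazinedione
)

DEFAULT_R_GROUPS: tuple[str, ...] = ("C", "O", "N", "F", "Cl", "Br")

DEFAULT_CLUSTER_SIZES: tuple[int, ...] = (30, 29, 28, 26, 24, 20)


@dataclass(frozen=True)
class SyntheticLibrarySpec:
    """Parameters of the combinatorial-library generator."""

    n_scaffolds: int = 6
    cluster_sizes: tuple[int, ...] = DEFAULT_CLUSTER_SIZES
    scaffolds: tuple[str, ...] = DEFAULT_SCAFFOLDS
    r_group_pool: tuple[str, ...] = DEFAULT_R_GROUPS
    seed: int = 0
    max_retries: int = 20

    def __post_init__(self) -> None:
        if len(self.cluster_sizes) != self.n_scaffolds:
            raise ValueError("len(cluster_sizes) must equal n_scaffolds")
        if len(self.scaffolds) < self.n_scaffolds:
            raise ValueError("not enough scaffolds for n_scaffolds")
        if any(s < 2 for s in self.cluster_sizes):
            raise ValueError("every cluster size must be >= 2")


def substitute(scaffold: str, r_groups: Sequence[str]) -> Chem.Mol | None:
    """Attach R-group fragments at the scaffold's labeled attachment points."""
    core = Chem.MolFromSmiles(scaffold)
    if core is None:
        raise ValueError(f"scaffold does not parse: {scaffold!r}")
    combo = core
    for i, r in enumerate(r_groups, start=1):
        frag = Chem.MolFromSmiles(f"[*:{i}]{r}")
        if frag is None:
            return None
        combo = Chem.CombineMols(combo, frag)
    try:
        mol = Chem.molzip(combo)
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def _build_library(
    spec: SyntheticLibrarySpec, rng: random.Random
) -> tuple[list[MoleculeRecord], Clustering]:
    records: list[MoleculeRecord] = []
    assignment: dict[str, int] = {}
    for ci in range(spec.n_scaffolds):
        template = spec.scaffolds[ci]
        size = spec.cluster_sizes[ci]
        combos = list(itertools.product(spec.r_group_pool, repeat=2))
        rng.shuffle(combos)
        seen: set[str] = set()
        count = 0
        for r_pair in combos:
            if count >= size:
                break
            mol = substitute(template, r_pair)
            if mol is None:
                continue
            canonical = Chem.MolToSmiles(mol)
            if canonical in seen:
                continue
            seen.add(canonical)
            count += 1
            mol_id = f"lib{ci + 1}_{count:03d}"
            records.append(
                MoleculeRecord(
                    id=mol_id,
                    smiles_raw=canonical,
                    smiles_canonical=canonical,
                    heavy_atom_count=mol.GetNumHeavyAtoms(),
                )
            )
            assignment[mol_id] = ci + 1
        if count < size:
            raise SeparationError(
                f"scaffold {ci + 1}: only {count} distinct molecules available, "
                f"{size} requested; enlarge the R-group pool"
            )
    return records, Clustering(assignment=assignment, method="planted", seed=spec.seed)


def separation_gap(
    records: Sequence[MoleculeRecord], reference: Clustering, diameter: int = 4
) -> tuple[float, float]:
    """(min intra-cluster, max inter-cluster) ECFP Tanimoto over all pairs."""
    fps = [ecfp(rec, diameter) for rec in records]
    labels = [reference.assignment[rec.id] for rec in records]
    min_intra, max_inter = 1.0, 0.0
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            t = tanimoto(fps[i], fps[j])
            if labels[i] == labels[j]:
                min_intra = min(min_intra, t)
            else:
                max_inter = max(max_inter, t)
    return min_intra, max_inter


def generate_combinatorial_libraries(
    spec: SyntheticLibrarySpec | None = None,
) -> tuple[list[MoleculeRecord], Clustering]:
    """Generate the scaffold libraries and their planted reference clustering.

    Deterministic per seed.  The separation property (minimum intra-cluster
    ECFP_4 Tanimoto strictly above the maximum inter-cluster value) is
    enforced by rejection sampling with a bounded number of retries.
    """
    spec = spec or SyntheticLibrarySpec()
    rng = random.Random(spec.seed)
    min_intra = max_inter = float("nan")
    for _ in range(max(1, spec.max_retries)):
        records, reference = _build_library(spec, rng)
        min_intra, max_inter = separation_gap(records, reference)
        if min_intra > max_inter:
            return records, reference
    raise SeparationError(
        f"no separated library found in {spec.max_retries} attempts "
        f"(last gap: intra {min_intra:.3f} vs inter {max_inter:.3f})"
    )


def generate_random_network(n: int, p: float, seed: int = 0) -> SimilarityNetwork:
    """Erdos-Renyi G(n, p) graph as a similarity network (threshold 0)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"edge probability must be in [0, 1], got {p}")
    g = nx.gnp_random_graph(n, p, seed=seed)
    nodes = tuple(f"n{i}" for i in range(n))
    edges = frozenset(
        (nodes[min(a, b)], nodes[max(a, b)]) for a, b in g.edges()
    )
    return SimilarityNetwork(nodes=nodes, edges=edges, threshold=0.0)


def generate_block_matrix(
    blocks: Sequence[int],
    s_intra_range: tuple[float, float] = (0.7, 0.9),
    s_inter_range: tuple[float, float] = (0.05, 0.2),
    seed: int = 0,
) -> SparseSimilarityMatrix:
    """Similarity matrix with planted blocks separated by a similarity gap.

    Within-block similarities are drawn uniformly from ``s_intra_range``,
    between-block ones from ``s_inter_range``; the inter range must lie
    entirely below the intra range, so every threshold inside the gap
    yields exactly the planted blocks as connected components.
    """
    if not blocks or any(b < 1 for b in blocks):
        raise ValueError("blocks must be a non-empty list of positive sizes")
    if s_inter_range[1] >= s_intra_range[0]:
        raise ValueError(
            f"inter range {s_inter_range} must lie entirely below intra range {s_intra_range}"
        )
    rng = random.Random(seed)
    ids: list[str] = []
    labels: list[int] = []
    for bi, size in enumerate(blocks, start=1):
        for j in range(1, size + 1):
            ids.append(f"b{bi}m{j}")
            labels.append(bi)
    entries: dict[tuple[str, str], float] = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            lo, hi = s_intra_range if labels[i] == labels[j] else s_inter_range
            entries[(ids[i], ids[j])] = rng.uniform(lo, hi)
    return SparseSimilarityMatrix(tuple(ids), entries, t_store=0.0)


def planted_clustering(blocks: Sequence[int]) -> Clustering:
    """Reference partition matching :func:`generate_block_matrix` ids."""
    assignment = {
        f"b{bi}m{j}": bi
        for bi, size in enumerate(blocks, start=1)
        for j in range(1, size + 1)
    }
    return Clustering(assignment=assignment, method="planted", seed=None)
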