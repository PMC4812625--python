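"""Tanimoto similarity and the sparse pairwise similarity matrix.

The similarity matrix S over a molecule set M is symmetric with a unit
diagonal, so only the upper triangle of off-diagonal entries is stored, and
only entries at or above a storage floor ``t_store``.  A pair absent from
the store is semantically "below the floor"; networks can therefore only be
generated at thresholds t >= t_store.  Because the >= boundary decides edge
existence, the floor comparison is carried out exactly on the integer
counts (|A n B| * q >= p * |A u B| for t_store = p/q) rather than on the
floating-point quotient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping

from .fingerprints import FeatureFingerprint


def tanimoto(fp_a: FeatureFingerprint, fp_b: FeatureFingerprint) -> float:
    """|A n B| / |A u B| over the feature sets; 0 when both sets are empty.

    The coefficient is symmetric and bounded: 1 for identical nonempty sets
    (maximal similarity), 0 for disjoint sets (minimal similarity).
    """
    if not fp_a.compatible_with(fp_b):
        raise ValueError(
            f"fingerprint kinds/parameters differ: "
            f"({fp_a.kind}, d={fp_a.diameter}, L={fp_a.length}) vs "
            f"({fp_b.kind}, d={fp_b.diameter}, L={fp_b.length})"
        )
    union = len(fp_a.features | fp_b.features)
    if union == 0:
        return 0.0
    return len(fp_a.features & fp_b.features) / union


@dataclass
class SparseSimilarityMatrix:
    """Upper-triangle pair store of Tanimoto coefficients >= t_store.

    ``entries`` maps ``(id_i, id_j)`` with i preceding j in ``ids`` order to
    s_ij; the diagonal (identically 1) is never materialized.
    """

    ids: tuple[str, ...]
    entries: dict[tuple[str, str], float]
    t_store: float = 0.0
    _index: dict[str, int] = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self._index is None:
            self._index = {mol_id: k for k, mol_id in enumerate(self.ids)}

    @property
    def n_molecules(self) -> int:
        return len(self.ids)

    @property
    def n_pairs(self) -> int:
        return len(self.entries)

    def key(self, a: str, b: str) -> tuple[str, str]:
        """Canonical unordered-pair key (ids ordered by matrix position)."""
        if a == b:
            raise ValueError(f"self-pair {a!r} has no stored entry")
        return (a, b) if self._index[a] < self._index[b] else (b, a)

    def get(self, a: str, b: str) -> float | None:
        """Stored similarity, or None when the pair is below the floor."""
        return self.entries.get(self.key(a, b))

    def restricted(self, t_store: float) -> "SparseSimilarityMatrix":
        """The same matrix under a higher storage floor."""
        if t_store < self.t_store:
            raise ValueError(
                f"cannot lower the floor: {t_store} < stored floor {self.t_store}"
            )
        kept = {pair: s for pair, s in self.entries.items() if s >= t_store}
        return SparseSimilarityMatrix(self.ids, kept, t_store=t_store)


def build_similarity_matrix(
    fps: Mapping[str, FeatureFingerprint], t_store: float = 0.0
) -> SparseSimilarityMatrix:
    """All-pairs Tanimoto matrix, keeping pairs with s_ij >= t_store.

    ``t_store = 0`` yields the complete matrix.  The floor test is exact:
    t_store is interpreted as the decimal fraction printed (e.g. 0.30 is
    30/100) and compared by integer cross-multiplication.
    """
    if not fps:
        raise ValueError("empty fingerprint map")
    if not 0.0 <= t_store <= 1.0:
        raise ValueError(f"t_store must be in [0, 1], got {t_store}")
    ids = tuple(fps)
    floor = Fraction(str(t_store))
    p, q = floor.numerator, floor.denominator
    sets = [fps[i].features for i in ids]
    first = fps[ids[0]]
    for i in ids:
        if not fps[i].compatible_with(first):
            raise ValueError(f"fingerprint {i!r} differs in kind/parameters")
    entries: dict[tuple[str, str], float] = {}
    for a in range(len(ids)):
        sa = sets[a]
        for b in range(a + 1, len(ids)):
            sb = sets[b]
            inter = len(sa & sb)
            union = len(sa | sb)
            # exact floor test; union == 0 (both empty) counts as s = 0
            if inter * q >= p * union:
                entries[(ids[a], ids[b])] = inter / union if union else 0.0
    return SparseSimilarityMatrix(ids, entries, t_store=t_store)


def write_similarity(matrix: SparseSimilarityMatrix, path: str | Path) -> None:
    """TSV ``id_i<TAB>id_j<TAB>s_ij`` with the floor recorded in the header."""
    with open(path, "w") as fh:
        fh.write(f"# t_store={matrix.t_store} n_molecules={matrix.n_molecules}\n")
        fh.write("# ids=" + ",".join(matrix.ids) + "\n")
        for (a, b), s in matrix.entries.items():
            fh.write(f"{a}\t{b}\t{s:.12g}\n")


def read_similarity(path: str | Path) -> SparseSimilarityMatrix:
    """Inverse of :func:`write_similarity`."""
    t_store = 0.0
    ids: tuple[str, ...] = ()
    entries: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    key, _, val = tok.partition("=")
                    if key == "t_store":
                        t_store = float(val)
                    elif key == "ids":
                        ids = tuple(val.split(","))
                continue
            a, b, s = line.split("\t")
            entries[(a, b)] = float(s)
    if not ids:
        raise ValueError(f"{path}: missing '# ids=' header")
    matrix = SparseSimilarityMatrix(ids, {}, t_store=t_store)
    for (a, b), s in entries.items():
        matrix.entries[matrix.key(a, b)] = s
    return matrix
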