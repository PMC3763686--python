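"""Distance-based clustering of gene-family sequences with Neighbor-Joining
plus bootstrap, and exon/intron structural comparison across family members.

Distances are p-distances with pairwise gap deletion (columns with a gap or N
in either sequence of a pair are skipped); a Jukes-Cantor correction is
available. The tree is the standard Saitou-Nei agglomeration with the
Studier-Keppler Q criterion; negative branch lengths are clamped to zero.
Bootstrap support for an internal bipartition of the full-data tree is the
percentage of column-resampled replicates whose NJ tree contains the same
split (split semantics, invariant to leaf relabeling).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import GeneModel, SequenceRecord
from .tree import Clade, PhyloTree

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape must match number of labels")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("diagonal must be zero")
        if (self.d < -1e-12).any():
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.labels)


def pairwise_distances(
    aligned: list[SequenceRecord], jukes_cantor: bool = False
) -> DistanceMatrix:
    """p-distance with pairwise gap/N deletion over an aligned set."""
    if len(aligned) < 2:
        raise ValueError("need at least two sequences")
    length = len(aligned[0].residues)
    for r in aligned:
        if len(r.residues) != length:
            raise ValueError("aligned sequences must have equal length")
    mats = np.array(
        [list(r.residues.upper()) for r in aligned], dtype="U1"
    )
    valid = (mats != "-") & (mats != "N")
    n = len(aligned)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            compared = int(both.sum())
            if compared == 0:
                raise ValueError(
                    f"no comparable columns between "
                    f"'{aligned[i].id}' and '{aligned[j].id}'"
                )
            p = float((mats[i][both] != mats[j][both]).sum()) / compared
            if jukes_cantor:
                if p >= 0.75:
                    raise ValueError(
                        "p-distance too large for Jukes-Cantor correction"
                    )
                p = -0.75 * math.log(1 - 4 * p / 3)
            d[i, j] = d[j, i] = p
    return DistanceMatrix([r.id for r in aligned], d)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor-Joining (Saitou-Nei) tree from a distance matrix.

    Q-matrix ties are broken by the smallest (label_i, label_j) pair in
    lexicographic order, making the result deterministic. The returned tree
    is unrooted, represented with a degree-3 root; negative branch length
    estimates are clamped to zero.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("NJ requires at least 3 taxa")
    nodes: list[Clade] = [Clade(name=label) for label in dm.labels]
    labels = list(dm.labels)
    d = dm.d.copy()

    def clamp(x: float) -> float:
        if x < 0:
            log.debug("clamped negative branch length %.4g to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, min(labels[i], labels[j]), max(labels[i], labels[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        parent = Clade(children=[nodes[i], nodes[j]])
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[: m - 2, : m - 2] = d[np.ix_(keep, keep)]
        d2[m - 2, : m - 2] = d2[: m - 2, m - 2] = dnew[keep]
        d = d2
        nodes = [nodes[x] for x in keep] + [parent]
        labels = [labels[x] for x in keep] + [min(labels[i], labels[j])]

    # closed-form star resolution of the last three nodes
    (a, b, c) = nodes
    da, db, dc = d[0, 1], d[0, 2], d[1, 2]
    a.length = clamp((da + db - dc) / 2)
    b.length = clamp((da + dc - db) / 2)
    c.length = clamp((db + dc - da) / 2)
    return PhyloTree(root=Clade(children=[a, b, c]))


def bootstrap_support(
    aligned: list[SequenceRecord],
    reps: int = 1000,
    seed: int = 0,
    jukes_cantor: bool = False,
) -> PhyloTree:
    """NJ tree of the full alignment with bootstrap supports on internal
    nodes (percent of replicates containing the same bipartition)."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    full = nj_tree(pairwise_distances(aligned, jukes_cantor=jukes_cantor))
    names = sorted(n for n in full.leaf_names)
    ref = names[0]
    all_names = frozenset(names)
    counts: dict[frozenset, int] = {s: 0 for s in full.bipartitions()}
    rng = np.random.default_rng(seed)
    length = len(aligned[0].residues)
    rows = [r.residues for r in aligned]
    for _ in range(reps):
        cols = rng.integers(0, length, size=length)
        resampled = [
            SequenceRecord(r.id, "", "".join(row[c] for c in cols))
            for r, row in zip(aligned, rows)
        ]
        try:
            rep_tree = nj_tree(
                pairwise_distances(resampled, jukes_cantor=jukes_cantor)
            )
        except ValueError:
            continue  # degenerate replicate (no comparable columns)
        rep_splits = rep_tree.bipartitions()
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    # attach supports to matching internal nodes of the full tree
    for node in full.root.walk():
        if node is full.root or node.is_leaf:
            continue
        side = frozenset(x.name for x in node.walk() if x.is_leaf)
        if ref in side:
            side = all_names - side
        if side in counts:
            node.support = round(100.0 * counts[side] / reps)
    return full


@dataclass
class ExonIntronProfile:
    """Exon/intron architecture of one family member."""

    gene_id: str
    exon_lengths: list[int]
    intron_lengths: list[int]

    def __post_init__(self):
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError(
                f"{self.gene_id}: #introns must equal #exons - 1"
            )

    @property
    def coding_length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def total_intron(self) -> int:
        return sum(self.intron_lengths)

    @classmethod
    def from_gene_model(cls, model: GeneModel) -> "ExonIntronProfile":
        return cls(
            gene_id=model.gene_id,
            exon_lengths=[e - s + 1 for s, e in model.exons],
            intron_lengths=[e - s + 1 for s, e in model.introns],
        )


@dataclass
class StructureComparison:
    gene_a: str
    gene_b: str
    exon_count_diff: int  # b minus a; positive = gain in b
    exon_length_ratios: list[float]
    coding_length_diff: int
    total_intron_diff: int
    discordant_exons: list[int] = field(default_factory=list)  # 1-based indices
    concordant: bool = False


def compare_exon_intron(
    a: ExonIntronProfile, b: ExonIntronProfile, tol: float = 0.2
) -> StructureComparison:
    """Structural concordance of two family members: exon count loss/gain,
    per-exon length ratios, coding and total-intron length differences.

    Concordant iff exon counts match and every exon-length ratio is within
    ``tol`` of 1. Exons beyond the shorter profile's count are flagged as
    discordant (loss/gain localizes to those indices).
    """
    n = min(len(a.exon_lengths), len(b.exon_lengths))
    ratios = [b.exon_lengths[i] / a.exon_lengths[i] for i in range(n)]
    discordant = [i + 1 for i, r in enumerate(ratios) if abs(r - 1) > tol]
    extra = max(len(a.exon_lengths), len(b.exon_lengths))
    discordant += list(range(n + 1, extra + 1))
    count_diff = len(b.exon_lengths) - len(a.exon_lengths)
    return StructureComparison(
        gene_a=a.gene_id,
        gene_b=b.gene_id,
        exon_count_diff=count_diff,
        exon_length_ratios=ratios,
        coding_length_diff=b.coding_length - a.coding_length,
        total_intron_diff=b.total_intron - a.total_intron,
        discordant_exons=discordant,
        concordant=(count_diff == 0 and not discordant),
    )
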