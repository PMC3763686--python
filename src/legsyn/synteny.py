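"""Synteny-block detection between the single-copy (A) and duplicated (B)
maps, comparative-map assembly, and tentative placement of unanchored loci.

A block is three or more shared anchors whose B positions are strictly
monotone along increasing A position; orientation is forward when B positions
increase and reverse when they decrease (an inverted segment). Chaining is
rank-based: a chain may skip up to ``max_rank_gap`` consecutive out-of-order
anchors, tolerating minor local rearrangement without any base-pair distance
rule.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from .insilico_map import ChromosomeMap, MapFeature


@dataclass
class Anchor:
    """One feature placed on both genomes (A position x one B copy)."""

    feature_id: str
    chrom_a: str
    chrom_b: str
    pos_a: int
    pos_b: int
    copy_label: str
    strand_b: str = "+"

    def __post_init__(self):
        if self.pos_a < 1 or self.pos_b < 1:
            raise ValueError(f"{self.feature_id}: positions must be >= 1")


@dataclass
class SyntenyBlock:
    chrom_a: str
    chrom_b: str
    copy_label: str
    anchors: list[Anchor]
    orientation: str  # "forward" | "reverse"

    def __post_init__(self):
        self.anchors = sorted(self.anchors, key=lambda a: a.pos_a)

    @property
    def span_a(self) -> tuple[int, int]:
        return self.anchors[0].pos_a, self.anchors[-1].pos_a

    @property
    def span_b(self) -> tuple[int, int]:
        pb = [a.pos_b for a in self.anchors]
        return min(pb), max(pb)

    def __len__(self) -> int:
        return len(self.anchors)


@dataclass
class ComparativeMap:
    """Figure-style layout: per A chromosome, copy-1 blocks on the left panel
    and copy-2 blocks on the right, over the backbone feature map."""

    panels: dict[str, dict[str, list[SyntenyBlock]]]
    backbone: dict[str, ChromosomeMap]

    def to_json(self) -> str:
        payload = {
            chrom: {
                side: [
                    {
                        "chrom_b": b.chrom_b,
                        "copy_label": b.copy_label,
                        "orientation": b.orientation,
                        "span_a": list(b.span_a),
                        "span_b": list(b.span_b),
                        "n_anchors": len(b),
                        "anchor_ids": [a.feature_id for a in b.anchors],
                    }
                    for b in blocks
                ]
                for side, blocks in sides.items()
            }
            for chrom, sides in self.panels.items()
        }
        return json.dumps(payload, indent=2, sort_keys=True)


_SUFFIX = re.compile(r"-[12](-[a-z])?$")


def infer_source_query(feature_id: str) -> str:
    """Strip the '-<copy>[-<sub>]' suffix a mapped feature id carries."""
    return _SUFFIX.sub("", feature_id)


def find_shared_features(
    maps_a: list[ChromosomeMap], maps_b: list[ChromosomeMap]
) -> list[Anchor]:
    """Pair every A placement of a query with each B copy placement.

    A query mapped once in A and twice in B yields two anchors (copy 1 and
    copy 2); queries absent from either map yield none. When a copy is a
    tandem cluster, its representative position is the first (lowest-
    coordinate) member.
    """
    a_feats: dict[str, list[MapFeature]] = {}
    for m in maps_a:
        for f in m.features:
            q = f.source_query or infer_source_query(f.feature_id)
            a_feats.setdefault(q, []).append(f)
    anchors: list[Anchor] = []
    for m in maps_b:
        reps: dict[tuple[str, str], MapFeature] = {}
        for f in m.features:
            q = f.source_query or infer_source_query(f.feature_id)
            key = (q, f.copy_label or "1")
            if key not in reps or f.position < reps[key].position:
                reps[key] = f
        for (q, copy_label), bf in sorted(reps.items()):
            for af in a_feats.get(q, ()):
                anchors.append(
                    Anchor(
                        feature_id=af.feature_id,
                        chrom_a=af.chromosome,
                        chrom_b=bf.chromosome,
                        pos_a=af.position,
                        pos_b=bf.position,
                        copy_label=copy_label,
                        strand_b=bf.strand,
                    )
                )
    anchors.sort(key=lambda a: (a.chrom_a, a.pos_a, a.chrom_b, a.copy_label))
    return anchors


# ---------------------------------------------------------------------------
# chaining


def _best_chain(pos_b: list[int], max_rank_gap: int, increasing: bool):
    """Longest strictly monotone chain over anchors in current rank order,
    where consecutive chain members may skip at most ``max_rank_gap``
    intervening anchors. Among maximum-length chains, returns the one with
    the lexicographically smallest index tuple.
    """
    n = len(pos_b)
    if n == 0:
        return []
    step = max_rank_gap + 1
    f = [1] * n  # best chain length starting at i
    for i in range(n - 2, -1, -1):
        for j in range(i + 1, min(n, i + step + 1)):
            ok = pos_b[j] > pos_b[i] if increasing else pos_b[j] < pos_b[i]
            if ok and f[j] + 1 > f[i]:
                f[i] = f[j] + 1
    best = max(f)
    start = min(i for i in range(n) if f[i] == best)
    chain = [start]
    cur = start
    while f[cur] > 1:
        for j in range(cur + 1, min(n, cur + step + 1)):
            ok = pos_b[j] > pos_b[cur] if increasing else pos_b[j] < pos_b[cur]
            if ok and f[j] == f[cur] - 1:
                chain.append(j)
                cur = j
                break
    return chain


def detect_blocks(
    anchors: list[Anchor],
    min_block: int = 3,
    max_rank_gap: int = 2,
) -> list[SyntenyBlock]:
    """Greedy extraction of monotone anchor chains as synteny blocks.

    Anchors are grouped by chromosome pair (chrom_a, chrom_b) and sorted by A
    position; a block's copy label is the majority label of its member
    anchors (per-query labels on one chromosome pair can disagree when the
    two homeologs score similarly, but the pair's panel side is a property of
    the block). Repeatedly, the best chain among the remaining anchors is
    extracted (longest; ties prefer forward orientation, then the
    lexicographically smallest anchor-index tuple) until no chain reaches
    ``min_block``. Each anchor joins at most one block; leftovers are the
    shared singletons/doubletons reported by :func:`unchained_anchors`.
    """
    groups: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.chrom_a, a.chrom_b), []).append(a)
    blocks: list[SyntenyBlock] = []
    for (ca, cb), group in sorted(groups.items()):
        remaining = sorted(group, key=lambda a: (a.pos_a, a.pos_b, a.feature_id))
        while len(remaining) >= min_block:
            pb = [a.pos_b for a in remaining]
            fwd = _best_chain(pb, max_rank_gap, increasing=True)
            rev = _best_chain(pb, max_rank_gap, increasing=False)
            chain, orientation = (
                (fwd, "forward") if len(fwd) >= len(rev) else (rev, "reverse")
            )
            if len(chain) < min_block:
                break
            members = [remaining[i] for i in chain]
            n1 = sum(1 for m in members if m.copy_label == "1")
            copy_label = "1" if 2 * n1 >= len(members) else "2"
            blocks.append(
                SyntenyBlock(ca, cb, copy_label, members, orientation)
            )
            taken = set(chain)
            remaining = [a for i, a in enumerate(remaining) if i not in taken]
    blocks.sort(
        key=lambda b: (b.chrom_a, b.span_a, b.chrom_b, b.copy_label)
    )
    return blocks


def unchained_anchors(
    anchors: list[Anchor], blocks: list[SyntenyBlock]
) -> list[Anchor]:
    """Shared features left outside every block (singletons/doubletons)."""
    used = {id(a) for b in blocks for a in b.anchors}
    return [a for a in anchors if id(a) not in used]


def assemble_comparative_map(
    blocks: list[SyntenyBlock], backbone: list[ChromosomeMap]
) -> ComparativeMap:
    """Lay out blocks around each A chromosome: copy 1 left, copy 2 right."""
    known = {m.chromosome for m in backbone}
    panels: dict[str, dict[str, list[SyntenyBlock]]] = {
        m.chromosome: {"left": [], "right": []} for m in backbone
    }
    for b in blocks:
        if b.chrom_a not in known:
            raise ValueError(f"block references unknown chromosome '{b.chrom_a}'")
        side = "left" if b.copy_label == "1" else "right"
        panels[b.chrom_a][side].append(b)
    for sides in panels.values():
        for side in sides.values():
            side.sort(key=lambda b: (b.span_a, b.chrom_b))
    return ComparativeMap(panels=panels, backbone={m.chromosome: m for m in backbone})


@dataclass
class TentativeInterval:
    locus_id: str
    chromosome: str
    start: int
    end: int
    tentative: bool = True
    flanks: tuple[str, str] = field(default=("", ""))


def place_unanchored_locus(
    locus_id: str,
    flank_left: str,
    flank_right: str,
    cmap: ChromosomeMap | list[ChromosomeMap],
) -> TentativeInterval:
    """Tentatively place a locus between its closest flanking markers.

    Errors name a missing marker; flanks resolving to different chromosomes
    (when a whole map is given) are an error.
    """
    maps = [cmap] if isinstance(cmap, ChromosomeMap) else list(cmap)
    found: dict[str, MapFeature] = {}
    for name in (flank_left, flank_right):
        for m in maps:
            f = m.find(name)
            if f is not None:
                found[name] = f
                break
        else:
            raise ValueError(f"flanking marker '{name}' not found on map")
    fa, fb = found[flank_left], found[flank_right]
    if fa.chromosome != fb.chromosome:
        raise ValueError(
            f"flanking markers on different chromosomes: "
            f"{fa.chromosome} vs {fb.chromosome}"
        )
    return TentativeInterval(
        locus_id=locus_id,
        chromosome=fa.chromosome,
        start=min(fa.position, fb.position),
        end=max(fa.position, fb.position),
        flanks=(flank_left, flank_right),
    )


def blocks_to_rows(blocks: list[SyntenyBlock]) -> list[dict]:
    return [
        {
            "chrom_a": b.chrom_a,
            "span_a_start": b.span_a[0],
            "span_a_end": b.span_a[1],
            "chrom_b": b.chrom_b,
            "span_b_start": b.span_b[0],
            "span_b_end": b.span_b[1],
            "copy_label": b.copy_label,
            "n_anchors": len(b),
            "orientation": b.orientation,
        }
        for b in blocks
    ]
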