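"""Per-chromosome ordered in-silico maps and their summaries.

A map feature is a placed sequence: its position is the first nucleotide of
the placed alignment on the physical map (1-based). Coverage of a chromosome
map is end - start, the span from first to last mapped feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .homology import CopyAssignment

CATEGORIES = ("gene", "g_marker", "SSR", "color_marker")


@dataclass
class MapFeature:
    feature_id: str
    chromosome: str
    position: int
    strand: str
    category: str = "gene"
    source_query: str | None = None
    copy_label: str | None = None
    sub_label: str | None = None

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"{self.feature_id}: position must be >= 1")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.feature_id}: unknown category '{self.category}'")


@dataclass
class ChromosomeMap:
    chromosome: str
    features: list[MapFeature]

    def __post_init__(self):
        self.features = sorted(self.features, key=lambda f: (f.position, f.feature_id))

    def __len__(self) -> int:
        return len(self.features)

    def find(self, feature_id: str) -> MapFeature | None:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        return None


@dataclass
class MapSummary:
    chromosome: str
    total_features: int
    start: int
    end: int
    coverage: int


def build_map(
    assignments: list[CopyAssignment],
    extra_features: list[MapFeature] = (),
    categories: dict[str, str] | None = None,
) -> list[ChromosomeMap]:
    """Turn copy assignments (plus any pre-placed features) into ordered
    per-chromosome maps.

    Each assignment member becomes one feature with id
    ``<query>-<copy_label>[-<sub_label>]``, position = t_start of the member
    hit, and strand from the hit. ``categories`` optionally maps query id to
    feature category (default "gene"). Duplicate feature ids are an error.
    """
    feats: list[MapFeature] = list(extra_features)
    for a in assignments:
        for copy in a.copies:
            for m in copy.members:
                fid = f"{a.query_id}-{copy.copy_label}"
                if m.sub_label:
                    fid += f"-{m.sub_label}"
                feats.append(
                    MapFeature(
                        feature_id=fid,
                        chromosome=copy.chromosome,
                        position=m.hit.t_start,
                        strand=m.hit.strand,
                        category=(categories or {}).get(a.query_id, "gene"),
                        source_query=a.query_id,
                        copy_label=copy.copy_label,
                        sub_label=m.sub_label,
                    )
                )
    seen = set()
    for f in feats:
        if f.feature_id in seen:
            raise ValueError(f"duplicate feature_id '{f.feature_id}'")
        seen.add(f.feature_id)
    by_chrom: dict[str, list[MapFeature]] = {}
    for f in feats:
        by_chrom.setdefault(f.chromosome, []).append(f)
    return [ChromosomeMap(c, by_chrom[c]) for c in sorted(by_chrom)]


def summarize_map(cmap: ChromosomeMap) -> MapSummary:
    """Total features, start/end positions, and coverage = end - start."""
    if not cmap.features:
        raise ValueError(f"{cmap.chromosome}: cannot summarize an empty map")
    positions = [f.position for f in cmap.features]
    start, end = min(positions), max(positions)
    return MapSummary(
        chromosome=cmap.chromosome,
        total_features=len(cmap.features),
        start=start,
        end=end,
        coverage=end - start,
    )


def feature_distance(a: MapFeature, b: MapFeature) -> int:
    """Distance in bp between two features on the same chromosome."""
    if a.chromosome != b.chromosome:
        raise ValueError(
            f"features on different chromosomes: {a.chromosome} vs {b.chromosome}"
        )
    return abs(a.position - b.position)


def total_features(maps: list[ChromosomeMap]) -> int:
    return sum(len(m) for m in maps)


def maps_to_frame(maps: list[ChromosomeMap]) -> pd.DataFrame:
    rows = [
        {
            "feature_id": f.feature_id,
            "category": f.category,
            "chromosome": f.chromosome,
            "position": f.position,
            "strand": f.strand,
            "copy_label": f.copy_label or "",
        }
        for m in maps
        for f in m.features
    ]
    return pd.DataFrame(
        rows,
        columns=["feature_id", "category", "chromosome", "position", "strand", "copy_label"],
    )


def summaries_to_frame(maps: list[ChromosomeMap]) -> pd.DataFrame:
    rows = []
    for m in maps:
        s = summarize_map(m)
        rows.append(
            {
                "chromosome": s.chromosome,
                "total_features": s.total_features,
                "start": s.start,
                "end": s.end,
                "coverage": s.coverage,
            }
        )
    return pd.DataFrame(
        rows, columns=["chromosome", "total_features", "start", "end", "coverage"]
    )


def read_map_table(path) -> list[ChromosomeMap]:
    df = pd.read_csv(path, sep="\t", comment="#")
    feats = [
        MapFeature(
            feature_id=str(r.feature_id),
            chromosome=str(r.chromosome),
            position=int(r.position),
            strand=str(r.strand),
            category=str(r.category),
            copy_label=str(r.copy_label) if str(r.copy_label) not in ("", "nan") else None,
        )
        for r in df.itertuples(index=False)
    ]
    by_chrom: dict[str, list[MapFeature]] = {}
    for f in feats:
        by_chrom.setdefault(f.chromosome, []).append(f)
    return [ChromosomeMap(c, by_chrom[c]) for c in sorted(by_chrom)]
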