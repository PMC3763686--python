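"""Allelic sequence comparison: global alignment, SNP/indel extraction under
physical-map reporting conventions, and gene-region classification.

Conventions for one reference (e.g. the Andean landrace allele) against one
query (e.g. the Mesoamerican allele):

* a maximal run of gap columns in the query is ONE deletion event, reported
  as the reference coordinate of the last aligned reference base before the
  run plus the run length ("starts after the indicated nucleotide");
* a maximal run of gap columns in the reference is ONE insertion event,
  reported as the query-coordinate range of the inserted bases;
* each mismatch column is one SNP at its reference coordinate; columns
  containing N emit no variant.

Gap runs are left-normalized (shifted left while the base preceding the run
equals its last base) so that equivalent optimal alignments yield identical
variant records. Region classification uses the reference gene model: a SNP
by its site, a deletion by its first deleted base, an insertion by the
reference base preceding the insertion point. Events whose reference extent
crosses a region boundary keep the region of their first base and carry a
boundary flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .homology import SearchParams
from .io_formats import GeneModel, SequenceRecord


@dataclass
class AlignScores:
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


@dataclass
class PairwiseAlignment:
    ref_id: str
    qry_id: str
    aligned_ref: str
    aligned_qry: str
    score: float

    def __post_init__(self):
        if len(self.aligned_ref) != len(self.aligned_qry):
            raise ValueError("aligned rows must have equal length")
        for a, b in zip(self.aligned_ref, self.aligned_qry):
            if a == "-" and b == "-":
                raise ValueError("column with gap in both rows")

    @property
    def ref(self) -> str:
        return self.aligned_ref.replace("-", "")

    @property
    def qry(self) -> str:
        return self.aligned_qry.replace("-", "")


@dataclass
class VariantRecord:
    """One SNP / insertion / deletion event.

    ``ref_pos``: SNP site, last reference base before a deletion, or the
    reference base preceding an insertion point. ``qry_range`` is set for
    insertions (1-based inclusive query coordinates).
    """

    kind: str  # "SNP" | "insertion" | "deletion"
    ref_pos: int
    length: int = 1
    qry_range: tuple[int, int] | None = None
    region: str | None = None
    ref_bases: str = ""
    qry_bases: str = ""
    boundary: bool = False

    def __post_init__(self):
        if self.kind not in ("SNP", "insertion", "deletion"):
            raise ValueError(f"unknown variant kind '{self.kind}'")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.kind == "SNP" and self.length != 1:
            raise ValueError("SNP length must be 1")


@dataclass
class RegionCell:
    snps: int = 0
    insertions: list[tuple[int, int]] = field(default_factory=list)
    deletions: list[tuple[int, int]] = field(default_factory=list)  # (ref_pos, -length)


@dataclass
class PolymorphismReport:
    """Region-by-event-type grid in the layout of a published polymorphism
    table: one column per gene region, rows for SNP counts, insertion query
    ranges, and deletion anchors with negative lengths."""

    gene_id: str
    regions: list[str]
    cells: dict[str, RegionCell]

    @property
    def total_snps(self) -> int:
        return sum(c.snps for c in self.cells.values())

    @property
    def total_variants(self) -> int:
        return sum(
            c.snps + len(c.insertions) + len(c.deletions)
            for c in self.cells.values()
        )

    def is_all_zero(self) -> bool:
        return self.total_variants == 0

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "SNPs": {r: self.cells[r].snps for r in self.regions},
            "Insertions": {
                r: ";".join(
                    f"{a}" if a == b else f"{a}-{b}"
                    for a, b in self.cells[r].insertions
                )
                or "0"
                for r in self.regions
            },
            "Deletions": {
                r: ";".join(f"{p} ({d})" for p, d in self.cells[r].deletions) or "0"
                for r in self.regions
            },
        }
        return pd.DataFrame(rows).T[self.regions]


def global_align(
    ref: SequenceRecord,
    qry: SequenceRecord,
    scores: AlignScores | None = None,
) -> PairwiseAlignment:
    """Optimal global alignment with affine gaps (a length-L gap costs
    gap_open + L * gap_extend); deterministic traceback."""
    if not ref.residues or not qry.residues:
        raise ValueError("cannot align an empty sequence")
    scores = scores or AlignScores()
    params = SearchParams(
        match=scores.match,
        mismatch=scores.mismatch,
        gap_open=scores.gap_open,
        gap_extend=scores.gap_extend,
    )
    aligner = params.aligner("global")
    aln = aligner.align(ref.residues, qry.residues)[0]
    return PairwiseAlignment(
        ref_id=ref.id,
        qry_id=qry.id,
        aligned_ref=str(aln[0]),
        aligned_qry=str(aln[1]),
        score=aln.score,
    )


def _left_normalize_deletion(ref: str, start: int, end: int) -> tuple[int, int]:
    # shift the deleted run [start, end] (1-based on ref) left while the base
    # before the run equals the run's last base
    while start > 1 and ref[start - 2] == ref[end - 1]:
        start -= 1
        end -= 1
    return start, end


def _left_normalize_insertion(
    qry: str, qs: int, qe: int, ref_pos: int
) -> tuple[int, int, int]:
    while qs > 1 and ref_pos > 0 and qry[qs - 2] == qry[qe - 1]:
        qs -= 1
        qe -= 1
        ref_pos -= 1
    return qs, qe, ref_pos


def extract_variants(aln: PairwiseAlignment) -> list[VariantRecord]:
    """Scan alignment columns into SNP / insertion / deletion events
    (regions unset)."""
    ref_seq, qry_seq = aln.ref, aln.qry
    variants: list[VariantRecord] = []
    rpos = qpos = 0  # last consumed 1-based positions
    i = 0
    cols_ref = aln.aligned_ref
    cols_qry = aln.aligned_qry
    n = len(cols_ref)
    while i < n:
        a, b = cols_ref[i], cols_qry[i]
        if a != "-" and b != "-":
            rpos += 1
            qpos += 1
            if a != b and "N" not in (a, b):
                variants.append(
                    VariantRecord(
                        kind="SNP", ref_pos=rpos, ref_bases=a, qry_bases=b
                    )
                )
            i += 1
        elif b == "-":  # deletion: ref bases absent from query
            j = i
            while j < n and cols_qry[j] == "-":
                j += 1
            run = j - i
            del_start, del_end = rpos + 1, rpos + run
            del_start, del_end = _left_normalize_deletion(
                ref_seq, del_start, del_end
            )
            variants.append(
                VariantRecord(
                    kind="deletion",
                    ref_pos=del_start - 1,
                    length=run,
                    ref_bases=ref_seq[del_start - 1 : del_end],
                )
            )
            rpos += run
            i = j
        else:  # insertion: query bases absent from reference
            j = i
            while j < n and cols_ref[j] == "-":
                j += 1
            run = j - i
            qs, qe = qpos + 1, qpos + run
            qs, qe, anchor = _left_normalize_insertion(qry_seq, qs, qe, rpos)
            variants.append(
                VariantRecord(
                    kind="insertion",
                    ref_pos=anchor,
                    length=run,
                    qry_range=(qs, qe),
                    qry_bases=qry_seq[qs - 1 : qe],
                )
            )
            qpos += run
            i = j
    variants.sort(key=lambda v: (v.ref_pos, v.kind))
    return variants


def classify_variants(
    variants: list[VariantRecord], model: GeneModel
) -> list[VariantRecord]:
    """Set each variant's region from the reference gene model."""
    out = []
    for v in variants:
        if v.kind == "SNP":
            anchor = v.ref_pos
            last = v.ref_pos
        elif v.kind == "deletion":
            anchor = v.ref_pos + 1  # first deleted base
            last = v.ref_pos + v.length
        else:
            anchor = max(v.ref_pos, 1)  # base preceding the insertion point
            last = anchor
        region = model.region_of(anchor)
        boundary = v.kind == "deletion" and model.region_of(last) != region
        out.append(
            VariantRecord(
                kind=v.kind,
                ref_pos=v.ref_pos,
                length=v.length,
                qry_range=v.qry_range,
                region=region,
                ref_bases=v.ref_bases,
                qry_bases=v.qry_bases,
                boundary=boundary,
            )
        )
    return out


def build_report(
    variants: list[VariantRecord], model: GeneModel
) -> PolymorphismReport:
    """Tabulate classified variants per gene region (zero-filled grid).

    A perfectly identical allele pair yields an all-zero report.
    """
    regions = model.region_labels()
    cells = {r: RegionCell() for r in regions}
    for v in sorted(variants, key=lambda v: (v.ref_pos, v.kind)):
        if v.region is None:
            raise ValueError("variants must be classified before reporting")
        cell = cells[v.region]
        if v.kind == "SNP":
            cell.snps += 1
        elif v.kind == "insertion":
            cell.insertions.append(v.qry_range)
        else:
            cell.deletions.append((v.ref_pos, -v.length))
    return PolymorphismReport(gene_id=model.gene_id, regions=regions, cells=cells)


def apply_variants(ref: str, variants: list[VariantRecord]) -> str:
    """Reconstruct the query sequence from the reference plus variants."""
    snps = {v.ref_pos: v.qry_bases for v in variants if v.kind == "SNP"}
    inserts: dict[int, str] = {}
    deleted: set[int] = set()
    for v in variants:
        if v.kind == "insertion":
            inserts[v.ref_pos] = inserts.get(v.ref_pos, "") + v.qry_bases
        elif v.kind == "deletion":
            deleted.update(range(v.ref_pos + 1, v.ref_pos + v.length + 1))
    out = [inserts.get(0, "")]
    for pos in range(1, len(ref) + 1):
        if pos not in deleted:
            out.append(snps.get(pos, ref[pos - 1]))
        out.append(inserts.get(pos, ""))
    return "".join(out)


def variants_to_frame(variants: list[VariantRecord]) -> pd.DataFrame:
    rows = [
        {
            "kind": v.kind,
            "ref_pos": v.ref_pos,
            "qry_start": v.qry_range[0] if v.qry_range else "",
            "qry_end": v.qry_range[1] if v.qry_range else "",
            "length": v.length,
            "region": v.region or "",
            "boundary": v.boundary,
        }
        for v in variants
    ]
    return pd.DataFrame(
        rows,
        columns=["kind", "ref_pos", "qry_start", "qry_end", "length", "region", "boundary"],
    )
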