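"""Readers and writers for the external formats the pipeline touches.

All coordinates are 1-based inclusive on load and stay 1-based everywhere
downstream, matching the convention of printed physical-map positions
("first nucleotide on the physical map"). Minus-strand hits are stored with
ascending target coordinates plus an explicit strand flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .tree import PhyloTree, from_dendropy

log = logging.getLogger(__name__)

_VALID = set("ACGTN")
# IUPAC ambiguity codes folded to N on read; everything else is an error.
_AMBIG = set("RYSWKMBDHV")


class FormatError(ValueError):
    """Malformed input file (parse or validation failure)."""


@dataclass
class SequenceRecord:
    """A DNA sequence over {A, C, G, T, N}."""

    id: str
    description: str = ""
    residues: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "SequenceRecord":
        rc = str(Seq(self.residues).reverse_complement())
        return SequenceRecord(self.id, self.description, rc)


@dataclass
class GeneModel:
    """Exon/intron/UTR structure of one gene, 1-based inclusive coordinates.

    ``exons`` are the coding exons E1..En; introns are the implied gaps
    between consecutive exons (I1..I(n-1)); UTRs are separate intervals that
    must not overlap the coding exons.
    """

    gene_id: str
    seq_id: str
    strand: str
    exons: list[tuple[int, int]]
    utr5: tuple[int, int] | None = None
    utr3: tuple[int, int] | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise FormatError(f"{self.gene_id}: strand must be + or -")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise FormatError(f"{self.gene_id}: exon start {s} > end {e}")
            if prev_end is not None and s <= prev_end:
                raise FormatError(f"{self.gene_id}: overlapping exons at {s}")
            prev_end = e
        for utr in (self.utr5, self.utr3):
            if utr is None:
                continue
            for s, e in self.exons:
                if utr[0] <= e and s <= utr[1]:
                    raise FormatError(
                        f"{self.gene_id}: UTR {utr} overlaps exon ({s}, {e})"
                    )

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        ]

    @property
    def span(self) -> tuple[int, int]:
        points = [s for s, _ in self.exons] + [e for _, e in self.exons]
        for utr in (self.utr5, self.utr3):
            if utr:
                points.extend(utr)
        return min(points), max(points)

    def regions(self) -> list[tuple[str, int, int]]:
        """Ordered (label, start, end) covering the gene: 5'UTR, E1, I1, ...,
        En, 3'UTR (UTR entries only when present)."""
        out = []
        if self.utr5:
            out.append(("5'UTR", *self.utr5))
        introns = self.introns
        for i, (s, e) in enumerate(self.exons):
            out.append((f"E{i + 1}", s, e))
            if i < len(introns):
                out.append((f"I{i + 1}", *introns[i]))
        if self.utr3:
            out.append(("3'UTR", *self.utr3))
        return sorted(out, key=lambda r: r[1])

    def region_labels(self) -> list[str]:
        return [label for label, _, _ in self.regions()]

    def region_of(self, pos: int) -> str:
        lo, hi = self.span
        if not lo <= pos <= hi:
            raise ValueError(
                f"{self.gene_id}: position {pos} outside model span ({lo}, {hi})"
            )
        for label, s, e in self.regions():
            if s <= pos <= e:
                return label
        # inside the span but in an unlabeled gap (e.g. between UTR and E1):
        # attribute to the nearest following region for robustness.
        for label, s, e in self.regions():
            if pos < s:
                return label
        return self.regions()[-1][0]


@dataclass
class HitRecord:
    """One filtered-homology hit in BLAST outfmt-6 terms.

    Target coordinates are normalized ascending (t_start <= t_end); a hit whose
    raw tabular coordinates were descending carries strand '-'.
    """

    query_id: str
    target_id: str
    percent_identity: float
    alignment_length: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str
    bit_score: float
    e_value: float
    mismatches: int = 0
    gap_opens: int = 0
    raw_score: float | None = None

    def __post_init__(self):
        if self.alignment_length < 1:
            raise FormatError("alignment_length must be >= 1")
        if not (self.e_value >= 0 and self.e_value == self.e_value):
            raise FormatError("e_value must be finite and non-negative")
        if self.t_start > self.t_end:
            self.t_start, self.t_end = self.t_end, self.t_start
            self.strand = "-"


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[SequenceRecord]:
    """Parse FASTA, upper-casing residues, folding IUPAC ambiguity codes
    (other than N) to N with a warning, and validating ids/alphabet.

    Raises FormatError naming the offending line for empty files, duplicate
    ids, and illegal characters.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    cur_id = cur_desc = None
    cur_seq: list[str] = []
    n_ambig = 0

    def flush(line_no):
        nonlocal cur_id, cur_desc, cur_seq
        if cur_id is None:
            return
        if not cur_seq:
            raise FormatError(f"line {line_no}: record '{cur_id}' has no sequence")
        records.append(SequenceRecord(cur_id, cur_desc, "".join(cur_seq)))
        cur_id, cur_desc, cur_seq = None, None, []

    with open(path) as fh:
        lines = fh.readlines()
    if not any(line.strip() for line in lines):
        raise FormatError(f"{path}: empty FASTA file")
    for i, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            flush(i)
            head = line[1:].strip()
            if not head:
                raise FormatError(f"line {i}: empty FASTA header")
            parts = head.split(None, 1)
            cur_id = parts[0]
            cur_desc = parts[1] if len(parts) > 1 else ""
            if cur_id in seen:
                raise FormatError(f"line {i}: duplicate sequence id '{cur_id}'")
            seen.add(cur_id)
        else:
            if cur_id is None:
                raise FormatError(f"line {i}: sequence data before first header")
            chunk = line.strip().upper()
            bad = set(chunk) - _VALID
            ambig = bad & _AMBIG
            if bad - _AMBIG:
                raise FormatError(
                    f"line {i}: illegal characters {sorted(bad - _AMBIG)} "
                    f"in record '{cur_id}'"
                )
            if ambig:
                n_ambig += sum(chunk.count(c) for c in ambig)
                chunk = "".join("N" if c in _AMBIG else c for c in chunk)
            cur_seq.append(chunk)
    flush(len(lines) + 1)
    if n_ambig:
        log.warning("folded %d IUPAC ambiguity bases to N", n_ambig)
    return records


def write_fasta(records, path, wrap: int = 60) -> None:
    """Write standard FASTA with the given wrap width (deterministic)."""
    if wrap < 1:
        raise ValueError("wrap must be >= 1")
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=wrap).write_file(bio)


# ---------------------------------------------------------------------------
# GFF3 gene models


def read_gene_models(path) -> list[GeneModel]:
    """Read gene/exon/UTR rows from a GFF3 file into GeneModels.

    Requires a ``##gff-version 3`` header. Exons are attached to their gene by
    the Parent attribute; validation failures name the gene_id.
    """
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("##gff-version 3"):
            raise FormatError(f"{path}: missing ##gff-version 3 header")
        for i, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"line {i}: expected 9 GFF3 columns, got {len(cols)}")
            seq_id, _src, ftype, start, end, _score, strand, _frame, attrs = cols
            try:
                start, end = int(start), int(end)
            except ValueError:
                raise FormatError(f"line {i}: non-integer coordinates") from None
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr.get("ID")
                if not gid:
                    raise FormatError(f"line {i}: gene row without ID attribute")
                genes.setdefault(
                    gid,
                    {"seq_id": seq_id, "strand": strand, "span": (start, end),
                     "exons": [], "utr5": None, "utr3": None},
                )
                genes[gid].update(seq_id=seq_id, strand=strand, span=(start, end))
                if gid not in order:
                    order.append(gid)
            elif ftype in ("exon", "five_prime_UTR", "three_prime_UTR"):
                gid = attr.get("Parent") or attr.get("ID")
                if not gid:
                    raise FormatError(f"line {i}: {ftype} row without Parent")
                entry = genes.setdefault(
                    gid,
                    {"seq_id": seq_id, "strand": strand, "span": None,
                     "exons": [], "utr5": None, "utr3": None},
                )
                if gid not in order:
                    order.append(gid)
                if ftype == "exon":
                    entry["exons"].append((start, end))
                elif ftype == "five_prime_UTR":
                    entry["utr5"] = (start, end)
                else:
                    entry["utr3"] = (start, end)
    models = []
    for gid in order:
        g = genes[gid]
        if not g["exons"]:
            raise FormatError(f"gene '{gid}' has no exon rows")
        model = GeneModel(gid, g["seq_id"], g["strand"], g["exons"],
                          utr5=g["utr5"], utr3=g["utr3"])
        if g["span"]:
            lo, hi = model.span
            if lo < g["span"][0] or hi > g["span"][1]:
                raise FormatError(
                    f"gene '{gid}': exon/UTR outside gene span {g['span']}"
                )
        models.append(model)
    return models


def write_gene_models(models: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            lo, hi = m.span
            fh.write(
                f"{m.seq_id}\tlegsyn\tgene\t{lo}\t{hi}\t.\t{m.strand}\t.\tID={m.gene_id}\n"
            )
            if m.utr5:
                fh.write(
                    f"{m.seq_id}\tlegsyn\tfive_prime_UTR\t{m.utr5[0]}\t{m.utr5[1]}\t."
                    f"\t{m.strand}\t.\tParent={m.gene_id}\n"
                )
            for s, e in m.exons:
                fh.write(
                    f"{m.seq_id}\tlegsyn\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"Parent={m.gene_id}\n"
                )
            if m.utr3:
                fh.write(
                    f"{m.seq_id}\tlegsyn\tthree_prime_UTR\t{m.utr3[0]}\t{m.utr3[1]}\t."
                    f"\t{m.strand}\t.\tParent={m.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# BLAST outfmt-6 tables

_HIT_COLS = [
    "query_id", "target_id", "percent_identity", "alignment_length",
    "mismatches", "gap_opens", "q_start", "q_end", "t_start", "t_end",
    "e_value", "bit_score",
]


def read_hits_table(path) -> list[HitRecord]:
    """Read a 12-column BLAST outfmt-6 TSV. Strand is inferred from
    t_start > t_end and target coordinates are normalized ascending."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=_HIT_COLS, dtype=str)
    except pd.errors.EmptyDataError:
        return []
    hits = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if any(pd.isna(v) for v in row):
            raise FormatError(f"line {i}: expected 12 tab-separated columns")
        try:
            hits.append(
                HitRecord(
                    query_id=row.query_id,
                    target_id=row.target_id,
                    percent_identity=float(row.percent_identity),
                    alignment_length=int(row.alignment_length),
                    mismatches=int(row.mismatches),
                    gap_opens=int(row.gap_opens),
                    q_start=int(row.q_start),
                    q_end=int(row.q_end),
                    t_start=int(row.t_start),
                    t_end=int(row.t_end),
                    strand="+",
                    e_value=float(row.e_value),
                    bit_score=float(row.bit_score),
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"line {i}: non-numeric field ({exc})") from None
    return hits


def write_hits_table(hits: list[HitRecord], path, header: str | None = None) -> None:
    """Write hits as outfmt-6; minus-strand hits get descending t coords."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for h in hits:
            ts, te = (h.t_end, h.t_start) if h.strand == "-" else (h.t_start, h.t_end)
            fh.write(
                f"{h.query_id}\t{h.target_id}\t{h.percent_identity:.2f}\t"
                f"{h.alignment_length}\t{h.mismatches}\t{h.gap_opens}\t"
                f"{h.q_start}\t{h.q_end}\t{ts}\t{te}\t"
                f"{h.e_value:.3g}\t{h.bit_score:.1f}\n"
            )


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree: PhyloTree, path) -> None:
    """Serialize with branch lengths; internal nodes carry integer bootstrap
    percentages (support of 1000/1000 replicates prints as 100)."""
    Path(path).write_text(tree.to_newick() + "\n")


def read_newick(path) -> PhyloTree:
    import dendropy

    dtree = dendropy.Tree.get(path=str(path), schema="newick")
    return from_dendropy(dtree)
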