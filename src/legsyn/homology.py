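"""Self-contained local homology search plus the significance filters and
duplicate-copy / tandem-cluster labeling used for comparative mapping.

The search is a k-mer-seeded local aligner: exact word matches between query
and target are clustered by diagonal, and each cluster window is aligned with
an affine-gap local alignment (Smith-Waterman via Bio.Align). Significance is
a Karlin-Altschul E-value, E = K * m * n * exp(-lambda * S), with lambda and K
configurable (the defaults are uncalibrated placeholders; substitute real
BLAST output via read_hits_table when calibrated statistics matter).

Hits are then filtered at E <= 1e-30 and alignment length >= 150 bp, and each
query's surviving hits are reduced to duplicate-copy assignments: in
"duplicated" mode the two best-supported chromosomes become copy 1 and copy 2;
tandem clusters within one copy get sub-labels a, b, c, ... in coordinate
order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .io_formats import HitRecord, SequenceRecord

_BASE_CODE = np.full(128, -1, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _BASE_CODE[ord(b)] = i


@dataclass
class SearchParams:
    """Scoring and significance parameters for the built-in search."""

    k: int = 11
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    karlin_lambda: float = 1.28
    karlin_k: float = 0.46
    e_threshold: float = 1e-30
    min_aln_len: int = 150
    # seeding knobs: minimum word hits per cluster, diagonal band half-width,
    # and the ungapped-extension score a cluster's dominant diagonal must
    # reach before gapped alignment is attempted
    min_seed_hits: int = 3
    diag_band: int = 16
    window_pad: int = 50
    ungapped_trigger: int = 25

    def __post_init__(self):
        if self.k < 4:
            raise ValueError("seed word length k must be >= 4")
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin parameters must be positive")
        if self.e_threshold <= 0:
            raise ValueError("e_threshold must be > 0")
        if self.min_aln_len < 1:
            raise ValueError("min_aln_len must be >= 1")

    def aligner(self, mode: str) -> Align.PairwiseAligner:
        """Affine-gap aligner where a gap of length L costs
        gap_open + L * gap_extend."""
        a = Align.PairwiseAligner()
        a.mode = mode
        a.match_score = self.match
        a.mismatch_score = self.mismatch
        a.open_gap_score = self.gap_open + self.gap_extend
        a.extend_gap_score = self.gap_extend
        return a


@dataclass
class CopyMember:
    sub_label: str | None
    hit: HitRecord


@dataclass
class CopyPlacement:
    copy_label: str  # "1" or "2"
    chromosome: str
    members: list[CopyMember]

    @property
    def best_hit(self) -> HitRecord:
        return max(self.members, key=lambda m: m.hit.bit_score).hit


@dataclass
class CopyAssignment:
    """Duplicate-copy placements of one query: copy "1" is the top hit's
    chromosome, copy "2" the second-best distinct chromosome (duplicated
    mode only). Empty ``copies`` means the query is unanchored."""

    query_id: str
    copies: list[CopyPlacement] = field(default_factory=list)

    @property
    def chromosomes(self) -> list[str]:
        return [c.chromosome for c in self.copies]


# ---------------------------------------------------------------------------
# k-mer machinery


def encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[arr]


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (codes, positions) of all valid k-mers (no N) as base-4 ints.

    Positions are 0-based starts.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    vals = np.zeros(n, dtype=np.int64)
    invalid = np.zeros(n, dtype=bool)
    c = codes.astype(np.int64)
    for j in range(k):
        win = c[j : j + n]
        vals = vals * 4 + np.where(win < 0, 0, win)
        invalid |= win < 0
    pos = np.nonzero(~invalid)[0]
    return vals[pos], pos


class TargetIndex:
    """Sorted k-mer index over one target sequence."""

    def __init__(self, seq: str, k: int):
        self.k = k
        self.length = len(seq)
        self.codes = encode(seq)
        vals, pos = kmer_codes(self.codes, k)
        order = np.argsort(vals, kind="stable")
        self.sorted_vals = vals[order]
        self.sorted_pos = pos[order]

    def lookup(self, query_vals: np.ndarray, query_pos: np.ndarray):
        """All (q_pos, t_pos) exact word matches (0-based)."""
        lo = np.searchsorted(self.sorted_vals, query_vals, side="left")
        hi = np.searchsorted(self.sorted_vals, query_vals, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        qp = np.repeat(query_pos, counts)
        tp = np.concatenate(
            [self.sorted_pos[a:b] for a, b in zip(lo, hi) if b > a]
        )
        return qp, tp


def _cluster_seeds(qp: np.ndarray, tp: np.ndarray, qlen: int, band: int):
    """Group seed matches into candidate loci.

    Seeds are grouped when their diagonals lie within ``band`` of one another
    and their target positions within about a query length; each group yields
    a target window for gapped alignment.
    """
    diag = tp - qp
    order = np.lexsort((tp, diag))
    diag, qp, tp = diag[order], qp[order], tp[order]
    clusters = []
    start = 0
    max_tgap = qlen + 1000
    for i in range(1, len(diag) + 1):
        if (
            i == len(diag)
            or diag[i] - diag[i - 1] > band
            or (diag[i] == diag[i - 1] and tp[i] - tp[i - 1] > max_tgap)
        ):
            clusters.append((qp[start:i], tp[start:i]))
            start = i
    # a far-apart tandem copy can share a diagonal range; split each cluster
    # further on target-position gaps
    final = []
    for cq, ct in clusters:
        o = np.argsort(ct, kind="stable")
        cq, ct = cq[o], ct[o]
        s = 0
        for i in range(1, len(ct) + 1):
            if i == len(ct) or ct[i] - ct[i - 1] > max_tgap:
                final.append((cq[s:i], ct[s:i]))
                s = i
    return final


def _ungapped_score(
    q_codes: np.ndarray, t_codes: np.ndarray, diag: int, params: SearchParams
) -> float:
    """Best ungapped segment score along one diagonal (vectorized Kadane)."""
    qlen, tlen = len(q_codes), len(t_codes)
    q_lo = max(0, -diag)
    q_hi = min(qlen, tlen - diag)
    if q_hi <= q_lo:
        return 0.0
    qs = q_codes[q_lo:q_hi]
    ts = t_codes[q_lo + diag : q_hi + diag]
    per = np.where((qs == ts) & (qs >= 0), params.match, params.mismatch)
    cum = np.cumsum(per)
    running_min = np.minimum.accumulate(np.concatenate(([0], cum[:-1])))
    return float(np.max(cum - running_min))


def _alignment_stats(aln) -> tuple[str, str, int, int, float]:
    """(aligned_q, aligned_t, n_match, length, identity%) of one alignment."""
    a, b = aln[0], aln[1]
    n_match = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    length = len(a)
    return a, b, n_match, length, 100.0 * n_match / length


def compute_evalue(score: float, m: int, n: int, params: SearchParams) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S)."""
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    return params.karlin_k * m * n * math.exp(-params.karlin_lambda * score)


def bit_score(score: float, params: SearchParams) -> float:
    return (params.karlin_lambda * score - math.log(params.karlin_k)) / math.log(2)


def local_search(
    query: SequenceRecord,
    targets: list[SequenceRecord],
    params: SearchParams | None = None,
    indexes: dict[str, TargetIndex] | None = None,
) -> list[HitRecord]:
    """Search the query against each target on both strands.

    Reverse-strand hits are found by searching the reverse-complemented query;
    their query coordinates are mapped back to the forward query and target
    coordinates are reported ascending with strand '-'. Hits are sorted by
    descending bit score. Pre-built ``indexes`` (keyed by target id) may be
    supplied to amortize indexing across many queries.
    """
    params = params or SearchParams()
    if len(query) < params.k:
        raise ValueError(
            f"query '{query.id}' shorter than seed length k={params.k}"
        )
    total_n = sum(len(t) for t in targets)
    aligner = params.aligner("local")
    qlen = len(query)
    oriented = {
        "+": query.residues,
        "-": query.reverse_complement().residues,
    }
    qk = {
        s: kmer_codes(encode(seq), params.k) for s, seq in oriented.items()
    }
    hits: list[HitRecord] = []
    for target in targets:
        idx = (indexes or {}).get(target.id) or TargetIndex(
            target.residues, params.k
        )
        for strand, qseq in oriented.items():
            vals, pos = qk[strand]
            if len(vals) == 0:
                continue
            qp, tp = idx.lookup(vals, pos)
            if len(qp) == 0:
                continue
            q_codes = encode(qseq)
            windows = []
            for cq, ct in _cluster_seeds(qp, tp, qlen, params.diag_band):
                if len(cq) < params.min_seed_hits:
                    continue
                diags = ct - cq
                vals_d, counts_d = np.unique(diags, return_counts=True)
                dominant = int(vals_d[np.argmax(counts_d)])
                if (
                    _ungapped_score(q_codes, idx.codes, dominant, params)
                    < params.ungapped_trigger
                ):
                    continue
                lo = max(0, int(diags.min()) - params.window_pad)
                hi = min(
                    idx.length,
                    int((ct + (qlen - cq)).max()) + params.window_pad,
                )
                windows.append((lo, hi))
            for lo, hi in _merge_windows(windows):
                sub = target.residues[lo:hi]
                alns = aligner.align(qseq, sub)
                try:
                    aln = alns[0]
                except IndexError:
                    continue
                if alns.score <= 0:
                    continue
                a, b, n_match, length, ident = _alignment_stats(aln)
                (qs0, qe0) = aln.aligned[0][0][0], aln.aligned[0][-1][1]
                (ts0, te0) = aln.aligned[1][0][0], aln.aligned[1][-1][1]
                if strand == "+":
                    q_start, q_end = qs0 + 1, qe0
                else:
                    q_start, q_end = qlen - qe0 + 1, qlen - qs0
                t_start, t_end = lo + ts0 + 1, lo + te0
                score = aln.score
                mism = sum(
                    1 for x, y in zip(a, b) if x != y and "-" not in (x, y)
                )
                gapo = _count_gap_opens(a) + _count_gap_opens(b)
                hits.append(
                    HitRecord(
                        query_id=query.id,
                        target_id=target.id,
                        percent_identity=round(ident, 2),
                        alignment_length=length,
                        q_start=int(q_start),
                        q_end=int(q_end),
                        t_start=int(min(t_start, t_end)),
                        t_end=int(max(t_start, t_end)),
                        strand=strand,
                        bit_score=round(bit_score(score, params), 2),
                        e_value=compute_evalue(score, qlen, total_n, params),
                        mismatches=mism,
                        gap_opens=gapo,
                        raw_score=score,
                    )
                )
    hits = _dedupe(hits)
    hits.sort(key=lambda h: (-h.bit_score, h.target_id, h.t_start, h.strand))
    return hits


def _merge_windows(windows):
    if not windows:
        return []
    windows = sorted(windows)
    merged = [list(windows[0])]
    for lo, hi in windows[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [tuple(w) for w in merged]


def _count_gap_opens(s: str) -> int:
    opens = 0
    in_gap = False
    for c in s:
        if c == "-":
            if not in_gap:
                opens += 1
            in_gap = True
        else:
            in_gap = False
    return opens


def _dedupe(hits: list[HitRecord]) -> list[HitRecord]:
    """Drop hits mostly contained in a better hit on the same target/strand."""
    kept: list[HitRecord] = []
    for h in sorted(hits, key=lambda h: -h.bit_score):
        redundant = False
        for k in kept:
            if k.target_id != h.target_id or k.strand != h.strand:
                continue
            ov = min(k.t_end, h.t_end) - max(k.t_start, h.t_start) + 1
            if ov > 0.5 * (h.t_end - h.t_start + 1):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def filter_hits(hits: list[HitRecord], params: SearchParams | None = None) -> list[HitRecord]:
    """Keep hits with E <= e_threshold and alignment length >= min_aln_len.

    Order-preserving and idempotent.
    """
    params = params or SearchParams()
    return [
        h
        for h in hits
        if h.e_value <= params.e_threshold
        and h.alignment_length >= params.min_aln_len
    ]


def assign_copies(
    query_id: str,
    hits: list[HitRecord],
    mode: str = "duplicated",
    cluster_window: int = 250_000,
) -> CopyAssignment:
    """Reduce a query's filtered hits to duplicate-copy placements.

    Chromosomes are ranked by their best hit's bit score (ties broken by
    lexicographic chromosome id); "duplicated" mode keeps the top two distinct
    chromosomes as copies 1 and 2, "single" mode keeps one. Within a kept
    chromosome, hits chained within ``cluster_window`` of the top hit form one
    tandem cluster, sub-labeled a, b, c, ... by ascending t_start when the
    cluster has two or more members. An empty hit list yields an unanchored
    (empty) assignment.
    """
    if mode not in ("single", "duplicated"):
        raise ValueError(f"unknown mode '{mode}'")
    for h in hits:
        if h.query_id != query_id:
            raise ValueError(
                f"hit for '{h.query_id}' passed to assignment of '{query_id}'"
            )
    if not hits:
        return CopyAssignment(query_id)
    by_chrom: dict[str, list[HitRecord]] = {}
    for h in hits:
        by_chrom.setdefault(h.target_id, []).append(h)
    ranked = sorted(
        by_chrom,
        key=lambda c: (-max(h.bit_score for h in by_chrom[c]), c),
    )
    n_keep = 2 if mode == "duplicated" else 1
    copies = []
    for label, chrom in zip("12", ranked[:n_keep]):
        chrom_hits = sorted(by_chrom[chrom], key=lambda h: h.t_start)
        top = max(chrom_hits, key=lambda h: h.bit_score)
        # single-linkage chains of hits within cluster_window; keep the chain
        # containing the top hit
        chains: list[list[HitRecord]] = [[chrom_hits[0]]]
        for h in chrom_hits[1:]:
            if h.t_start - chains[-1][-1].t_start <= cluster_window:
                chains[-1].append(h)
            else:
                chains.append([h])
        members_hits = next(c for c in chains if top in c)
        if len(members_hits) >= 2:
            subs = [chr(ord("a") + i) for i in range(len(members_hits))]
        else:
            subs = [None]
        copies.append(
            CopyPlacement(
                copy_label=label,
                chromosome=chrom,
                members=[CopyMember(s, h) for s, h in zip(subs, members_hits)],
            )
        )
    return CopyAssignment(query_id, copies)
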