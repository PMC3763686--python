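"""Synthetic genome pairs with known truth for exercising the pipeline.

The generator emulates the comparative setting of a single-copy legume genome
(A, common-bean-like) versus a paleopolyploid one (B, soybean-like): an
ancestral genome is simulated with annotated genes and markers; genome A is
the ancestor mutated at a small divergence; genome B carries two homeologous
copies of every ancestral chromosome, each mutated at its own rate, with
Poisson-distributed segmental inversions, fractionation (physical deletion of
duplicated gene copies), and tandem family expansions at designated loci
(CHS-like clusters). Allelic gene pairs carry SNPs and indels injected per
gene region at configured rates. Every stochastic choice flows from a single
seed; a fixed seed gives byte-identical outputs.

All emitted truth (anchor positions and copy labels, block segments with
orientation, cluster member coordinates, injected variants) is machine
readable and consistent with the emitted FASTA/GFF coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io_formats import (
    GeneModel,
    SequenceRecord,
    write_fasta,
    write_gene_models,
)
from .polymorphism import VariantRecord, apply_variants

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 0, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class SimConfig:
    seed: int = 1
    n_chrom_a: int = 3
    genes_per_chrom: int = 40
    markers_per_chrom: int = 30
    chrom_len: int = 2_000_000
    gene_len: int = 2500  # nominal mean gene span, used for density checks
    marker_len: int = 300
    query_len: int = 600  # EST-like query fragment taken from each gene
    wgd_divergence: tuple[float, float] = (0.05, 0.08)
    a_divergence: float = 0.02
    inversions_per_chrom: float = 1.0  # Poisson mean per B homeolog
    # span in consecutive features; the floor keeps inverted segments at
    # five or more surviving anchors under default fractionation loss
    inversion_span_features: tuple[int, int] = (8, 14)
    fractionation_loss: float = 0.2
    tandem_families: list[tuple[int, int]] = field(
        default_factory=lambda: [(6, 8000)]
    )
    tandem_member_divergence: float = 0.02
    snp_rate_by_region: dict = field(
        default_factory=lambda: {"exon": 0.003, "intron": 0.008, "utr": 0.004}
    )
    indel_rate_by_region: dict = field(
        default_factory=lambda: {"exon": 0.0003, "intron": 0.0015, "utr": 0.0008}
    )

    def __post_init__(self):
        rates = [self.a_divergence, self.fractionation_loss, *self.wgd_divergence]
        rates += list(self.snp_rate_by_region.values())
        rates += list(self.indel_rate_by_region.values())
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        for count in (self.n_chrom_a, self.genes_per_chrom,
                      self.markers_per_chrom, self.chrom_len, self.gene_len):
            if count < 1:
                raise ValueError("counts and lengths must be >= 1")


@dataclass
class Feature:
    """One annotated interval (gene or marker) on a chromosome."""

    id: str
    kind: str  # "gene" | "marker"
    chrom: str
    start: int
    end: int
    strand: str = "+"
    model: GeneModel | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Genome:
    name: str
    sequences: dict[str, str]
    features: list[Feature]

    def features_on(self, chrom: str) -> list[Feature]:
        return sorted(
            (f for f in self.features if f.chrom == chrom),
            key=lambda f: f.start,
        )

    def records(self) -> list[SequenceRecord]:
        return [
            SequenceRecord(c, "", s) for c, s in sorted(self.sequences.items())
        ]


@dataclass
class TruthSet:
    """Ground truth emitted alongside the synthetic pair."""

    anchors: dict = field(default_factory=dict)
    blocks: list = field(default_factory=list)
    clusters: list = field(default_factory=list)
    variants: dict = field(default_factory=dict)


@dataclass
class SpeciesPair:
    genome_a: Genome
    genome_b: Genome
    truth: TruthSet
    config: SimConfig


# ---------------------------------------------------------------------------
# sequence helpers


def _random_seq(rng, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _mutate(seq: str, rate: float, rng) -> str:
    """Substitute bases uniformly at `rate` per site (always to a different
    base)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    codes = _CODE[arr]
    mask = rng.random(len(arr)) < rate
    shifts = rng.integers(1, 4, size=int(mask.sum()))
    codes[mask] = (codes[mask] + shifts) % 4
    arr[:] = _BASES[codes]
    return arr.tobytes().decode()


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTN", "TGCAN")
    return seq.translate(comp)[::-1]


# ---------------------------------------------------------------------------
# ancestor


def _sample_gene_structure(rng) -> dict:
    """Relative gene architecture: 4-6 exons with a long first exon."""
    n_exons = int(rng.integers(4, 7))
    utr5 = int(rng.integers(60, 150))
    exons = [int(rng.integers(600, 1200))]  # large exon 1
    exons += [int(rng.integers(80, 300)) for _ in range(n_exons - 1)]
    introns = [int(rng.integers(80, 400)) for _ in range(n_exons - 1)]
    utr3 = int(rng.integers(100, 250))
    return {"utr5": utr5, "exons": exons, "introns": introns, "utr3": utr3}


def _structure_to_model(gene_id, chrom, start, struct, strand="+") -> GeneModel:
    pos = start
    utr5 = (pos, pos + struct["utr5"] - 1)
    pos = utr5[1] + 1
    exons = []
    for i, elen in enumerate(struct["exons"]):
        exons.append((pos, pos + elen - 1))
        pos = exons[-1][1] + 1
        if i < len(struct["introns"]):
            pos += struct["introns"][i]
    utr3 = (pos, pos + struct["utr3"] - 1)
    return GeneModel(gene_id, chrom, strand, exons, utr5=utr5, utr3=utr3)


def generate_ancestor(cfg: SimConfig) -> Genome:
    """Simulate the ancestral genome: random chromosomes with genes and
    markers placed uniformly without overlap."""
    rng = np.random.default_rng(cfg.seed)
    sequences: dict[str, str] = {}
    features: list[Feature] = []
    min_gap = 100
    for ci in range(cfg.n_chrom_a):
        chrom = f"anc{ci + 1:02d}"
        items = []
        for gi in range(cfg.genes_per_chrom):
            struct = _sample_gene_structure(rng)
            span = (
                struct["utr5"]
                + sum(struct["exons"])
                + sum(struct["introns"])
                + struct["utr3"]
            )
            items.append(("gene", f"g{ci + 1}-{gi + 1:02d}", span, struct))
        for mi in range(cfg.markers_per_chrom):
            items.append(("marker", f"m{ci + 1}-{mi + 1:02d}", cfg.marker_len, None))
        order = rng.permutation(len(items))
        items = [items[i] for i in order]
        total = sum(it[2] for it in items)
        slack = cfg.chrom_len - total - (len(items) + 1) * min_gap
        if slack < 0 or cfg.genes_per_chrom * cfg.gene_len > cfg.chrom_len:
            raise ValueError(
                "features do not fit on the chromosome; lower the density "
                "(fewer/shorter genes or a longer chromosome)"
            )
        gaps = rng.multinomial(slack, [1.0 / (len(items) + 1)] * (len(items) + 1))
        seq = _random_seq(rng, cfg.chrom_len)
        pos = 1
        for (kind, fid, span, struct), gap in zip(items, gaps):
            pos += int(gap) + min_gap
            start, end = pos, pos + span - 1
            model = (
                _structure_to_model(fid, chrom, start, struct)
                if kind == "gene"
                else None
            )
            features.append(Feature(fid, kind, chrom, start, end, "+", model))
            pos = end + 1
        sequences[chrom] = seq
    return Genome("ancestor", sequences, features)


# ---------------------------------------------------------------------------
# species derivation


def _remap_model(model: GeneModel, mapper, chrom: str, flip: bool) -> GeneModel:
    def mv(iv):
        a, b = mapper(iv[0]), mapper(iv[1])
        return (min(a, b), max(a, b))

    strand = model.strand
    if flip:
        strand = "-" if strand == "+" else "+"
    return GeneModel(
        model.gene_id,
        chrom,
        strand,
        [mv(e) for e in model.exons],
        utr5=mv(model.utr5) if model.utr5 else None,
        utr3=mv(model.utr3) if model.utr3 else None,
    )


def _shift_model(model: GeneModel, delta: int, chrom: str) -> GeneModel:
    return GeneModel(
        model.gene_id,
        chrom,
        model.strand,
        [(s + delta, e + delta) for s, e in model.exons],
        utr5=tuple(x + delta for x in model.utr5) if model.utr5 else None,
        utr3=tuple(x + delta for x in model.utr3) if model.utr3 else None,
    )


def _apply_inversion(seq: str, feats: list[Feature], lo: int, hi: int, chrom: str):
    """Reverse-complement seq[lo..hi] (1-based incl) and remap features."""
    seq = seq[: lo - 1] + _revcomp(seq[lo - 1 : hi]) + seq[hi:]

    def mapper(p: int) -> int:
        return lo + (hi - p)

    out = []
    for f in feats:
        if f.start >= lo and f.end <= hi:
            ns, ne = mapper(f.end), mapper(f.start)
            model = (
                _remap_model(f.model, mapper, chrom, flip=True) if f.model else None
            )
            strand = "-" if f.strand == "+" else "+"
            out.append(Feature(f.id, f.kind, chrom, ns, ne, strand, model))
        else:
            out.append(f)
    return seq, out


def derive_species_pair(ancestor: Genome, cfg: SimConfig) -> SpeciesPair:
    """Derive genome A (single copy) and genome B (two homeologs per
    ancestral chromosome) plus the truth tables."""
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    truth = TruthSet()
    anc_chroms = sorted(ancestor.sequences)

    # ---- genome A: ancestor mutated at a_divergence
    a_sequences, a_features = {}, []
    for ci, anc in enumerate(anc_chroms):
        chrom = f"A{ci + 1:02d}"
        a_sequences[chrom] = _mutate(ancestor.sequences[anc], cfg.a_divergence, rng)
        for f in ancestor.features_on(anc):
            model = _shift_model(f.model, 0, chrom) if f.model else None
            a_features.append(
                Feature(f.id, f.kind, chrom, f.start, f.end, f.strand, model)
            )
    genome_a = Genome("A", a_sequences, a_features)

    for f in a_features:
        truth.anchors[f.id] = {
            "kind": f.kind,
            "a_chrom": f.chrom,
            "a_pos": f.start,
            "b": [],
        }

    # ---- designate tandem-family genes (one per configured family)
    gene_ids = [f.id for f in ancestor.features if f.kind == "gene"]
    tandem_plan = []  # (gene_id, fam_size, spacing, b_chrom_name)
    taken = set()
    for fam_size, spacing in cfg.tandem_families:
        while True:
            gid = gene_ids[int(rng.integers(0, len(gene_ids)))]
            if gid not in taken:
                taken.add(gid)
                break
        copy_idx = int(rng.integers(0, 2))
        tandem_plan.append((gid, fam_size, spacing, copy_idx))
    tandem_by_gene = {p[0]: p for p in tandem_plan}

    # ---- genome B: two homeologs per ancestral chromosome
    b_sequences, b_features = {}, []
    for ci, anc in enumerate(anc_chroms):
        for copy_idx, rate in enumerate(cfg.wgd_divergence):
            chrom = f"B{2 * ci + copy_idx + 1:02d}"
            seq = _mutate(ancestor.sequences[anc], rate, rng)
            feats = [
                Feature(
                    f.id, f.kind, chrom, f.start, f.end, f.strand,
                    _shift_model(f.model, 0, chrom) if f.model else None,
                )
                for f in ancestor.features_on(anc)
            ]

            # inversions: disjoint windows of consecutive features, chosen up
            # front (one-feature buffer between windows) so segment bounds
            # come from the unperturbed layout and windows never interact
            n_inv = int(rng.poisson(cfg.inversions_per_chrom))
            used_idx: set[int] = set()
            windows = []
            for _ in range(n_inv):
                w = int(
                    rng.integers(
                        cfg.inversion_span_features[0],
                        cfg.inversion_span_features[1] + 1,
                    )
                )
                if w >= len(feats) - 1:
                    continue
                for _try in range(20):
                    s = int(rng.integers(1, len(feats) - w))
                    if not set(range(s - 1, s + w + 1)) & used_idx:
                        break
                else:
                    continue
                used_idx |= set(range(s, s + w))
                first, last = feats[s], feats[s + w - 1]
                lo = (feats[s - 1].end + first.start) // 2 + 1
                hi = (last.end + feats[s + w].start) // 2
                windows.append((lo, hi, {f.id for f in feats[s : s + w]}))
            inv_id_sets = []
            for lo, hi, ids in windows:
                seq, feats = _apply_inversion(seq, feats, lo, hi, chrom)
                inv_id_sets.append(ids)

            # tandem expansion (after inversions; insertion shifts downstream)
            feats.sort(key=lambda f: f.start)
            for gid, fam_size, spacing, tcopy in tandem_plan:
                if tcopy != copy_idx:
                    continue
                match = [f for f in feats if f.id == gid]
                if not match:
                    continue
                base = match[0]
                unit_len = spacing
                if base.length + 200 > unit_len:
                    unit_len = base.length + 200
                gene_seq = seq[base.start - 1 : base.end]
                insert_chunks = []
                member_starts = [base.start]
                for m in range(1, fam_size):
                    filler = _random_seq(rng, unit_len - base.length)
                    copy_seq = _mutate(
                        gene_seq, cfg.tandem_member_divergence, rng
                    )
                    insert_chunks.append(filler + copy_seq)
                    member_starts.append(base.start + m * unit_len)
                insert = "".join(insert_chunks)
                p = base.end  # insert after the gene
                seq = seq[:p] + insert + seq[p:]
                delta = len(insert)
                for f in feats:
                    if f.start > p:
                        f.start += delta
                        f.end += delta
                        if f.model:
                            f.model = _shift_model(f.model, delta, chrom)
                truth.clusters.append(
                    {
                        "query_id": gid,
                        "chrom_b": chrom,
                        "member_starts": member_starts,
                        "spacing": unit_len,
                        "size": fam_size,
                    }
                )

            # fractionation: physically delete duplicated gene copies
            survivors = []
            lost = set()
            for f in sorted(feats, key=lambda f: -f.start):
                if (
                    f.kind == "gene"
                    and f.id not in tandem_by_gene
                    and rng.random() < cfg.fractionation_loss
                ):
                    seq = seq[: f.start - 1] + seq[f.end :]
                    delta = f.length
                    lost.add(f.id)
                    for g in feats:
                        if g.start > f.end:
                            g.start -= delta
                            g.end -= delta
                            if g.model:
                                g.model = _shift_model(g.model, -delta, chrom)
                else:
                    survivors.append(f)
            feats = sorted(survivors, key=lambda f: f.start)

            b_sequences[chrom] = seq
            b_features.extend(feats)
            for f in feats:
                truth.anchors[f.id]["b"].append(
                    {
                        "chrom": chrom,
                        "pos": f.start,
                        "copy_index": copy_idx,
                        "strand": f.strand,
                        "surviving": True,
                    }
                )
            for gid in lost:
                truth.anchors[gid]["b"].append(
                    {
                        "chrom": chrom,
                        "pos": None,
                        "copy_index": copy_idx,
                        "strand": None,
                        "surviving": False,
                    }
                )

            # truth blocks: surviving features partitioned by inversion windows
            a_chrom = f"A{ci + 1:02d}"
            anc_order = {
                f.id: f.start for f in ancestor.features_on(anc)
            }
            ordered = sorted(feats, key=lambda f: anc_order[f.id])
            segments: list[tuple[str, list[Feature]]] = []
            for f in ordered:
                seg = next(
                    (f"inv{k}" for k, ids in enumerate(inv_id_sets) if f.id in ids),
                    None,
                )
                if seg is None:
                    n_before = sum(
                        1
                        for ids in inv_id_sets
                        if max(anc_order[i] for i in ids if i in anc_order)
                        < anc_order[f.id]
                        if ids
                    )
                    seg = f"fwd{n_before}"
                if segments and segments[-1][0] == seg:
                    segments[-1][1].append(f)
                else:
                    segments.append((seg, [f]))
            for seg, members in segments:
                truth.blocks.append(
                    {
                        "chrom_a": a_chrom,
                        "chrom_b": chrom,
                        "orientation": "reverse" if seg.startswith("inv") else "forward",
                        "queries": [f.id for f in members],
                        "n": len(members),
                    }
                )

    genome_b = Genome("B", b_sequences, b_features)
    return SpeciesPair(genome_a, genome_b, truth, cfg)


def make_queries(pair: SpeciesPair) -> tuple[list[SequenceRecord], dict[str, str]]:
    """EST-like query set: a fragment from the start of each genome-A gene
    plus each full marker sequence. Returns (records, categories)."""
    cfg = pair.config
    queries, categories = [], {}
    for f in sorted(pair.genome_a.features, key=lambda f: (f.chrom, f.start)):
        seq = pair.genome_a.sequences[f.chrom]
        if f.kind == "gene":
            frag = seq[f.start - 1 : f.start - 1 + min(cfg.query_len, f.length)]
            categories[f.id] = "gene"
        else:
            frag = seq[f.start - 1 : f.end]
            categories[f.id] = "g_marker"
        queries.append(SequenceRecord(f.id, f"{f.chrom}:{f.start}", frag))
    return queries, categories


# ---------------------------------------------------------------------------
# allelic variant injection


def _region_type(label: str) -> str:
    if label.endswith("UTR"):
        return "utr"
    return "exon" if label.startswith("E") else "intron"


def inject_allelic_variants(
    gene: SequenceRecord,
    model: GeneModel,
    cfg: SimConfig,
    rng=None,
) -> tuple[SequenceRecord, list[VariantRecord]]:
    """Create a variant allele of ``gene`` with SNPs and indels placed per
    region at the configured rates.

    Events never overlap (>= 12 bp apart), stay >= 10 bp from region
    boundaries, and indels are placed in left-normalized form in
    non-repetitive context so truth coordinates are exact. Returns the
    variant allele and the truth records (kind, position, length, region).
    """
    rng = np.random.default_rng(cfg.seed + 97) if rng is None else rng
    ref = gene.residues
    margin, spacing = 10, 12
    occupied: list[tuple[int, int]] = []

    def free(lo: int, hi: int) -> bool:
        return all(hi < s - spacing or lo > e + spacing for s, e in occupied)

    events: list[VariantRecord] = []
    for label, rs, re_ in model.regions():
        rtype = _region_type(label)
        rlen = re_ - rs + 1
        if rlen < 2 * margin + 2:
            continue
        n_snp = rng.binomial(rlen, cfg.snp_rate_by_region.get(rtype, 0.0))
        n_indel = rng.binomial(rlen, cfg.indel_rate_by_region.get(rtype, 0.0))
        for _ in range(int(n_indel)):
            for _try in range(50):
                length = min(20, int(rng.geometric(0.35)))
                kind = "deletion" if rng.random() < 0.5 else "insertion"
                if re_ - margin - length <= rs + margin:
                    continue
                pos = int(rng.integers(rs + margin, re_ - margin - length))
                if kind == "deletion":
                    s, e = pos + 1, pos + length
                    if not free(s - 1, e + 1):
                        continue
                    if ref[s - 2] == ref[e - 1]:
                        continue  # would left-shift
                    run = ref[s - 1 : e]
                    if ref[max(0, s - 1 - length) : s - 1] == run:
                        continue
                    if ref[e : e + length] == run:
                        continue
                    events.append(
                        VariantRecord(
                            kind="deletion",
                            ref_pos=s - 1,
                            length=length,
                            region=label,
                            ref_bases=run,
                        )
                    )
                    occupied.append((s - 1, e + 1))
                else:
                    ins = _random_seq(rng, length)
                    if not free(pos, pos + 1):
                        continue
                    if ins[-1] == ref[pos - 1] or ins[0] == ref[pos]:
                        continue
                    if ins == ref[pos : pos + length]:
                        continue
                    if ins == ref[pos - length : pos]:
                        continue
                    events.append(
                        VariantRecord(
                            kind="insertion",
                            ref_pos=pos,
                            length=length,
                            region=label,
                            qry_bases=ins,
                        )
                    )
                    occupied.append((pos, pos + 1))
                break
        for _ in range(int(n_snp)):
            for _try in range(50):
                pos = int(rng.integers(rs + margin, re_ - margin + 1))
                if not free(pos, pos):
                    continue
                base = ref[pos - 1]
                alt = "ACGT"[("ACGT".index(base) + int(rng.integers(1, 4))) % 4]
                events.append(
                    VariantRecord(
                        kind="SNP",
                        ref_pos=pos,
                        region=label,
                        ref_bases=base,
                        qry_bases=alt,
                    )
                )
                occupied.append((pos, pos))
                break

    events.sort(key=lambda v: (v.ref_pos, v.kind))
    # fill in query coordinates for insertions
    shift = 0
    for v in events:
        if v.kind == "insertion":
            qs = v.ref_pos + shift + 1
            v.qry_range = (qs, qs + v.length - 1)
            shift += v.length
        elif v.kind == "deletion":
            shift -= v.length
    alt = apply_variants(ref, events)
    return SequenceRecord(gene.id + "_alt", "variant allele", alt), events


def extract_gene(pair: SpeciesPair, feature: Feature) -> tuple[SequenceRecord, GeneModel]:
    """Genomic sequence and gene-local model (coordinates from 1) for one
    genome-A gene."""
    seq = pair.genome_a.sequences[feature.chrom]
    sub = seq[feature.start - 1 : feature.end]
    model = _shift_model(feature.model, -(feature.start - 1), feature.id)
    return SequenceRecord(feature.id, f"{feature.chrom}:{feature.start}", sub), model


# ---------------------------------------------------------------------------
# fixture bundles


def write_fixture_set(cfg: SimConfig, outdir) -> Path:
    """Write a complete, self-describing fixture bundle: genomes A/B with
    gene models, the query set, allelic gene pairs with injected variants,
    and machine-readable truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ancestor = generate_ancestor(cfg)
    pair = derive_species_pair(ancestor, cfg)
    queries, categories = make_queries(pair)

    write_fasta(pair.genome_a.records(), outdir / "genome_a.fasta")
    write_fasta(pair.genome_b.records(), outdir / "genome_b.fasta")
    write_gene_models(
        [f.model for f in pair.genome_a.features if f.model],
        outdir / "genome_a.gff3",
    )
    write_gene_models(
        [f.model for f in pair.genome_b.features if f.model],
        outdir / "genome_b.gff3",
    )
    write_fasta(queries, outdir / "queries.fasta")
    (outdir / "query_categories.tsv").write_text(
        "".join(f"{q}\t{c}\n" for q, c in sorted(categories.items()))
    )

    rng = np.random.default_rng(cfg.seed + 2_000_003)
    alleles_dir = outdir / "alleles"
    alleles_dir.mkdir(exist_ok=True)
    genes = [f for f in pair.genome_a.features if f.kind == "gene"]
    for f in genes[:8]:
        record, model = extract_gene(pair, f)
        alt, variants = inject_allelic_variants(record, model, cfg, rng)
        write_fasta([record, alt], alleles_dir / f"{f.id}.fasta")
        write_gene_models([model], alleles_dir / f"{f.id}.gff3")
        pair.truth.variants[f.id] = [
            {
                "kind": v.kind,
                "ref_pos": v.ref_pos,
                "length": v.length,
                "qry_range": list(v.qry_range) if v.qry_range else None,
                "region": v.region,
            }
            for v in variants
        ]

    (outdir / "truth.json").write_text(
        json.dumps(asdict(pair.truth), indent=2, sort_keys=True)
    )
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
        },
        "files": sorted(
            str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
            if p.name != "manifest.json"
        ),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
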