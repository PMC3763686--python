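"""End-to-end pipeline driver over synthetic genome pairs, and the metrics
used to score recovery against the generator's truth (copy-assignment
recovery, synteny-block F1 with orientation accuracy, planted-homolog
detection, allelic-variant recovery)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .homology import (
    CopyAssignment,
    SearchParams,
    TargetIndex,
    assign_copies,
    filter_hits,
    local_search,
)
from .insilico_map import ChromosomeMap, build_map
from .io_formats import SequenceRecord
from .polymorphism import (
    apply_variants,
    classify_variants,
    extract_variants,
    global_align,
)
from .synteny import Anchor, SyntenyBlock, detect_blocks, find_shared_features
from .synthetic_data import (
    SimConfig,
    SpeciesPair,
    derive_species_pair,
    generate_ancestor,
    inject_allelic_variants,
    make_queries,
)


@dataclass
class PipelineResult:
    pair: SpeciesPair
    queries: list[SequenceRecord]
    assignments_a: dict[str, CopyAssignment]
    assignments_b: dict[str, CopyAssignment]
    maps_a: list[ChromosomeMap]
    maps_b: list[ChromosomeMap]
    anchors: list[Anchor]
    blocks: list[SyntenyBlock]
    stage_counts: dict = field(default_factory=dict)


def run_synthetic_pipeline(
    cfg: SimConfig,
    params: SearchParams | None = None,
    min_block: int = 3,
    max_rank_gap: int = 2,
) -> PipelineResult:
    """Simulate a genome pair and run search -> filter -> assign -> maps ->
    anchors -> blocks."""
    params = params or SearchParams()
    ancestor = generate_ancestor(cfg)
    pair = derive_species_pair(ancestor, cfg)
    queries, categories = make_queries(pair)

    targets_a = pair.genome_a.records()
    targets_b = pair.genome_b.records()
    idx_a = {t.id: TargetIndex(t.residues, params.k) for t in targets_a}
    idx_b = {t.id: TargetIndex(t.residues, params.k) for t in targets_b}

    assignments_a, assignments_b = {}, {}
    for q in queries:
        hits_a = filter_hits(local_search(q, targets_a, params, idx_a), params)
        hits_b = filter_hits(local_search(q, targets_b, params, idx_b), params)
        assignments_a[q.id] = assign_copies(q.id, hits_a, mode="single")
        assignments_b[q.id] = assign_copies(q.id, hits_b, mode="duplicated")

    maps_a = build_map(list(assignments_a.values()), categories=categories)
    maps_b = build_map(list(assignments_b.values()), categories=categories)
    anchors = find_shared_features(maps_a, maps_b)
    blocks = detect_blocks(anchors, min_block=min_block, max_rank_gap=max_rank_gap)
    counts = {
        "queries": len(queries),
        "anchored_a": sum(1 for a in assignments_a.values() if a.copies),
        "anchored_b": sum(1 for a in assignments_b.values() if a.copies),
        "anchors": len(anchors),
        "blocks": len(blocks),
    }
    return PipelineResult(
        pair, queries, assignments_a, assignments_b, maps_a, maps_b,
        anchors, blocks, counts,
    )


# ---------------------------------------------------------------------------
# copy-assignment recovery


def copy_recovery_duplicated(result: PipelineResult) -> float:
    """Fraction of queries with both homeolog copies surviving whose
    duplicated-mode assignment recovers exactly the two truth chromosomes."""
    truth = result.pair.truth.anchors
    eligible = correct = 0
    for qid, t in truth.items():
        surv = [b for b in t["b"] if b["surviving"]]
        if len({b["chrom"] for b in surv}) != 2:
            continue
        eligible += 1
        got = set(result.assignments_b[qid].chromosomes)
        if got == {b["chrom"] for b in surv}:
            correct += 1
    if eligible == 0:
        raise ValueError("no queries with two surviving copies")
    return correct / eligible


def copy_recovery_single(result: PipelineResult) -> float:
    """Fraction of queries whose single-mode assignment recovers the truth
    genome-A chromosome."""
    truth = result.pair.truth.anchors
    correct = 0
    for qid, t in truth.items():
        got = result.assignments_a[qid].chromosomes
        if got and got[0] == t["a_chrom"]:
            correct += 1
    return correct / len(truth)


# ---------------------------------------------------------------------------
# synteny-block recovery


def _match_blocks(detected: list[SyntenyBlock], truth_blocks: list[dict],
                  min_jaccard: float = 0.5):
    """Greedy one-to-one matching between detected and truth blocks on the
    same chromosome pair, requiring anchor-set Jaccard >= min_jaccard."""
    pairs = []
    for ti, t in enumerate(truth_blocks):
        tset = set(t["queries"])
        for di, d in enumerate(detected):
            if d.chrom_a != t["chrom_a"] or d.chrom_b != t["chrom_b"]:
                continue
            dset = {_strip_labels(a.feature_id) for a in d.anchors}
            jac = len(tset & dset) / len(tset | dset)
            if jac >= min_jaccard:
                pairs.append((jac, ti, di))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_t, used_d, matches = set(), set(), []
    for jac, ti, di in pairs:
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        matches.append((ti, di, jac))
    return matches


def _strip_labels(feature_id: str) -> str:
    from .synteny import infer_source_query

    return infer_source_query(feature_id)


def block_recovery(
    result: PipelineResult,
    min_truth_anchors: int = 3,
    min_jaccard: float = 0.5,
) -> dict:
    """Block-level F1 against truth segments, plus orientation accuracy over
    matched truth blocks (including every recovered inverted segment)."""
    truth_blocks = [
        t for t in result.pair.truth.blocks if t["n"] >= min_truth_anchors
    ]
    detected = result.blocks
    matches = _match_blocks(detected, truth_blocks, min_jaccard)
    tp = len(matches)
    precision = tp / len(detected) if detected else 0.0
    recall = tp / len(truth_blocks) if truth_blocks else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    orient_total = orient_ok = 0
    inv_total = inv_ok = 0
    for ti, di, _ in matches:
        t, d = truth_blocks[ti], detected[di]
        orient_total += 1
        ok = d.orientation == t["orientation"]
        orient_ok += ok
        if t["orientation"] == "reverse":
            inv_total += 1
            inv_ok += ok
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "n_truth": len(truth_blocks),
        "n_detected": len(detected),
        "orientation_accuracy": orient_ok / orient_total if orient_total else 1.0,
        "inverted_recovered": inv_total,
        "inverted_orientation_accuracy": inv_ok / inv_total if inv_total else 1.0,
    }


# ---------------------------------------------------------------------------
# planted-homolog detection


def planted_homolog_rate(
    n_trials: int = 100,
    seed: int = 0,
    target_len: int = 100_000,
    homolog_len: int = 200,
    identity: float = 0.95,
    params: SearchParams | None = None,
) -> float:
    """Fraction of seeded trials in which a homolog planted at the given
    identity inside a random target is found by the search with a filtered
    hit overlapping the planted interval."""
    from .synthetic_data import _mutate, _random_seq

    params = params or SearchParams()
    rng = np.random.default_rng(seed)
    found = 0
    for _ in range(n_trials):
        query_seq = _random_seq(rng, homolog_len)
        target_seq = _random_seq(rng, target_len)
        pos = int(rng.integers(0, target_len - homolog_len))
        planted = _mutate(query_seq, 1.0 - identity, rng)
        target_seq = (
            target_seq[:pos] + planted + target_seq[pos + homolog_len:]
        )
        query = SequenceRecord("q", "", query_seq)
        target = SequenceRecord("t", "", target_seq)
        hits = filter_hits(local_search(query, [target], params), params)
        for h in hits:
            ov = min(h.t_end, pos + homolog_len) - max(h.t_start, pos + 1) + 1
            if ov > 0 and h.alignment_length >= params.min_aln_len:
                found += 1
                break
    return found / n_trials


# ---------------------------------------------------------------------------
# allelic-variant recovery


def variant_recovery(
    n_pairs: int = 50,
    seed: int = 0,
    cfg: SimConfig | None = None,
) -> dict:
    """Inject variants into synthetic allele pairs, re-extract them through
    alignment, and compare to truth exactly (kind, position, length, region);
    also checks that applying the extracted variants regenerates the variant
    allele byte-exactly."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(seed)
    base = generate_ancestor(
        SimConfig(
            seed=seed,
            n_chrom_a=1,
            genes_per_chrom=max(n_pairs, 1),
            markers_per_chrom=1,
            chrom_len=max(200_000, n_pairs * 5000),
        )
    )
    pair_cfg = cfg
    exact = 0
    reconstructed = 0
    genes = [f for f in base.features if f.kind == "gene"][:n_pairs]
    chrom = genes[0].chrom
    seq = base.sequences[chrom]
    from .synthetic_data import _shift_model

    for f in genes:
        record = SequenceRecord(f.id, "", seq[f.start - 1 : f.end])
        model = _shift_model(f.model, -(f.start - 1), f.id)
        alt, truth = inject_allelic_variants(record, model, pair_cfg, rng)
        aln = global_align(record, alt)
        variants = classify_variants(extract_variants(aln), model)
        if apply_variants(record.residues, variants) == alt.residues:
            reconstructed += 1
        got = sorted(
            (v.kind, v.ref_pos, v.length, v.qry_range, v.region)
            for v in variants
        )
        want = sorted(
            (v.kind, v.ref_pos, v.length, v.qry_range, v.region)
            for v in truth
        )
        if got == want:
            exact += 1
    return {
        "n_pairs": len(genes),
        "exact_recovery_rate": exact / len(genes),
        "reconstruction_rate": reconstructed / len(genes),
    }
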