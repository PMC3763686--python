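"""Published reference values bundled for arithmetic checks and worked
examples.

These are the chromosome-level characteristics of the published common bean
(Pv) and soybean (Gm) phenylpropanoid-pathway in-silico sequence maps
(per-chromosome feature counts and start/end physical positions), the two
4CL1 paralog start positions on Pv3, the four-member CHS tandem cluster on
Pv2, and the region-level polymorphism rows for two OAC Rex 4CL accessions
(KF303291: 18 SNPs and two deletions; KF303292: a perfect alignment, all
zeros).

Coverage values are deliberately NOT stored: they are recomputed from the
start/end columns by :func:`published_map`. Note the published common bean
per-chromosome feature counts sum to 505 although the published total row
prints 507; this package always reports the computed sum.
"""

from __future__ import annotations

from .insilico_map import ChromosomeMap, MapFeature
from .io_formats import GeneModel
from .polymorphism import VariantRecord

# chromosome, total features, start (nt), end (nt)
COMMON_BEAN_MAP_TABLE = [
    ("Pv1", 56, 1_071_371, 52_150_964),
    ("Pv2", 83, 238_724, 48_041_224),
    ("Pv3", 54, 950_004, 51_791_104),
    ("Pv4", 25, 1_428_273, 45_736_396),
    ("Pv5", 26, 2_347_029, 40_478_924),
    ("Pv6", 51, 9_243_136, 31_761_604),
    ("Pv7", 51, 599_228, 50_145_180),
    ("Pv8", 69, 155_567, 59_310_664),
    ("Pv9", 40, 5_750_860, 36_534_776),
    ("Pv10", 25, 2_032_367, 43_002_236),
    ("Pv11", 25, 169_275, 49_713_356),
]

SOYBEAN_MAP_TABLE = [
    ("Gm01", 33, 992_725, 55_451_076),
    ("Gm02", 59, 19_669, 51_366_328),
    ("Gm03", 33, 1_606_119, 46_881_240),
    ("Gm04", 35, 189_069, 48_284_344),
    ("Gm05", 46, 242_329, 41_919_824),
    ("Gm06", 52, 229_125, 50_276_300),
    ("Gm07", 54, 305_682, 42_294_768),
    ("Gm08", 100, 329_749, 46_669_032),
    ("Gm09", 65, 349_423, 45_986_536),
    ("Gm10", 47, 648_359, 50_652_976),
    ("Gm11", 52, 305_133, 39_002_116),
    ("Gm12", 34, 136_883, 39_748_568),
    ("Gm13", 74, 798_836, 44_256_628),
    ("Gm14", 48, 402_041, 48_273_860),
    ("Gm15", 55, 190_218, 50_089_752),
    ("Gm16", 31, 493_954, 37_180_576),
    ("Gm17", 44, 542_091, 40_950_824),
    ("Gm18", 71, 31_200, 62_243_640),
    ("Gm19", 41, 740_074, 50_265_556),
    ("Gm20", 37, 1_123_688, 46_134_760),
]

# the two 4CL1 paralog start positions on common bean chromosome Pv3
FOUR_CL1_PARALOG_STARTS = {"4CL1-2": 34_628_464, "4CL1-1": 34_642_252}

# four-member CHS tandem cluster on common bean chromosome Pv2 (start nt)
CHS_CLUSTER_PV2_STARTS = (3_726_784, 3_733_338, 3_765_494, 3_775_079)


def published_map(table) -> list[ChromosomeMap]:
    """Represent each published chromosome row as a two-feature map (the
    first and last mapped feature positions) so that summary arithmetic runs
    through the same code path as computed maps."""
    maps = []
    for chrom, _n, start, end in table:
        maps.append(
            ChromosomeMap(
                chrom,
                [
                    MapFeature(f"{chrom}-first", chrom, start, "+", "gene"),
                    MapFeature(f"{chrom}-last", chrom, end, "+", "gene"),
                ],
            )
        )
    return maps


def feature_counts(table) -> dict[str, int]:
    return {chrom: n for chrom, n, _s, _e in table}


# ---------------------------------------------------------------------------
# published 4CL polymorphism rows (region-level)

# KF303291 vs Phvul.006G057300: SNP counts per region plus two deletions
# ("864 (-8)" in I1 and "2716 (-1)" in I4); the gene model lacks a 3'UTR row.
KF303291_SNPS = {
    "5'UTR": 0, "E1": 3, "I1": 4, "E2": 2, "I2": 0, "E3": 0, "I3": 0,
    "E4": 0, "I4": 4, "E5": 0, "I5": 4, "E6": 1,
}
KF303291_DELETIONS = [("I1", 864, 8), ("I4", 2716, 1)]

# KF303292 vs Phvul.011G020200: the alignment between genotypes was perfect.
KF303292_SNPS = {
    "5'UTR": 0, "E1": 0, "I1": 0, "E2": 0, "I2": 0, "E3": 0, "I3": 0,
    "E4": 0, "I4": 0, "E5": 0,
}


def kf303291_gene_model() -> GeneModel:
    """Synthetic coordinate scaffold for the KF303291 reference locus.

    The published table reports region labels only; these exon/intron
    coordinates are synthetic but consistent with the published region
    assignments (position 865 falls in intron 1 and 2717 in intron 4) and the
    aligned reference length of 3436 nt.
    """
    return GeneModel(
        gene_id="Phvul.006G057300",
        seq_id="Phvul.006G057300",
        strand="+",
        exons=[
            (101, 700),    # E1
            (1101, 1300),  # E2
            (1701, 1900),  # E3
            (2201, 2400),  # E4
            (2901, 3000),  # E5
            (3301, 3436),  # E6
        ],
        utr5=(1, 100),
    )


def kf303291_variants() -> list[VariantRecord]:
    """Variant records reconstructed from the published region-level row.

    SNP positions are not printed, so each SNP is placed at a synthetic
    position inside its published region; the two deletions use their
    published reference coordinates and lengths.
    """
    model = kf303291_gene_model()
    spans = {label: (s, e) for label, s, e in model.regions()}
    records: list[VariantRecord] = []
    for region, count in KF303291_SNPS.items():
        s, _e = spans[region]
        for i in range(count):
            records.append(
                VariantRecord(kind="SNP", ref_pos=s + 20 + 3 * i, region=region)
            )
    for region, ref_pos, length in KF303291_DELETIONS:
        records.append(
            VariantRecord(
                kind="deletion", ref_pos=ref_pos, length=length, region=region
            )
        )
    return records
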