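"""Default amplicon panel for chromosome-9 fine-mapping simulations.

The 48 diagnostic-SNP amplicon positions (bp, 1-based) below are the
chromosome-9 marker panel used for amplicon-sequencing fine mapping of the
secondary Cry1Ac-resistance locus; they span ~1.27-12.02 Mb and are densest
around the aminopeptidase-N gene cluster near 2 Mb.
"""

from __future__ import annotations

from .genome import ChromosomeMap, GenomeMap

CHR9_AMPLICON_POSITIONS = (
    1_270_927, 1_528_061, 1_767_405, 1_867_402, 1_975_571, 2_024_328,
    2_073_992, 2_094_322, 2_162_567, 2_253_615, 2_342_930, 2_442_248,
    2_546_746, 2_636_392, 2_721_717, 2_813_373, 2_911_624, 3_327_419,
    3_667_757, 3_782_249, 4_635_304, 4_731_012, 4_826_566, 4_953_916,
    5_062_280, 5_154_509, 5_255_852, 6_649_406, 6_762_647, 6_864_555,
    9_011_689, 9_981_535, 10_087_559, 10_189_242, 10_287_749, 10_398_424,
    10_511_091, 10_622_622, 10_734_239, 10_839_102, 10_917_949, 11_065_021,
    11_229_448, 11_329_127, 11_429_199, 11_498_404, 11_584_169, 12_015_084,
)


def finemap_genome(causal_pos: int = 2_100_000, physical_length: int = 12_500_000,
                   genetic_length: float = 50.0):
    """Single-chromosome map for fine-mapping simulations.

    Markers are the 48 panel positions plus the causal site. Returns
    ``(gmap, r2_locus, amplicon_markers)`` where ``amplicon_markers`` is the
    (chrom, pos) list to pass to the amplicon simulator.
    """
    markers = sorted(set(CHR9_AMPLICON_POSITIONS) | {int(causal_pos)})
    chrom = ChromosomeMap(
        label="chr9",
        physical_length=physical_length,
        genetic_length=genetic_length,
        markers=markers,
    )
    gmap = GenomeMap(chromosomes=(chrom,))
    amplicons = [("chr9", p) for p in CHR9_AMPLICON_POSITIONS]
    return gmap, ("chr9", int(causal_pos)), amplicons
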