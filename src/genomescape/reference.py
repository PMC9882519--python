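"""Reference genome dictionaries.

All coordinates in the package are 0-based, half-open. A reference
dictionary is a mapping ``chrom -> length``; every interval is validated
against one. The default is the GRCh38 primary assembly; simulations use
small toy genomes with named p/q arms so whole-cohort runs stay desk-scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# GRCh38 primary-assembly chromosome lengths.
GRCH38_LENGTHS: dict[str, int] = {
    "chr1": 248956422, "chr2": 242193529, "chr3": 198295559,
    "chr4": 190214555, "chr5": 181538259, "chr6": 170805979,
    "chr7": 159345973, "chr8": 145138636, "chr9": 138394717,
    "chr10": 133797422, "chr11": 135086622, "chr12": 133275309,
    "chr13": 114364328, "chr14": 107043718, "chr15": 101991189,
    "chr16": 90338345, "chr17": 83257441, "chr18": 80373285,
    "chr19": 58617616, "chr20": 64444167, "chr21": 46709983,
    "chr22": 50818468, "chrX": 156040895, "chrY": 57227415,
}

SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})

# TP53 gene body on GRCh38 (0-based half-open).
TP53_LOCUS_GRCH38 = ("chr17", 7668401, 7687549)


@dataclass(frozen=True)
class ReferenceDict:
    """Chromosome name -> length table, with optional arm boundaries.

    ``centromeres`` maps a chromosome to the position splitting its p arm
    ``[0, cen)`` from its q arm ``[cen, length)``.
    """

    lengths: dict[str, int]
    centromeres: dict[str, int] = field(default_factory=dict)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in reference dictionary") from None

    def autosomes(self) -> list[str]:
        return [c for c in self.lengths if c not in SEX_CHROMS]

    def arm(self, chrom: str, arm: str) -> tuple[int, int]:
        """Return the (start, end) of arm 'p' or 'q' of ``chrom``."""
        cen = self.centromeres.get(chrom)
        if cen is None:
            raise KeyError(f"no centromere recorded for {chrom!r}")
        if arm == "p":
            return 0, cen
        if arm == "q":
            return cen, self.length(chrom)
        raise ValueError(f"arm must be 'p' or 'q', got {arm!r}")

    def arm_of(self, chrom: str, pos: int) -> str:
        cen = self.centromeres.get(chrom)
        if cen is None:
            raise KeyError(f"no centromere recorded for {chrom!r}")
        return "p" if pos < cen else "q"


def grch38() -> ReferenceDict:
    return ReferenceDict(lengths=dict(GRCH38_LENGTHS))


def toy_genome() -> ReferenceDict:
    """Four-chromosome toy genome (10-50 Mb) mirroring the recurrently
    altered chromosomes of TP53-mutated myeloid malignancies.

    chr5 and chr7 carry the common q-arm losses, chr12p hosts the toy ETV6
    locus, chr17p the toy TP53 locus.
    """
    return ReferenceDict(
        lengths={"chr5": 50_000_000, "chr7": 40_000_000,
                 "chr12": 30_000_000, "chr17": 20_000_000},
        centromeres={"chr5": 25_000_000, "chr7": 20_000_000,
                     "chr12": 14_000_000, "chr17": 8_000_000},
    )


# Toy gene annotation (chrom, start, end) used by simulations and examples.
TOY_GENES: dict[str, tuple[str, int, int]] = {
    "TP53": ("chr17", 5_000_000, 5_020_000),
    "NF1": ("chr17", 12_000_000, 12_280_000),
    "ETV6": ("chr12", 11_000_000, 11_240_000),
    "CDKN1B": ("chr12", 12_400_000, 12_410_000),
    "EGR1": ("chr5", 35_000_000, 35_004_000),
    "EZH2": ("chr7", 32_000_000, 32_080_000),
}

TP53_LOCUS_TOY = TOY_GENES["TP53"]
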