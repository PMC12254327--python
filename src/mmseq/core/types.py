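"""Shared domain types for the MM-seq co-detection pipeline.

Coordinates are 0-based half-open everywhere inside the package; converters
at the I/O boundaries (SAM, BED) apply the convention exactly once.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Stream(enum.Enum):
    """Which information channel a read pair / fragment carries.

    GENET: protected copy strand, UMIs intact -> genetic alterations.
    METH:  original strand, UMIs C->T (G->A) converted -> methylation.
    """

    GENET = "GENET"
    METH = "METH"
    UNASSIGNED = "UNASSIGNED"


class MatchMode(enum.Enum):
    EXACT = "EXACT"
    C2T = "C2T"
    G2A = "G2A"
    NONE = "NONE"


class Meth(enum.IntEnum):
    UNMETHYLATED = 0
    METHYLATED = 1


class RegionKind(enum.Enum):
    SEQUENCE_PROBE = "SEQUENCE_PROBE"
    METHYL_MARKER = "METHYL_MARKER"
    IMMUNE_MARKER = "IMMUNE_MARKER"
    PROMOTER_CLUSTER = "PROMOTER_CLUSTER"


# SAM flag pairs for the four legal duplex strand/stream combinations.
GENET_WATSON_FLAGS = (99, 147)
GENET_CRICK_FLAGS = (83, 163)
METH_WATSON_FLAGS = (67, 131)
METH_CRICK_FLAGS = (115, 179)

WATSON = "WATSON"
CRICK = "CRICK"


def strand_of_flags(flag1: int, flag2: int) -> str | None:
    """Watson/Crick class of a duplex flag pair, or None if not a legal pair."""
    pair = (flag1, flag2)
    if pair in (GENET_WATSON_FLAGS, METH_WATSON_FLAGS):
        return WATSON
    if pair in (GENET_CRICK_FLAGS, METH_CRICK_FLAGS):
        return CRICK
    return None


@dataclass
class ReadPair:
    """A paired-end read whose mates each start with an 8-base observed UMI."""

    name: str
    read1_seq: str
    read2_seq: str
    read1_qual: str
    read2_qual: str
    umi_length: int = 8

    def __post_init__(self) -> None:
        if len(self.read1_seq) < self.umi_length or len(self.read2_seq) < self.umi_length:
            raise ValueError(f"read pair {self.name!r}: mate shorter than the UMI length")

    @property
    def umi1(self) -> str:
        return self.read1_seq[: self.umi_length]

    @property
    def umi2(self) -> str:
        return self.read2_seq[: self.umi_length]


@dataclass
class AlignedFragment:
    """A mapped molecule with strand flags, UMI pair and (for METH) CpG states.

    ``bases`` is the fragment's observed sequence in plus-strand orientation,
    one character per reference position in [start, end). ``cpg_states`` maps
    the plus-strand C position of a CpG dyad to the observed state.
    """

    contig: str
    start: int
    end: int
    flag1: int
    flag2: int
    umi1: str
    umi2: str
    stream: Stream
    bases: str = ""
    cpg_states: dict[int, Meth] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"fragment {self.name!r}: start {self.start} >= end {self.end}")
        if self.stream is Stream.GENET and self.cpg_states:
            raise ValueError("cpg_states only populated for METH fragments")

    @property
    def strand(self) -> str | None:
        return strand_of_flags(self.flag1, self.flag2)

    def base_at(self, position: int) -> str | None:
        if self.bases and self.start <= position < self.end:
            return self.bases[position - self.start]
        return None


@dataclass
class Region:
    contig: str
    start: int
    end: int
    name: str = ""
    kind: RegionKind = RegionKind.METHYL_MARKER

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region {self.name!r}: start {self.start} >= end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    def overlaps(self, start: int, end: int) -> bool:
        return start < self.end and end > self.start


@dataclass
class CpGCall:
    """Per-site methylation call; beta = methylated / covered."""

    contig: str
    position: int  # 0-based plus-strand C of the CpG dyad (or the C itself for CH)
    n_methylated: int
    n_unmethylated: int
    context: str = "CpG"  # CpG | CHG | CHH

    @property
    def total(self) -> int:
        return self.n_methylated + self.n_unmethylated

    @property
    def beta(self) -> float | None:
        """Methylated fraction; None (undefined) with zero coverage."""
        if self.total == 0:
            return None
        return self.n_methylated / self.total


@dataclass
class VariantCall:
    contig: str
    position: int
    ref: str
    alt: str
    depth: int
    alt_count: int
    in_wbc: bool = False
    annotation: str = "other"  # synonymous | intron | utr | other

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError("alt equals ref")

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0

    @property
    def is_ctga(self) -> bool:
        """C>T or G>A, the substitution classes deamination can fake."""
        return (self.ref, self.alt) in (("C", "T"), ("G", "A"))


@dataclass
class GeneEvent:
    gene: str
    loh: bool = False
    major_cn: int = 1
    minor_cn: int = 1
    promoter_methylated: bool = False
    deleterious_mutations: int = 0
    homozygous_deletion: bool = False
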