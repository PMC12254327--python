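"""Duplex phasing: match MM-genet and MM-meth fragments that originate from
the same double-stranded molecule, then test allele-specific methylation.

Two fragments pair when they (1) share exact mapping coordinates, (2) carry
the same UMI pair up to conversion (each meth-mate UMI equals the C->T or
G->A collapse of the corresponding genet-mate UMI) and (3) have a consistent
strand of origin, encoded in the proper-pair SAM flags: Watson = genet flags
99/147 with meth flags 67/131; Crick = genet flags 83/163 with meth flags
115/179. Secondary/supplementary alignments are outside this flag table and
are dropped upstream.
"""
from __future__ import annotations

from collections import defaultdict
from collections.abc import Sequence
from dataclasses import dataclass

from scipy import stats as sstats

from .core.seqs import collapse_sequence
from .core.types import AlignedFragment, Meth, Stream


@dataclass
class DuplexPair:
    genet_frag: AlignedFragment
    meth_frag: AlignedFragment
    strand: str  # WATSON | CRICK

    @property
    def key(self) -> tuple:
        f = self.genet_frag
        return (f.contig, f.start, f.end)


@dataclass
class PairingResult:
    pairs: list[DuplexPair]
    n_meth_total: int
    n_genet_total: int

    @property
    def pairing_rate(self) -> float:
        """Fraction of METH fragments that found their duplex partner."""
        return len(self.pairs) / self.n_meth_total if self.n_meth_total else 0.0


def _umi_matches_collapsed(genet_umi: str, meth_umi: str) -> bool:
    return meth_umi in (collapse_sequence(genet_umi, "C2T"),
                        collapse_sequence(genet_umi, "G2A"))


def pair_duplex(genet_frags: Sequence[AlignedFragment],
                meth_frags: Sequence[AlignedFragment]) -> PairingResult:
    """Greedy one-to-one duplex matching.

    Both inputs should be deduplicated to molecule level. Candidates are
    indexed by (contig, start, end, strand class); within a key, fragments
    are taken in sort order and each is used at most once (ambiguous
    multi-candidate joins resolve deterministically by that order).
    """
    index: dict[tuple, list[AlignedFragment]] = defaultdict(list)
    n_genet = 0
    for g in genet_frags:
        if g.stream is not Stream.GENET or g.strand is None:
            continue
        n_genet += 1
        index[(g.contig, g.start, g.end, g.strand)].append(g)
    for cands in index.values():
        cands.sort(key=lambda f: (f.umi1, f.umi2, f.name))

    pairs: list[DuplexPair] = []
    used: set[int] = set()
    n_meth = 0
    meth_sorted = sorted(
        (m for m in meth_frags if m.stream is Stream.METH and m.strand is not None),
        key=lambda f: (f.contig, f.start, f.end, f.umi1, f.umi2, f.name))
    for m in meth_sorted:
        n_meth += 1
        for g in index.get((m.contig, m.start, m.end, m.strand), []):
            if id(g) in used:
                continue
            if _umi_matches_collapsed(g.umi1, m.umi1) \
                    and _umi_matches_collapsed(g.umi2, m.umi2):
                used.add(id(g))
                pairs.append(DuplexPair(genet_frag=g, meth_frag=m, strand=m.strand))
                break
    return PairingResult(pairs=pairs, n_meth_total=n_meth, n_genet_total=n_genet)


# ------------------------------------------------------------- Fisher exact

def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Two-sidedness by the minimum-likelihood rule: sum the hypergeometric
    probabilities of all tables with fixed margins no more probable than the
    observed one.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative entries in contingency table")
    return float(sstats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


# ------------------------------------------------------------------ ASM test

@dataclass
class ASMResult:
    snp: tuple[str, int, str, str]  # contig, position, ref, alt
    ref_methylated: int
    ref_unmethylated: int
    alt_methylated: int
    alt_unmethylated: int
    fisher_p: float | None  # undefined (None) when a table margin is zero
    n_pairs_used: int = 0
    n_pairs_unallocated: int = 0

    @property
    def table(self) -> list[list[int]]:
        return [[self.ref_methylated, self.ref_unmethylated],
                [self.alt_methylated, self.alt_unmethylated]]


def asm_test(pairs: Sequence[DuplexPair], contig: str, position: int,
             ref: str, alt: str, window: int = 200) -> ASMResult:
    """Allele-specific methylation at one heterozygous SNP.

    Each duplex pair is allocated to the REF or ALT allele by the genet
    fragment's base at the SNP; its meth fragment then contributes the
    methylated/unmethylated counts of CpGs within ``window`` bp of the SNP.
    The 2x2 allele x state table is tested with the two-sided Fisher exact
    test; a zero margin leaves the p value undefined.
    """
    counts = {ref: [0, 0], alt: [0, 0]}
    used = unallocated = 0
    for p in pairs:
        g, m = p.genet_frag, p.meth_frag
        if g.contig != contig or not (g.start <= position < g.end):
            continue
        base = g.base_at(position)
        if base not in counts:
            unallocated += 1
            continue
        used += 1
        for pos, state in m.cpg_states.items():
            if abs(pos - position) <= window:
                counts[base][0 if state is Meth.METHYLATED else 1] += 1
    rm, ru = counts[ref]
    am, au = counts[alt]
    margins = (rm + ru, am + au, rm + am, ru + au)
    p_value = fisher_exact([[rm, ru], [am, au]]) if all(m > 0 for m in margins) else None
    return ASMResult(snp=(contig, position, ref, alt),
                     ref_methylated=rm, ref_unmethylated=ru,
                     alt_methylated=am, alt_unmethylated=au,
                     fisher_p=p_value, n_pairs_used=used,
                     n_pairs_unallocated=unallocated)
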