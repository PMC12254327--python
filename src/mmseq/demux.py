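"""UMI-based stream assignment.

A read pair is routed by matching the first 8 bases of each mate against the
fixed UMI pool: an exact match means the UMI survived conversion intact (a
protected copy strand, genetic information), while a match to the C->T or
G->A collapsed form means the UMI was deaminated (an original strand,
methylation information). Both mates must agree; discordant or unmatched
pairs are left unassigned — the conservative rule that keeps stream
contamination out of variant calling.
"""
from __future__ import annotations

import json
from collections.abc import Iterable, Iterator
from dataclasses import dataclass
from pathlib import Path

from .core.io import read_fastq_pairs, write_fastq_pairs
from .core.types import MatchMode, ReadPair, Stream
from .core.umi import UMIPool


@dataclass
class DemuxResult:
    stream: Stream
    matched_umi1: str | None
    matched_umi2: str | None
    mode1: MatchMode
    mode2: MatchMode


@dataclass
class DemuxStats:
    n_total: int = 0
    n_genet: int = 0
    n_meth: int = 0
    n_unassigned: int = 0
    n_both_exact: int = 0

    @property
    def perfect_match_fraction(self) -> float:
        """Fraction of pairs with both UMIs exactly matching the pool."""
        return self.n_both_exact / self.n_total if self.n_total else 0.0

    def to_json(self) -> str:
        return json.dumps({
            "n_total": self.n_total, "n_genet": self.n_genet,
            "n_meth": self.n_meth, "n_unassigned": self.n_unassigned,
            "perfect_match_fraction": self.perfect_match_fraction}, indent=2)


def _match_umi(umi: str, pool: UMIPool) -> tuple[MatchMode, str | None]:
    """Lookup order: exact, then C2T collapse, then G2A collapse.

    Matching is exact string comparison; an N never matches because pool
    entries and their collapses contain no N.
    """
    if umi in pool:
        return MatchMode.EXACT, umi
    hit = pool.c2t_index.get(umi)
    if hit is not None:
        return MatchMode.C2T, hit
    hit = pool.g2a_index.get(umi)
    if hit is not None:
        return MatchMode.G2A, hit
    return MatchMode.NONE, None


_CONVERTED = (MatchMode.C2T, MatchMode.G2A)


def classify_read_pair(pair: ReadPair, pool: UMIPool) -> DemuxResult:
    mode1, hit1 = _match_umi(pair.umi1, pool)
    mode2, hit2 = _match_umi(pair.umi2, pool)
    if mode1 is MatchMode.EXACT and mode2 is MatchMode.EXACT:
        stream = Stream.GENET
    elif mode1 in _CONVERTED and mode2 in _CONVERTED:
        stream = Stream.METH
    else:
        stream = Stream.UNASSIGNED
    return DemuxResult(stream=stream, matched_umi1=hit1, matched_umi2=hit2,
                       mode1=mode1, mode2=mode2)


def demux_pairs(pairs: Iterable[ReadPair], pool: UMIPool
                ) -> Iterator[tuple[ReadPair, DemuxResult]]:
    for pair in pairs:
        yield pair, classify_read_pair(pair, pool)


def demux_stream(r1_path: str | Path, r2_path: str | Path, pool: UMIPool,
                 out_prefix: str | Path, umi_length: int = 8) -> DemuxStats:
    """Split synchronized FASTQ mate files into genet/meth/unassigned outputs.

    UMI prefixes are preserved on the routed reads. Returns counts; the
    partition is exact (every input pair lands in exactly one output).
    """
    prefix = str(out_prefix)
    stats = DemuxStats()
    buckets: dict[Stream, list[ReadPair]] = {s: [] for s in Stream}
    for pair, result in demux_pairs(
            read_fastq_pairs(r1_path, r2_path, umi_length=umi_length), pool):
        stats.n_total += 1
        buckets[result.stream].append(pair)
        if result.mode1 is MatchMode.EXACT and result.mode2 is MatchMode.EXACT:
            stats.n_both_exact += 1
    stats.n_genet = len(buckets[Stream.GENET])
    stats.n_meth = len(buckets[Stream.METH])
    stats.n_unassigned = len(buckets[Stream.UNASSIGNED])
    for stream, tag in [(Stream.GENET, "genet"), (Stream.METH, "meth"),
                        (Stream.UNASSIGNED, "unassigned")]:
        write_fastq_pairs(buckets[stream], f"{prefix}.{tag}.R1.fastq",
                          f"{prefix}.{tag}.R2.fastq")
    Path(f"{prefix}.demux_stats.json").write_text(stats.to_json() + "\n")
    return stats
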