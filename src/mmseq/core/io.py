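"""Standard-format I/O for the pipeline.

Conventions applied exactly once at these boundaries:
  * SAM positions (1-based) -> internal 0-based half-open spans;
  * BED is already 0-based half-open and passes through unchanged;
  * UMI pairs ride in the read name suffix ``...:UMI1-UMI2`` (aligner-agnostic);
  * METH fragments carry per-CpG states in the custom SAM tag ``XC`` as
    ``pos=state`` pairs (state 1 = methylated), and the stream in ``XS``.
"""
from __future__ import annotations

import gzip
from collections.abc import Iterable, Iterator
from pathlib import Path

import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .types import AlignedFragment, Meth, ReadPair, Region, RegionKind, Stream


class ParseError(ValueError):
    pass


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- FASTQ pairs

def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path,
                     umi_length: int = 8) -> Iterator[ReadPair]:
    """Iterate synchronized mate files as ReadPairs; desync is an error."""
    with _open_text(r1_path) as f1, _open_text(r2_path) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        for i, (rec1, rec2) in enumerate(zip(it1, it2, strict=True)):
            (t1, s1, q1), (t2, s2, q2) = rec1, rec2
            n1, n2 = t1.split()[0], t2.split()[0]
            if n1 != n2:
                raise ParseError(f"desynchronized mates at record {i + 1}: {n1!r} vs {n2!r}")
            yield ReadPair(n1, s1, s2, q1, q2, umi_length=umi_length)


def write_fastq_pairs(pairs: Iterable[ReadPair], r1_path: str | Path,
                      r2_path: str | Path) -> int:
    n = 0
    with _open_text(r1_path, "wt") as f1, _open_text(r2_path, "wt") as f2:
        for p in pairs:
            f1.write(f"@{p.name}\n{p.read1_seq}\n+\n{p.read1_qual}\n")
            f2.write(f"@{p.name}\n{p.read2_seq}\n+\n{p.read2_qual}\n")
            n += 1
    return n


# ----------------------------------------------------------------- SAM / BAM

def _encode_cpg_states(states: dict[int, Meth]) -> str:
    return ",".join(f"{pos}={int(state)}" for pos, state in sorted(states.items()))


def _decode_cpg_states(tag: str) -> dict[int, Meth]:
    out: dict[int, Meth] = {}
    if not tag:
        return out
    for item in tag.split(","):
        pos, _, state = item.partition("=")
        out[int(pos)] = Meth(int(state))
    return out


def write_fragments_sam(frags: Iterable[AlignedFragment], path: str | Path,
                        contig_lengths: dict[str, int]) -> int:
    """One alignment line per fragment (mate 1 representation)."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": c, "LN": ln} for c, ln in contig_lengths.items()]}
    n = 0
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for frag in frags:
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"{frag.name or f'frag{n}'}:{frag.umi1}-{frag.umi2}"
            a.flag = frag.flag1
            a.reference_name = frag.contig
            a.reference_start = frag.start  # pysam is 0-based; SAM text gets +1
            a.mapping_quality = 60
            length = frag.end - frag.start
            a.query_sequence = frag.bases or ("N" * length)
            a.cigarstring = f"{length}M"
            a.template_length = length
            a.set_tag("XS", frag.stream.value)
            a.set_tag("XF", frag.flag2)
            if frag.cpg_states:
                a.set_tag("XC", _encode_cpg_states(frag.cpg_states))
            out.write(a)
            n += 1
    return n


def read_fragments_sam(path: str | Path) -> list[AlignedFragment]:
    frags = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped or a.is_secondary or a.is_supplementary:
                continue
            name, _, umis = a.query_name.rpartition(":")
            umi1, _, umi2 = umis.partition("-")
            if not (name and umi1 and umi2):
                raise ParseError(f"read name {a.query_name!r} lacks the ':UMI1-UMI2' suffix")
            stream = Stream(a.get_tag("XS")) if a.has_tag("XS") else Stream.UNASSIGNED
            states = _decode_cpg_states(a.get_tag("XC")) if a.has_tag("XC") else {}
            frags.append(AlignedFragment(
                contig=a.reference_name,
                start=a.reference_start,
                end=a.reference_start + (a.query_length or len(a.query_sequence or "")),
                flag1=a.flag,
                flag2=int(a.get_tag("XF")) if a.has_tag("XF") else 0,
                umi1=umi1, umi2=umi2, stream=stream,
                bases=a.query_sequence or "",
                cpg_states=states, name=name))
    return frags


# ----------------------------------------------------------------------- BED

def read_bed(path: str | Path, kind: RegionKind = RegionKind.METHYL_MARKER) -> list[Region]:
    regions = []
    with _open_text(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{i}: BED line has {len(fields)} fields, need >=3")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: non-integer BED coordinates") from exc
            name = fields[3] if len(fields) > 3 else f"region{i}"
            regions.append(Region(fields[0], start, end, name=name, kind=kind))
    return regions


def write_bed(regions: Iterable[Region], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for r in regions:
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.name}\n")


# --------------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# -------------------------------------------------------------------- tables

def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Delimited cohort table (TSV by default)."""
    kwargs.setdefault("sep", "\t")
    return pd.read_csv(path, **kwargs)


def write_table(df: pd.DataFrame, path: str | Path, **kwargs) -> None:
    kwargs.setdefault("sep", "\t")
    kwargs.setdefault("index", False)
    df.to_csv(path, **kwargs)


# -------------------------------------------------------------------- config

def load_config(path: str | Path) -> dict:
    with _open_text(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"config {path} did not parse to a mapping")
    return cfg
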