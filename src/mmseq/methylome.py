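"""Methylation-stream processing: duplicate removal, per-cytosine methylation
calling (CpG / CHG / CHH), and conversion QC on the spike-in analogs.

Calling convention: on an original-top (Watson) fragment a plus-strand
reference C read as C is methylated and read as T is unmethylated; on an
original-bottom (Crick) fragment the informative base is the plus-strand G
(the minus-strand C), read as G / A respectively. Plus- and minus-strand
calls at a CpG dyad are summed into one site keyed by the plus-strand C.
"""
from __future__ import annotations

from collections import defaultdict
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .core.seqs import hamming
from .core.types import AlignedFragment, CpGCall, Meth, Region, Stream


class UnsortedInputError(ValueError):
    pass


# ------------------------------------------------------------- deduplication

def cluster_fragments(frags: Sequence[AlignedFragment], coord_tolerance: int = 0,
                      umi_aware: bool = False, max_umi_mismatch: int = 1
                      ) -> list[list[AlignedFragment]]:
    """Group fragments into duplicate clusters.

    Fragments join a cluster when they share the representative's flag pair
    (duplicates preserve strand orientation, as in MarkDuplicates), both
    start and end coordinates are within ``coord_tolerance`` of the cluster
    representative (the first member) and, if ``umi_aware``, each mate's UMI
    is within ``max_umi_mismatch`` Hamming distance of the representative's.
    Input must be sorted by (contig, start); the result is then independent
    of any further input ordering because representatives are taken in sort
    order.
    """
    prev = None
    for f in frags:
        if prev is not None and (f.contig, f.start) < prev:
            raise UnsortedInputError("fragments must be sorted by contig and start")
        prev = (f.contig, f.start)

    clusters: list[list[AlignedFragment]] = []
    open_clusters: list[list[AlignedFragment]] = []  # reps still within reach
    for f in frags:
        open_clusters = [c for c in open_clusters
                         if c[0].contig == f.contig
                         and f.start - c[0].start <= coord_tolerance]
        placed = False
        for c in open_clusters:
            rep = c[0]
            if (f.flag1, f.flag2) != (rep.flag1, rep.flag2):
                continue
            if abs(f.end - rep.end) > coord_tolerance:
                continue
            if umi_aware and (hamming(f.umi1, rep.umi1) > max_umi_mismatch
                              or hamming(f.umi2, rep.umi2) > max_umi_mismatch):
                continue
            c.append(f)
            placed = True
            break
        if not placed:
            c = [f]
            clusters.append(c)
            open_clusters.append(c)
    return clusters


def deduplicate_fragments(frags: Sequence[AlignedFragment], coord_tolerance: int = 0,
                          umi_aware: bool = False, max_umi_mismatch: int = 1
                          ) -> tuple[list[AlignedFragment], float]:
    """Keep one representative per duplicate cluster; report the duplicate rate.

    Defaults mirror MarkDuplicates-style dedup (exact coordinates); the QC
    definition of duplicates uses ``coord_tolerance=5, umi_aware=True,
    max_umi_mismatch=1``.
    """
    clusters = cluster_fragments(frags, coord_tolerance, umi_aware, max_umi_mismatch)
    unique = [c[0] for c in clusters]
    rate = 1.0 - len(unique) / len(frags) if frags else 0.0
    return unique, rate


# ---------------------------------------------------------- methylation call

def _context(seq: str, pos: int, strand: str) -> str:
    """CpG / CHG / CHH context of the cytosine at ``pos`` on ``strand``."""
    n = len(seq)
    if strand == "+":
        n1 = seq[pos + 1] if pos + 1 < n else "N"
        n2 = seq[pos + 2] if pos + 2 < n else "N"
    else:  # minus-strand C sits at a plus-strand G; read 3' -> 5' on plus
        n1 = _comp(seq[pos - 1]) if pos - 1 >= 0 else "N"
        n2 = _comp(seq[pos - 2]) if pos - 2 >= 0 else "N"
    if n1 == "G":
        return "CpG"
    if n2 == "G":
        return "CHG"
    return "CHH"


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _comp(b: str) -> str:
    return _COMP.get(b, "N")


_WATSON_METH_FLAGS = {(67, 131)}
_CRICK_METH_FLAGS = {(115, 179)}


def call_methylation(frags: Sequence[AlignedFragment],
                     reference: dict[str, str] | None = None) -> list[CpGCall]:
    """Per-cytosine methylation calls from deduplicated METH fragments.

    With a reference, calls are made from base comparisons in all three
    contexts and CpG dyads are merged (keyed by the plus-strand C). Without a
    reference, the fragments' recorded per-CpG states are tallied (CpG only).
    """
    counts: dict[tuple[str, int, str], list[int]] = defaultdict(lambda: [0, 0])

    for f in frags:
        if f.stream is not Stream.METH:
            continue
        if reference is not None:
            if f.contig not in reference:
                raise ValueError(f"fragment contig {f.contig!r} absent from reference")
            seq = reference[f.contig]
            pair = (f.flag1, f.flag2)
            if pair in _WATSON_METH_FLAGS:
                for p in range(f.start, f.end):
                    if seq[p] != "C":
                        continue
                    obs = f.bases[p - f.start]
                    ctx = _context(seq, p, "+")
                    if ctx == "CpG" and p + 1 >= f.end:
                        continue  # dyad partner outside the fragment
                    key_pos = p  # CpG dyad keyed by its plus-strand C
                    if obs == "C":
                        counts[(f.contig, key_pos, ctx)][0] += 1
                    elif obs == "T":
                        counts[(f.contig, key_pos, ctx)][1] += 1
            elif pair in _CRICK_METH_FLAGS:
                for p in range(f.start, f.end):
                    if seq[p] != "G":
                        continue
                    obs = f.bases[p - f.start]
                    ctx = _context(seq, p, "-")
                    if ctx == "CpG" and p - 1 < f.start:
                        continue  # dyad partner outside the fragment
                    # merge the dyad: the paired plus-strand C is at p - 1
                    key_pos = p - 1 if ctx == "CpG" else p
                    if obs == "G":
                        counts[(f.contig, key_pos, ctx)][0] += 1
                    elif obs == "A":
                        counts[(f.contig, key_pos, ctx)][1] += 1
            # fragments with other flag pairs carry no usable strand info
        else:
            for pos, state in f.cpg_states.items():
                counts[(f.contig, pos, "CpG")][int(state) == 0] += 1

    calls = [CpGCall(contig=c, position=p, n_methylated=m, n_unmethylated=u,
                     context=ctx)
             for (c, p, ctx), (m, u) in sorted(counts.items())]
    return calls


# ------------------------------------------------------------ conversion QC

@dataclass
class ConversionQC:
    sensitivity: float | None   # converted unmethylated C / total, lambda analog
    specificity: float | None   # unconverted methylated C / total, pUC19 analog
    ctga_substitution_rate: float | None  # C>T + G>A rate, GENET stream, QC region


def conversion_qc(calls: Sequence[CpGCall], lambda_contig: str, puc19_contig: str,
                  genet_frags: Sequence[AlignedFragment] | None = None,
                  reference: dict[str, str] | None = None,
                  qc_region: Region | None = None) -> ConversionQC:
    """Spike-in conversion metrics plus the substitution-rate QC.

    Sensitivity counts converted (read-as-T) cytosines on the fully
    unmethylated lambda analog (all contexts — every lambda cytosine is
    unmethylated); specificity counts unconverted (read-as-C) cytosines on
    the fully CpG-methylated pUC19 analog, restricted to CpG context (its
    CHG/CHH cytosines are unmethylated). Zero covered spike-in cytosines
    leaves the metric undefined (None).
    """
    lam_m = lam_u = puc_m = puc_u = 0
    for c in calls:
        if c.contig == lambda_contig:
            lam_m += c.n_methylated
            lam_u += c.n_unmethylated
        elif c.contig == puc19_contig and c.context == "CpG":
            puc_m += c.n_methylated
            puc_u += c.n_unmethylated
    sens = lam_u / (lam_m + lam_u) if (lam_m + lam_u) else None
    spec = puc_m / (puc_m + puc_u) if (puc_m + puc_u) else None

    rate = None
    if genet_frags is not None and reference is not None and qc_region is not None:
        seq = reference.get(qc_region.contig)
        if seq is None:
            raise ValueError(f"QC region contig {qc_region.contig!r} absent from reference")
        sub = total = 0
        for f in genet_frags:
            if f.stream is not Stream.GENET or f.contig != qc_region.contig:
                continue
            lo = max(f.start, qc_region.start)
            hi = min(f.end, qc_region.end)
            for p in range(lo, hi):
                ref = seq[p]
                obs = f.bases[p - f.start]
                if ref == "C":
                    total += 1
                    sub += obs == "T"
                elif ref == "G":
                    total += 1
                    sub += obs == "A"
        rate = sub / total if total else None
    return ConversionQC(sensitivity=sens, specificity=spec,
                        ctga_substitution_rate=rate)


# --------------------------------------------------------- dilution recovery

@dataclass
class DilutionRecovery:
    levels: list[float]
    mean_betas: list[float]
    pearson_r: float | None  # undefined when the configured levels are constant


def dilution_recovery(calls: Sequence[CpGCall],
                      dilution_contigs: dict[str, float]) -> DilutionRecovery:
    """Mean called beta per pUC19 dilution contig vs the configured levels."""
    if len(dilution_contigs) < 2:
        raise ValueError("need at least two dilution levels")
    by_contig: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for c in calls:
        if c.contig in dilution_contigs and c.context == "CpG":
            by_contig[c.contig].append((c.n_methylated, c.total))
    levels, means = [], []
    for contig, level in sorted(dilution_contigs.items(), key=lambda kv: -kv[1]):
        pairs = by_contig.get(contig, [])
        meth = sum(m for m, _ in pairs)
        tot = sum(t for _, t in pairs)
        levels.append(level)
        means.append(meth / tot if tot else float("nan"))
    arr_l, arr_m = np.asarray(levels), np.asarray(means)
    ok = ~np.isnan(arr_m)
    r = None
    if ok.sum() >= 2 and np.std(arr_l[ok]) > 0 and np.std(arr_m[ok]) > 0:
        r = float(sstats.pearsonr(arr_l[ok], arr_m[ok]).statistic)
    return DilutionRecovery(levels=levels, mean_betas=means, pearson_r=r)
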