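"""Genetic-stream processing: duplex consensus clustering, germline SNP
calling with the printed filters, somatic variant filtering, and binned CNV
detection with GC correction.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core.types import AlignedFragment, Stream, VariantCall
from .methylome import cluster_fragments

CONSENSUS_AGREEMENT = 0.70  # below this majority fraction a position is masked to N


# ----------------------------------------------------------------- consensus

def cluster_consensus(frags: Sequence[AlignedFragment], coord_tolerance: int = 5,
                      max_umi_mismatch: int = 1,
                      agreement: float = CONSENSUS_AGREEMENT
                      ) -> list[AlignedFragment]:
    """Collapse duplicate clusters into consensus fragments.

    Clusters reuse the duplicate definition (coordinates within 5 bp, UMI-pair
    Hamming distance <= 1 per mate, same orientation). The consensus base at
    each position is the majority call; positions where the majority falls
    below ``agreement`` are masked to N. Cluster size is recorded in the
    consensus fragment's name suffix ``|depth=<n>``.
    """
    clusters = cluster_fragments(frags, coord_tolerance=coord_tolerance,
                                 umi_aware=True, max_umi_mismatch=max_umi_mismatch)
    out = []
    for members in clusters:
        rep = members[0]
        length = rep.end - rep.start
        if len(members) == 1:
            consensus = rep.bases
        else:
            chars = []
            for i in range(length):
                votes = Counter()
                for m in members:
                    # members may be offset by up to the coordinate tolerance
                    j = rep.start + i - m.start
                    if 0 <= j < len(m.bases):
                        votes[m.bases[j]] += 1
                total = sum(votes.values())
                base, count = votes.most_common(1)[0]
                chars.append(base if total and count / total >= agreement else "N")
            consensus = "".join(chars)
        out.append(AlignedFragment(
            contig=rep.contig, start=rep.start, end=rep.end,
            flag1=rep.flag1, flag2=rep.flag2, umi1=rep.umi1, umi2=rep.umi2,
            stream=Stream.GENET, bases=consensus,
            name=f"{rep.name}|depth={len(members)}"))
    return out


# -------------------------------------------------------------------- pileup

def pileup(frags: Sequence[AlignedFragment]) -> dict[tuple[str, int], Counter]:
    """Per-position base counts over consensus fragments (N excluded).

    Each consensus fragment contributes one observation per position (a
    molecule-level count, not a raw-read count).
    """
    piles: dict[tuple[str, int], Counter] = defaultdict(Counter)
    for f in frags:
        for i, b in enumerate(f.bases):
            if b != "N":
                piles[(f.contig, f.start + i)][b] += 1
    return piles


# ------------------------------------------------------------- germline SNPs

def call_germline_snps(piles: dict[tuple[str, int], Counter],
                       reference: dict[str, str],
                       min_coverage: int = 10, min_alt_reads: int = 2,
                       min_vaf: float = 0.15) -> list[VariantCall]:
    """Simple pileup caller with the printed filters: coverage >= 10x,
    >= 2 supporting reads, VAF >= 0.15. No genotype model."""
    calls = []
    for (contig, pos), counts in sorted(piles.items()):
        depth = sum(counts.values())
        if depth < min_coverage:
            continue
        ref = reference[contig][pos]
        for alt, n in counts.most_common():
            if alt == ref or alt == "N":
                continue
            if n >= min_alt_reads and n / depth >= min_vaf:
                calls.append(VariantCall(contig=contig, position=pos, ref=ref,
                                         alt=alt, depth=depth, alt_count=n))
    return calls


# ----------------------------------------------------------- somatic filters

def filter_somatic(variants: Sequence[VariantCall], min_alt_reads: int = 5,
                   min_vaf: float = 0.001, retain_ctga: bool = False
                   ) -> list[VariantCall]:
    """The printed somatic exclusion rules, as a pure predicate.

    Keep a variant iff it has >= 5 supporting reads, VAF >= 0.1%, is not a
    C>T / G>A substitution (retained in DNA-seq comparison mode via
    ``retain_ctga``), is absent from the paired WBC sample, and is not
    synonymous / intronic / UTR.
    """
    kept = []
    for v in variants:
        if v.alt_count < min_alt_reads or v.vaf < min_vaf:
            continue
        if v.is_ctga and not retain_ctga:
            continue
        if v.in_wbc:
            continue
        if v.annotation != "other":
            continue
        kept.append(v)
    return kept


# ---------------------------------------------------------------------- CNV

@dataclass
class CNVSegment:
    contig: str
    start: int
    end: int
    n_bins: int
    mean_copy_number: float
    kind: str  # gain | loss


def bin_coverage(per_base: np.ndarray, reference_seq: str, contig: str = "chr1",
                 bin_size: int = 10_000) -> pd.DataFrame:
    """Aggregate per-base coverage into non-overlapping bins with GC content.

    The trailing short bin is dropped.
    """
    n_bins = len(per_base) // bin_size
    rows = []
    for i in range(n_bins):
        s = i * bin_size
        chunk = reference_seq[s:s + bin_size]
        gc = (chunk.count("G") + chunk.count("C")) / bin_size
        rows.append({"contig": contig, "start": s, "end": s + bin_size,
                     "raw_coverage": float(per_base[s:s + bin_size].mean()),
                     "gc_fraction": gc})
    return pd.DataFrame(rows)


def cnv_bins(bins: pd.DataFrame, min_coverage: float = 1.0,
             lowess_frac: float = 0.3, diploid_copies: float = 2.0) -> pd.DataFrame:
    """Copy-number estimates per 10 kb bin.

    Bins under ``min_coverage`` are filtered out; copy_ratio = coverage /
    genome-wide median; a LOWESS fit of ratio against GC removes the GC trend
    (near-constant GC falls back to a constant fit); copy_number = 2 x
    GC-corrected ratio (diploid baseline).
    """
    kept = bins[bins["raw_coverage"] >= min_coverage].copy()
    if kept.empty:
        raise ValueError("all bins filtered out (coverage below minimum)")
    median = float(kept["raw_coverage"].median())
    kept["copy_ratio"] = kept["raw_coverage"] / median
    gc = kept["gc_fraction"].to_numpy()
    ratio = kept["copy_ratio"].to_numpy()
    if np.ptp(gc) < 1e-6 or len(kept) < 10:
        fitted = np.full(len(kept), ratio.mean())
    else:
        smoothed = lowess(ratio, gc, frac=lowess_frac, return_sorted=True)
        fitted = np.interp(gc, smoothed[:, 0], smoothed[:, 1])
    fitted = np.where(fitted <= 0, 1.0, fitted)
    kept["gc_corrected_ratio"] = ratio / fitted
    # re-center so a diploid background sits at ratio 1 after correction
    kept["gc_corrected_ratio"] /= float(np.median(kept["gc_corrected_ratio"]))
    kept["copy_number"] = diploid_copies * kept["gc_corrected_ratio"]
    return kept


def cnv_segments(bins: pd.DataFrame, gain_threshold: float = 3.5,
                 loss_threshold: float = 0.5, min_consecutive: int = 3
                 ) -> list[CNVSegment]:
    """Maximal runs of >= ``min_consecutive`` bins beyond the copy-number
    thresholds (gain > 3.5, loss < 0.5), per contig in coordinate order."""
    segments = []
    for contig, grp in bins.groupby("contig", sort=False):
        grp = grp.sort_values("start")
        state = np.where(grp["copy_number"] > gain_threshold, 1,
                         np.where(grp["copy_number"] < loss_threshold, -1, 0))
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cn = grp["copy_number"].to_numpy()
        i = 0
        while i < len(state):
            if state[i] == 0:
                i += 1
                continue
            j = i
            while j + 1 < len(state) and state[j + 1] == state[i] \
                    and starts[j + 1] == ends[j]:
                j += 1
            if j - i + 1 >= min_consecutive:
                segments.append(CNVSegment(
                    contig=contig, start=int(starts[i]), end=int(ends[j]),
                    n_bins=j - i + 1, mean_copy_number=float(cn[i:j + 1].mean()),
                    kind="gain" if state[i] == 1 else "loss"))
            i = j + 1
    return segments
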