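"""Clinical decision layers.

ctDNA fraction from fully CpG-methylated marker fragments and the positivity
rule; immune-derived cfDNA deconvolution with CBC-based calibration and the
neutrophil-to-lymphocyte ratio; expression-correlated promoter CpG selection
and gene methylation status; the purity/ploidy-aware LOH grid model; the
four biallelic-loss rules and their HRD association; greedy mutation-panel
design; and the qPCR call rules.
"""
from __future__ import annotations

import math
from collections import defaultdict
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core.types import AlignedFragment, CpGCall, GeneEvent, Meth, Region, Stream
from .phasing import fisher_exact


# -------------------------------------------------------------------- ctDNA

@dataclass
class CtdnaResult:
    n_eligible_fragments: int
    n_ctdna_fragments: int
    somatic_mutations: list = field(default_factory=list)

    @property
    def ctdna_fraction(self) -> float | None:
        """Fully methylated / eligible; undefined with zero eligible fragments."""
        if self.n_eligible_fragments == 0:
            return None
        return self.n_ctdna_fragments / self.n_eligible_fragments


def ctdna_fraction(meth_frags: Sequence[AlignedFragment], markers: Sequence[Region],
                   min_cpgs: int = 5) -> CtdnaResult:
    """Tumor-derived fragment counting on hypermethylated markers.

    A fragment is eligible if it covers at least ``min_cpgs`` CpG sites
    within a marker region; an eligible fragment whose covered marker CpGs
    are all methylated counts as ctDNA (the markers are hypermethylated in
    tumor, so a fully methylated fragment is taken as tumor-derived).
    """
    n_eligible = n_ctdna = 0
    for f in meth_frags:
        if f.stream is not Stream.METH:
            continue
        for marker in markers:
            if marker.contig != f.contig or not marker.overlaps(f.start, f.end):
                continue
            states = [s for pos, s in f.cpg_states.items() if marker.contains(pos)]
            if len(states) < min_cpgs:
                continue
            n_eligible += 1
            if all(s is Meth.METHYLATED or s == Meth.METHYLATED for s in states):
                n_ctdna += 1
            break  # a fragment is counted on at most one marker
    return CtdnaResult(n_eligible_fragments=n_eligible, n_ctdna_fragments=n_ctdna)


def call_ctdna_status(result: CtdnaResult, fraction_threshold: float = 0.001,
                      min_ctdna_fragments: int = 3,
                      min_total_fragments: int = 3000) -> str:
    """POSITIVE iff any somatic mutation was kept, or the methylation-derived
    fraction exceeds 0.1% with >= 3 ctDNA fragments and >= 3000 total."""
    if result.somatic_mutations:
        return "POSITIVE"
    frac = result.ctdna_fraction
    if (frac is not None and frac > fraction_threshold
            and result.n_ctdna_fragments >= min_ctdna_fragments
            and result.n_eligible_fragments >= min_total_fragments):
        return "POSITIVE"
    return "NEGATIVE"


# ------------------------------------------------------------ immune cfDNA

LYMPHOCYTE_TYPES = ("lymphocyte_b", "lymphocyte_t", "nk")
NEUTROPHIL_GROUP = ("neutrophil", "eosinophil", "monocyte")


@dataclass
class ImmuneProfile:
    raw: dict[str, float]
    calibrated: dict[str, float]

    @property
    def nlr(self) -> float | None:
        """Neutrophil-to-lymphocyte ratio; undefined at zero lymphocytes."""
        neut = self.calibrated.get("neutrophil", 0.0)
        lymph = sum(self.calibrated.get(t, 0.0) for t in LYMPHOCYTE_TYPES)
        if lymph == 0:
            return None
        return neut / lymph


def immune_fractions_from_counts(counts: pd.DataFrame) -> dict[str, float]:
    """Raw cell-type fractions from a marker count table.

    ``counts`` columns: marker, cell_type, n_fragments, n_unmethylated. The
    per-marker proportion of fully unmethylated covering fragments is
    averaged over each cell type's markers; markers with zero covering
    fragments are excluded from the mean.
    """
    per_type: dict[str, list[float]] = defaultdict(list)
    for rec in counts.itertuples(index=False):
        if rec.n_fragments > 0:
            per_type[rec.cell_type].append(rec.n_unmethylated / rec.n_fragments)
    return {t: float(np.mean(v)) for t, v in per_type.items() if v}


def immune_fractions(frags: Sequence[AlignedFragment], markers: Sequence[Region],
                     marker_cell_types: dict[str, str],
                     marker_cpgs: dict[str, list[int]],
                     requisite: dict[str, int] | None = None) -> dict[str, float]:
    """Raw fractions from fragments: a fragment counts for a marker only when
    it covers all the marker's CpG sites, and counts as cell-type-derived
    when at least the requisite number of them (default: all) read
    unmethylated."""
    table_rows = []
    for marker in markers:
        cpgs = marker_cpgs[marker.name]
        need = (requisite or {}).get(marker.name, len(cpgs))
        n_cov = n_unmeth = 0
        for f in frags:
            if f.stream is not Stream.METH or f.contig != marker.contig:
                continue
            if not all(pos in f.cpg_states for pos in cpgs):
                continue
            n_cov += 1
            unmeth = sum(f.cpg_states[pos] == Meth.UNMETHYLATED for pos in cpgs)
            if unmeth >= need:
                n_unmeth += 1
        table_rows.append({"marker": marker.name,
                           "cell_type": marker_cell_types[marker.name],
                           "n_fragments": n_cov, "n_unmethylated": n_unmeth})
    return immune_fractions_from_counts(pd.DataFrame(table_rows))


def calibrate_fractions(raw: dict[str, float],
                        training: dict[str, list[tuple[float, float]]]
                        ) -> ImmuneProfile:
    """CBC-anchored calibration.

    Per cell type an ordinary least-squares line is fitted through the
    training pairs (raw marker-derived fraction, CBC proportion) and applied
    to the sample's raw fraction; negatives clip to 0 and the result is
    renormalized so the fractions sum to exactly 1.
    """
    calibrated = {}
    for cell_type, raw_value in raw.items():
        pairs = training.get(cell_type)
        if not pairs or len(pairs) < 2:
            raise ValueError(f"need >= 2 training pairs for {cell_type!r}")
        x = np.array([p[0] for p in pairs], dtype=float)
        y = np.array([p[1] for p in pairs], dtype=float)
        if np.ptp(x) < 1e-12:
            raise ValueError(f"degenerate training data for {cell_type!r} "
                             "(zero variance in raw fractions)")
        slope, intercept = np.polyfit(x, y, 1)
        calibrated[cell_type] = max(0.0, float(slope * raw_value + intercept))
    total = sum(calibrated.values())
    if total == 0:
        raise ValueError("all calibrated fractions are zero; cannot normalize")
    calibrated = {t: v / total for t, v in calibrated.items()}
    return ImmuneProfile(raw=dict(raw), calibrated=calibrated)


def normalize_fcm(fcm: dict[str, float], cbc: dict[str, float],
                  lymphocyte_types: Sequence[str] = LYMPHOCYTE_TYPES,
                  neutrophil_group: Sequence[str] = NEUTROPHIL_GROUP
                  ) -> dict[str, float]:
    """Rescale flow-cytometry subsets so each group's sum matches the CBC.

    The lymphocyte subsets are scaled so their sum equals the CBC lymphocyte
    total; the neutrophil/eosinophil/monocyte subsets likewise.
    """
    out = dict(fcm)
    for group in (lymphocyte_types, neutrophil_group):
        members = [t for t in group if t in fcm]
        fcm_sum = sum(fcm[t] for t in members)
        cbc_sum = sum(cbc.get(t, 0.0) for t in group)
        if fcm_sum == 0:
            raise ValueError(f"zero FCM group sum for {tuple(group)}")
        for t in members:
            out[t] = fcm[t] * cbc_sum / fcm_sum
    return out


# ------------------------------------------- promoter CpG selection / status

@dataclass
class CpGCluster:
    gene: str
    contig: str
    start: int
    end: int
    members: list[int]          # CpG positions
    member_ids: list[str] = field(default_factory=list)

    def mean_beta(self, betas: dict[int, float]) -> float | None:
        vals = [betas[p] for p in self.members if p in betas]
        return float(np.mean(vals)) if vals else None


def select_correlated_cpgs(meth: pd.DataFrame, expr: pd.DataFrame,
                           cpg_annotation: pd.DataFrame, tss: pd.DataFrame,
                           r_threshold: float = -0.15,
                           promoter_upstream: int = 1000,
                           promoter_downstream: int = 750,
                           min_neighbors: int = 5, neighbor_window: int = 75,
                           merge_flank: int = 100,
                           isolated_flank: int = 75) -> list[CpGCluster]:
    """Expression-correlated promoter CpG clusters.

    A CpG qualifies when (1) its methylation/expression Pearson correlation
    is below ``r_threshold``, (2) it lies in the promoter (1000 bp upstream
    to 750 bp downstream of the TSS, strand-aware), and (3) more than
    ``min_neighbors`` CpGs lie within ``neighbor_window`` bp of it.
    Candidates whose 100 bp flanks overlap merge into one cluster; an
    isolated candidate becomes a cluster with a 75 bp flank.
    """
    shared = [s for s in meth.columns if s in expr.columns]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples between matrices")
    meth = meth[shared]
    expr = expr[shared]
    tss_by_gene = {row.gene: row for row in tss.itertuples(index=False)}

    clusters: list[CpGCluster] = []
    for gene, ann in cpg_annotation.groupby("gene"):
        info = tss_by_gene.get(gene)
        if info is None or gene not in expr.index:
            continue
        strand = getattr(info, "strand", "+")
        if strand == "+":
            promoter = (info.tss - promoter_upstream, info.tss + promoter_downstream)
        else:
            promoter = (info.tss - promoter_downstream, info.tss + promoter_upstream)
        positions = ann["position"].to_numpy()
        e = expr.loc[gene].to_numpy(dtype=float)
        candidates = []
        for row in ann.itertuples(index=False):
            if not (promoter[0] <= row.position <= promoter[1]):
                continue
            n_near = int((np.abs(positions - row.position) <= neighbor_window).sum()) - 1
            if n_near <= min_neighbors:
                continue
            m = meth.loc[row.cpg_id].to_numpy(dtype=float)
            if np.std(m) == 0 or np.std(e) == 0:
                continue
            r = float(np.corrcoef(m, e)[0, 1])
            if r < r_threshold:
                candidates.append((int(row.position), row.cpg_id))
        if not candidates:
            continue
        candidates.sort()
        # merge candidates whose merge_flank-bp flanks overlap
        current = [candidates[0]]
        groups = []
        for pos, cid in candidates[1:]:
            if pos - merge_flank <= current[-1][0] + merge_flank:
                current.append((pos, cid))
            else:
                groups.append(current)
                current = [(pos, cid)]
        groups.append(current)
        for grp in groups:
            pos_list = [p for p, _ in grp]
            flank = merge_flank if len(grp) > 1 else isolated_flank
            clusters.append(CpGCluster(
                gene=gene, contig=info.contig,
                start=min(pos_list) - flank, end=max(pos_list) + flank + 1,
                members=pos_list, member_ids=[c for _, c in grp]))
    return clusters


def gene_methylation_status(calls: Sequence[CpGCall], cluster: CpGCluster,
                            threshold: float = 0.07) -> bool | None:
    """Hypermethylated iff the mean beta over the cluster's member CpGs
    strictly exceeds ``threshold``; None when no member is covered."""
    betas = [c.beta for c in calls
             if c.contig == cluster.contig and c.position in set(cluster.members)
             and c.beta is not None]
    if not betas:
        return None
    return float(np.mean(betas)) > threshold


# ----------------------------------------------------------------- LOH model

@dataclass
class LOHFit:
    major_cn: int
    minor_cn: int
    log_posterior: float

    @property
    def loh(self) -> bool:
        return self.minor_cn == 0 and self.major_cn >= 1


def expected_baf(major: int, minor: int, purity: float) -> float:
    """Major-allele B-allele frequency under purity ``p``:
    (M*p + (1-p)) / ((M+N)*p + 2*(1-p)); 0.5 in the no-DNA corner case."""
    denom = (major + minor) * purity + 2.0 * (1.0 - purity)
    if denom == 0:
        return 0.5
    return (major * purity + (1.0 - purity)) / denom


def expected_depth(major: int, minor: int, purity: float, ploidy: float) -> float:
    """Normalized depth: ((M+N)*p + 2(1-p)) / (ploidy*p + 2(1-p))."""
    return ((major + minor) * purity + 2.0 * (1.0 - purity)) / (
        ploidy * purity + 2.0 * (1.0 - purity))


def fit_loh(norm_depth: float, baf: float, purity: float, ploidy: float = 2.0,
            max_copies: int = 8, sigma_baf: float = 0.05,
            sigma_depth: float = 0.1) -> LOHFit:
    """Maximum-posterior integer allele copy numbers for one gene.

    Grid search over M >= N >= 0, M <= ``max_copies`` maximizing a Gaussian
    likelihood on the observed BAF (major-allele frequency) and normalized
    depth, with a uniform prior over the grid. LOH = (N == 0 and M >= 1).
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity {purity} outside (0, 1]")
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    best: LOHFit | None = None
    for major in range(0, max_copies + 1):
        for minor in range(0, major + 1):
            e_baf = expected_baf(major, minor, purity)
            e_dep = expected_depth(major, minor, purity, ploidy)
            logp = (-((baf - e_baf) ** 2) / (2 * sigma_baf ** 2)
                    - ((norm_depth - e_dep) ** 2) / (2 * sigma_depth ** 2))
            if best is None or logp > best.log_posterior:
                best = LOHFit(major_cn=major, minor_cn=minor, log_posterior=logp)
    assert best is not None
    return best


# ------------------------------------------------------------ biallelic loss

def classify_biallelic(event: GeneEvent) -> bool:
    """Biallelic loss of function: homozygous deletion, LOH + promoter
    methylation, LOH + deleterious mutation, or two deleterious mutations."""
    return (event.homozygous_deletion
            or (event.loh and event.promoter_methylated)
            or (event.loh and event.deleterious_mutations >= 1)
            or event.deleterious_mutations >= 2)


@dataclass
class HRDAssociation:
    table: list[list[int]]  # [[biallelic HRD, non HRD], [biallelic HRP, non HRP]]
    fisher_p: float


def hrd_association(patients: pd.DataFrame) -> HRDAssociation:
    """Fisher association between per-patient biallelic loss and HRD status.

    ``patients`` columns: patient, hrd_status (HRD/HRP), biallelic (bool:
    biallelic loss in at least one gene).
    """
    hrd = patients[patients["hrd_status"] == "HRD"]
    hrp = patients[patients["hrd_status"] == "HRP"]
    if hrd.empty or hrp.empty:
        raise ValueError("both HRD and HRP groups must be non-empty")
    table = [[int(hrd["biallelic"].sum()), int((~hrd["biallelic"]).sum())],
             [int(hrp["biallelic"].sum()), int((~hrp["biallelic"]).sum())]]
    return HRDAssociation(table=table, fisher_p=fisher_exact(table))


# --------------------------------------------------------------- panel design

@dataclass
class PanelDesign:
    exons: list[str]            # base exons plus greedy additions, in order
    added: list[str]
    coverage: dict[str, float]  # final per-cohort coverage
    target_reached: bool


def _coverage(matrix: pd.DataFrame, exons: list[str]) -> float:
    cols = [e for e in exons if e in matrix.columns]
    if not cols:
        return 0.0
    return float((matrix[cols].sum(axis=1) > 0).mean())


def design_panel_greedy(cohorts: dict[str, pd.DataFrame], base_exons: Sequence[str],
                        target: float = 0.85) -> PanelDesign:
    """Greedy exon addition until every cohort covers > ``target`` patients.

    Each step adds the exon maximizing the minimum coverage gain across
    cohorts (ties broken by total gain, then exon order); the loop stops when
    the minimum cohort coverage strictly exceeds the target, or when no exon
    adds coverage anywhere (the design is then returned with
    ``target_reached=False``).
    """
    if not cohorts:
        raise ValueError("no cohorts given")
    all_exons = list(next(iter(cohorts.values())).columns)
    for name, m in cohorts.items():
        if list(m.columns) != all_exons:
            raise ValueError(f"cohort {name!r} has a different exon set")
    selected = list(base_exons)
    remaining = [e for e in all_exons if e not in selected]
    added: list[str] = []
    while True:
        cov = {n: _coverage(m, selected) for n, m in cohorts.items()}
        if min(cov.values()) > target:
            return PanelDesign(exons=selected, added=added, coverage=cov,
                               target_reached=True)
        best_exon, best_key = None, None
        for idx, exon in enumerate(remaining):
            gains = [_coverage(m, selected + [exon]) - cov[n]
                     for n, m in cohorts.items()]
            key = (min(gains), sum(gains), -idx)
            if best_key is None or key > best_key:
                best_exon, best_key = exon, key
        if best_exon is None or best_key[1] <= 1e-12:
            return PanelDesign(exons=selected, added=added, coverage=cov,
                               target_reached=False)
        selected.append(best_exon)
        added.append(best_exon)
        remaining.remove(best_exon)


# ---------------------------------------------------------------------- qPCR

def qpcr_call(ct_mutation: float | None, delta_ct_a: float | None,
              delta_ct_b: float | None, ct_threshold: float = 26.0,
              dct_a_threshold: float = 10.0, dct_b_threshold: float = 10.5
              ) -> tuple[bool, bool]:
    """(mutation_positive, methylation_positive) from Ct values.

    Mutation positive iff Ct < 26 (strict); methylation positive iff
    marker-A dCt < 10 or marker-B dCt < 10.5 (strict). Missing values
    (None/NaN) are negative.
    """
    def _ok(value: float | None, threshold: float) -> bool:
        return value is not None and not math.isnan(value) and value < threshold

    mutation = _ok(ct_mutation, ct_threshold)
    methylation = _ok(delta_ct_a, dct_a_threshold) or _ok(delta_ct_b, dct_b_threshold)
    return mutation, methylation
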