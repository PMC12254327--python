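"""Synthetic cohort tables emulating the structure of the public-cohort and
clinical inputs the decision layers consume (methylation/expression matrices,
mutation incidence, immune mixtures, gene-level events, binned coverage).

These stand-ins reproduce the statistical features the methods rely on
(planted promoter CpG/expression anti-correlation, multinomial marker counts,
biallelic-loss enrichment in HRD patients) without any external data.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ----------------------------------------------------- methylation/expression

@dataclass
class MethExprCohort:
    meth: pd.DataFrame            # CpG id x sample betas
    expr: pd.DataFrame            # gene x sample expression
    cpg_annotation: pd.DataFrame  # cpg_id, gene, contig, position
    tss: pd.DataFrame             # gene, contig, tss, strand
    planted_cpgs: list[str]       # truth: CpGs constructed to pass selection


def simulate_meth_expr(n_samples: int = 300, n_genes: int = 8,
                       planted_r: float = -0.6, planted_per_gene: int = 20,
                       background_per_gene: int = 30,
                       seed: int = 0) -> MethExprCohort:
    """Methylation + expression matrices with planted promoter CpG clusters.

    Planted CpGs sit densely (10 bp spacing) inside each gene's promoter and
    anti-correlate with expression at about ``planted_r``; background CpGs sit
    outside the promoter (or sparsely within) with no planted correlation.
    """
    if n_samples < 3 or n_genes < 1:
        raise ValueError("degenerate cohort size")
    if not -1.0 < planted_r < 0.0:
        raise ValueError("planted_r must be a negative correlation in (-1, 0)")
    rng = np.random.default_rng(seed)
    samples = [f"S{i:03d}" for i in range(n_samples)]
    # effect scale: beta = 0.5 - a*z + e with r = a / sqrt(a^2 + sigma^2)
    sigma = 0.2
    a = abs(planted_r) * sigma / np.sqrt(1.0 - planted_r ** 2)

    meth_rows, ann_rows, tss_rows, expr_rows = [], [], [], []
    planted: list[str] = []
    for g in range(n_genes):
        gene = f"GENE{g}"
        contig = "chr1"
        tss = 100_000 * (g + 1)
        tss_rows.append({"gene": gene, "contig": contig, "tss": tss, "strand": "+"})
        z = rng.standard_normal(n_samples)
        expr_rows.append(pd.Series(z, index=samples, name=gene))
        # planted cluster: dense CpGs inside the promoter window
        for j in range(planted_per_gene):
            pos = tss - 300 + 10 * j
            cpg = f"cg_{gene}_p{j}"
            beta = np.clip(0.5 - a * z + rng.normal(0.0, sigma, n_samples), 0.0, 1.0)
            meth_rows.append(pd.Series(beta, index=samples, name=cpg))
            ann_rows.append({"cpg_id": cpg, "gene": gene, "contig": contig,
                             "position": pos})
            planted.append(cpg)
        # background: uncorrelated CpGs far downstream of the promoter
        for j in range(background_per_gene):
            pos = tss + 5_000 + 400 * j
            cpg = f"cg_{gene}_b{j}"
            beta = np.clip(rng.normal(0.5, 0.25, n_samples), 0.0, 1.0)
            meth_rows.append(pd.Series(beta, index=samples, name=cpg))
            ann_rows.append({"cpg_id": cpg, "gene": gene, "contig": contig,
                             "position": pos})
    meth = pd.DataFrame(meth_rows)
    expr = pd.DataFrame(expr_rows)
    return MethExprCohort(meth=meth, expr=expr,
                          cpg_annotation=pd.DataFrame(ann_rows),
                          tss=pd.DataFrame(tss_rows), planted_cpgs=planted)


# ------------------------------------------------------------ exon incidence

def simulate_incidence(n_patients: int, exon_rates: dict[str, float],
                       seed: int = 0) -> pd.DataFrame:
    """Binary patient x exon mutation incidence with per-exon hit rates."""
    if n_patients < 1 or not exon_rates:
        raise ValueError("degenerate incidence size")
    rng = np.random.default_rng(seed)
    data = {exon: (rng.random(n_patients) < rate).astype(int)
            for exon, rate in exon_rates.items()}
    return pd.DataFrame(data, index=[f"P{i:03d}" for i in range(n_patients)])


# ------------------------------------------------------------- immune mixing

IMMUNE_CELL_TYPES = ("neutrophil", "lymphocyte_b", "lymphocyte_t", "nk",
                     "monocyte", "eosinophil", "megakaryocyte")


def make_immune_markers(n_markers: int = 17, seed: int = 0) -> pd.DataFrame:
    """Marker table: marker id, target cell type and a fixed per-marker
    detection efficiency (a property of the marker, shared across samples)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_markers):
        cell = IMMUNE_CELL_TYPES[i % len(IMMUNE_CELL_TYPES)]
        rows.append({"marker": f"imm{i:02d}", "cell_type": cell,
                     "efficiency": float(np.clip(rng.normal(0.95, 0.03), 0.8, 1.0))})
    return pd.DataFrame(rows)


def random_mixture(rng: np.random.Generator,
                   kind: str = "blood") -> dict[str, float]:
    """A plausible blood leukocyte composition (fractions summing to 1)."""
    alpha = {"neutrophil": 30.0, "lymphocyte_b": 3.0, "lymphocyte_t": 10.0,
             "nk": 2.0, "monocyte": 4.0, "eosinophil": 1.5, "megakaryocyte": 1.0}
    draw = rng.dirichlet([alpha[t] for t in IMMUNE_CELL_TYPES])
    return dict(zip(IMMUNE_CELL_TYPES, draw))


def simulate_immune_counts(truth_fractions: dict[str, float], markers: pd.DataFrame,
                           n_fragments: int = 2000, background: float = 0.005,
                           seed: int = 0) -> pd.DataFrame:
    """Per-marker fragment counts for one sample.

    At a marker specific to cell type t, a covering fragment is fully
    unmethylated with probability ``fraction_t * efficiency + background``;
    counts are binomial in the number of covering fragments.
    """
    total = sum(truth_fractions.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"truth fractions sum to {total}, expected 1")
    rng = np.random.default_rng(seed)
    rows = []
    for rec in markers.itertuples(index=False):
        p = truth_fractions[rec.cell_type] * rec.efficiency + background
        n_unmeth = int(rng.binomial(n_fragments, min(p, 1.0)))
        rows.append({"marker": rec.marker, "cell_type": rec.cell_type,
                     "n_fragments": n_fragments, "n_unmethylated": n_unmeth})
    return pd.DataFrame(rows)


@dataclass
class ImmuneCohort:
    markers: pd.DataFrame
    counts: dict[str, pd.DataFrame]         # sample -> marker count table
    truth: dict[str, dict[str, float]]      # sample -> cell type fractions
    cbc: dict[str, dict[str, float]]        # training samples -> CBC fractions
    training_samples: list[str] = field(default_factory=list)


def simulate_immune_cohort(n_training: int = 5, n_test: int = 5,
                           n_fragments: int = 2000, seed: int = 0) -> ImmuneCohort:
    """Training samples (with CBC ground truth) plus test samples."""
    rng = np.random.default_rng(seed)
    markers = make_immune_markers(seed=seed)
    counts, truth, cbc = {}, {}, {}
    training = []
    for i in range(n_training + n_test):
        sample = f"D{i:02d}"
        mix = random_mixture(rng)
        truth[sample] = mix
        counts[sample] = simulate_immune_counts(
            mix, markers, n_fragments=n_fragments,
            seed=int(rng.integers(0, 2 ** 31)))
        if i < n_training:
            training.append(sample)
            cbc[sample] = mix  # CBC reports the true composition
    return ImmuneCohort(markers=markers, counts=counts, truth=truth, cbc=cbc,
                        training_samples=training)


# ------------------------------------------------------------- gene events

def simulate_gene_cohort(n_hrd: int = 16, n_hrp: int = 11,
                         genes: tuple[str, ...] = ("BRCA1", "BRCA2", "RAD51C",
                                                   "RAD51D", "BRIP1", "CDK12",
                                                   "FANCA", "PALB2"),
                         p_biallelic_hrd: float = 0.75,
                         p_biallelic_hrp: float = 0.09,
                         seed: int = 0) -> pd.DataFrame:
    """Per-patient, per-gene LOH / methylation / mutation events with HRD labels.

    HRD patients carry a biallelic-loss event in at least one gene with the
    configured enrichment; the event is realised as LOH plus promoter
    methylation (the dominant mechanism in the clinical cohort this mimics).
    """
    if n_hrd < 1 or n_hrp < 1 or not genes:
        raise ValueError("degenerate cohort")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_hrd + n_hrp):
        label = "HRD" if i < n_hrd else "HRP"
        patient = f"T{i:02d}"
        p_bi = p_biallelic_hrd if label == "HRD" else p_biallelic_hrp
        hit_gene = rng.choice(genes) if rng.random() < p_bi else None
        for gene in genes:
            loh = bool(rng.random() < 0.5)
            methylated = bool(rng.random() < 0.05)
            mutations = int(rng.random() < 0.02)
            if gene == hit_gene:
                loh, methylated = True, True
            rows.append({"patient": patient, "hrd_status": label, "gene": gene,
                         "loh": loh, "promoter_methylated": methylated,
                         "deleterious_mutations": mutations,
                         "homozygous_deletion": False})
    return pd.DataFrame(rows)


# --------------------------------------------------------------- coverage

@dataclass
class CoverageTrack:
    bins: pd.DataFrame  # contig, start, end, raw_coverage, gc_fraction
    truth_segments: list[tuple[str, int, int, float]]  # contig, start, end, CN


def simulate_cnv_coverage(genome_length: int = 10_000_000, bin_size: int = 10_000,
                          depth: float = 30.0,
                          gains: list[tuple[int, int, float]] | None = None,
                          gc_bias: float = 0.0, seed: int = 0) -> CoverageTrack:
    """Per-bin coverage for a diploid genome with planted copy-number segments.

    ``gains`` lists (start, end, copy_number) segments; coverage in a bin is
    Poisson around ``depth * CN/2`` times an optional linear GC bias.
    """
    rng = np.random.default_rng(seed)
    n_bins = genome_length // bin_size
    starts = np.arange(n_bins) * bin_size
    gc = np.clip(rng.normal(0.41, 0.05, n_bins), 0.2, 0.7)
    cn = np.full(n_bins, 2.0)
    truth = []
    for (s, e, c) in gains or []:
        cn[(starts >= s) & (starts + bin_size <= e)] = c
        truth.append(("chr1", s, e, c))
    bias = 1.0 + gc_bias * (gc - float(gc.mean()))
    lam = depth * (cn / 2.0) * bias
    cov = rng.poisson(lam * bin_size) / bin_size
    bins = pd.DataFrame({"contig": "chr1", "start": starts,
                         "end": starts + bin_size,
                         "raw_coverage": cov, "gc_fraction": gc})
    return CoverageTrack(bins=bins, truth_segments=truth)
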