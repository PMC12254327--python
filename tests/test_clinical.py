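"""Decision layers: ctDNA rule, immune deconvolution, promoter clusters,
LOH model, biallelic classification, panel greedy, qPCR calls."""
import itertools

import numpy as np
import pandas as pd
import pytest

from mmseq.clinical import (
    CtdnaResult,
    call_ctdna_status,
    calibrate_fractions,
    classify_biallelic,
    ctdna_fraction,
    design_panel_greedy,
    expected_baf,
    fit_loh,
    gene_methylation_status,
    hrd_association,
    immune_fractions_from_counts,
    normalize_fcm,
    qpcr_call,
    select_correlated_cpgs,
    expected_depth,
)
from mmseq.core.types import AlignedFragment, CpGCall, GeneEvent, Meth, Region, Stream
from mmseq.simulate import simulate_gene_cohort, simulate_meth_expr


def meth_frag(states, start=100, end=200, name="f"):
    return AlignedFragment("chr1", start, end, 67, 131, "A" * 8, "A" * 8,
                           Stream.METH, bases="A" * (end - start),
                           cpg_states=states, name=name)


MARKER = Region("chr1", 100, 200, name="mk")


class TestCtdnaFraction:
    def test_fraction_arithmetic(self):
        frags = [meth_frag({110 + i: Meth.METHYLATED for i in range(5)},
                           name=f"t{j}") for j in range(5)]
        frags += [meth_frag({110 + i: (Meth.METHYLATED if i else Meth.UNMETHYLATED)
                             for i in range(5)}, name=f"n{j}") for j in range(3995)]
        result = ctdna_fraction(frags, [MARKER])
        assert result.n_eligible_fragments == 4000
        assert result.n_ctdna_fragments == 5
        assert result.ctdna_fraction == pytest.approx(0.00125)

    def test_fragment_with_four_cpgs_excluded(self):
        frags = [meth_frag({110 + i: Meth.METHYLATED for i in range(4)})]
        result = ctdna_fraction(frags, [MARKER])
        assert result.n_eligible_fragments == 0
        assert result.ctdna_fraction is None

    def test_partially_methylated_fragment_eligible_not_ctdna(self):
        states = {110 + i: Meth.METHYLATED for i in range(5)}
        states[116] = Meth.UNMETHYLATED
        result = ctdna_fraction([meth_frag(states)], [MARKER])
        assert (result.n_eligible_fragments, result.n_ctdna_fragments) == (1, 0)


class TestCtdnaStatusRule:
    def _result(self, n_ctdna, n_eligible, n_mut=0):
        return CtdnaResult(n_eligible_fragments=n_eligible,
                           n_ctdna_fragments=n_ctdna,
                           somatic_mutations=["m"] * n_mut)

    @pytest.mark.parametrize("n_ctdna,n_eligible,n_mut,expected", [
        (5, 4000, 0, "POSITIVE"),    # 0.125% > 0.1%, counts satisfied
        (2, 4000, 0, "NEGATIVE"),    # fails fraction and fragment count
        (5, 2500, 0, "NEGATIVE"),    # total below 3000
        (0, 4000, 1, "POSITIVE"),    # mutation alone suffices
        (4, 4000, 0, "NEGATIVE"),    # 0.1% exactly: strict >
        (0, 0, 0, "NEGATIVE"),       # undefined fraction, no mutation
    ])
    def test_printed_rule(self, n_ctdna, n_eligible, n_mut, expected):
        assert call_ctdna_status(self._result(n_ctdna, n_eligible, n_mut)) == expected

    def test_truth_table_over_boundary_adjacent_inputs(self):
        """Status equals the printed boolean formula on an exhaustive grid of
        threshold-adjacent values."""
        for n_mut, n_ctdna, n_eligible in itertools.product(
                (0, 1), (2, 3, 4, 5), (2999, 3000, 3001, 4000)):
            result = self._result(n_ctdna, n_eligible, n_mut)
            frac = n_ctdna / n_eligible
            expected = bool(n_mut) or (frac > 0.001 and n_ctdna >= 3
                                       and n_eligible >= 3000)
            assert (call_ctdna_status(result) == "POSITIVE") is expected


class TestImmune:
    def test_marker_mean_per_cell_type(self):
        counts = pd.DataFrame([
            {"marker": "a", "cell_type": "neutrophil", "n_fragments": 100,
             "n_unmethylated": 10},
            {"marker": "b", "cell_type": "neutrophil", "n_fragments": 100,
             "n_unmethylated": 20},
        ])
        assert immune_fractions_from_counts(counts) == {"neutrophil": pytest.approx(0.15)}

    def test_zero_coverage_marker_excluded_from_mean(self):
        counts = pd.DataFrame([
            {"marker": "a", "cell_type": "nk", "n_fragments": 100,
             "n_unmethylated": 10},
            {"marker": "b", "cell_type": "nk", "n_fragments": 0,
             "n_unmethylated": 0},
        ])
        assert immune_fractions_from_counts(counts) == {"nk": pytest.approx(0.10)}

    def test_identity_training_renormalizes_raw(self):
        raw = {"neutrophil": 0.5, "lymphocyte_t": 0.3}
        training = {t: [(0.1, 0.1), (0.6, 0.6)] for t in raw}
        profile = calibrate_fractions(raw, training)
        assert profile.calibrated["neutrophil"] == pytest.approx(0.5 / 0.8)
        assert sum(profile.calibrated.values()) == pytest.approx(1.0, abs=1e-12)

    def test_slope_two_training_doubles_then_renormalizes(self):
        raw = {"neutrophil": 0.3, "lymphocyte_t": 0.1}
        training = {t: [(0.1, 0.2), (0.4, 0.8)] for t in raw}
        profile = calibrate_fractions(raw, training)
        # doubling both then renormalizing reproduces the raw proportions
        assert profile.calibrated["neutrophil"] == pytest.approx(0.75)

    def test_degenerate_training_rejected(self):
        with pytest.raises(ValueError, match="degenerate|training"):
            calibrate_fractions({"nk": 0.1}, {"nk": [(0.2, 0.1), (0.2, 0.3)]})

    def test_nlr_and_undefined_at_zero_lymphocytes(self):
        from mmseq.clinical import ImmuneProfile
        p = ImmuneProfile(raw={}, calibrated={"neutrophil": 0.6,
                                              "lymphocyte_t": 0.2,
                                              "lymphocyte_b": 0.1, "nk": 0.1})
        assert p.nlr == pytest.approx(1.5)
        q = ImmuneProfile(raw={}, calibrated={"neutrophil": 1.0})
        assert q.nlr is None

    def test_fcm_normalization_rescales_groups(self):
        fcm = {"lymphocyte_t": 0.2, "lymphocyte_b": 0.2, "neutrophil": 0.5}
        cbc = {"lymphocyte_t": 0.15, "lymphocyte_b": 0.15, "nk": 0.0,
               "neutrophil": 0.5, "eosinophil": 0.1, "monocyte": 0.0}
        out = normalize_fcm(fcm, cbc)
        assert out["lymphocyte_t"] == pytest.approx(0.15)
        assert out["lymphocyte_b"] == pytest.approx(0.15)
        assert out["neutrophil"] == pytest.approx(0.6)

    def test_fcm_identity_when_groups_match(self):
        fcm = {"lymphocyte_t": 0.3, "neutrophil": 0.6, "monocyte": 0.1}
        cbc = dict(fcm)
        out = normalize_fcm(fcm, cbc)
        assert out == pytest.approx(fcm)

    def test_fcm_zero_group_rejected(self):
        with pytest.raises(ValueError):
            normalize_fcm({"lymphocyte_t": 0.0, "neutrophil": 0.5},
                          {"lymphocyte_t": 0.3, "neutrophil": 0.5})


class TestPromoterSelection:
    def test_planted_cluster_selected_and_background_rejected(self):
        cohort = simulate_meth_expr(n_samples=300, n_genes=2, seed=16)
        clusters = select_correlated_cpgs(cohort.meth, cohort.expr,
                                          cohort.cpg_annotation, cohort.tss)
        selected = {cid for cl in clusters for cid in cl.member_ids}
        planted = set(cohort.planted_cpgs)
        assert len(selected & planted) / len(planted) >= 0.9
        assert not any(cid.split("_")[2].startswith("b") for cid in selected)

    def test_merging_matches_interval_union_oracle(self):
        cohort = simulate_meth_expr(n_samples=200, n_genes=3, seed=17)
        clusters = select_correlated_cpgs(cohort.meth, cohort.expr,
                                          cohort.cpg_annotation, cohort.tss)
        for cl in clusters:
            positions = sorted(cl.members)
            # brute-force union of +-100 bp intervals must be one component
            gaps = [b - a for a, b in zip(positions, positions[1:])]
            assert all(g <= 200 for g in gaps)

    def test_two_candidates_150bp_apart_merge(self):
        # construct a minimal two-candidate gene directly
        rng = np.random.default_rng(0)
        samples = [f"S{i}" for i in range(100)]
        z = rng.standard_normal(100)
        beta = np.clip(0.5 - 0.2 * z, 0, 1)
        positions = [1000, 1150] + [1000 + 7 * k for k in range(1, 7)] \
            + [1150 + 7 * k for k in range(1, 7)]
        rows, ann = [], []
        for i, pos in enumerate(positions):
            cid = f"cg{i}"
            noise = rng.normal(0, 0.01, 100)
            rows.append(pd.Series(np.clip(beta + noise, 0, 1),
                                  index=samples, name=cid))
            ann.append({"cpg_id": cid, "gene": "G", "contig": "chr1",
                        "position": pos})
        meth = pd.DataFrame(rows)
        expr = pd.DataFrame([pd.Series(z, index=samples, name="G")])
        tss = pd.DataFrame([{"gene": "G", "contig": "chr1", "tss": 1500,
                             "strand": "+"}])
        clusters = select_correlated_cpgs(meth, expr, pd.DataFrame(ann), tss)
        genes = [c for c in clusters if {1000, 1150} <= set(c.members)]
        assert genes, "candidates 150 bp apart must merge (100 bp flanks overlap)"

    def test_too_few_shared_samples_rejected(self):
        cohort = simulate_meth_expr(n_samples=10, n_genes=1, seed=18)
        meth = cohort.meth[cohort.meth.columns[:2]]
        with pytest.raises(ValueError, match="shared"):
            select_correlated_cpgs(meth, cohort.expr, cohort.cpg_annotation,
                                   cohort.tss)


class TestGeneMethylationStatus:
    def _cluster(self):
        from mmseq.clinical import CpGCluster
        return CpGCluster(gene="G", contig="chr1", start=0, end=100,
                          members=[10, 20])

    def test_mean_above_threshold(self):
        calls = [CpGCall("chr1", 10, 5, 95), CpGCall("chr1", 20, 15, 85)]
        assert gene_methylation_status(calls, self._cluster()) is True  # mean 0.10

    def test_exactly_threshold_is_negative(self):
        calls = [CpGCall("chr1", 10, 7, 93), CpGCall("chr1", 20, 7, 93)]
        assert gene_methylation_status(calls, self._cluster()) is False  # 0.07 strict

    def test_uncovered_cluster_undefined(self):
        assert gene_methylation_status([], self._cluster()) is None


class TestLOH:
    def test_purity_one_hemizygous(self):
        fit = fit_loh(norm_depth=0.5, baf=1.0, purity=1.0, ploidy=2.0)
        assert (fit.major_cn, fit.minor_cn) == (1, 0)
        assert fit.loh

    def test_diploid_het_no_loh(self):
        fit = fit_loh(norm_depth=1.0, baf=0.5, purity=1.0, ploidy=2.0)
        assert (fit.major_cn, fit.minor_cn) == (1, 1)
        assert not fit.loh

    def test_half_purity_loh_expected_baf(self):
        assert expected_baf(1, 0, 0.5) == pytest.approx(2 / 3)
        fit = fit_loh(norm_depth=expected_depth(1, 0, 0.5, 2.0), baf=2 / 3,
                      purity=0.5)
        assert (fit.major_cn, fit.minor_cn) == (1, 0)

    def test_recovers_all_planted_states_on_noise_free_grid(self):
        for purity in (0.3, 0.6, 1.0):
            for major in range(0, 5):
                for minor in range(0, major + 1):
                    fit = fit_loh(expected_depth(major, minor, purity, 2.0),
                                  expected_baf(major, minor, purity), purity)
                    assert (fit.major_cn, fit.minor_cn) == (major, minor), \
                        (purity, major, minor, fit)

    def test_invalid_purity_rejected(self):
        with pytest.raises(ValueError):
            fit_loh(1.0, 0.5, purity=0.0)


class TestBiallelic:
    @pytest.mark.parametrize("kwargs,expected", [
        ({"homozygous_deletion": True}, True),
        ({"loh": True, "promoter_methylated": True}, True),
        ({"loh": True, "deleterious_mutations": 1}, True),
        ({"deleterious_mutations": 2}, True),
        ({"loh": True}, False),
        ({"promoter_methylated": True}, False),
        ({"deleterious_mutations": 1}, False),
        ({}, False),
    ])
    def test_four_rules(self, kwargs, expected):
        assert classify_biallelic(GeneEvent(gene="G", **kwargs)) is expected

    def test_hrd_association_on_printed_counts(self):
        rows = ([{"patient": f"d{i}", "hrd_status": "HRD", "biallelic": i < 12}
                 for i in range(16)]
                + [{"patient": f"p{i}", "hrd_status": "HRP", "biallelic": i < 1}
                   for i in range(11)])
        assoc = hrd_association(pd.DataFrame(rows))
        assert assoc.table == [[12, 4], [1, 10]]
        assert assoc.fisher_p <= 0.01

    def test_identical_rates_not_significant(self):
        rows = ([{"patient": f"d{i}", "hrd_status": "HRD", "biallelic": i < 5}
                 for i in range(10)]
                + [{"patient": f"p{i}", "hrd_status": "HRP", "biallelic": i < 5}
                   for i in range(10)])
        assert hrd_association(pd.DataFrame(rows)).fisher_p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            hrd_association(pd.DataFrame(
                [{"patient": "a", "hrd_status": "HRD", "biallelic": True}]))

    def test_planted_cohort_enrichment_beats_permutation_null(self):
        """On a simulated cohort with planted enrichment the Fisher p falls
        below the empirical permutation p at the same table."""
        events = simulate_gene_cohort(seed=19)
        patients = (events.assign(bi=[classify_biallelic(GeneEvent(
            gene=r.gene, loh=r.loh, promoter_methylated=r.promoter_methylated,
            deleterious_mutations=r.deleterious_mutations,
            homozygous_deletion=r.homozygous_deletion))
            for r in events.itertuples(index=False)])
            .groupby(["patient", "hrd_status"])["bi"].any().reset_index()
            .rename(columns={"bi": "biallelic"}))
        assoc = hrd_association(patients)
        # permutation oracle: shuffle labels, compare observed enrichment
        rng = np.random.default_rng(0)
        flags = patients["biallelic"].to_numpy()
        labels = (patients["hrd_status"] == "HRD").to_numpy()
        observed = flags[labels].mean() - flags[~labels].mean()
        n_perm = 2000
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            stat = flags[perm].mean() - flags[~perm].mean()
            hits += abs(stat) >= abs(observed) - 1e-12
        perm_p = (hits + 1) / (n_perm + 1)
        assert assoc.fisher_p <= perm_p + 0.02


def brute_force_greedy(cohorts, base, target):
    """Independent re-derivation of the greedy rule with explicit loops."""
    def cov(matrix, exons):
        hit = 0
        for _, row in matrix.iterrows():
            if any(row[e] for e in exons if e in matrix.columns):
                hit += 1
        return hit / len(matrix)

    selected = list(base)
    remaining = [e for e in next(iter(cohorts.values())).columns
                 if e not in selected]
    while True:
        current = {n: cov(m, selected) for n, m in cohorts.items()}
        if min(current.values()) > target:
            return selected
        best = None
        for idx, e in enumerate(remaining):
            gains = [cov(m, selected + [e]) - current[n]
                     for n, m in cohorts.items()]
            key = (min(gains), sum(gains), -idx)
            if best is None or key > best[0]:
                best = (key, e)
        if best is None or best[0][1] <= 1e-12:
            return selected
        selected.append(best[1])
        remaining.remove(best[1])


class TestPanelGreedy:
    def test_three_exon_worked_example(self):
        # patients 1..4; A covers {1,2}, B covers {3}, C covers {1}
        matrix = pd.DataFrame({"A": [1, 1, 0, 0], "B": [0, 0, 1, 0],
                               "C": [1, 0, 0, 0]})
        design = design_panel_greedy({"cohort": matrix}, [], target=0.75)
        assert design.added == ["A", "B"]
        assert not design.target_reached  # 0.75 is not strictly exceeded
        assert design.coverage["cohort"] == pytest.approx(0.75)

    def test_base_already_covering_returns_unchanged(self):
        matrix = pd.DataFrame({"A": [1] * 9 + [0], "B": [0] * 10})
        design = design_panel_greedy({"c": matrix}, ["A"], target=0.85)
        assert design.exons == ["A"] and design.added == []
        assert design.target_reached

    def test_matches_enumeration_oracle_on_random_instances(self):
        rng = np.random.default_rng(20)
        for trial in range(30):
            n_pat = int(rng.integers(2, 9))
            n_ex = int(rng.integers(1, 7))
            exons = [f"E{j}" for j in range(n_ex)]
            cohorts = {
                name: pd.DataFrame(rng.integers(0, 2, size=(n_pat, n_ex)),
                                   columns=exons)
                for name in (["one"] if trial % 2 else ["one", "two"])}
            target = float(rng.choice([0.5, 0.75, 0.85]))
            design = design_panel_greedy(cohorts, [], target=target)
            assert design.exons == brute_force_greedy(cohorts, [], target), \
                (trial, cohorts, target)

    def test_mismatched_exon_sets_rejected(self):
        a = pd.DataFrame({"A": [1]})
        b = pd.DataFrame({"B": [1]})
        with pytest.raises(ValueError):
            design_panel_greedy({"a": a, "b": b}, [])


class TestQPCR:
    @pytest.mark.parametrize("ct,a,b,expected", [
        (25.9, None, None, (True, False)),   # boundary below 26
        (26.0, None, None, (False, False)),  # strict <
        (None, 10.0, 10.4, (False, True)),   # positive via marker B only
        (None, 9.9, None, (False, True)),
        (None, 10.0, 10.5, (False, False)),
        (30.0, float("nan"), 12.0, (False, False)),
    ])
    def test_call_rules(self, ct, a, b, expected):
        assert qpcr_call(ct, a, b) == expected
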