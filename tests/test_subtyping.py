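"""POLE/MSI/CNH/CNL decision tree, consensus clustering, driver genotypes."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from cstyper.profiles import TumorProfile
from cstyper.subtyping import (
    MSI_MARKERS, DriverMutationSubtype, MsiPanelResult, assign_cnh, call_msi_high,
    call_pole, classify_cohort, classify_subtype, consensus_cluster,
    driver_mutation_subtype,
)
from cstyper.variants import SomaticVariant


def sv(gene="POLE", protein_change="p.P286R", consequence="missense", **kw):
    base = dict(sample_id="S1", chrom="chr1", pos=100, ref="T", alt="G",
                gene=gene, protein_change=protein_change,
                consequence=consequence, vaf=0.4, depth=200)
    base.update(kw)
    return SomaticVariant(**base)


def panel(n_unstable):
    return MsiPanelResult(
        {m: (i < n_unstable) for i, m in enumerate(MSI_MARKERS)}
    )


class TestCallPole:
    def test_hotspot_in_exonuclease_domain_detected(self):
        assert call_pole([sv()]) is not None

    def test_domain_membership_by_codon(self):
        assert call_pole([sv(protein_change="p.L424V")]) is not None
        assert call_pole([sv(protein_change="p.K600R")]) is None

    def test_synonymous_in_domain_not_evidence(self):
        assert call_pole([sv(consequence="synonymous")]) is None

    def test_hotspot_list_overrides_domain_range(self):
        v = sv(protein_change="p.X600Y")
        assert call_pole([v], hotspot_list={"X600Y"}) is v

    def test_unparseable_protein_change_skipped(self):
        assert call_pole([sv(protein_change="???")]) is None


class TestMsiHigh:
    @pytest.mark.parametrize("n, expected", [(0, False), (1, False), (2, True), (6, True)])
    def test_marker_count_threshold(self, n, expected):
        assert call_msi_high(panel(n)) is expected

    def test_panel_must_cover_all_six_markers(self):
        with pytest.raises(ValueError):
            MsiPanelResult({"BAT25": True})


class TestConsensusCluster:
    def test_well_separated_blobs_give_binary_consensus(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.05, (8, 4)), rng.normal(5, 0.05, (9, 4))])
        res = consensus_cluster(X, k_range=(2, 3), reps=100, seed=1)
        assert res.chosen_k == 2
        cons = res.consensus[2]
        within = cons[:8, :8]
        across = cons[:8, 8:]
        assert within.min() > 0.99
        assert across.max() < 0.01

    def test_duplicated_samples_always_co_cluster(self):
        rng = np.random.default_rng(1)
        row = rng.normal(0, 1, 5)
        X = np.vstack([row, row, rng.normal(4, 0.1, (6, 5))])
        res = consensus_cluster(X, k_range=(2,), reps=100, seed=2)
        assert res.consensus[2][0, 1] == pytest.approx(1.0)

    def test_planted_four_clusters_recovered(self):
        rng = np.random.default_rng(2)
        centers = rng.normal(0, 3, (4, 8))
        truth = np.repeat(np.arange(4), 12)
        X = centers[truth] + rng.normal(0, 0.3, (48, 8))
        res = consensus_cluster(X, k_range=(2, 3, 4, 5), reps=300, seed=3)
        assert res.chosen_k == 4
        assert adjusted_rand_score(truth, res.labels) > 0.9

    def test_k_at_least_n_samples_rejected(self):
        with pytest.raises(ValueError):
            consensus_cluster(np.zeros((3, 2)), k_range=(3,), reps=10, seed=0)


class TestAssignCnh:
    def test_high_burden_cluster_labeled(self):
        labels = np.array([0] * 6 + [1] * 6)
        counts = np.array([17, 15, 20, 18, 16, 17, 2, 1, 3, 2, 2, 1])
        mask = assign_cnh(labels, counts)
        assert mask[:6].all() and not mask[6:].any()

    def test_no_aberrations_no_cnh(self):
        assert not assign_cnh(np.array([0, 0, 1, 1]), np.zeros(4)).any()


class TestDecisionTree:
    def make_profile(self, sid="S1", variants=(), n_unstable=0, segments=()):
        return TumorProfile(
            sample_id=sid, somatic_variants=list(variants),
            segments=list(segments), msi_panel=panel(n_unstable),
        )

    def test_pole_takes_precedence_over_msi(self):
        p = self.make_profile(variants=[sv()], n_unstable=4)
        call = classify_subtype(p)
        assert call.label == "POLE"
        assert call.pole_evidence.protein_change == "p.P286R"

    def test_msi_before_copy_number(self, small_cohort):
        profiles, truth, _ = small_cohort
        cnh_sample = next(
            p for p in profiles if truth.samples[p.sample_id]["subtype"] == "CNH"
        )
        p = self.make_profile(variants=[], n_unstable=3, segments=cnh_sample.segments)
        assert classify_subtype(p).label == "MSI"

    def test_residual_class_is_cnl(self):
        assert classify_subtype(self.make_profile()).label == "CNL"

    def test_missing_msi_panel_is_an_error(self):
        p = TumorProfile(sample_id="S1")
        with pytest.raises(ValueError, match="MSI panel"):
            classify_subtype(p)

    def test_cohort_recovery_and_burden_ranks(self, default_cohort):
        """Subtype recovery on a default cohort, with the expected burden
        ordering: POLE highest SNVs, MSI highest indels, CNH most CNVs."""
        profiles, truth = default_cohort
        calls = classify_cohort(profiles, seed=7)
        acc = np.mean([
            truth.samples[p.sample_id]["subtype"] == c.label
            for p, c in zip(profiles, calls)
        ])
        assert acc >= 0.95

        frame = truth.to_frame().set_index("sample_id")
        med = frame.groupby("subtype")[["n_snv", "n_indel", "n_cnv"]].median()
        assert med["n_snv"].idxmax() == "POLE"
        assert med["n_indel"].idxmax() == "MSI"
        assert med["n_cnv"].idxmax() == "CNH"

    def test_labels_stable_under_sample_permutation(self, small_cohort):
        profiles, _, _ = small_cohort
        calls = classify_cohort(profiles, seed=5)
        perm = list(reversed(profiles))
        calls_perm = classify_cohort(perm, seed=5)
        by_id = {c.sample_id: c.label for c in calls}
        assert all(by_id[c.sample_id] == c.label for c in calls_perm)


class TestDriverMutationSubtype:
    def test_endometrioid_rule(self):
        res = driver_mutation_subtype([sv(gene="PTEN", consequence="truncating")])
        assert res.label == "endometrioid_like" and res.genes == {"PTEN"}

    def test_serous_rule(self):
        res = driver_mutation_subtype([sv(gene="TP53")])
        assert res.label == "serous_like"

    def test_unclassified_without_the_four_genes(self):
        res = driver_mutation_subtype([sv(gene="KRAS")])
        assert res.label == "unclassified" and not res.genes

    def test_both_pairs_resolves_endometrioid_flagged_ambiguous(self):
        res = driver_mutation_subtype([sv(gene="ARID1A"), sv(gene="PPP2R1A", pos=200)])
        assert res.label == "endometrioid_like" and res.ambiguous

    def test_synonymous_hits_do_not_count(self):
        res = driver_mutation_subtype([sv(gene="TP53", consequence="synonymous")])
        assert res.label == "unclassified"

    def test_invariant_unclassified_iff_empty_genes(self):
        with pytest.raises(ValueError):
            DriverMutationSubtype("unclassified", frozenset({"PTEN"}))
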