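"""Shared-status labelling, frequency comparisons, correlations, CNV/fusions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clonedivergence import (
    AlterationClass,
    Cohort,
    Lesion,
    PatientPair,
    SampleProfile,
    SharedStatus,
    Variant,
    cnv_chromosome_distribution,
    compare_fusions,
    compare_gene_frequencies,
    gene_alteration_frequency,
    label_shared_status,
    paired_lesion_correlation,
)
from clonedivergence.association import (
    Contingency2x2,
    fisher_exact_bruteforce,
    test_2x2 as run_2x2,
)
from clonedivergence.landscape import LandscapeError

from conftest import make_clinical, make_pair, make_snv


class TestSharedStatus:
    def test_partition_of_simple_overlap(self):
        pair = make_pair("A", {(1, 10), (1, 20)}, {(1, 20), (1, 30)})
        labels = {k[1:3]: v for k, v in label_shared_status(pair).items()}
        assert labels[("1", 10)] is SharedStatus.P
        assert labels[("1", 20)] is SharedStatus.S
        assert labels[("1", 30)] is SharedStatus.M

    def test_identical_sets_all_shared(self):
        pair = make_pair("A", {(1, 10), (2, 5)}, {(1, 10), (2, 5)})
        assert set(label_shared_status(pair).values()) == {SharedStatus.S}

    def test_unpaired_rejected(self):
        pair = PatientPair("A", make_clinical("A"),
                           primary=SampleProfile("A", Lesion.PRIMARY, ()))
        with pytest.raises(LandscapeError, match="not paired"):
            label_shared_status(pair)

    @given(
        pk=st.sets(st.integers(0, 30), max_size=15),
        mk=st.sets(st.integers(0, 30), max_size=15),
    )
    @settings(max_examples=50, deadline=None)
    def test_status_partitions_union(self, pk, mk):
        pair = make_pair("A", {(1, p + 1) for p in pk}, {(1, m + 1) for m in mk})
        labels = label_shared_status(pair)
        assert len(labels) == len(pk | mk)
        counts = {s: sum(1 for v in labels.values() if v is s) for s in SharedStatus}
        assert counts[SharedStatus.S] == len(pk & mk)
        assert counts[SharedStatus.P] == len(pk - mk)
        assert counts[SharedStatus.M] == len(mk - pk)


class TestGeneFrequency:
    def _cohort_with_shared_tp53(self, n_shared=22, n_total=64):
        pairs = []
        for i in range(n_total):
            pid = f"P{i:02d}"
            if i < n_shared:
                pair = PatientPair(
                    pid, make_clinical(pid),
                    primary=SampleProfile(pid, Lesion.PRIMARY,
                                          (make_snv(pid, "primary", "TP53"),)),
                    metastasis=SampleProfile(pid, Lesion.METASTASIS,
                                             (make_snv(pid, "metastasis", "TP53"),)),
                )
            else:
                pair = PatientPair(
                    pid, make_clinical(pid),
                    primary=SampleProfile(pid, Lesion.PRIMARY,
                                          (make_snv(pid, "primary", "OTHER"),)),
                    metastasis=SampleProfile(pid, Lesion.METASTASIS, ()),
                )
            pairs.append(pair)
        return Cohort(pairs=tuple(pairs))

    def test_shared_tp53_frequency_matches_printed_34_38(self):
        cohort = self._cohort_with_shared_tp53()
        freq = gene_alteration_frequency(cohort, shared_status=SharedStatus.S)
        row = freq.set_index("gene").loc["TP53"]
        assert row["n_mutated_patients"] == 22
        assert row["n_patients"] == 64
        assert round(100 * row["frequency"], 2) == 34.38

    def test_patient_counted_once_despite_multiple_hits(self):
        pid = "A"
        prof = SampleProfile(pid, Lesion.PRIMARY, (
            make_snv(pid, "primary", "ARID1A", pos=10),
            make_snv(pid, "primary", "ARID1A", pos=99),
        ))
        pair = PatientPair(pid, make_clinical(pid), primary=prof)
        freq = gene_alteration_frequency(Cohort(pairs=(pair,)))
        assert freq.set_index("gene").loc["ARID1A", "n_mutated_patients"] == 1

    def test_empty_selection_rejected(self, synthetic):
        with pytest.raises(LandscapeError, match="empty"):
            gene_alteration_frequency(synthetic["cohort"], patients=[])


class TestCompareGeneFrequencies:
    @staticmethod
    def _freq_table(counts, n, group):
        import pandas as pd
        return pd.DataFrame(
            {
                "gene": list(counts),
                "group": group,
                "n_mutated_patients": list(counts.values()),
                "n_patients": n,
                "frequency": [c / n for c in counts.values()],
            }
        )

    def test_fisher_p_for_0_of_41_vs_6_of_33(self):
        a = self._freq_table({"FUS": 0}, 41, "a")
        b = self._freq_table({"FUS": 6}, 33, "b")
        res = compare_gene_frequencies(a, b, min_count=3)
        assert res.loc[0, "p_value"] == pytest.approx(0.0060, abs=5e-4)

    def test_identical_frequencies_p_one(self):
        a = self._freq_table({"TP53": 5}, 10, "a")
        b = self._freq_table({"TP53": 5}, 10, "b")
        res = compare_gene_frequencies(a, b, min_count=3, method="fisher")
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_min_count_filter_omits_rare_genes(self):
        a = self._freq_table({"RARE": 1, "COMMON": 8}, 20, "a")
        b = self._freq_table({"RARE": 1, "COMMON": 2}, 20, "b")
        res = compare_gene_frequencies(a, b, min_count=3)
        assert list(res["gene"]) == ["COMMON"]

    @given(
        st.integers(0, 12), st.integers(0, 12),
        st.integers(1, 14), st.integers(1, 14),
    )
    @settings(max_examples=60, deadline=None)
    def test_fisher_matches_bruteforce_enumeration(self, ka, kb, na, nb):
        ka, kb = min(ka, na), min(kb, nb)
        if ka + kb == 0:
            return
        tab = Contingency2x2(ka, na - ka, kb, nb - kb)
        assert run_2x2(tab, method="fisher").p_value == pytest.approx(
            fisher_exact_bruteforce(tab), abs=1e-10
        )


class TestPairedCorrelation:
    def test_identical_vaf_vectors_r_one(self):
        pair = make_pair("A", {(1, 10), (1, 20), (1, 30), (1, 40)},
                         {(1, 10), (1, 20), (1, 30), (1, 40)})
        # same sites but give them distinct VAFs on both sides
        import dataclasses
        prim = tuple(dataclasses.replace(v, vaf=0.1 * (i + 1))
                     for i, v in enumerate(pair.primary.variants))
        met = tuple(dataclasses.replace(v, vaf=0.1 * (i + 1))
                    for i, v in enumerate(pair.metastasis.variants))
        pair = dataclasses.replace(
            pair,
            primary=dataclasses.replace(pair.primary, variants=prim),
            metastasis=dataclasses.replace(pair.metastasis, variants=met),
        )
        res = paired_lesion_correlation(pair, "SNV")
        assert res.r == pytest.approx(1.0)

    def test_below_min_keys_undefined_with_reason(self):
        pair = make_pair("A", {(1, 10)}, {(1, 20)})
        res = paired_lesion_correlation(pair, "SNV", min_keys=3)
        assert res.r is None and "union keys" in res.reason

    def test_symmetric_in_lesion_order(self, synthetic):
        import dataclasses
        for pair in synthetic["cohort"].paired()[:5]:
            fwd = paired_lesion_correlation(pair, "SNV")
            swapped = dataclasses.replace(
                pair,
                primary=dataclasses.replace(
                    pair.metastasis, lesion=Lesion.PRIMARY,
                    variants=tuple(dataclasses.replace(v, lesion=Lesion.PRIMARY)
                                   for v in pair.metastasis.variants)),
                metastasis=dataclasses.replace(
                    pair.primary, lesion=Lesion.METASTASIS,
                    variants=tuple(dataclasses.replace(v, lesion=Lesion.METASTASIS)
                                   for v in pair.primary.variants)),
            )
            rev = paired_lesion_correlation(swapped, "SNV")
            if fwd.r is None:
                assert rev.r is None
            else:
                assert fwd.r == pytest.approx(rev.r, abs=1e-12)

    def test_shared_trunk_drives_positive_correlation(self, synthetic):
        truth = synthetic["truth"].set_index("patient_id")
        rs = {}
        for pair in synthetic["cohort"].paired():
            res = paired_lesion_correlation(pair, "SNV")
            if res.r is not None:
                rs[pair.patient_id] = res.r
        high = [rs[p] for p in rs if truth.loc[p, "true_class"] == "linear"]
        low = [rs[p] for p in rs if truth.loc[p, "true_class"] == "parallel"]
        assert np.mean(high) > np.mean(low)


class TestCNVAndFusions:
    def test_all_cnvs_on_one_chromosome(self):
        pid = "A"
        cnvs = tuple(
            Variant(pid, Lesion.PRIMARY, f"G{i}", "17", 100 + i, "-", "-",
                    AlterationClass.AMPLIFICATION)
            for i in range(4)
        )
        pair = PatientPair(pid, make_clinical(pid),
                           primary=SampleProfile(pid, Lesion.PRIMARY, cnvs))
        counts, _ = cnv_chromosome_distribution(Cohort(pairs=(pair,)))
        assert counts["count"].sum() == 4
        assert set(counts["chrom"]) == {"17"}
        assert set(counts["direction"]) == {"amplification"}

    def test_metastasis_deletion_excess_detected(self, big_synthetic):
        """The generator biases metastatic deletions to chromosome 9."""
        counts, tests = cnv_chromosome_distribution(big_synthetic["cohort"])
        row = tests[(tests["chrom"] == "9") & (tests["direction"] == "deletion")]
        assert len(row) == 1
        assert row["n_metastasis"].iloc[0] > row["n_primary"].iloc[0]
        assert row["p_value"].iloc[0] < 0.05

    def test_empty_cnv_set_gives_empty_tables(self):
        pair = make_pair("A", {(1, 10)}, {(1, 20)})
        counts, tests = cnv_chromosome_distribution(Cohort(pairs=(pair,)))
        assert counts.empty and tests.empty

    def test_fusion_shared_iff_unordered_pair_in_both_lesions(self):
        pid = "A"
        fus = lambda lesion, a, b: Variant(
            pid, Lesion(lesion), a, "3", 100, "-", "-",
            AlterationClass.FUSION_REARRANGEMENT, fusion_partner=b)
        pair = PatientPair(
            pid, make_clinical(pid),
            primary=SampleProfile(pid, Lesion.PRIMARY,
                                  (fus("primary", "CLDN18", "ARHGAP26"),)),
            metastasis=SampleProfile(pid, Lesion.METASTASIS,
                                     (fus("metastasis", "ARHGAP26", "CLDN18"),
                                      fus("metastasis", "TCF3", "MBD3"))),
        )
        table = compare_fusions(Cohort(pairs=(pair,)))
        by_pair = table.set_index(["gene_a", "gene_b"])["status"]
        assert by_pair[("ARHGAP26", "CLDN18")] == "shared"
        assert by_pair[("MBD3", "TCF3")] == "metastasis_only"

    def test_no_fusions_empty_output(self):
        pair = make_pair("A", {(1, 10)}, {(1, 20)})
        assert compare_fusions(Cohort(pairs=(pair,))).empty
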