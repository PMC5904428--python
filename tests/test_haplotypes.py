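import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barcodegeo.alignment_io import AlignedSequenceSet, SpecimenRecord
from barcodegeo.distances import distance_matrix
from barcodegeo.haplotypes import (
    classify_site_change,
    collapse_haplotypes,
    collapse_nonsynonymous_only,
    diversity_stats,
    haplotype_diversity,
    nucleotide_diversity,
    region_frequency_matrix,
    region_summary,
    write_popart_nexus,
)


def aln_of(*seqs):
    return AlignedSequenceSet.from_records(
        [(f"s{i + 1}", s) for i, s in enumerate(seqs)]
    )


def oracle_collapse(seqs):
    """Manual column mask + string grouping, the independent oracle."""
    keep = [
        c
        for c in range(len(seqs[0]))
        if all(s[c] in "ACGT" for s in seqs)
    ]
    groups = {}
    for i, s in enumerate(seqs):
        key = "".join(s[c] for c in keep)
        groups.setdefault(key, []).append(i)
    return keep, list(groups.values())


class TestCollapse:
    def test_identical_records_one_haplotype(self):
        table = collapse_haplotypes(aln_of("ACGT", "ACGT", "ACGT", "ACGT"))
        assert table.s_obs == 1
        assert table.abundances.tolist() == [4]

    def test_column_with_missing_data_removed_dataset_wide(self):
        table = collapse_haplotypes(aln_of("ACGT", "ACGT", "ACTT", "ANGT"))
        assert table.retained_sites == (0, 2, 3)
        assert table.abundances.tolist() == [3, 1]
        members = {m for _, _, mem in table.haplotypes for m in mem}
        assert members == {"s1", "s2", "s3", "s4"}

    def test_survey_scale_haplotype_count(self, survey_fixture):
        table = collapse_haplotypes(survey_fixture.alignment)
        assert table.s_obs == 47
        assert table.n == 97

    def test_zero_retained_sites_is_an_error(self):
        with pytest.raises(ValueError, match="retained"):
            collapse_haplotypes(aln_of("N", "A"))

    def test_strict_policy_requires_complete_matrix(self):
        with pytest.raises(ValueError, match="strict"):
            collapse_haplotypes(aln_of("AN", "AA"), missing_policy="strict")

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(0, 10_000))
    def test_matches_oracle_and_is_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        n, L = int(rng.integers(2, 8)), int(rng.integers(3, 15))
        seqs = [
            "".join(rng.choice(list("ACGTN"), size=L, p=[0.235] * 4 + [0.06]))
            for _ in range(n)
        ]
        keep, groups = oracle_collapse(seqs)
        if not keep:
            with pytest.raises(ValueError):
                collapse_haplotypes(aln_of(*seqs))
            return
        table = collapse_haplotypes(aln_of(*seqs))
        assert list(table.retained_sites) == keep
        assert sorted(len(g) for g in groups) == sorted(table.abundances.tolist())
        # collapsing the representatives reproduces the same partition size
        reps = aln_of(*[s for _, s, _ in table.haplotypes])
        assert collapse_haplotypes(reps).s_obs == table.s_obs


class TestDiversity:
    def test_all_identical_is_zero_everywhere(self):
        stats = diversity_stats(aln_of("ACGTAC", "ACGTAC"))
        assert stats.segregating_sites == 0
        assert stats.total_mutations == 0
        assert stats.haplotype_diversity == 0.0
        assert stats.nucleotide_diversity == 0.0

    def test_hd_nei_formula_by_hand(self):
        # X = (2, 1, 1), n = 4: Hd = (4/3)(1 - (4+1+1)/16)
        assert haplotype_diversity([2, 1, 1]) == pytest.approx(4 / 3 * (1 - 6 / 16))

    def test_pi_direct_pairwise_mean(self):
        aln = aln_of("ACGTACGTAC", "ACGTACGTAT")
        assert nucleotide_diversity(aln) == pytest.approx(0.1)

    def test_pi_equals_distance_matrix_mean_on_complete_data(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(6)]
        aln = aln_of(*seqs)
        dm = distance_matrix(aln)
        iu = np.triu_indices(6, k=1)
        assert nucleotide_diversity(aln) == pytest.approx(dm.p[iu].mean())

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(0, 10_000))
    def test_eta_at_least_s_and_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n, L = int(rng.integers(2, 7)), 12
        seqs = ["".join(rng.choice(list("ACGT"), size=L)) for _ in range(n)]
        stats = diversity_stats(aln_of(*seqs))
        assert stats.total_mutations >= stats.segregating_sites
        # eta == S iff every polymorphic column is biallelic
        kmax = max(
            len({s[c] for s in seqs}) for c in range(L)
        )
        if kmax <= 2:
            assert stats.total_mutations == stats.segregating_sites
        perm = rng.permutation(n)
        shuffled = diversity_stats(aln_of(*[seqs[i] for i in perm]))
        assert shuffled.segregating_sites == stats.segregating_sites
        assert shuffled.total_mutations == stats.total_mutations
        assert shuffled.haplotype_diversity == pytest.approx(stats.haplotype_diversity)
        assert shuffled.nucleotide_diversity == pytest.approx(stats.nucleotide_diversity)

    def test_hd_undefined_for_single_specimen(self):
        with pytest.raises(ValueError):
            haplotype_diversity([1])


class TestSiteClassification:
    @pytest.mark.parametrize(
        "before,after,expected",
        [
            ("TTA", "TTG", "synonymous"),  # Leu -> Leu
            ("ATA", "TTA", "replacement"),  # Met -> Leu (invertebrate mito)
            ("GGA", "GGT", "synonymous"),  # Gly -> Gly
            ("AAA", "GAA", "replacement"),  # Lys -> Glu
        ],
    )
    def test_examples(self, before, after, expected):
        assert classify_site_change(before, after) == expected

    def test_identical_codons_rejected(self):
        with pytest.raises(ValueError):
            classify_site_change("GGA", "GGA")

    def test_multi_step_change_rejected(self):
        with pytest.raises(ValueError):
            classify_site_change("AAA", "TTA")


class TestNonSynonymousCollapse:
    def test_only_synonymous_variation_collapses_to_one(self):
        # TTA/TTG both Leu at codon 2
        table = collapse_nonsynonymous_only(aln_of("GGATTA", "GGATTG", "GGATTA"))
        assert table.s_obs == 1

    def test_single_replacement_site_keeps_two_haplotypes(self):
        # ATA (Met) vs TTA (Leu) at codon 1, plus a synonymous site at codon 2
        table = collapse_nonsynonymous_only(aln_of("ATAGGA", "TTAGGT", "ATAGGT"))
        assert table.s_obs == 2
        assert sorted(table.abundances.tolist()) == [1, 2]

    def test_mixed_sites_match_manual_masking(self):
        seqs = ["ATAGGACTA", "TTAGGTCTA", "ATAGGACTG"]
        # replacement at site 0 (ATA/TTA), synonymous at sites 5 and 8
        table = collapse_nonsynonymous_only(aln_of(*seqs))
        masked = ["ATAGGACTA", "TTAGGACTA", "ATAGGACTA"]
        _, oracle_groups = oracle_collapse(masked)
        assert sorted(len(g) for g in oracle_groups) == sorted(
            table.abundances.tolist()
        )


class TestRegionalTables:
    def test_frequency_matrix_counts(self, toy_alignment, toy_metadata):
        table = collapse_haplotypes(toy_alignment)
        freq = region_frequency_matrix(table, toy_metadata)
        assert freq.values.sum() == 4
        assert freq.sum(axis=1).tolist() == table.abundances.tolist()

    def test_fixture_marginals_consistent(self, survey_fixture):
        table = collapse_haplotypes(survey_fixture.alignment)
        freq = region_frequency_matrix(table, survey_fixture.dataset.metadata)
        assert freq.values.sum() == 97
        assert freq.sum(axis=1).tolist() == table.abundances.tolist()
        samples_per_region = {}
        for m in survey_fixture.dataset.metadata:
            samples_per_region[m.bioregion] = samples_per_region.get(m.bioregion, 0) + 1
        for region in freq.columns:
            assert freq[region].sum() == samples_per_region[region]

    def test_member_without_region_excluded_with_warning(self, toy_alignment):
        meta = [
            SpecimenRecord("s1", "T", 0, 0, "A"),
            SpecimenRecord("s2", "T", 0, 0, None),
            SpecimenRecord("s3", "T", 0, 0, "A"),
            SpecimenRecord("s4", "T", 0, 0, "A"),
        ]
        table = collapse_haplotypes(toy_alignment)
        with pytest.warns(UserWarning, match="no bioregion"):
            freq = region_frequency_matrix(table, meta)
        assert freq.values.sum() == 3

    def test_region_summary_single_region_equals_total(self, toy_alignment):
        meta = [SpecimenRecord(f"s{i}", "T", 0, 0, "A") for i in range(1, 5)]
        table = collapse_haplotypes(toy_alignment)
        dm = distance_matrix(toy_alignment)
        summary = region_summary(table, meta, dm).set_index("bioregion")
        assert summary.loc["A", "samples"] == summary.loc["Total", "samples"] == 4
        assert summary.loc["A", "mean_p"] == pytest.approx(summary.loc["Total", "mean_p"])

    def test_region_with_one_sample_has_undefined_mean(self, toy_alignment):
        meta = [
            SpecimenRecord("s1", "T", 0, 0, "A"),
            SpecimenRecord("s2", "T", 0, 0, "A"),
            SpecimenRecord("s3", "T", 0, 0, "A"),
            SpecimenRecord("s4", "T", 0, 0, "B"),
        ]
        table = collapse_haplotypes(toy_alignment)
        dm = distance_matrix(toy_alignment)
        summary = region_summary(table, meta, dm).set_index("bioregion")
        assert np.isnan(summary.loc["B", "mean_p"])
        assert summary.loc["B", "haplotypes_per_sample"] == 1.0


class TestNexusExport:
    def test_traits_block_round_trippable_structure(self, tmp_path, toy_alignment, toy_metadata):
        table = collapse_haplotypes(toy_alignment)
        freq = region_frequency_matrix(table, toy_metadata)
        out = tmp_path / "traits.nex"
        write_popart_nexus(table, freq, out)
        text = out.read_text()
        assert text.startswith("#NEXUS")
        assert "BEGIN TRAITS;" in text
        assert f"NTRAITS={freq.shape[1]}" in text
        for hap, row in freq.iterrows():
            assert f"{hap} " + ",".join(str(int(v)) for v in row) in text
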