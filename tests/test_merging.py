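"""Annotation merging: tandem collapse, pairwise and final merging,
baselines, and whole-proteome invariants."""

import random

import pytest

from padds.labels import EquivalenceOverrides
from padds.merging import (
    DomainAnnotation,
    UnknownProteinError,
    build_final_annotation,
    merge_database_pair,
    merge_proteome,
    merge_tandem_repeats,
    naive_merge,
    sequence_only_merge,
    sequence_overlap_length,
    summarize,
)

import oracles

A = DomainAnnotation


class TestTandemRepeats:
    def test_two_repeats_span_with_linker(self):
        result = merge_tandem_repeats(
            [A("p", "db", "Drf_GBD", 10, 60), A("p", "db", "Drf_GBD", 70, 120)]
        )
        assert len(result) == 1
        assert (result[0].start, result[0].end) == (10, 120)

    def test_single_record_unchanged(self):
        ann = A("p", "db", "X", 5, 50)
        assert merge_tandem_repeats([ann]) == [ann]

    def test_three_repeats_collapse_to_full_span(self):
        result = merge_tandem_repeats(
            [A("p", "db", "X", 1, 10), A("p", "db", "X", 20, 30), A("p", "db", "X", 40, 50)]
        )
        assert [(r.start, r.end) for r in result] == [(1, 50)]

    def test_distinct_labels_pass_through(self):
        result = merge_tandem_repeats(
            [A("p", "db", "X", 1, 10), A("p", "db", "Y", 5, 20)]
        )
        assert len(result) == 2

    def test_mixed_databases_rejected(self):
        with pytest.raises(ValueError):
            merge_tandem_repeats(
                [A("p", "db1", "X", 1, 10), A("p", "db2", "X", 5, 20)]
            )


@pytest.mark.parametrize(
    "d1, d2, expected",
    [(((1, 100), (91, 200)), None, 10), (((1, 100), (92, 200)), None, 9),
     (((1, 50), (60, 100)), None, 0)],
)
def test_sequence_overlap_length(d1, d2, expected):
    assert sequence_overlap_length(*d1) == expected


class TestDatabasePair:
    def test_colocated_equivalent_labels_merge(self):
        merged, exceptions = merge_database_pair(
            "p",
            [A("p", "PFAM", "FH2", 700, 1100)],
            [A("p", "SF", "FH2 domain", 710, 1090)],
        )
        assert len(merged) == 1
        assert merged[0].labels == {"FH2", "FH2 domain"}
        assert (merged[0].start, merged[0].end) == (700, 1100)
        assert exceptions == []

    def test_overlapping_distinct_labels_stay_apart(self):
        merged, exceptions = merge_database_pair(
            "p",
            [A("p", "PFAM", "Drf_FH3", 250, 450)],
            [A("p", "SF", "ARM repeat", 100, 600)],
        )
        assert len(merged) == 2
        assert exceptions == [("ARM repeat", "Drf_FH3")]

    def test_empty_second_database(self):
        merged, _ = merge_database_pair(
            "p", [A("p", "PFAM", "X", 1, 50), A("p", "PFAM", "Y", 100, 150)], []
        )
        assert len(merged) == 2
        assert all(len(m.members) == 1 for m in merged)

    def test_below_threshold_overlap_not_merged(self):
        merged, _ = merge_database_pair(
            "p",
            [A("p", "a", "kinase", 1, 100)],
            [A("p", "b", "pkinase", 96, 200)],  # 5-residue overlap < k=10
        )
        assert len(merged) == 2


class TestFinalAnnotation:
    def test_transitive_equivalence_through_shared_member(self):
        """Three databases' labels of one ABC-transporter region unite even
        though one label pair never matches directly."""
        annots = [
            A("p", "db1", "abc-smc5", 100, 300),
            A("p", "db2", "abc-atpase", 110, 310),
            A("p", "db3", "smc", 95, 295),
        ]
        final, _ = merge_proteome(annots, {"p": 400})
        assert len(final) == 1
        assert final[0].labels == {"abc-smc5", "abc-atpase", "smc"}

    def test_single_database_reduces_to_tandem_merge(self):
        annots = [
            A("p", "db", "X", 1, 100),
            A("p", "db", "X", 150, 250),
            A("p", "db", "Y", 300, 400),
        ]
        final, _ = merge_proteome(annots, {"p": 500})
        assert sorted((d.canonical_label, d.start, d.end) for d in final) == [
            ("X", 1, 250),
            ("Y", 300, 400),
        ]


class TestWorkedExample:
    def test_four_final_domains(self, worked_example_annotations, worked_example_proteome):
        final, report = merge_proteome(
            worked_example_annotations, worked_example_proteome
        )
        groups = sorted(sorted(d.labels) for d in final)
        assert groups == [
            ["ARM repeat"],
            ["Drf_FH3"],
            ["Drf_GBD"],
            ["FH2", "Formin Homology", "Formin homology 2 domain (FH2 domain)"],
        ]

    def test_naive_counts_every_record(self, worked_example_annotations):
        assert len(naive_merge(worked_example_annotations)) == 7

    def test_sequence_only_fuses_across_labels(self, worked_example_annotations):
        clusters = sequence_only_merge(worked_example_annotations)
        assert len(clusters) == 2
        assert any(
            c.labels >= {"ARM repeat", "Drf_FH3", "Drf_GBD"} for c in clusters
        )

    def test_exceptions_report_overlapping_unmerged_pairs(
        self, worked_example_annotations, worked_example_proteome
    ):
        _, report = merge_proteome(worked_example_annotations, worked_example_proteome)
        assert ("YNL271C", "ARM repeat", "Drf_FH3") in report.exceptions
        assert ("YNL271C", "ARM repeat", "Drf_GBD") in report.exceptions


class TestProteomeInvariants:
    def _random_annotations(self, rng, n_proteins=4, n_dbs=3):
        labels = ["kinase", "pkinase", "helicase", "abc", "abc-atpase", "zn-finger"]
        annots = []
        for p in range(n_proteins):
            for d in range(n_dbs):
                for _ in range(rng.randint(0, 3)):
                    start = rng.randint(1, 400)
                    annots.append(
                        A(
                            f"p{p}",
                            f"db{d}",
                            rng.choice(labels),
                            start,
                            start + rng.randint(20, 200),
                        )
                    )
        proteome = {f"p{p}": 700 for p in range(n_proteins)}
        return annots, proteome

    @pytest.mark.parametrize("seed", range(8))
    def test_input_order_invariance(self, seed):
        rng = random.Random(seed)
        annots, proteome = self._random_annotations(rng)
        final_a, _ = merge_proteome(annots, proteome)
        shuffled = annots[:]
        rng.shuffle(shuffled)
        final_b, _ = merge_proteome(shuffled, proteome)
        assert final_a == final_b

    @pytest.mark.parametrize("seed", range(8))
    def test_count_ordering_naive_merged_sequence_only(self, seed):
        rng = random.Random(100 + seed)
        annots, proteome = self._random_annotations(rng)
        merged, _ = merge_proteome(annots, proteome)
        assert len(naive_merge(annots)) >= len(merged) >= len(sequence_only_merge(annots))

    @pytest.mark.parametrize("seed", range(8))
    def test_every_record_in_exactly_one_final_domain(self, seed):
        rng = random.Random(200 + seed)
        annots, proteome = self._random_annotations(rng)
        merged, report = merge_proteome(annots, proteome)
        members = [m for d in merged for m in d.members]
        assert sorted(members, key=A.sort_key) == sorted(set(annots), key=A.sort_key)
        assert len(members) == len(set(members))

    @pytest.mark.parametrize("seed", range(4))
    def test_idempotence(self, seed):
        rng = random.Random(300 + seed)
        annots, proteome = self._random_annotations(rng)
        merged, _ = merge_proteome(annots, proteome)
        as_single_db = [
            A(d.protein_id, "merged", d.canonical_label, d.start, d.end)
            for d in merged
        ]
        remerged, _ = merge_proteome(as_single_db, proteome)
        assert [(d.protein_id, d.canonical_label, d.start, d.end) for d in remerged] == [
            (d.protein_id, d.canonical_label, d.start, d.end) for d in merged
        ]

    @pytest.mark.parametrize("seed", range(4))
    def test_exceptions_overlap_but_are_not_equivalent(self, seed):
        from padds.labels import labels_equivalent

        rng = random.Random(400 + seed)
        annots, proteome = self._random_annotations(rng)
        _, report = merge_proteome(annots, proteome)
        for _, la, lb in report.exceptions:
            assert not labels_equivalent(la, lb)

    def test_unknown_protein_rejected(self):
        with pytest.raises(UnknownProteinError):
            merge_proteome([A("ghost", "db", "X", 1, 10)], {"p": 100})

    def test_interval_past_sequence_end_rejected(self):
        with pytest.raises(ValueError):
            merge_proteome([A("p", "db", "X", 1, 200)], {"p": 100})


class TestBaselines:
    def test_naive_counts_identical_records_separately(self):
        annots = [A("p", f"db{i}", "X", 1, 50) for i in range(3)]
        assert len(naive_merge(annots)) == 3

    def test_naive_empty(self):
        assert naive_merge([]) == []

    def test_sequence_only_transitive_chain(self):
        """A overlaps B, B overlaps C, A and C disjoint: one cluster."""
        annots = [
            A("p", "a", "X", 1, 100),
            A("p", "b", "Y", 91, 200),
            A("p", "c", "Z", 191, 300),
        ]
        clusters = sequence_only_merge(annots)
        assert len(clusters) == 1
        intervals = [(1, 100), (91, 200), (191, 300)]
        assert len(oracles.brute_force_overlap_clusters(intervals, 10)) == 1

    def test_sequence_only_disjoint(self):
        annots = [A("p", "a", "X", 1, 50), A("p", "b", "Y", 100, 150)]
        assert len(sequence_only_merge(annots)) == 2


class TestSummarize:
    def test_empty_set_all_zero(self):
        s = summarize([], {"p": 100})
        assert (
            s.n_proteins_annotated,
            s.residues_covered,
            s.n_domain_instances,
            s.n_unique_domains,
            s.avg_domains_per_protein,
        ) == (0, 0, 0, 0, 0.0)

    def test_half_covered_protein(self):
        merged, _ = merge_proteome([A("p", "db", "X", 1, 50)], {"p": 100})
        s = summarize(merged, {"p": 100})
        assert s.fraction_residues_covered == 0.5
        assert s.avg_domains_per_protein == 1.0
        assert s.fraction_proteins_annotated == 1.0

    def test_overlapping_domains_count_residues_once(self):
        domains, _ = merge_proteome(
            [A("p", "a", "X", 1, 60), A("p", "b", "Y", 41, 100)], {"p": 100}
        )
        s = summarize(domains, {"p": 100})
        assert s.residues_covered == 100
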