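import pytest

from minimito import fixtures as packaged
from minimito.event_inference import (
    LOSS,
    MERGER,
    SPLIT,
    TRANSLOCATION,
    TallyConfigurationError,
    detect_events,
    tally_events,
)
from minimito.karyotype_model import parse_karyotype


@pytest.fixture(scope="module")
def anoplura_mrca():
    return packaged.load_karyotype("anoplura_mrca")


class TestDetectSplits:
    def test_three_stem_splits_to_seal_lice(self, anoplura_mrca, seal_ancestor):
        report = detect_events(anoplura_mrca, seal_ancestor, branch="stem")
        splits = report.of_kind(SPLIT)
        assert len(splits) == 3
        assert sorted(s.ancestral_minichromosomes[0] for s in splits) == [
            "D-Y-cox2-nad6",
            "Q-nad1-T*-G-nad3-W",
            "R-nad4L-P-cox3-A",
        ]

    def test_missing_anchor_never_vetoes_split(self, anoplura_mrca, seal_ancestor):
        # nad6 was never identified, yet cox2 sitting alone still
        # evidences the D-Y-cox2-nad6 split
        report = detect_events(anoplura_mrca, seal_ancestor)
        split = next(
            s
            for s in report.of_kind(SPLIT)
            if s.ancestral_minichromosomes == ("D-Y-cox2-nad6",)
        )
        assert split.descendant_minichromosomes == ("cox2",)

    def test_gorilla_cox3_A_split(self):
        pubis = packaged.load_karyotype("pthirus_pubis")
        gorilla = packaged.load_karyotype("pthirus_gorillae")
        report = detect_events(pubis, gorilla, branch="gorilla")
        splits = report.of_kind(SPLIT)
        assert len(splits) == 1
        (split,) = splits
        assert split.ancestral_minichromosomes == ("cox3-A",)
        assert split.descendant_minichromosomes == ("A", "cox3")
        assert report.of_kind(MERGER) == []

    def test_k_way_split_counts_once(self):
        anc = parse_karyotype("#taxon anc\nR-nad4L-P-cox3-A\n")
        desc = parse_karyotype("#taxon desc\nR-nad4L\nP-cox3\nA\n")
        report = detect_events(anc, desc)
        assert len(report.of_kind(SPLIT)) == 1
        (split,) = report.of_kind(SPLIT)
        assert len(split.descendant_minichromosomes) == 3


class TestDetectMergers:
    def test_fluctus_merger_of_nad4L_and_rrnS(self, seal_ancestor):
        fluctus = packaged.load_karyotype("proechinophthirus_fluctus")
        report = detect_events(seal_ancestor, fluctus, branch="fluctus")
        mergers = report.of_kind(MERGER)
        assert len(mergers) == 1
        (merger,) = mergers
        assert len(merger.ancestral_minichromosomes) == 2
        assert merger.ancestral_minichromosomes == ("R-nad4L", "rrnS")
        assert report.of_kind(SPLIT) == []

    def test_merger_requires_anchors_from_two_sources(self):
        anc = parse_karyotype("#taxon anc\nE-cob\nK-nad4\n")
        desc = parse_karyotype("#taxon desc\nE-cob-K-nad4\n")
        report = detect_events(anc, desc)
        assert len(report.of_kind(MERGER)) == 1


class TestOtherKinds:
    def test_identical_karyotypes_zero_events(self):
        a = packaged.load_karyotype("antarctophthirus_carlinii")
        b = packaged.load_karyotype("antarctophthirus_lobodontis")
        assert len(detect_events(a, b)) == 0

    def test_tRNA_relocation_is_translocation(self):
        anc = parse_karyotype("#taxon anc\nE-cob\nK-nad4\n")
        desc = parse_karyotype("#taxon desc\ncob\nE-K-nad4\n")
        report = detect_events(anc, desc)
        assert [e.kind for e in report.events] == [TRANSLOCATION]
        assert report.events[0].anchor_genes == ("E",)

    def test_declared_missing_gene_is_no_event(self):
        anc = parse_karyotype("#taxon anc\nE-cob\n")
        desc = parse_karyotype("#taxon desc\n#missing E\ncob\n")
        assert len(detect_events(anc, desc)) == 0

    def test_undeclared_absence_is_loss(self):
        anc = parse_karyotype("#taxon anc\nE-cob\n")
        desc = parse_karyotype("#taxon desc\ncob\n")
        report = detect_events(anc, desc)
        assert [e.kind for e in report.events] == [LOSS]

    def test_gained_gene_is_warning_note_not_event(self):
        anc = parse_karyotype("#taxon anc\ncob\n")
        desc = parse_karyotype("#taxon desc\nE-cob\n")
        report = detect_events(anc, desc)
        assert len(report.events) == 0
        assert any("E" in note for note in report.notes)

    def test_paralog_emergence_is_duplication_note(self):
        anc = parse_karyotype("#taxon anc\nQ-nad1-T-W\nH-nad5\n")
        desc = parse_karyotype("#taxon desc\nQ-nad1-T-W1\nH-nad5-W2\n")
        report = detect_events(anc, desc)
        assert any("duplication" in note for note in report.notes)


class TestSymmetry:
    def test_split_merger_duality(self, anoplura_mrca, seal_ancestor):
        forward = detect_events(anoplura_mrca, seal_ancestor)
        backward = detect_events(seal_ancestor, anoplura_mrca)
        fwd_split_anchors = sorted(
            e.anchor_genes for e in forward.of_kind(SPLIT)
            if not set("".join(e.anchor_genes)) & set()  # keep all
        )
        bwd_merge_targets = sorted(
            e.descendant_minichromosomes for e in backward.of_kind(MERGER)
        )
        # every stem split whose anchors survive corresponds to a merger
        # in the reversed comparison onto the same ancestral label
        fwd = {
            e.ancestral_minichromosomes[0]
            for e in forward.of_kind(SPLIT)
            if len(e.descendant_minichromosomes) >= 2
        }
        bwd = {e.descendant_minichromosomes[0] for e in backward.of_kind(MERGER)}
        assert fwd <= bwd | {
            # splits evidenced only via a missing anchor have no
            # reversible counterpart
            e.ancestral_minichromosomes[0]
            for e in forward.of_kind(SPLIT)
            if len(e.descendant_minichromosomes) < 2
        }

    def test_simple_symmetry(self):
        anc = parse_karyotype("#taxon anc\nE-cob-K-nad4\n")
        desc = parse_karyotype("#taxon desc\nE-cob\nK-nad4\n")
        assert len(detect_events(anc, desc).of_kind(SPLIT)) == 1
        assert len(detect_events(desc, anc).of_kind(MERGER)) == 1


@pytest.fixture(scope="module")
def tally():
    return tally_events(
        packaged.load_tree(),
        packaged.event_tally_karyotypes(),
        packaged.load_family_map(),
    )


class TestTally:
    def test_total_mergers_is_four(self, tally):
        assert tally.total(MERGER) == 4

    def test_mergers_span_three_families(self, tally):
        families = {
            f
            for f, counts in tally.per_family.items()
            if counts.get(MERGER, 0) > 0
        }
        assert families == {
            "Haematopinidae",
            "Pedicinidae",
            "Echinophthiriidae",
        }

    def test_haematopinidae_has_two_mergers(self, tally):
        assert tally.per_family["Haematopinidae"][MERGER] == 2

    def test_nad2_in_two_separate_mergers(self, tally):
        mergers = [
            e for e in tally.events_involving("nad2") if e.kind == MERGER
        ]
        assert len(mergers) == 2
        assert len({e.branch for e in mergers}) == 2

    def test_totals_equal_sum_of_branches(self, tally):
        summed = sum(
            (counts for counts in tally.per_branch.values()),
            start=type(tally.totals)(),
        )
        assert summed == tally.totals

    def test_each_event_on_exactly_one_branch(self, tally):
        assert len(tally.events) == sum(tally.totals.values())

    def test_stem_events_assigned_to_stem_branch(self, tally):
        stem = tally.per_branch["anoplura_mrca->sealice_mrca"]
        assert stem[SPLIT] == 3

    def test_single_branch_identical_tip_zero_events(self):
        import dendropy

        tree = dendropy.Tree.get(
            data="(tip)root;",
            schema="newick",
            suppress_internal_node_taxa=False,
        )
        k = packaged.load_karyotype("anoplura_mrca")
        tally = tally_events(tree, {"root": k, "tip": k})
        assert sum(tally.totals.values()) == 0

    def test_strict_mode_raises_for_missing_karyotype(self):
        tree = packaged.load_tree()
        with pytest.raises(TallyConfigurationError):
            tally_events(
                tree,
                packaged.event_tally_karyotypes(),
                strict=True,
            )
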