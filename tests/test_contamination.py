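"""Contaminant panel matching, episode categorization, review rules, ranking."""

import itertools

import pytest

from bckpi.contamination import (
    AdjudicationRecord,
    Category,
    ContaminantPanel,
    apply_adjudications,
    assess_episode,
    auto_review_rule,
    contaminant_species_ranking,
    is_contaminant,
)
from bckpi.episodes import build_episodes
from bckpi.model import BottleStatus, BottleType
from helpers import literal_same_set_pair_rule, make_bottle

PANEL = ContaminantPanel()


@pytest.mark.parametrize("name,expected", [
    ("Staphylococcus epidermidis", True),
    ("staphylococcus  EPIDERMIDIS ", True),          # case/whitespace-insensitive
    ("Staphylococcus lugdunensis", False),           # excluded CoNS
    ("Staphylococcus aureus", False),                # coagulase-positive
    ("Corynebacterium striatum", False),
    ("Corynebacterium jeikeium", False),
    ("Corynebacterium amycolatum", True),
    ("Micrococcus luteus", True),
    ("Bacillus sp.", True),                          # genus-level identification
    ("Lactobacillus rhamnosus", True),
    ("Aerococcus viridans", True),
    ("Cutibacterium acnes", True),
    ("Cutibacterium granulosum", False),             # species-level rule only
    ("coagulase-negative staphylococci", True),
    ("Escherichia coli", False),
    ("Candida albicans", False),
])
def test_panel_membership(name, expected):
    assert is_contaminant(name, PANEL) is expected


def _pv_episode(*spec, n_sets=2):
    """Episode from (sample_idx, organisms) bottle specs, padded to n_sets."""
    bottles = []
    for i, (set_idx, organisms) in enumerate(spec):
        bottles.append(make_bottle(
            f"B{i}", sample_id=f"S{set_idx}", hours=0.01 * i,
            btype=BottleType.AEROBIC if i % 2 == 0 else BottleType.ANAEROBIC,
            status=BottleStatus.POSITIVE if organisms else BottleStatus.NEGATIVE,
            organisms=organisms))
    used = {s for s, _ in spec}
    for j in range(n_sets):
        if j not in used:
            bottles.append(make_bottle(f"BX{j}", sample_id=f"S{j}",
                                       hours=0.5 + 0.01 * j))
    ep, = build_episodes(bottles)
    return ep


class TestAssessEpisode:
    def test_panel_organism_in_one_bottle_is_restrictive(self):
        ep = _pv_episode((0, ("Staphylococcus epidermidis",)), (0, ()), (1, ()), (1, ()))
        assert assess_episode(ep, PANEL).category is Category.RESTRICTIVE_CONTAMINATION

    def test_panel_organism_in_three_bottles_is_review_candidate(self):
        ep = _pv_episode((0, ("Staphylococcus hominis",)),
                         (0, ("Staphylococcus hominis",)),
                         (1, ("Staphylococcus hominis",)), (1, ()))
        a = assess_episode(ep, PANEL)
        assert a.category is Category.REVIEW_CANDIDATE
        assert a.panel_hits["Staphylococcus hominis"] == ("B0", "B1", "B2")

    def test_pathogen_only_episode_has_no_panel_organism(self):
        ep = _pv_episode((0, ("Escherichia coli",)), (1, ("Escherichia coli",)))
        assert assess_episode(ep, PANEL).category is Category.NO_PANEL_ORGANISM

    def test_solitary_and_cvc_episodes_are_not_eligible(self):
        solitary, = build_episodes([make_bottle("B1",
                                   status=BottleStatus.POSITIVE,
                                   organisms=("Staphylococcus epidermidis",))])
        assert assess_episode(solitary, PANEL).category is Category.NOT_ELIGIBLE
        from bckpi.model import SpecimenOrigin
        cvc = _pv_episode((0, ("Staphylococcus epidermidis",)), (1, ()))
        cvc.episode_type = "CVC"
        assert assess_episode(cvc, PANEL).category is Category.NOT_ELIGIBLE

    def test_mixed_contaminant_plus_pathogen_still_restrictive(self):
        ep = _pv_episode((0, ("Staphylococcus epidermidis",)),
                         (1, ("Escherichia coli",)))
        a = assess_episode(ep, PANEL)
        assert a.category is Category.RESTRICTIVE_CONTAMINATION
        assert "non-panel" in a.rationale

    def test_two_distinct_singleton_contaminants_restrictive(self):
        ep = _pv_episode((0, ("Staphylococcus epidermidis",)),
                         (1, ("Micrococcus luteus",)))
        assert assess_episode(ep, PANEL).category is Category.RESTRICTIVE_CONTAMINATION

    def test_assessment_invariant_to_bottle_order(self):
        ep = _pv_episode((0, ("Staphylococcus hominis",)),
                         (1, ("Staphylococcus hominis",)), (1, ()))
        a1 = assess_episode(ep, PANEL)
        ep.bottles = tuple(reversed(ep.bottles))
        a2 = assess_episode(ep, PANEL)
        assert a1.category is a2.category and a1.panel_hits == a2.panel_hits


class TestAutoReviewRule:
    def test_same_set_pair_confirms(self):
        ep = _pv_episode((0, ("Staphylococcus epidermidis",)),
                         (0, ("Staphylococcus epidermidis",)),
                         (1, ()), (1, ()), (2, ()), (2, ()), n_sets=3)
        a = assess_episode(ep, PANEL)
        assert auto_review_rule(ep, a) is True
        assert a.category is Category.CONFIRMED_AFTER_REVIEW

    def test_cross_set_pair_does_not_confirm(self):
        ep = _pv_episode((0, ("Staphylococcus epidermidis",)),
                         (1, ("Staphylococcus epidermidis",)), (1, ()))
        a = assess_episode(ep, PANEL)
        assert auto_review_rule(ep, a) is False
        assert a.category is Category.REVIEW_CANDIDATE

    def test_three_occurrences_including_full_set_do_not_confirm(self):
        ep = _pv_episode((0, ("Staphylococcus epidermidis",)),
                         (0, ("Staphylococcus epidermidis",)),
                         (1, ("Staphylococcus epidermidis",)), (1, ()))
        a = assess_episode(ep, PANEL)
        assert auto_review_rule(ep, a) is False

    def test_missing_set_structure_is_not_evaluable(self):
        ep = _pv_episode((0, ("Staphylococcus hominis",)),
                         (1, ("Staphylococcus hominis",)))
        a = assess_episode(ep, PANEL)
        ep.sets = None
        assert auto_review_rule(ep, a) is None

    def test_agrees_with_exhaustive_enumeration_small(self):
        """Spot-check vs. the literal criterion on all 2-organism patterns
        over a 2x2-set episode (the full sweep lives in the acceptance suite)."""
        organisms = ("Staphylococcus epidermidis", "Micrococcus luteus")
        set_sizes = (2, 2)
        set_of_bottle = {"B0": "S0", "B1": "S0", "B2": "S1", "B3": "S1"}
        for pattern in itertools.product(range(4), repeat=4):
            spec = []
            for i, code in enumerate(pattern):
                orgs = tuple(o for k, o in enumerate(organisms) if code >> k & 1)
                spec.append((i // 2, orgs))
            ep = _pv_episode(*spec)
            a = assess_episode(ep, PANEL)
            if a.category is not Category.REVIEW_CANDIDATE:
                continue
            hits = {org: set(bottles) for org, bottles in a.panel_hits.items()}
            expected = literal_same_set_pair_rule(hits, set_of_bottle)
            assert auto_review_rule(ep, a) is expected, pattern


class TestAdjudications:
    def _candidate(self):
        ep = _pv_episode((0, ("Staphylococcus hominis",)),
                         (1, ("Staphylococcus hominis",)), (1, ()))
        return ep, assess_episode(ep, PANEL)

    def test_contaminated_decision_confirms(self):
        ep, a = self._candidate()
        rejected = apply_adjudications([a], [AdjudicationRecord(ep.episode_id,
                                                                "CONTAMINATED", "rev")])
        assert not rejected and a.category is Category.CONFIRMED_AFTER_REVIEW

    def test_not_contaminated_decision_clears(self):
        ep, a = self._candidate()
        apply_adjudications([a], [AdjudicationRecord(ep.episode_id,
                                                     "NOT_CONTAMINATED")])
        assert a.category is Category.REVIEWED_NOT_CONTAMINATED

    def test_adjudication_of_non_candidate_rejected(self):
        ep = _pv_episode((0, ("Escherichia coli",)), (1, ()))
        a = assess_episode(ep, PANEL)
        rejected = apply_adjudications([a], [AdjudicationRecord(ep.episode_id,
                                                                "CONTAMINATED")])
        assert len(rejected) == 1 and a.category is Category.NO_PANEL_ORGANISM

    def test_human_overrides_auto_confirmation(self):
        ep = _pv_episode((0, ("Staphylococcus epidermidis",)),
                         (0, ("Staphylococcus epidermidis",)), (1, ()), (1, ()))
        a = assess_episode(ep, PANEL)
        auto_review_rule(ep, a)
        assert a.category is Category.CONFIRMED_AFTER_REVIEW
        apply_adjudications([a], [AdjudicationRecord(ep.episode_id,
                                                     "NOT_CONTAMINATED", "rev")])
        assert a.category is Category.REVIEWED_NOT_CONTAMINATED


class TestRanking:
    def _restrictive(self, organism, tag):
        ep = _pv_episode((0, (organism,)), (1, ()))
        ep.episode_id = tag
        return assess_episode(ep, PANEL)

    def test_simple_proportions(self):
        assessments = [self._restrictive("Staphylococcus epidermidis", f"e{i}")
                       for i in range(9)]
        assessments.append(self._restrictive("Micrococcus luteus", "m0"))
        assert contaminant_species_ranking(assessments) == [
            ("CoNS", 90.0), ("Micrococcus spp.", 10.0)]

    def test_single_contamination_is_100_percent(self):
        ranking = contaminant_species_ranking(
            [self._restrictive("Bacillus cereus", "b0")])
        assert ranking == [("Others", 100.0)]

    def test_empty_input_gives_empty_ranking(self):
        assert contaminant_species_ranking([]) == []

    def test_largest_remainder_shares_sum_to_100(self):
        counts = {"Staphylococcus epidermidis": 5, "Micrococcus luteus": 5,
                  "Bacillus cereus": 5, "Corynebacterium amycolatum": 4,
                  "Cutibacterium acnes": 4}
        assessments, k = [], 0
        for org, n in counts.items():
            for _ in range(n):
                assessments.append(self._restrictive(org, f"e{k}"))
                k += 1
        ranking = contaminant_species_ranking(assessments)
        assert sum(share for _, share in ranking) == 100.0
        assert all(share == int(share) for _, share in ranking)
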