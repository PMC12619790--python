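"""Contaminant-panel matching and contamination categorization.

Skin-flora organisms recovered from blood cultures frequently represent
collection contamination rather than bloodstream infection.  The engine
works from a configurable panel of contaminant organisms:

* coagulase-negative staphylococci (CoNS), excluding *S. lugdunensis*
* *Micrococcus* spp.
* *Cutibacterium acnes* (species-level rule)
* *Corynebacterium* spp., excluding *C. jeikeium* and *C. striatum*
* *Bacillus* spp., *Lactobacillus* spp., *Aerococcus* spp.

Only non-solitary peripheral-vein episodes are eligible for contamination
calls (a solitary episode gives no occurrence pattern to reason about, and
device-drawn episodes follow different rules); other episodes are marked
NOT_ELIGIBLE so denominators stay auditable.  Within an eligible episode:

* restrictive contamination — every panel organism present occurs in
  exactly one bottle (a criterion valid under both single- and
  multi-sampling strategies);
* review candidate — some panel organism occurs in more than one bottle;
  an operator (or the automatic review rule, which confirms the candidate
  when the organism occupies exactly the two bottles of one sampling set)
  then classifies it as contaminated or not.
"""

from __future__ import annotations

import csv
import dataclasses
import enum
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .episodes import Episode
from .model import BottleStatus

logger = logging.getLogger(__name__)


def normalize_name(name: str) -> str:
    """Whitespace-normalized, case-folded organism name."""
    return " ".join(name.split()).lower()


#: Default CoNS membership (the group label itself is accepted verbatim, as
#: some identification systems report it without a species call).
DEFAULT_CONS_SPECIES = (
    "Staphylococcus epidermidis",
    "Staphylococcus hominis",
    "Staphylococcus haemolyticus",
    "Staphylococcus capitis",
    "Staphylococcus caprae",
    "Staphylococcus warneri",
    "Staphylococcus saprophyticus",
    "Staphylococcus cohnii",
    "Staphylococcus simulans",
    "Staphylococcus pasteuri",
    "Staphylococcus pettenkofferi",
    "coagulase-negative staphylococci",
)

#: Ranking group labels.
GROUP_CONS = "CoNS"
GROUP_CORYNEBACTERIUM = "Corynebacterium spp."
GROUP_MICROCOCCUS = "Micrococcus spp."
GROUP_CUTIBACTERIUM_ACNES = "Cutibacterium acnes"
GROUP_OTHERS = "Others"
RANKING_GROUPS = (GROUP_CONS, GROUP_CORYNEBACTERIUM, GROUP_MICROCOCCUS,
                  GROUP_CUTIBACTERIUM_ACNES, GROUP_OTHERS)


@dataclasses.dataclass
class ContaminantPanel:
    """Genus/species inclusion-exclusion rules for contaminant organisms."""

    genus_rules: tuple[tuple[str, tuple[str, ...]], ...] = (
        ("Micrococcus", ()),
        ("Corynebacterium", ("Corynebacterium jeikeium", "Corynebacterium striatum")),
        ("Bacillus", ()),
        ("Lactobacillus", ()),
        ("Aerococcus", ()),
    )
    species_rules: tuple[str, ...] = ("Cutibacterium acnes",)
    cons_species: tuple[str, ...] = DEFAULT_CONS_SPECIES
    cons_excluded: tuple[str, ...] = ("Staphylococcus lugdunensis",)

    def __post_init__(self) -> None:
        self._cons = {normalize_name(s) for s in self.cons_species}
        self._cons_excl = {normalize_name(s) for s in self.cons_excluded}
        self._species = {normalize_name(s) for s in self.species_rules}
        self._genus = {
            normalize_name(genus): {normalize_name(x) for x in excluded}
            for genus, excluded in self.genus_rules
        }
        self._unknown_logged: set[str] = set()

    def is_contaminant(self, species_name: str) -> bool:
        name = normalize_name(species_name)
        if not name:
            return False
        if name in self._cons_excl:
            return False
        if name in self._cons or name in self._species:
            return True
        genus = name.split()[0]
        if genus in self._genus:
            # genus-level identifications ("Bacillus sp.") match the genus rule
            return name not in self._genus[genus]
        if name not in self._unknown_logged:
            self._unknown_logged.add(name)
            logger.debug("panel: %r not a panel organism", species_name)
        return False

    def group_of(self, species_name: str) -> Optional[str]:
        """Ranking group of a panel organism; None for non-panel names."""
        if not self.is_contaminant(species_name):
            return None
        name = normalize_name(species_name)
        if name in self._cons:
            return GROUP_CONS
        if name in self._species:
            return GROUP_CUTIBACTERIUM_ACNES
        genus = name.split()[0]
        if genus == "corynebacterium":
            return GROUP_CORYNEBACTERIUM
        if genus == "micrococcus":
            return GROUP_MICROCOCCUS
        return GROUP_OTHERS

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ContaminantPanel":
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = {}
        if "genus_rules" in data:
            kwargs["genus_rules"] = tuple(
                (genus, tuple(excl or ())) for genus, excl in data["genus_rules"].items())
        for key in ("species_rules", "cons_species", "cons_excluded"):
            if key in data:
                kwargs[key] = tuple(data[key])
        return cls(**kwargs)


def is_contaminant(species_name: str, panel: ContaminantPanel) -> bool:
    return panel.is_contaminant(species_name)


class Category(str, enum.Enum):
    NOT_ELIGIBLE = "NOT_ELIGIBLE"
    NO_PANEL_ORGANISM = "NO_PANEL_ORGANISM"
    RESTRICTIVE_CONTAMINATION = "RESTRICTIVE_CONTAMINATION"
    REVIEW_CANDIDATE = "REVIEW_CANDIDATE"
    CONFIRMED_AFTER_REVIEW = "CONFIRMED_AFTER_REVIEW"
    REVIEWED_NOT_CONTAMINATED = "REVIEWED_NOT_CONTAMINATED"


#: Categories counting as contamination for reporting.
CONTAMINATED_CATEGORIES = (Category.RESTRICTIVE_CONTAMINATION,
                           Category.CONFIRMED_AFTER_REVIEW)


@dataclasses.dataclass
class ContaminationAssessment:
    episode_id: str
    patient_id: str
    anchor_time: object
    panel_hits: dict  # display organism name -> sorted tuple of bottle_ids
    category: Category
    rationale: str = ""
    auto_review: Optional[bool] = None   # auto rule outcome (None: not run / not evaluable)
    adjudicated_by: Optional[str] = None


@dataclasses.dataclass
class AdjudicationRecord:
    episode_id: str
    decision: str          # "CONTAMINATED" | "NOT_CONTAMINATED"
    reviewer: str = ""
    note: str = ""


def _panel_hits(episode: Episode, panel: ContaminantPanel) -> dict:
    """Map panel organism (display name) -> sorted bottle_ids, over positives."""
    hits: dict[str, set] = {}
    display: dict[str, str] = {}
    for bottle in episode.bottles:
        if bottle.status is not BottleStatus.POSITIVE:
            continue
        for organism in set(bottle.organisms):
            if not panel.is_contaminant(organism):
                continue
            key = normalize_name(organism)
            display.setdefault(key, organism)
            hits.setdefault(key, set()).add(bottle.bottle_id)
    return {display[k]: tuple(sorted(v)) for k, v in hits.items()}


def assess_episode(episode: Episode, panel: ContaminantPanel) -> ContaminationAssessment:
    """Categorize one episode against the contaminant panel.

    Pure in the episode's positive-bottle organism sets: the category does
    not depend on bottle order.
    """
    hits = _panel_hits(episode, panel)
    base = dict(episode_id=episode.episode_id, patient_id=episode.patient_id,
                anchor_time=episode.anchor_time, panel_hits=hits)
    if episode.episode_type != "PV" or episode.is_solitary:
        kind = "solitary" if episode.is_solitary else "CVC"
        return ContaminationAssessment(
            category=Category.NOT_ELIGIBLE,
            rationale=f"{kind} episode: not eligible for contamination criteria",
            **base)
    if not hits:
        return ContaminationAssessment(
            category=Category.NO_PANEL_ORGANISM,
            rationale="no panel organism among positive bottles", **base)
    multi = sorted(org for org, bottles in hits.items() if len(bottles) > 1)
    if multi:
        return ContaminationAssessment(
            category=Category.REVIEW_CANDIDATE,
            rationale=f"panel organism(s) in >1 bottle: {', '.join(multi)}", **base)
    non_panel_positive = any(
        b.status is BottleStatus.POSITIVE
        and any(not panel.is_contaminant(o) for o in b.organisms)
        for b in episode.bottles)
    note = "; episode also grew non-panel organism(s)" if non_panel_positive else ""
    return ContaminationAssessment(
        category=Category.RESTRICTIVE_CONTAMINATION,
        rationale="each panel organism found in exactly one bottle" + note, **base)


def auto_review_rule(episode: Episode,
                     assessment: ContaminationAssessment) -> Optional[bool]:
    """Automatic confirmation rule for review candidates.

    Returns True when some panel organism is positive in exactly two bottles
    of the episode and both belong to the same sampling set (multi-sampling
    data only); False when no organism matches; None when the episode
    carries no usable set structure, making the rule not evaluable.
    A True outcome promotes the assessment to CONFIRMED_AFTER_REVIEW.
    """
    if assessment.category is not Category.REVIEW_CANDIDATE:
        raise ValueError("auto_review_rule applies to REVIEW_CANDIDATE assessments only")
    if episode.sets is None:
        assessment.auto_review = None
        return None
    set_of_bottle = {b: s.sample_id for s in episode.sets for b in s.bottle_ids}
    confirmed = []
    for organism, bottles in assessment.panel_hits.items():
        if len(bottles) != 2:
            continue
        if set_of_bottle.get(bottles[0]) == set_of_bottle.get(bottles[1]):
            confirmed.append(organism)
    result = bool(confirmed)
    assessment.auto_review = result
    if result:
        assessment.category = Category.CONFIRMED_AFTER_REVIEW
        assessment.rationale = (
            "auto review: "
            f"{', '.join(sorted(confirmed))} in both bottles of one set")
    return result


def run_auto_review(episodes: Sequence[Episode],
                    assessments: Sequence[ContaminationAssessment]) -> int:
    """Apply the auto rule to every review candidate; return confirmations."""
    by_id = {ep.episode_id: ep for ep in episodes}
    n = 0
    for a in assessments:
        if a.category is Category.REVIEW_CANDIDATE:
            if auto_review_rule(by_id[a.episode_id], a):
                n += 1
    return n


def apply_adjudications(
    assessments: Sequence[ContaminationAssessment],
    adjudications: Iterable[AdjudicationRecord],
) -> list[AdjudicationRecord]:
    """Apply operator decisions to review candidates, in place.

    A human decision overrides the automatic rule (conflicts are logged).
    Adjudications of episodes that are not review candidates (by id or by
    category) are rejected and returned.
    """
    by_id = {a.episode_id: a for a in assessments}
    rejected: list[AdjudicationRecord] = []
    for adj in adjudications:
        a = by_id.get(adj.episode_id)
        reviewable = a is not None and a.category in (
            Category.REVIEW_CANDIDATE,
            Category.CONFIRMED_AFTER_REVIEW,
            Category.REVIEWED_NOT_CONTAMINATED,
        )
        if not reviewable:
            logger.warning("adjudication rejected: %r is not a review candidate",
                           adj.episode_id)
            rejected.append(adj)
            continue
        decision = adj.decision.strip().upper()
        if decision == "CONTAMINATED":
            new_cat = Category.CONFIRMED_AFTER_REVIEW
        elif decision == "NOT_CONTAMINATED":
            new_cat = Category.REVIEWED_NOT_CONTAMINATED
        else:
            logger.warning("adjudication rejected: unknown decision %r", adj.decision)
            rejected.append(adj)
            continue
        if a.auto_review is not None and (new_cat is Category.CONFIRMED_AFTER_REVIEW) != a.auto_review:
            logger.info("adjudication for %r overrides auto rule (%s -> %s)",
                        adj.episode_id, a.auto_review, decision)
        a.category = new_cat
        a.adjudicated_by = adj.reviewer or "operator"
        a.rationale = f"manual review ({a.adjudicated_by}): {decision.lower()}"
        if adj.note:
            a.rationale += f" — {adj.note}"
    return rejected


def contaminant_species_ranking(
    assessments: Sequence[ContaminationAssessment],
    panel: Optional[ContaminantPanel] = None,
    decimals: int = 0,
) -> list[tuple[str, float]]:
    """Share of each panel group among confirmed contaminations.

    Counts one occurrence per (episode, panel group) over restrictive and
    after-review contaminations; shares use largest-remainder rounding so
    they sum to exactly 100 at the requested precision.  Empty input gives
    an empty ranking.
    """
    panel = panel or ContaminantPanel()
    counts: dict[str, int] = {}
    for a in assessments:
        if a.category not in CONTAMINATED_CATEGORIES:
            continue
        groups = {panel.group_of(org) for org in a.panel_hits}
        for g in groups - {None}:
            counts[g] = counts.get(g, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return []
    scale = 10 ** decimals
    raw = {g: n / total * 100 * scale for g, n in counts.items()}
    floors = {g: int(raw[g]) for g in raw}
    leftover = round(100 * scale - sum(floors.values()))
    order = sorted(raw, key=lambda g: (-(raw[g] - floors[g]), -counts[g], g))
    shares = dict(floors)
    for g in order[:leftover]:
        shares[g] += 1
    ranked = sorted(shares, key=lambda g: (-shares[g], -counts[g], g))
    return [(g, shares[g] / scale) for g in ranked]


def write_review_queue(assessments: Sequence[ContaminationAssessment],
                       path: Union[str, Path]) -> int:
    """Export review candidates (one row per episode x multi-bottle organism)."""
    n = 0
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["episode_id", "patient_id", "anchor_time", "organism",
                         "bottle_ids", "auto_rule_result"])
        for a in assessments:
            if a.category is not Category.REVIEW_CANDIDATE:
                continue
            for organism, bottles in sorted(a.panel_hits.items()):
                if len(bottles) <= 1:
                    continue
                writer.writerow([a.episode_id, a.patient_id,
                                 a.anchor_time.isoformat(), organism,
                                 ";".join(bottles),
                                 "" if a.auto_review is None else str(a.auto_review)])
                n += 1
    return n


def read_adjudications(path: Union[str, Path]) -> tuple[list[AdjudicationRecord], list[int]]:
    """Read operator decisions; returns (valid records, rejected row numbers)."""
    records: list[AdjudicationRecord] = []
    bad_rows: list[int] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for i, row in enumerate(reader, start=1):
            episode_id = (row.get("episode_id") or "").strip()
            decision = (row.get("decision") or "").strip().upper()
            if not episode_id or decision not in ("CONTAMINATED", "NOT_CONTAMINATED"):
                bad_rows.append(i)
                continue
            records.append(AdjudicationRecord(
                episode_id=episode_id, decision=decision,
                reviewer=(row.get("reviewer") or "").strip(),
                note=(row.get("note") or "").strip()))
    return records, bad_rows
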