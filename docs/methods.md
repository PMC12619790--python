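# Methods

## Episode model

The atomic datum is one blood-culture bottle with patient, location,
sampling, instrument-status, organism and fill-volume fields.  Grouping is
two-level:

* **Set** — bottles sharing a sample identification code, i.e. one
  venipuncture or one catheter draw.  In `STRICT` mode a code whose bottles
  cannot plausibly come from one procedure (two bottles of the same
  aerobic/anaerobic type, or mixed specimen origins) is split into
  singleton sets with a warning; `LENIENT` keeps the exported grouping.
  A code spanning two patients is a fatal consistency error.
* **Episode** — within each `(patient, area)` group (configurable to
  `(patient, ward)` or patient-only), bottles are sorted by collection time
  with ties broken by bottle id; the earliest unassigned bottle anchors an
  episode at hour 0 and claims every bottle in the **closed** interval
  `[t0, t0 + 24 h]`; the next unassigned bottle anchors the next episode.
  Windows are anchored, not sliding, and never chain: a bottle at hour 25
  starts a fresh episode.  "Within 24 h" is read inclusively; a bottle at
  exactly +24 h is logged as a boundary case.  The partition is invariant
  to input row order, and for small cohorts it is property-tested against
  an independently coded quadratic re-derivation of the rule.

Classification: an episode is *CVC* iff it contains ≥1 device-drawn bottle
(peripheral-vein bottles of the same episode are absorbed into it),
*solitary* iff it has exactly one set — this covers both the single-set and
the single-bottle case — and *positive* iff any bottle flagged positive.
Bottles from other intravascular devices (arterial line, port) count as
CVC-like by default; a policy switch treats them as PV or ignores them.
The episode's ward is taken from the index (anchor) bottle, which is the
only deterministic choice when a patient moves mid-episode.

## Contamination rules

Panel matching normalizes names (case, whitespace) and supports
genus-level rules with species exclusions, an explicit CoNS species list
(the bare label "coagulase-negative staphylococci" is accepted, since some
identification systems report no species), and species-level rules
(*Cutibacterium acnes* only — other *Cutibacterium* species are not
contaminants by default).  Unknown names are never contaminants.

Only **non-solitary PV** episodes are eligible for contamination calls;
CVC and solitary episodes are marked `NOT_ELIGIBLE` rather than folded
into "no panel organism" so that every denominator remains auditable.
Within an eligible episode, occurrence patterns are computed over positive
bottles only:

* every panel organism in exactly one bottle → `RESTRICTIVE_CONTAMINATION`
  (valid under both single- and multi-sampling strategies).  Two different
  panel organisms, each in one bottle, still qualify (the criterion is
  applied per organism); a co-occurring true pathogen does not disqualify
  the call but is flagged in the rationale for reviewer attention.
* any panel organism in >1 bottle → `REVIEW_CANDIDATE`.  The automatic
  review rule confirms a candidate when some panel organism occupies
  exactly two bottles of the episode and both belong to the same set; it
  returns a not-evaluable marker when the set structure is absent
  (single-sampling data).  The rule is property-tested against exhaustive
  enumeration of all ≤6-bottle / ≤2-organism occurrence patterns.
  Operator adjudications override the automatic outcome (logged).

The confirmed-contaminant ranking groups episodes by panel group and
rounds shares by largest remainder so they sum to exactly 100 — note that
independently rounded per-group percentages (as quality reports often
print them) need not.

## KPI computation

Every cell carries its raw numerator and denominator; rates are ×100.  A
zero denominator leaves the value undefined and not displayable.  Strata
are disjoint and cover all episodes at every level, so numerators and
denominators are additive up to the overall cell (tested).  KPI 2's
denominator is **all** episodes, PV and CVC alike — the only reading under
which the reference totals (12,149 solitary / 55,819 episodes = 21.8%) are
arithmetically consistent.  KPI 4's denominator is non-solitary PV
episodes; the after-review numerator is a superset of the restrictive one
by construction.  Bottles without a volume measurement are excluded from
KPI 1's numerator and denominator and surfaced as a first-class
missingness count; an episode with no measured bottle is likewise excluded
from the episode-level mean.  Display rounding is half-even at 1 decimal
for rates and 2 decimals for volumes and bottles/episode; machine outputs
always retain the raw counts.

Ward-level representativeness thresholds are strict as printed
(">500 episodes" for KPIs 1–2, ">75 CVC episodes" for KPI 3) and
configurable.  Heatmap criticality is scaled linearly between the per-KPI
minimum and maximum across displayed wards (low fill volume = worse;
high rates = worse); no absolute red thresholds are defined upstream, so
the absolute benchmarks (≥8.0 mL/bottle, ≤10% solitary) appear only as
reference annotations.

## Synthetic cohorts

The generator emulates a continuous-monitoring export: per patient a
zero-truncated Poisson number of episodes (every included patient has ≥1
episode by definition); per episode a set count drawn from a
type-conditional distribution over {1..5}; aerobic/anaerobic pairing per
set; truncated-normal fill volumes (default N(6.45, 1.5²) on [0, 12] mL);
true-pathogen positivity from a small fixed species list (the pathogen
list is an invention of the generator — only the contaminant panel is
externally specified); and contaminant injection into non-solitary PV
episodes, either into a single bottle (restrictive pattern) or into both
bottles of one set (the pattern the automatic review rule must confirm).
Episode anchors within a patient are ≥25 h apart **by construction**, so
the pipeline's 24-h grouping recovers the generated episodes exactly and
every downstream rate can be validated against the ground-truth sidecar;
window-boundary behavior (a bottle at exactly +24 h) is exercised by
dedicated fixtures instead.

The default configuration *is* the documented multicenter scenario:
2.1 episodes/patient, 21.4% CVC episodes, 14.9% unpaired CVC, 6.45 mL mean
fill, 21.8% solitary overall, contamination 4.2%/4.7% (restrictive/after
review), CoNS-dominated contaminant mix.  Two calibration details are
forced by feasibility rather than free choices:

* a solitary CVC episode is necessarily unpaired, so one shared set-count
  distribution cannot satisfy solitary 21.8% and unpaired 14.9% at once;
  set counts are therefore type-conditional (P(1 set | CVC) = 0.117, the
  value implied by the reference totals) and the unpaired flag of
  multi-set CVC episodes is rescaled to hit the marginal.  Configurations
  violating `p_cvc_unpaired ≥ P(1 set | CVC)` are rejected as infeasible.
* the published contaminant shares (91/4/4/2/1) sum to 102 after rounding;
  the preset keeps CoNS at 0.91 and rescales the minor groups to 0.09.

True-pathogen positivity defaults to 0.185 so that total positivity
including injected contaminations lands near the documented 20.6% mean.

What the generator does **not** model: seasonality, inter-center
correlation, patient transfers splitting a procedure across areas,
area-dependent CVC propensity (the reference data show ICU-heavy CVC use;
the generator samples type and area independently), resistance phenotypes,
and volume missingness (volumes are always present unless injected by a
test).  Passing recovery tests therefore demonstrates correctness of the
grouping/classification/rate machinery under the stated marginals, not
fidelity to any real hospital's joint distribution.

## Problem sizes and tolerances

Recovery tests compare pipeline estimates to configured parameters within
3 binomial (rates) or 3 CLT (volume) standard errors at the realized
denominator.  The full-scale check and the acceptance script use the
complete preset size (26,559 patients, ≈55,800 episodes, ≈235,000
bottles), which runs in well under a minute; unit and property suites use
cohorts of ≤1,000 patients.  Oracle-equivalence sweeps cover all anchored
partitions of ≤50-bottle cohorts and all ≤6-bottle/≤2-organism
contamination patterns exhaustively.

## Known limitations

* Ward labels are assumed unique across centers for `SERVICE` strata
  (`CENTER_X_AREA` is available for disambiguation).
* Differential time to positivity, instrument-side volume measurement and
  species identification are out of scope; volumes and identifications
  arrive as input fields.
* The reference report prints two slightly different counts for the same
  after-review denominator (32,596 vs. 32,592 non-solitary PV episodes)
  and a handful of per-center rates that differ from their printed
  numerator/denominator at 1-decimal rounding (e.g. 2,142/3,401 = 63.0 vs.
  a printed 62.9).  The engine always reports the value computed from its
  own counts and does not reproduce inconsistent roundings.
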