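"""Case-level grading of signal cases: documentation completeness
(multiplicative vigiGrade-style score), WHO-UMC causality classification,
and time-to-onset summaries."""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .dates import days_between
from .reports import ICSR, ChallengeResult, DrugRecord, ReactionRecord
from .terms import EventDefinition, TermDictionary

DAYS_PER_YEAR = 365.25

#: Default penalty per missing documentation dimension. The score is the
#: product of (1 - penalty) over the dimensions that are missing; 1 means
#: fully documented, and a score > 0.8 counts as well documented.
DEFAULT_PENALTIES: Mapping[str, float] = {
    "time_to_onset": 0.5,
    "indication": 0.3,
    "outcome": 0.3,
    "sex": 0.1,
    "age": 0.1,
    "dose": 0.1,
    "country": 0.1,
    "reporter": 0.1,
    "report_type": 0.1,
    "comment": 0.1,
}

WELL_DOCUMENTED_THRESHOLD = 0.8


@dataclass(frozen=True)
class CompletenessScore:
    score: float
    penalties_applied: tuple[tuple[str, float], ...]
    well_documented: bool


def _onset_computable(icsr: ICSR) -> bool:
    # needs a day-precise suspected-drug start date and a day-precise
    # reaction onset date on the same report
    starts = [d.start_date for d in icsr.suspected_drugs()
              if d.start_date is not None and d.start_date.precise]
    onsets = [r.onset_date for r in icsr.reactions
              if r.onset_date is not None and r.onset_date.precise]
    return bool(starts) and bool(onsets)


def vigigrade(
    icsr: ICSR, penalties: Mapping[str, float] = DEFAULT_PENALTIES
) -> CompletenessScore:
    """Multiplicative completeness score over ten documentation dimensions.

    Each missing dimension multiplies the score by (1 - penalty); the
    heaviest default penalty (0.5) is for a non-computable time to onset,
    0.3 each for missing indication or outcome, 0.1 for the rest.
    """
    missing: list[str] = []
    if not _onset_computable(icsr):
        missing.append("time_to_onset")
    if not any(d.indication for d in icsr.suspected_drugs()):
        missing.append("indication")
    if icsr.outcome is None:
        missing.append("outcome")
    if icsr.sex is None:
        missing.append("sex")
    if icsr.age_years is None:
        missing.append("age")
    if not any(d.dose_documented for d in icsr.suspected_drugs()):
        missing.append("dose")
    if icsr.country is None:
        missing.append("country")
    if icsr.reporter_type is None:
        missing.append("reporter")
    if icsr.report_type is None:
        missing.append("report_type")
    if not icsr.comment_present:
        missing.append("comment")

    applied = tuple((f, penalties[f]) for f in missing if penalties.get(f, 0) > 0)
    score = 1.0
    for _, p in applied:
        score *= 1.0 - p
    return CompletenessScore(
        score=score,
        penalties_applied=applied,
        well_documented=score > WELL_DOCUMENTED_THRESHOLD,
    )


# ---------------------------------------------------------------------------
# WHO-UMC causality


class Temporal(str, enum.Enum):
    plausible = "plausible"
    implausible = "implausible"
    unknown = "unknown"


class OtherExplanations(str, enum.Enum):
    excluded = "excluded"
    possible = "possible"
    likely = "likely"
    unknown = "unknown"


class CausalityCategory(str, enum.Enum):
    certain = "certain"
    probable = "probable"
    possible = "possible"
    unlikely = "unlikely"
    conditional = "conditional"
    unassessable = "unassessable"


@dataclass(frozen=True)
class CausalityInput:
    temporal_relationship: Temporal
    other_explanations: OtherExplanations
    dechallenge: ChallengeResult
    rechallenge: ChallengeResult
    information_sufficient: bool = True
    information_contradictory: bool = False


def classify_causality(inp: CausalityInput) -> CausalityCategory:
    """First-match classification over the ordered WHO-UMC-style rules.

    Rule order (first match wins): unassessable, certain, probable,
    possible, unlikely, conditional. Total over the full input space.
    """
    if not inp.information_sufficient or inp.information_contradictory:
        return CausalityCategory.unassessable
    if (inp.temporal_relationship is Temporal.plausible
            and inp.other_explanations is OtherExplanations.excluded
            and inp.dechallenge is ChallengeResult.positive
            and inp.rechallenge is ChallengeResult.positive):
        return CausalityCategory.certain
    if (inp.temporal_relationship is Temporal.plausible
            and inp.other_explanations is OtherExplanations.excluded
            and inp.dechallenge is ChallengeResult.positive
            and inp.rechallenge is not ChallengeResult.positive):
        return CausalityCategory.probable
    if (inp.temporal_relationship is Temporal.plausible
            and inp.other_explanations in (OtherExplanations.possible,
                                           OtherExplanations.unknown)):
        return CausalityCategory.possible
    if (inp.temporal_relationship is Temporal.implausible
            or inp.other_explanations is OtherExplanations.likely):
        return CausalityCategory.unlikely
    return CausalityCategory.conditional


def derive_causality_input(
    icsr: ICSR,
    drug: str,
    event: EventDefinition,
    dictionary: Optional[TermDictionary] = None,
) -> CausalityInput:
    """Build a causality input from the structured report fields.

    Temporal relationship is judged from the drug start / event onset
    dates when both are day-precise (onset on or after start counts as
    plausible); alternative explanations are not captured in structured
    spontaneous reports and default to unknown.
    """
    pair = _matching_pair(icsr, drug, event, dictionary)
    temporal = Temporal.unknown
    if pair is not None:
        d, rx = pair
        if (d.start_date is not None and rx.onset_date is not None
                and d.start_date.precise and rx.onset_date.precise):
            lag = days_between(d.start_date, rx.onset_date)
            temporal = Temporal.plausible if lag >= 0 else Temporal.implausible
    return CausalityInput(
        temporal_relationship=temporal,
        other_explanations=OtherExplanations.unknown,
        dechallenge=icsr.dechallenge or ChallengeResult.unknown,
        rechallenge=icsr.rechallenge or ChallengeResult.unknown,
        information_sufficient=pair is not None,
        information_contradictory=False,
    )


# ---------------------------------------------------------------------------
# time to onset


@dataclass(frozen=True)
class TimeToOnsetSummary:
    n_cases: int
    n_estimable: int
    mean_years: Optional[float] = None
    sd_years: Optional[float] = None
    onsets_years: tuple[float, ...] = field(default=())


def _matching_pair(
    icsr: ICSR,
    drug: str,
    event: EventDefinition,
    dictionary: Optional[TermDictionary],
) -> Optional[tuple[DrugRecord, ReactionRecord]]:
    """First (suspected drug record, matching reaction) pair for the
    drug-event definition, or None."""
    drecs = [d for d in icsr.suspected_drugs()
             if d.drug_name.lower() == drug.lower()]
    if not drecs:
        return None
    if event.level == "pt":
        member = {event.name.lower()}
    else:
        if dictionary is None:
            raise ValueError("dictionary required for smq-level events")
        member = dictionary.members(event.name, event.scope)
    rxs = [r for r in icsr.reactions if r.pt_name.lower() in member]
    if not rxs:
        return None
    return drecs[0], rxs[0]


def time_to_onset(
    icsr: ICSR,
    drug: str,
    event: EventDefinition,
    dictionary: Optional[TermDictionary] = None,
) -> Optional[float]:
    """Years from drug start to event onset, or None when not estimable.

    Estimable only when both the suspected drug start date and the
    reaction onset date are present and day-precise.
    """
    pair = _matching_pair(icsr, drug, event, dictionary)
    if pair is None:
        return None
    d, rx = pair
    if d.start_date is None or rx.onset_date is None:
        return None
    if not (d.start_date.precise and rx.onset_date.precise):
        return None
    return days_between(d.start_date, rx.onset_date) / DAYS_PER_YEAR


def time_to_onset_summary(
    cases: Sequence[ICSR],
    drug: str,
    event: EventDefinition,
    dictionary: Optional[TermDictionary] = None,
) -> TimeToOnsetSummary:
    """Count, mean and sample SD (n-1) of estimable times to onset."""
    onsets = []
    for c in cases:
        t = time_to_onset(c, drug, event, dictionary)
        if t is not None:
            onsets.append(t)
    n = len(onsets)
    if n == 0:
        return TimeToOnsetSummary(n_cases=len(cases), n_estimable=0)
    mean = sum(onsets) / n
    sd = None
    if n >= 2:
        sd = math.sqrt(sum((x - mean) ** 2 for x in onsets) / (n - 1))
    return TimeToOnsetSummary(
        n_cases=len(cases), n_estimable=n,
        mean_years=mean, sd_years=sd, onsets_years=tuple(onsets),
    )
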