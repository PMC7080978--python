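"""Synthetic spontaneous-report database generator.

Builds report collections with the structure the screening pipeline
assumes: rare suspected-drug exposures with routes, PT-coded reactions
whose rates can rise with age, planted drug-event reporting-rate ratios
(RRR) against a large background of unrelated reports, plausible
drug-start/event-onset dates, and configurable per-field missingness.

``expected_cells`` evaluates the generative probabilities in closed form,
giving an analytic oracle for recovery tests: the empirical 2x2 cells of a
generated database converge to it.
"""
from __future__ import annotations

import datetime as dt
import logging
from typing import Optional, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .contingency import Stratum
from .dates import FuzzyDate
from .errors import DictionaryLookupError
from .reports import (
    ICSR,
    ChallengeResult,
    DrugRecord,
    DrugRole,
    Outcome,
    ReactionRecord,
    ReporterType,
    ReportType,
    Route,
    Sex,
)

log = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

_COUNTRIES = ["US", "GB", "DE", "IT", "FR", "JP", "BR", "AU"]
_INDICATIONS = [
    "macular degeneration", "diabetic macular oedema", "retinal vein occlusion",
    "hypertension", "infection", "pain",
]


class DrugSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    marginal_prob: float = Field(gt=0, le=1)
    route_dist: dict[Route, float] = Field(
        default_factory=lambda: {Route.intravitreal: 1.0}
    )
    #: multiplier on marginal_prob for persons aged >= 65 (age confounding)
    elderly_multiplier: float = Field(default=1.0, gt=0)

    @model_validator(mode="after")
    def _routes_sum_to_one(self) -> "DrugSpec":
        total = sum(self.route_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"route_dist for {self.name} sums to {total}, not 1")
        return self


class EventSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    pt_name: str
    baseline_prob: float = Field(gt=0, le=1)
    #: multiplicative rate change per decade of age relative to age_reference
    age_multiplier_per_decade: float = Field(default=1.0, gt=0)
    age_reference: float = 50.0


class PlantedAssociation(BaseModel):
    model_config = ConfigDict(frozen=True)

    drug_name: str
    pt_name: str
    rrr: float = Field(gt=0)


class AgeSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    prop_ge65: float = Field(default=0.3, ge=0, le=1)
    adult_range: tuple[int, int] = (18, 64)
    elderly_range: tuple[int, int] = (65, 90)


class MissingnessSpec(BaseModel):
    """Per-field absence probabilities (presence probabilities for the two
    boolean documentation fields)."""

    model_config = ConfigDict(frozen=True)

    age: float = Field(default=0.1, ge=0, le=1)
    sex: float = Field(default=0.05, ge=0, le=1)
    country: float = Field(default=0.05, ge=0, le=1)
    reporter_type: float = Field(default=0.2, ge=0, le=1)
    report_type: float = Field(default=0.1, ge=0, le=1)
    outcome: float = Field(default=0.3, ge=0, le=1)
    indication: float = Field(default=0.4, ge=0, le=1)
    start_date: float = Field(default=0.3, ge=0, le=1)
    onset_date: float = Field(default=0.3, ge=0, le=1)
    dechallenge: float = Field(default=0.7, ge=0, le=1)
    rechallenge: float = Field(default=0.9, ge=0, le=1)
    comment_prob: float = Field(default=0.3, ge=0, le=1)
    dose_prob: float = Field(default=0.3, ge=0, le=1)
    #: probability a present onset/start date is degraded to year precision
    imprecise_date_prob: float = Field(default=0.0, ge=0, le=1)


class CorrelatedGroup(BaseModel):
    """PTs that co-occur: when one member fires, each other member is added
    with probability ``rho`` (used to exercise SMQ-vs-PT count divergence)."""

    model_config = ConfigDict(frozen=True)

    pt_names: tuple[str, ...]
    rho: float = Field(ge=0, le=1)


class GeneratorConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_reports: int = Field(ge=1)
    seed: int = 0
    period: tuple[dt.date, dt.date] = (dt.date(2010, 1, 1), dt.date(2016, 12, 31))
    drugs: tuple[DrugSpec, ...] = ()
    events: tuple[EventSpec, ...] = ()
    planted_associations: tuple[PlantedAssociation, ...] = ()
    age: AgeSpec = AgeSpec()
    sex_ratio: float = Field(default=0.5, ge=0, le=1)
    missingness: MissingnessSpec = MissingnessSpec()
    correlated_groups: tuple[CorrelatedGroup, ...] = ()
    n_background_drugs: int = Field(default=40, ge=1)
    n_background_pts: int = Field(default=30, ge=1)
    background_route_dist: dict[Route, float] = Field(
        default_factory=lambda: {Route.oral: 0.6, Route.intravenous: 0.2,
                                 Route.other: 0.2}
    )
    mean_onset_years: float = Field(default=2.0, gt=0)
    #: probability of adding one concomitant background drug to a report
    concomitant_prob: float = Field(default=0.2, ge=0, le=1)

    @model_validator(mode="after")
    def _planted_pairs_known(self) -> "GeneratorConfig":
        dnames = {d.name.lower() for d in self.drugs}
        enames = {e.pt_name.lower() for e in self.events}
        for p in self.planted_associations:
            if p.drug_name.lower() not in dnames or p.pt_name.lower() not in enames:
                raise ValueError(
                    f"planted association {p.drug_name}/{p.pt_name} references "
                    "an unknown drug or event"
                )
        if self.period[0] > self.period[1]:
            raise ValueError("period start after end")
        return self

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# generation


def _age_grid(cfg: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Integer age support and probability weight of each age."""
    a_lo, a_hi = cfg.age.adult_range
    e_lo, e_hi = cfg.age.elderly_range
    adult = np.arange(a_lo, a_hi + 1)
    elderly = np.arange(e_lo, e_hi + 1)
    ages = np.concatenate([adult, elderly])
    w = np.concatenate([
        np.full(adult.size, (1 - cfg.age.prop_ge65) / adult.size),
        np.full(elderly.size, cfg.age.prop_ge65 / elderly.size),
    ])
    return ages, w


def _exposure_prob(spec: DrugSpec, ages: np.ndarray) -> np.ndarray:
    p = np.full(ages.shape, spec.marginal_prob, dtype=float)
    p[ages >= 65] = np.minimum(1.0, spec.marginal_prob * spec.elderly_multiplier)
    return p


def _event_rate(spec: EventSpec, ages: np.ndarray) -> np.ndarray:
    return spec.baseline_prob * spec.age_multiplier_per_decade ** (
        (ages - spec.age_reference) / 10.0
    )


def generate(config: GeneratorConfig) -> list[ICSR]:
    """Generate a deterministic collection of synthetic reports.

    Sampling is columnar in a fixed order from a single seeded PCG64
    stream, so identical (seed, config) yields an identical collection.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    miss = config.missingness

    ages_grid, w_grid = _age_grid(config)
    ages = rng.choice(ages_grid, size=n, p=w_grid)
    sexes = rng.random(n) < config.sex_ratio  # True = male

    start_day = config.period[0].toordinal()
    span = config.period[1].toordinal() - start_day + 1
    report_days = start_day + rng.integers(0, span, size=n)

    # study-drug exposure: independent Bernoulli per drug, with optional
    # elderly enrichment; route sampled per exposed report
    n_drugs = len(config.drugs)
    exposed = np.zeros((n, n_drugs), dtype=bool)
    routes = np.zeros((n, n_drugs), dtype=int)
    for j, dspec in enumerate(config.drugs):
        p = np.where(
            ages >= 65,
            min(1.0, dspec.marginal_prob * dspec.elderly_multiplier),
            dspec.marginal_prob,
        )
        exposed[:, j] = rng.random(n) < p
        route_names = list(dspec.route_dist)
        route_p = np.array([dspec.route_dist[r] for r in route_names])
        routes[:, j] = rng.choice(len(route_names), size=n, p=route_p)

    # events: independent per PT, baseline x age effect x planted RRRs
    n_events = len(config.events)
    rrr = np.ones((n_drugs, n_events))
    drug_idx = {d.name.lower(): j for j, d in enumerate(config.drugs)}
    event_idx = {e.pt_name.lower(): k for k, e in enumerate(config.events)}
    for p_assoc in config.planted_associations:
        rrr[drug_idx[p_assoc.drug_name.lower()],
            event_idx[p_assoc.pt_name.lower()]] = p_assoc.rrr

    has_event = np.zeros((n, n_events), dtype=bool)
    n_capped = 0
    for k, espec in enumerate(config.events):
        p = _event_rate(espec, ages)
        for j in range(n_drugs):
            if rrr[j, k] != 1.0:
                p = p * np.where(exposed[:, j], rrr[j, k], 1.0)
        capped = p > 1.0
        n_capped += int(capped.sum())
        has_event[:, k] = rng.random(n) < np.minimum(p, 1.0)
    if n_capped:
        log.warning("event probability capped at 1 for %d draws", n_capped)

    # co-occurrence within correlated PT groups
    for group in config.correlated_groups:
        idx = [event_idx[p.lower()] for p in group.pt_names if p.lower() in event_idx]
        if len(idx) < 2:
            continue
        any_fired = has_event[:, idx].any(axis=1)
        extra = rng.random((n, len(idx))) < group.rho
        for col, k in enumerate(idx):
            has_event[:, k] |= any_fired & extra[:, col]

    background_drug = rng.integers(0, config.n_background_drugs, size=n)
    concom_mask = rng.random(n) < config.concomitant_prob
    concom_drug = rng.integers(0, config.n_background_drugs, size=n)
    bkg_route_names = list(config.background_route_dist)
    bkg_route_p = np.array([config.background_route_dist[r] for r in bkg_route_names])
    background_route = rng.choice(len(bkg_route_names), size=n, p=bkg_route_p)
    background_pt = rng.integers(0, config.n_background_pts, size=n)

    # dates: event onset lags drug start exponentially; everything <= report_date
    onset_years = rng.exponential(config.mean_onset_years, size=(n, max(n_events, 1)))
    onset_back_days = rng.integers(0, 30, size=n)
    start_extra_days = rng.integers(0, 30, size=n)

    # missingness and documentation masks, one vector per field
    m_age = rng.random(n) < miss.age
    m_sex = rng.random(n) < miss.sex
    m_country = rng.random(n) < miss.country
    m_reporter = rng.random(n) < miss.reporter_type
    m_rtype = rng.random(n) < miss.report_type
    m_outcome = rng.random(n) < miss.outcome
    m_indication = rng.random(n) < miss.indication
    m_start = rng.random(n) < miss.start_date
    m_onset = rng.random(n) < miss.onset_date
    m_dechal = rng.random(n) < miss.dechallenge
    m_rechal = rng.random(n) < miss.rechallenge
    comment = rng.random(n) < miss.comment_prob
    dose = rng.random(n) < miss.dose_prob
    imprecise = rng.random(n) < miss.imprecise_date_prob

    country_ix = rng.integers(0, len(_COUNTRIES), size=n)
    reporter_ix = rng.integers(0, len(ReporterType), size=n)
    outcome_ix = rng.integers(0, len(Outcome), size=n)
    indication_ix = rng.integers(0, len(_INDICATIONS), size=n)
    chal_ix = rng.integers(0, len(ChallengeResult), size=(n, 2))

    reporter_values = list(ReporterType)
    outcome_values = list(Outcome)
    chal_values = list(ChallengeResult)
    drug_route_names = [list(d.route_dist) for d in config.drugs]

    reports: list[ICSR] = []
    width = len(str(n))
    for i in range(n):
        report_date = dt.date.fromordinal(int(report_days[i]))
        onset_date = None
        if not m_onset[i]:
            d0 = dt.date.fromordinal(int(report_days[i] - onset_back_days[i]))
            onset_date = FuzzyDate(d0.replace(month=1, day=1), "year") \
                if imprecise[i] else FuzzyDate(d0)
        # drug start precedes the (first) event onset by an exponential lag
        lag_days = int(onset_years[i, 0] * DAYS_PER_YEAR)
        start_ord = report_days[i] - onset_back_days[i] - lag_days - start_extra_days[i]
        start_date = None
        if not m_start[i]:
            d0 = dt.date.fromordinal(int(max(start_ord, 1)))
            start_date = FuzzyDate(d0.replace(month=1, day=1), "year") \
                if imprecise[i] else FuzzyDate(d0)

        indication = None if m_indication[i] else _INDICATIONS[indication_ix[i]]
        drugs: list[DrugRecord] = []
        for j, dspec in enumerate(config.drugs):
            if exposed[i, j]:
                drugs.append(DrugRecord(
                    drug_name=dspec.name,
                    role=DrugRole.suspected,
                    route=drug_route_names[j][routes[i, j]],
                    indication=indication,
                    start_date=start_date,
                    dose_documented=bool(dose[i]),
                ))
        if not drugs:
            drugs.append(DrugRecord(
                drug_name=f"backgrounddrug{background_drug[i]:02d}",
                role=DrugRole.suspected,
                route=bkg_route_names[background_route[i]],
                indication=indication,
                start_date=start_date,
                dose_documented=bool(dose[i]),
            ))
        if concom_mask[i]:
            drugs.append(DrugRecord(
                drug_name=f"backgrounddrug{concom_drug[i]:02d}",
                role=DrugRole.concomitant,
                route=bkg_route_names[background_route[i]],
                indication=None,
                start_date=None,
                dose_documented=False,
            ))
        reactions: list[ReactionRecord] = [
            ReactionRecord(pt_name=config.events[k].pt_name, onset_date=onset_date)
            for k in range(n_events) if has_event[i, k]
        ]
        if not reactions:
            reactions.append(ReactionRecord(
                pt_name=f"backgroundpt{background_pt[i]:02d}",
                onset_date=onset_date,
            ))
        reports.append(ICSR(
            report_id=f"R{i:0{width}d}",
            report_date=report_date,
            age_years=None if m_age[i] else float(ages[i]),
            sex=None if m_sex[i] else (Sex.male if sexes[i] else Sex.female),
            country=None if m_country[i] else _COUNTRIES[country_ix[i]],
            reporter_type=None if m_reporter[i] else reporter_values[reporter_ix[i]],
            report_type=None if m_rtype[i] else ReportType.spontaneous,
            outcome=None if m_outcome[i] else outcome_values[outcome_ix[i]],
            comment_present=bool(comment[i]),
            drugs=tuple(drugs),
            reactions=tuple(reactions),
            dechallenge=None if m_dechal[i] else chal_values[chal_ix[i, 0]],
            rechallenge=None if m_rechal[i] else chal_values[chal_ix[i, 1]],
        ))
    return reports


# ---------------------------------------------------------------------------
# analytic oracle


def expected_cells(
    config: GeneratorConfig,
    drug: str,
    pt: str,
    stratum: Optional[Stratum] = None,
    route: Route | str = Route.intravitreal,
) -> tuple[float, float, float, float]:
    """Closed-form expected 2x2 cell counts implied by the generator.

    Exposure means a suspected study-drug record with the analysis route;
    the comparator keeps reports of the drug via other routes (matching
    what the pipeline's exposure filter does). Exact for configurations
    without correlated PT groups and without probability capping.

    Strata restricting on age or sex account for the corresponding
    missingness (reports with the field missing drop out of those cohorts).
    """
    stratum = stratum or Stratum("all-ages")
    route = Route(route)
    try:
        j = next(i for i, d in enumerate(config.drugs)
                 if d.name.lower() == drug.lower())
        k = next(i for i, e in enumerate(config.events)
                 if e.pt_name.lower() == pt.lower())
    except StopIteration:
        raise DictionaryLookupError(
            f"pair {drug!r}/{pt!r} not in generator config"
        ) from None
    dspec, espec = config.drugs[j], config.events[k]

    rrr = 1.0
    other_rrr = {}
    for p_assoc in config.planted_associations:
        if p_assoc.pt_name.lower() != pt.lower():
            continue
        if p_assoc.drug_name.lower() == drug.lower():
            rrr = p_assoc.rrr
        else:
            other_rrr[p_assoc.drug_name.lower()] = p_assoc.rrr

    ages, w = _age_grid(config)
    keep = np.ones(ages.shape, dtype=bool)
    if stratum.min_age is not None:
        keep &= ages >= stratum.min_age
    if stratum.max_age is not None:
        keep &= (ages < stratum.max_age if stratum.max_exclusive
                 else ages <= stratum.max_age)
    ages, w = ages[keep], w[keep]

    factor = 1.0
    if stratum.min_age is not None or stratum.max_age is not None:
        factor *= 1.0 - config.missingness.age
    if stratum.sex is not None:
        p_male = config.sex_ratio
        factor *= (p_male if stratum.sex is Sex.male else 1 - p_male)
        factor *= 1.0 - config.missingness.sex

    r = dspec.route_dist.get(route, 0.0)
    p_x = _exposure_prob(dspec, ages)
    base = _event_rate(espec, ages)

    # independence factor from the other drugs' planted effects on this PT
    f_other = np.ones(ages.shape)
    for name, rr in other_rrr.items():
        od = next(d for d in config.drugs if d.name.lower() == name)
        p_o = _exposure_prob(od, ages)
        f_other *= 1 - p_o + p_o * rr

    p_exposed = p_x * r
    p_ev_and_exposed = p_x * r * base * rrr * f_other
    p_ev_and_unexposed = (p_x * (1 - r) * base * rrr * f_other
                          + (1 - p_x) * base * f_other)

    n = config.n_reports * factor
    e_a = float(n * np.sum(w * p_ev_and_exposed))
    e_b = float(n * np.sum(w * (p_exposed - p_ev_and_exposed)))
    e_c = float(n * np.sum(w * p_ev_and_unexposed))
    e_n = float(n * np.sum(w))
    e_d = e_n - e_a - e_b - e_c
    return e_a, e_b, e_c, e_d
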