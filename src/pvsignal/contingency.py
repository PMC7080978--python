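"""2x2 contingency tables for drug-event pairs against the all-other-reports
comparator, per analysis stratum."""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import PvSignalError
from .reports import ICSR, Route, Sex, filter_age, filter_sex, select_exposed
from .terms import EventDefinition, TermDictionary, event_matches


@dataclass(frozen=True)
class Stratum:
    """An analysis sub-population defined by age band and/or sex.

    Age bands are closed-open on the upper bound (``max_exclusive=True``)
    except an open-ended last band, so bands tile >=65 disjointly.
    """

    label: str
    min_age: Optional[float] = None
    max_age: Optional[float] = None
    max_exclusive: bool = True
    sex: Optional[Sex] = None

    def apply(self, reports: Sequence[ICSR]) -> list[ICSR]:
        out = list(reports)
        if self.min_age is not None or self.max_age is not None:
            out = filter_age(
                out,
                self.min_age if self.min_age is not None else 0.0,
                self.max_age,
                max_exclusive=self.max_exclusive,
            )
        if self.sex is not None:
            out = filter_sex(out, self.sex)
        return out


ALL_AGES = Stratum("all-ages")
GE65 = Stratum("ge65", min_age=65)
DEFAULT_STRATA = (
    ALL_AGES,
    GE65,
    Stratum("65-74", min_age=65, max_age=75, max_exclusive=True),
    Stratum("ge75", min_age=75),
    Stratum("male", sex=Sex.male),
    Stratum("female", sex=Sex.female),
)


@dataclass(frozen=True)
class ContingencyTable:
    """Counts a/b/c/d for one drug-event pair in one stratum cohort.

    a: exposed with event, b: exposed without, c: unexposed with event,
    d: neither. Every report of the cohort lands in exactly one cell.
    """

    a: int
    b: int
    c: int
    d: int
    drug: str = ""
    event: Optional[EventDefinition] = None
    stratum: str = "all-ages"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_drug(self) -> int:
        return self.a + self.b

    @property
    def n_event(self) -> int:
        return self.a + self.c

    @property
    def expected(self) -> float:
        """Expected exposed-with-event count under independence."""
        return self.n_drug * self.n_event / self.n_total


def build_table(
    reports: Sequence[ICSR],
    exposed_ids: set[str] | frozenset[str],
    dictionary: TermDictionary,
    event: EventDefinition,
    drug: str = "",
    stratum: str = "all-ages",
) -> ContingencyTable:
    """Partition a stratum cohort into the four cells for one event."""
    if not reports:
        raise ValueError("empty cohort")
    cohort_ids = {r.report_id for r in reports}
    if not exposed_ids <= cohort_ids:
        raise PvSignalError("exposed_ids not a subset of the cohort")
    a = b = c = d = 0
    for r in reports:
        exposed = r.report_id in exposed_ids
        has_event = event_matches(r, dictionary, event)
        if exposed and has_event:
            a += 1
        elif exposed:
            b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d, drug=drug, event=event, stratum=stratum)


def enumerate_tables(
    reports: Sequence[ICSR],
    drugs: Sequence[str],
    events: Sequence[EventDefinition],
    strata: Sequence[Stratum],
    dictionary: TermDictionary,
    route: Route | str = Route.intravitreal,
    require_suspected: bool = True,
    exclude_class_from_comparator: bool = False,
) -> list[ContingencyTable]:
    """One table per (drug, event, stratum), deterministically ordered
    drug-major, query-level events before PT-level events, strata in the
    given order. The comparator is recomputed within each stratum.

    By default the comparator for drug X keeps reports of the other study
    drugs; ``exclude_class_from_comparator`` drops them (sensitivity
    analysis).
    """
    ev_order = sorted(
        range(len(events)), key=lambda i: (0 if events[i].level == "smq" else 1, i)
    )
    ordered = [events[i] for i in ev_order]

    exposed_by_drug = {
        drug: frozenset(
            r.report_id
            for r in select_exposed(reports, {drug}, route, require_suspected)
        )
        for drug in drugs
    }
    all_class = frozenset().union(*exposed_by_drug.values()) if drugs else frozenset()

    tables: list[ContingencyTable] = []
    for drug in drugs:
        for event in ordered:
            for stratum in strata:
                cohort = stratum.apply(reports)
                if exclude_class_from_comparator:
                    keep = exposed_by_drug[drug]
                    cohort = [
                        r for r in cohort
                        if r.report_id in keep or r.report_id not in all_class
                    ]
                tables.append(
                    build_table(
                        cohort,
                        exposed_by_drug[drug] & {r.report_id for r in cohort},
                        dictionary,
                        event,
                        drug=drug,
                        stratum=stratum.label,
                    )
                )
    return tables


def tables_to_frame(tables: Iterable[ContingencyTable]) -> pd.DataFrame:
    """Export as a data frame: drug, event_level, event_name, stratum, a-d."""
    rows = []
    for t in tables:
        rows.append({
            "drug": t.drug,
            "event_level": t.event.level if t.event else "",
            "event_name": t.event.name if t.event else "",
            "stratum": t.stratum,
            "a": t.a, "b": t.b, "c": t.c, "d": t.d,
        })
    return pd.DataFrame(
        rows,
        columns=["drug", "event_level", "event_name", "stratum", "a", "b", "c", "d"],
    )


def restrict(table: ContingencyTable, **changes) -> ContingencyTable:
    return replace(table, **changes)
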