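"""Preferred-term to standardized-query membership and event matching.

A term dictionary maps preferred terms (PTs) into named standardized
queries (SMQ-style groupings) at ``narrow`` or ``broad`` scope. Event
definitions can address either a whole query (level ``smq``) or a single
preferred term (level ``pt``); a report counts at most once per event
definition no matter how many of its reactions match.
"""
from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from .errors import DictionaryLookupError, FormatError
from .reports import ICSR

log = logging.getLogger(__name__)


class Scope(str, enum.Enum):
    narrow = "narrow"
    broad = "broad"


@dataclass(frozen=True)
class EventDefinition:
    """What to count as 'the event': a whole query or one preferred term."""

    level: Literal["smq", "pt"]
    name: str
    scope: Scope = Scope.narrow

    @property
    def label(self) -> str:
        return f"{self.level}:{self.name}"


@dataclass
class TermDictionary:
    """Set of (pt_name, smq_name, scope) memberships.

    PT names are matched case-insensitively. A PT may belong to several
    queries; the (pt, smq) pair is unique.
    """

    entries: dict[tuple[str, str], Scope] = field(default_factory=dict)
    _by_smq: dict[str, dict[str, Scope]] = field(default_factory=dict, repr=False)
    _display: dict[str, str] = field(default_factory=dict, repr=False)

    def add(self, pt_name: str, smq_name: str, scope: Scope | str) -> bool:
        """Add a membership; returns False (and keeps the first) on duplicate."""
        scope = Scope(scope)
        key = (pt_name.lower(), smq_name.lower())
        if key in self.entries:
            return False
        self.entries[key] = scope
        self._by_smq.setdefault(smq_name.lower(), {})[pt_name.lower()] = scope
        self._display.setdefault(smq_name.lower(), smq_name)
        return True

    def smq_names(self) -> list[str]:
        """Query names as first seen (display case), sorted."""
        return sorted(self._display.values())

    def members(self, smq_name: str, scope: Scope | str = Scope.narrow) -> set[str]:
        """Member PTs (lower-cased) of a query at the requested scope.

        Broad scope is the sensitive superset: it includes the narrow terms.
        """
        scope = Scope(scope)
        try:
            table = self._by_smq[smq_name.lower()]
        except KeyError:
            raise DictionaryLookupError(f"unknown SMQ {smq_name!r}") from None
        if scope is Scope.broad:
            return set(table)
        return {pt for pt, sc in table.items() if sc is Scope.narrow}

    def __len__(self) -> int:
        return len(self.entries)


def load_dictionary(path: str | Path) -> TermDictionary:
    """Load a dictionary CSV with columns pt_name, smq_name, scope.

    Duplicate (pt, smq) pairs collapse to the first occurrence with a
    logged warning; an unknown scope value is a format error.
    """
    path = Path(path)
    d = TermDictionary()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"pt_name", "smq_name", "scope"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(
                f"{path}: dictionary CSV must have columns {sorted(required)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                scope = Scope(row["scope"].strip().lower())
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: unknown scope {row['scope']!r}"
                ) from None
            if not d.add(row["pt_name"].strip(), row["smq_name"].strip(), scope):
                log.warning(
                    "%s:%d: duplicate dictionary entry (%s, %s) ignored",
                    path, lineno, row["pt_name"], row["smq_name"],
                )
    return d


def event_matches(
    icsr: ICSR, dictionary: TermDictionary, event: EventDefinition
) -> bool:
    """True iff the report carries the event, counted at most once."""
    pts = {rx.pt_name.lower() for rx in icsr.reactions}
    if event.level == "pt":
        return event.name.lower() in pts
    members = dictionary.members(event.name, event.scope)
    return not pts.isdisjoint(members)


def count_events(
    reports: Iterable[ICSR], dictionary: TermDictionary, event: EventDefinition
) -> int:
    """Number of reports matching the event (each counted once)."""
    return sum(event_matches(r, dictionary, event) for r in reports)
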