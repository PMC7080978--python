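"""End-to-end screening pipeline: filters -> term mapping -> contingency ->
disproportionality -> (for flagged signals) case grading, driven by one
YAML study config, with deterministic CSV/JSON outputs."""
from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from collections import Counter
from pathlib import Path
from typing import Literal, Optional, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .contingency import ContingencyTable, Stratum, enumerate_tables, tables_to_frame
from .disproportionality import Z95, DisproportionalityResult, screen
from .grading import (
    classify_causality,
    derive_causality_input,
    time_to_onset,
    time_to_onset_summary,
    vigigrade,
)
from .reporting import fmt_estimate, percent, quartiles, round_half_away
from .reports import ICSR, Route, Sex, filter_period, read_reports, select_exposed
from .terms import EventDefinition, Scope, TermDictionary, event_matches, load_dictionary

log = logging.getLogger(__name__)

SIGNAL_COLUMNS = [
    "drug", "event_level", "event_name", "stratum", "n",
    "prr", "prr_low", "prr_high", "ror", "ror_low", "ror_high",
    "ic", "ic025", "signal",
]

GRADING_COLUMNS = [
    "drug", "event_level", "event_name", "stratum", "report_id",
    "completeness_score", "well_documented", "causality_category",
    "time_to_onset_years",
]


class StratumSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    label: str
    min_age: Optional[float] = None
    max_age: Optional[float] = None
    max_exclusive: bool = True
    sex: Optional[Sex] = None

    def to_stratum(self) -> Stratum:
        return Stratum(self.label, self.min_age, self.max_age,
                       self.max_exclusive, self.sex)


DEFAULT_STRATA_SPECS = (
    StratumSpec(label="all-ages"),
    StratumSpec(label="ge65", min_age=65),
    StratumSpec(label="65-74", min_age=65, max_age=75),
    StratumSpec(label="ge75", min_age=75),
)


class StudyConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    input: str
    dialect: Literal["jsonl", "flat_csv"] = "jsonl"
    dictionary: str
    drugs: tuple[str, ...] = Field(min_length=1)
    route: Route = Route.intravitreal
    require_suspected: bool = True
    smqs: tuple[str, ...] = ()
    scope: Scope = Scope.narrow
    pt_level: bool = True
    extra_pts: tuple[str, ...] = ()
    period: Optional[tuple[dt.date, dt.date]] = None
    date_field: Literal["report_date"] = "report_date"
    strata: tuple[StratumSpec, ...] = DEFAULT_STRATA_SPECS
    min_cases: int = Field(default=3, ge=1)
    z: float = Z95
    ic_method: Literal["approx", "gamma"] = "approx"
    exclude_class_from_comparator: bool = False
    suppress_small_cells: bool = False
    small_cell_threshold: int = 10

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


class ScreenOutput(BaseModel):
    model_config = ConfigDict(arbitrary_types_allowed=True)

    results: list[DisproportionalityResult]
    tables: list[ContingencyTable]
    grading: pd.DataFrame
    funnel: dict[str, int]
    events: list[EventDefinition]


def build_events(config: StudyConfig, dictionary: TermDictionary) -> list[EventDefinition]:
    """Query-level events first, then the member PTs (and extra PTs)."""
    events: list[EventDefinition] = [
        EventDefinition("smq", s, config.scope) for s in config.smqs
    ]
    if config.pt_level:
        seen: set[str] = set()
        for s in config.smqs:
            for pt in sorted(dictionary.members(s, config.scope)):
                if pt not in seen:
                    seen.add(pt)
                    events.append(EventDefinition("pt", pt, config.scope))
        for pt in config.extra_pts:
            if pt.lower() not in seen:
                seen.add(pt.lower())
                events.append(EventDefinition("pt", pt, config.scope))
    return events


def run_screen(config: StudyConfig, out_dir: str | Path) -> ScreenOutput:
    """Execute the full screen and write CSV/JSON outputs into ``out_dir``.

    Outputs: ``contingency.csv`` (raw cells), ``signals.csv`` (estimates,
    "NA" for uncomputed), ``grading.csv`` (case grading for flagged
    signals only), ``manifest.json`` (config hash + cohort funnel).
    A run with zero exposed reports is an explicit empty result, not an
    error.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    reports = read_reports(config.input, config.dialect)
    dictionary = load_dictionary(config.dictionary)
    funnel: dict[str, int] = {"total": len(reports)}

    if config.period is not None:
        reports = filter_period(reports, config.period[0], config.period[1])
    funnel["in_period"] = len(reports)

    exposed_any = select_exposed(
        reports, set(config.drugs), config.route, config.require_suspected
    )
    funnel["exposed"] = len(exposed_any)

    events = build_events(config, dictionary)
    strata = [s.to_stratum() for s in config.strata]

    exposed_ids = {r.report_id for r in exposed_any}
    for ev in events:
        funnel[f"exposed_{ev.level}_{ev.name}"] = sum(
            1 for r in exposed_any if event_matches(r, dictionary, ev)
        )

    if not exposed_any:
        log.warning("no exposed reports after filtering; writing empty outputs")

    tables = enumerate_tables(
        reports, list(config.drugs), events, strata, dictionary,
        route=config.route,
        require_suspected=config.require_suspected,
        exclude_class_from_comparator=config.exclude_class_from_comparator,
    )
    results = screen(tables, config.min_cases, config.z, config.ic_method)

    grading = _grade_signals(results, reports, exposed_ids, dictionary, config)

    _write_outputs(config, out_dir, tables, results, grading, funnel)
    return ScreenOutput(results=results, tables=tables, grading=grading,
                        funnel=funnel, events=events)


def _grade_signals(
    results: Sequence[DisproportionalityResult],
    reports: Sequence[ICSR],
    exposed_ids: set[str],
    dictionary: TermDictionary,
    config: StudyConfig,
) -> pd.DataFrame:
    """Case grading restricted to flagged signal pairs."""
    rows = []
    strata = {s.label: s.to_stratum() for s in config.strata}
    for res in results:
        if not res.signal:
            continue
        t = res.table
        stratum = strata[t.stratum]
        cohort = stratum.apply(reports)
        cases = [r for r in cohort
                 if r.report_id in exposed_ids
                 and event_matches(r, dictionary, t.event)]
        for case in cases:
            comp = vigigrade(case)
            causality = classify_causality(
                derive_causality_input(case, t.drug, t.event, dictionary)
            )
            tto = time_to_onset(case, t.drug, t.event, dictionary)
            rows.append({
                "drug": t.drug,
                "event_level": t.event.level,
                "event_name": t.event.name,
                "stratum": t.stratum,
                "report_id": case.report_id,
                "completeness_score": comp.score,
                "well_documented": comp.well_documented,
                "causality_category": causality.value,
                "time_to_onset_years": tto,
            })
    return pd.DataFrame(rows, columns=GRADING_COLUMNS)


def results_to_frame(results: Sequence[DisproportionalityResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        t = r.table
        rows.append({
            "drug": t.drug,
            "event_level": t.event.level if t.event else "",
            "event_name": t.event.name if t.event else "",
            "stratum": t.stratum,
            "n": r.n_observed,
            "prr": r.prr, "prr_low": r.prr_low, "prr_high": r.prr_high,
            "ror": r.ror, "ror_low": r.ror_low, "ror_high": r.ror_high,
            "ic": r.ic, "ic025": r.ic025,
            "signal": r.signal,
        })
    return pd.DataFrame(rows, columns=SIGNAL_COLUMNS)


def _write_outputs(config, out_dir, tables, results, grading, funnel) -> None:
    tables_to_frame(tables).to_csv(out_dir / "contingency.csv", index=False)

    frame = results_to_frame(results)
    # full precision in CSV; absent estimates as the literal "NA"
    frame.to_csv(out_dir / "signals.csv", index=False, na_rep="NA")

    if config.suppress_small_cells and len(grading):
        sizes = grading.groupby(
            ["drug", "event_level", "event_name", "stratum"]
        )["report_id"].transform("count")
        grading = grading[sizes > config.small_cell_threshold]
    grading.to_csv(out_dir / "grading.csv", index=False, na_rep="NA")

    manifest = {
        "pvsignal_version": __version__,
        "config_hash": config.config_hash(),
        "config": config.model_dump(mode="json"),
        "funnel": funnel,
        "n_tables": len(tables),
        "n_signals": int(sum(r.signal for r in results)),
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        # insertion order is meaningful for the funnel and deterministic
        json.dump(manifest, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# human-readable report


def run_report(out_dir: str | Path) -> str:
    """Render a markdown summary from a screen output directory and write
    it to ``report.md`` there."""
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.json"
    signals_path = out_dir / "signals.csv"
    if not manifest_path.exists() or not signals_path.exists():
        raise FileNotFoundError(
            f"screen outputs not found under {out_dir} (run `screen` first)"
        )
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    signals = pd.read_csv(signals_path, keep_default_na=False, na_values=[""])
    grading_path = out_dir / "grading.csv"
    grading = pd.read_csv(grading_path) if grading_path.exists() else pd.DataFrame()

    lines: list[str] = ["# Screening report", ""]
    funnel = manifest["funnel"]
    total = funnel.get("total", 0)
    lines.append("## Cohort funnel")
    lines.append("")
    lines.append("| step | n | % of total |")
    lines.append("|---|---:|---:|")
    for step, count in funnel.items():
        pct = percent(count, total, 2) if total else 0.0
        lines.append(f"| {step} | {count} | {pct:.2f} |")
    lines.append("")

    lines.append("## Disproportionality")
    lines.append("")
    n_signals = int(manifest.get("n_signals", 0))
    if n_signals == 0:
        lines.append("No signal of disproportionate reporting was found.")
    else:
        lines.append(f"{n_signals} signal row(s) flagged (bold).")
    lines.append("")
    lines.append("| drug | event | stratum | n | PRR (95% CI) | ROR (95% CI) "
                 "| IC (IC025) |")
    lines.append("|---|---|---|---:|---|---|---|")
    for _, row in signals.iterrows():
        cells = [
            str(row["drug"]),
            f"{row['event_level']}:{row['event_name']}",
            str(row["stratum"]),
            str(int(row["n"])),
            _interval(row, "prr"),
            _interval(row, "ror"),
            _ic_cell(row),
        ]
        if str(row["signal"]) == "True":
            cells = [f"**{c}**" for c in cells]
        lines.append("| " + " | ".join(cells) + " |")
    lines.append("")

    if len(grading):
        lines.append("## Case grading (flagged signals)")
        lines.append("")
        scores = grading["completeness_score"].tolist()
        q1, med, q3 = quartiles(scores)
        lines.append(
            f"Completeness: median {round_half_away(med, 2):.2f} "
            f"(Q1-Q3 {round_half_away(q1, 2):.2f}-{round_half_away(q3, 2):.2f}); "
            f"{int(grading['well_documented'].sum())} of {len(grading)} "
            "well documented (>0.8)."
        )
        lines.append("")
        counts = Counter(grading["causality_category"])
        n_cases = len(grading)
        parts = [
            f"{cat}: {cnt} ({percent(cnt, n_cases, 2):.2f}%)"
            for cat, cnt in sorted(counts.items())
        ]
        lines.append("Causality: " + "; ".join(parts) + ".")
        lines.append("")
        tto = grading["time_to_onset_years"].dropna().tolist()
        if tto:
            mean = sum(tto) / len(tto)
            if len(tto) >= 2:
                sd = (sum((x - mean) ** 2 for x in tto) / (len(tto) - 1)) ** 0.5
                sd_txt = f" +/- {round_half_away(sd, 1):.1f}"
            else:
                sd_txt = ""
            lines.append(
                f"Time to onset estimable for {len(tto)} of {n_cases} cases: "
                f"mean {round_half_away(mean, 1):.1f}{sd_txt} years."
            )
            lines.append("")

    text = "\n".join(lines)
    with open(out_dir / "report.md", "w", encoding="utf-8") as fh:
        fh.write(text)
    return text


def _num(row, col) -> Optional[float]:
    v = row[col]
    if v in ("NA", "", None) or pd.isna(v):
        return None
    return float(v)


def _interval(row, prefix: str) -> str:
    point = _num(row, prefix)
    if point is None:
        return "NA"
    lo, hi = _num(row, f"{prefix}_low"), _num(row, f"{prefix}_high")
    if lo is None or hi is None:
        return fmt_estimate(point)
    return f"{fmt_estimate(point)} ({fmt_estimate(lo)}-{fmt_estimate(hi)})"


def _ic_cell(row) -> str:
    ic = _num(row, "ic")
    if ic is None:
        return "NA"
    return f"{fmt_estimate(ic)} ({fmt_estimate(_num(row, 'ic025'))})"
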