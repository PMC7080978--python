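# pvsignal

Disproportionality-based safety-signal detection for spontaneous
adverse-event report collections, plus a synthetic report-database
generator for validating the whole pipeline end to end.

The package covers the classical screening workflow used with large
pharmacovigilance databases:

1. **Report store** (`pvsignal.reports`) — a validated data model for
   individual case safety reports (ICSRs) with nested drug and reaction
   records, JSON-lines and flat-CSV readers/writers, and cohort filters
   (suspected-drug + route exposure selection, reporting-period and age
   restriction). Partial dates ("2014", "2014-03") are accepted and
   tracked as imprecise.
2. **Term dictionary** (`pvsignal.terms`) — preferred-term (PT) to
   standardized-query (SMQ-style) membership with narrow/broad scope, and
   event matching at either query or PT level (a report counts once per
   event no matter how many matching reactions it carries).
3. **Contingency** (`pvsignal.contingency`) — 2×2 tables per
   (drug, event, stratum) against the all-other-reports comparator,
   recomputed within each stratum.
4. **Disproportionality** (`pvsignal.disproportionality`) — PRR and ROR
   with log-scale Wald 95% intervals, the shrunken information component
   with its IC025 lower credibility bound (closed-form or exact gamma
   quantile), a minimum-case rule (default ≥3), and signal flagging
   (lower PRR bound > 1).
5. **Case grading** (`pvsignal.grading`) — multiplicative completeness
   scoring over ten documentation dimensions (>0.8 = well documented),
   WHO-UMC-style causality classification, and time-to-onset summaries.
6. **Synthetic database** (`pvsignal.simulate`) — seeded generator with
   planted reporting-rate ratios, age-dependent event rates,
   elderly-enriched exposure (for confounding experiments), per-field
   missingness, and a closed-form `expected_cells` oracle.
7. **Pipeline + CLI** (`pvsignal.pipeline`, `pvsignal.cli`) — one YAML
   config drives filters → term mapping → contingency →
   disproportionality → case grading for flagged signals, with
   deterministic CSV/JSON outputs and a markdown report.

## CLI tutorial

```sh
# grab the bundled demo configs and illustrative dictionary
python - <<'EOF'
from importlib.resources import files
import shutil
for name in ("demo_generator.yaml", "demo_study.yaml", "smq_demo.csv"):
    shutil.copy(str(files("pvsignal") / "fixtures" / name), name)
EOF

pvsignal generate --config demo_generator.yaml --out reports.jsonl --seed 42
pvsignal screen   --config demo_study.yaml     --out out/
pvsignal report   --out out/            # renders out/report.md
pvsignal grade    --config demo_study.yaml --out grades.csv
```

`screen` writes `contingency.csv` (raw cells), `signals.csv` (estimates;
`NA` for pairs below the case threshold), `grading.csv` (case grading for
flagged signals only) and `manifest.json` (config hash + cohort funnel).
Re-running with the same config and inputs is byte-identical. An empty
result (no exposed reports) exits 0.

The bundled `fixtures/smq_demo.csv` is an illustrative PT/SMQ mapping for
demos and tests only — it is not licensed MedDRA content.

## Library example

```python
from pvsignal import (GeneratorConfig, generate, load_dictionary,
                      EventDefinition, select_exposed, build_table, screen)

cfg = GeneratorConfig.model_validate({
    "n_reports": 50_000, "seed": 1,
    "drugs": [{"name": "drugA", "marginal_prob": 0.01,
               "route_dist": {"intravitreal": 1.0}}],
    "events": [{"pt_name": "EventX", "baseline_prob": 0.01}],
    "planted_associations": [
        {"drug_name": "drugA", "pt_name": "EventX", "rrr": 3.0}],
})
reports = generate(cfg)
exposed = {r.report_id for r in
           select_exposed(reports, {"drugA"}, "intravitreal")}
from pvsignal.terms import TermDictionary
d = TermDictionary(); d.add("EventX", "demo query", "narrow")
table = build_table(reports, exposed, d, EventDefinition("pt", "EventX"))
result = screen([table])[0]
print(result.prr, result.prr_low, result.signal)
```
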