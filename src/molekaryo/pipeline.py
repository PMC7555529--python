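"""End-to-end orchestration: simulate → classify STR → karyotype → origin →
cohort report, with a single root seed and atomic per-case outputs."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

from .cohort import (CaseCall, CohortReport, case_call_from_estimate,
                     report_to_dict, summarize_cohort)
from .errors import ConfigError
from .io_formats import _atomic_write, write_final_report, write_str_table
from .karyotype import CallerConfig, estimate_karyotype, karyotype_to_dict
from .origin import (OriginConfig, mito_identity, origin_calls_for_sample,
                     origin_to_dict)
from .panel import LocusPanel, default_panel
from .simulate import (CaseSpec, NoiseModel, SimulatedCase,
                       default_cohort_specs, load_cohort_spec, simulate_cohort)
from .str_classify import classification_to_dict, classify_conceptus

log = logging.getLogger("molekaryo")


@dataclass
class PipelineConfig:
    """Everything a full run needs.

    ``cohort_spec`` is a YAML path or ``None`` for the packaged reference
    cohort; ``seed`` drives every random draw through hierarchical
    splitting.  The panel is rebuilt deterministically from its own fixed
    seed so rendered tables are comparable across runs that share it.
    """

    out_dir: Path
    seed: int
    cohort_spec: Path | None = None
    noise: NoiseModel = field(default_factory=NoiseModel)
    caller: CallerConfig = field(default_factory=CallerConfig)
    origin: OriginConfig = field(default_factory=OriginConfig)
    panel: LocusPanel | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("a seed is required for simulation")
        self.out_dir = Path(self.out_dir)


def analyze_case(case: SimulatedCase, panel: LocusPanel,
                 caller: CallerConfig = CallerConfig(),
                 origin: OriginConfig = OriginConfig()) -> tuple[CaseCall, dict]:
    """Run the full caller chain on one simulated (or loaded) duo.

    Returns the cohort-level :class:`CaseCall` plus a JSON-ready dict with
    the per-stage details (STR class, karyotype, origin calls, mito
    identity)."""
    str_class = classify_conceptus(case.mole_str, case.maternal_str)
    estimate = estimate_karyotype(case.mole_array, caller)
    origins = origin_calls_for_sample(case.mole_array, case.maternal_array,
                                      estimate.calls, panel=panel, config=origin)
    mito = mito_identity([case.mole_array, case.maternal_array])
    call = case_call_from_estimate(case.case_id, estimate, origins, case.outcome)
    details = {
        "case_id": case.case_id,
        "outcome": case.outcome,
        "str_classification": classification_to_dict(str_class),
        "karyotype": karyotype_to_dict(estimate),
        "origins": {c: origin_to_dict(o) for c, o in origins.items()},
        "mito_identical": mito.identical(case.mole_array.sample_id,
                                         case.maternal_array.sample_id),
        "mito_informative_loci": len(mito.informative_loci),
    }
    return call, details


def run_pipeline(config: PipelineConfig) -> CohortReport:
    """Simulate the cohort, write all artifacts, and return the report.

    Writes, under ``out_dir``: one final-report TSV and one STR CSV per
    duo, one JSON call file per case, and ``report.json``/``report.tsv``
    for the cohort.  Every file is written atomically, so a rerun never
    sees a torn partial output.  Deterministic under a fixed seed.
    """
    specs = (load_cohort_spec(config.cohort_spec) if config.cohort_spec
             else default_cohort_specs())
    panel = config.panel or default_panel()
    log.info("cohort: %d cases, panel: %d loci", len(specs), len(panel.table))

    cases = simulate_cohort(specs, seed=config.seed, panel=panel,
                            noise=config.noise)
    log.info("simulated %d duos", len(cases))

    out = config.out_dir
    calls = []
    for case in cases:
        case_dir = out / "cases" / case.case_id
        write_final_report([case.mole_array, case.maternal_array],
                           case_dir / f"{case.case_id}_duo.tsv")
        write_str_table([case.mole_str, case.maternal_str],
                        case_dir / f"{case.case_id}_str.csv")
        call, details = analyze_case(case, panel, config.caller, config.origin)
        _atomic_write(case_dir / f"{case.case_id}_calls.json",
                      json.dumps(details, indent=2, sort_keys=True) + "\n")
        calls.append(call)
        log.info("case %s: %s", case.case_id, call.karyotype)

    report = summarize_cohort(calls)
    _atomic_write(out / "report.json",
                  json.dumps(report_to_dict(report), indent=2, sort_keys=True) + "\n")
    tsv = report.cases.to_csv(sep="\t", index=False)
    _atomic_write(out / "report.tsv", tsv)
    log.info("cohort: %d euploid / %d aneuploid, GTN %d/%d",
             report.n_euploid, report.n_aneuploid, *report.gtn_overall)
    return report
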