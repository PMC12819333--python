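"""End-to-end orchestration: quarters -> deduplicated store -> cohort,
signal and time-to-onset tables.

``run`` reproduces the standard artifact set of a spontaneous-report
disproportionality study from a directory of FAERS-style quarters: a
demographic cohort summary, one signal row per exposure (all four
statistics plus positivity flags), pairwise onset-time tests, per-group
Weibull fits and cumulative-onset curves, and a flow-count audit of every
filtering step.  All randomness (Weibull bootstrap) flows from the single
configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cohort, disprop, faers_io, tto

logger = logging.getLogger("pvsignal")

__all__ = ["RunConfig", "run", "extract_tto_records"]

#: the six overlapping pairwise onset-time contrasts reported for this
#: study design; "All ICIs" overlaps each class, which violates the
#: independence assumption of the test -- kept for fidelity to the design,
#: flagged in the log.
DEFAULT_COMPARISONS = (
    ("All ICIs", "CTLA-4i"),
    ("All ICIs", "PD-L1i"),
    ("All ICIs", "PD-1i"),
    ("CTLA-4i", "PD-L1i"),
    ("CTLA-4i", "PD-1i"),
    ("PD-L1i", "PD-1i"),
)

SIGNAL_COLUMNS = (
    "exposure", "n", "ROR", "ROR_low", "ROR_high", "PRR", "chi2",
    "EBGM", "EBGM05", "IC", "IC025",
    "ror_pos", "prr_pos", "mgps_pos", "bcpnn_pos", "degenerate",
)


@dataclass
class RunConfig:
    quarter_dirs: list[str]
    out_dir: str
    drug_dictionary: str | None = None
    term_list: str | None = None
    exposures: list[str] | None = None  # default: all + classes + observed agents/combos
    delimiter: str = "$"
    yates: bool = False
    bootstrap_reps: int = 1000
    seed: int = 17
    tto_cutpoints: tuple[int, int] = (30, 180)
    comparisons: list[tuple[str, str]] = field(
        default_factory=lambda: [list(c) for c in DEFAULT_COMPARISONS])

    def validate(self) -> None:
        for q in self.quarter_dirs:
            if not Path(q).is_dir():
                raise FileNotFoundError(f"quarter directory missing: {q}")
        for p in (self.drug_dictionary, self.term_list):
            if p is not None and not Path(p).is_file():
                raise FileNotFoundError(f"config path missing: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _concat_tables(sets: list[faers_io.RawTableSet]) -> faers_io.RawTableSet:
    frames = {
        name: pd.concat([s.table(name) for s in sets], ignore_index=True)
        for name in faers_io.TABLE_NAMES
    }
    return faers_io.RawTableSet(
        **frames,
        source_quarter="+".join(s.source_quarter for s in sets),
        read_report={"combined_from": [s.read_report for s in sets]},
    )


def extract_tto_records(store: pd.DataFrame, ther: pd.DataFrame,
                        drug: pd.DataFrame, regimens: pd.DataFrame,
                        pids: set[int],
                        dictionary: cohort.DrugDictionary) -> pd.DataFrame:
    """Per-report onset spans for the given case reports.

    The therapy start is the earliest day-precision START_DT among THER
    rows linked to the suspect ICI via the drug-sequence key when both
    tables carry one, else among all THER rows of the report.  Returns one
    row per report with tto_days (nullable), the validity reason, and the
    primary-suspect class.
    """
    ther = ther.copy()
    ther["primaryid"] = pd.to_numeric(ther["PRIMARYID"], errors="coerce")
    ther = ther.dropna(subset=["primaryid"])
    ther["primaryid"] = ther["primaryid"].astype("int64")
    ther = ther[ther["primaryid"].isin(pids)]

    seq_col = next((c for c in ("DSG_DRUG_SEQ", "DRUG_SEQ") if c in ther.columns),
                   None)
    ici_seqs: dict[int, set[str]] = {}
    if seq_col is not None and "DRUG_SEQ" in drug.columns:
        d = drug.copy()
        d["primaryid"] = pd.to_numeric(d["PRIMARYID"], errors="coerce")
        d = d.dropna(subset=["primaryid"])
        d["primaryid"] = d["primaryid"].astype("int64")
        d = d[d["primaryid"].isin(pids)]
        d["agent"] = dictionary.map_series(d["DRUGNAME"])
        d = d.dropna(subset=["agent"])
        d = d[d["ROLE_COD"].str.strip().str.upper() == "PS"]
        for pid, grp in d.groupby("primaryid"):
            ici_seqs[int(pid)] = set(grp["DRUG_SEQ"].astype(str))

    starts: dict[int, faers_io.PartialDate | None] = {}
    for pid, grp in ther.groupby("primaryid"):
        pid = int(pid)
        rows = grp
        seqs = ici_seqs.get(pid)
        if seqs and seq_col is not None:
            linked = grp[grp[seq_col].astype(str).isin(seqs)]
            if len(linked):
                rows = linked
        best = None
        for raw in rows["START_DT"]:
            parsed = faers_io.parse_partial_date(raw)
            if parsed is not None and parsed.precision == "day":
                if best is None or parsed.to_date() < best.to_date():
                    best = parsed
        starts[pid] = best

    events = store.set_index("primaryid")["event_dt"]
    classes = {}
    reg = regimens["agents_ps"]
    for pid in pids:
        ps = reg.get(pid, ())
        classes[pid] = cohort.AGENT_CLASS.get(ps[0]) if ps else None

    rows = []
    for pid in sorted(pids):
        ev = faers_io.parse_partial_date(events.get(pid))
        result = tto.compute_tto(starts.get(pid), ev)
        rows.append((pid, classes.get(pid), result.tto_days, result.reason))
    return pd.DataFrame(rows, columns=["primaryid", "ici_class", "tto_days",
                                       "reason"])


def _signal_row(result: disprop.SignalResult) -> dict:
    return {
        "exposure": result.exposure, "n": result.n_cases,
        "ROR": result.ror, "ROR_low": result.ror_low, "ROR_high": result.ror_high,
        "PRR": result.prr, "chi2": result.chi2,
        "EBGM": result.ebgm, "EBGM05": result.ebgm05,
        "IC": result.ic_expect, "IC025": result.ic025,
        "ror_pos": result.flags["ror_pos"], "prr_pos": result.flags["prr_pos"],
        "mgps_pos": result.flags["mgps_pos"], "bcpnn_pos": result.flags["bcpnn_pos"],
        "degenerate": result.degenerate,
    }


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; writes the artifact bundle to
    ``config.out_dir`` and returns the bundle as in-memory objects."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run_log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run_inner(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_inner(config: RunConfig, out: Path) -> dict:
    logger.info("pvsignal %s on python %s", __version__, platform.python_version())
    logger.info("config: %s", json.dumps(dataclasses.asdict(config)))

    dictionary = (cohort.DrugDictionary.from_file(config.drug_dictionary)
                  if config.drug_dictionary else cohort.DrugDictionary.default())
    terms = (cohort.load_terms(config.term_list)
             if config.term_list else cohort.load_default_terms())

    try:
        sets = [faers_io.read_quarter(q, delimiter=config.delimiter)
                for q in config.quarter_dirs]
    except (FileNotFoundError, ValueError) as exc:
        raise RuntimeError(f"stage=read: {exc}") from exc
    tables = _concat_tables(sets)
    store, processing = faers_io.build_report_store(tables)
    faers_io.write_store(store, out, processing)

    regimens = cohort.assign_regimens(tables.drug, dictionary)
    kept = set(store["primaryid"].astype("int64"))
    event_pids = cohort.select_event_reports(tables.reac, terms) & kept
    ici_pids = {
        int(pid) for pid, ps in regimens["agents_ps"].items()
        if ps and pid in kept
    }
    case_pids = event_pids & ici_pids
    cases = store[store["primaryid"].isin(case_pids)]

    summary = cohort.summarize_cohort(
        cases, cohort.indications_for(tables.indi, case_pids))
    _write_cohort_summary(summary, out / "cohort_summary.tsv")

    if config.exposures is None:
        observed_combos = sorted({
            lab for pid, lab in regimens["combo_label"].items()
            if lab and pid in case_pids
        })
        observed_agents = [a for a in cohort.AGENTS if any(
            regimens.loc[pid, "regimen"] == "monotherapy"
            and regimens.loc[pid, "agents_ps"] == (a,)
            for pid in case_pids if pid in regimens.index
        )]
        exposures = (["all"] + list(cohort.CLASSES) + observed_agents
                     + observed_combos)
    else:
        exposures = list(config.exposures)

    try:
        grid = disprop.build_pair_grid(tables.drug, tables.reac, kept)
        hyper = disprop.mgps_fit(grid["a"], grid["E"]) if len(grid) >= 10 else None
    except ValueError as exc:
        logger.warning("MGPS prior fit unavailable: %s", exc)
        hyper = None

    signal_rows = []
    for exposure in exposures:
        table = disprop.build_contingency(store, regimens, event_pids, exposure)
        result = disprop.compute_signal(table, exposure, hyper=hyper,
                                        yates=config.yates)
        signal_rows.append(_signal_row(result))
    signals = pd.DataFrame(signal_rows, columns=list(SIGNAL_COLUMNS))
    signals.to_csv(out / "signals.tsv", sep="\t", index=False)

    # ---- time to onset ------------------------------------------------
    tto_records = extract_tto_records(store, tables.ther, tables.drug,
                                      regimens, case_pids, dictionary)
    valid = tto_records.dropna(subset=["tto_days"])
    groups = {"All ICIs": valid["tto_days"].to_numpy(dtype=float)}
    for cls in cohort.CLASSES:
        groups[cls] = valid.loc[valid["ici_class"] == cls,
                                "tto_days"].to_numpy(dtype=float)

    comparisons = [tuple(c) for c in config.comparisons]
    testable = [c for c in comparisons
                if len(groups.get(c[0], ())) and len(groups.get(c[1], ()))]
    if testable:
        tests = tto.mann_whitney_bonferroni(groups, testable)
        pd.DataFrame([dataclasses.asdict(t) for t in tests]).to_csv(
            out / "tto_tests.tsv", sep="\t", index=False)

    rng = np.random.default_rng(config.seed)
    weib_rows, curve_rows = [], []
    for label, values in groups.items():
        if len(values) == 0:
            continue
        s = tto.summarize_tto(values)
        row = {"group": label, "n": s.n, "median": s.median, "q1": s.q1,
               "q3": s.q3, "min": s.min, "max": s.max}
        if len(values) >= 10 and np.ptp(values) > 0:
            fit = tto.fit_weibull(values, n_boot=config.bootstrap_reps,
                                  seed=int(rng.integers(0, 2**31)))
            row.update({
                "alpha": fit.scale_alpha, "alpha_low": fit.alpha_ci[0],
                "alpha_high": fit.alpha_ci[1],
                "beta": fit.shape_beta, "beta_low": fit.beta_ci[0],
                "beta_high": fit.beta_ci[1], "failure_type": fit.failure_type,
            })
        weib_rows.append(row)
        curve = tto.km_onset(values)
        frac = tto.onset_fractions(values, config.tto_cutpoints)
        row.update(frac)
        for t, p in zip(curve.event_times, curve.cumulative_onset):
            curve_rows.append({"group": label, "time": t,
                               "cumulative_onset": p})
    pd.DataFrame(weib_rows).to_csv(out / "weibull.tsv", sep="\t", index=False)
    pd.DataFrame(curve_rows).to_csv(out / "onset_curves.tsv", sep="\t",
                                    index=False)

    flow = {
        "01_demo_rows_read": int(len(tables.demo)),
        "02_reports_after_dedup": int(len(store)),
        "03_event_reports": int(len(event_pids)),
        "04_event_reports_with_ps_ici": int(len(case_pids)),
        "05_valid_tto_records": int(len(valid)),
    }
    (out / "flow_counts.json").write_text(json.dumps(flow, indent=2))
    logger.info("flow counts: %s", flow)

    return {"store": store, "cohort_summary": summary, "signals": signals,
            "tto_records": tto_records, "flow_counts": flow}


def _write_cohort_summary(summary: cohort.CohortSummary, path: Path) -> None:
    rows = [("n", "cohort", summary.n),
            ("median_age", "years", summary.median_age)]
    for section, counts in (
        ("sex", summary.sex_counts), ("age_band", summary.age_bands),
        ("country", summary.country_counts),
        ("reporter", summary.reporter_counts),
        ("outcome", summary.outcome_counts),
        ("indication", summary.indication_counts),
    ):
        rows.extend((section, k, v) for k, v in counts.items())
    pd.DataFrame(rows, columns=["section", "category", "value"]).to_csv(
        path, sep="\t", index=False)
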