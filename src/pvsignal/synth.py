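"""Synthetic FAERS-format quarters with known ground truth.

The generator emits the six quarterly ASCII tables in the exact dialect
``faers_io.read_quarter`` consumes, with every latent quantity controlled:
per-agent exposure marginals, a multiplicative planted reporting-rate ratio
rho for chosen exposure/event pairs (the event probability is rho * p0 on
signal exposures, p0 elsewhere), per-class Weibull onset-time distributions,
demographic marginals, partial/missing-date degradation, and CASEID
duplication with a strictly later FDA receipt date so the deduplication
rule has a deterministic right answer.

``expected_cells`` returns the closed-form pre-duplication expectations of
the 2x2 cells for any exposure, which doubles as the oracle for the
contingency builder and for CI-coverage experiments; the implied odds ratio
derived from those four expectations is exact, so tests never rely on the
rho ~ ROR approximation holding.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as _cohort
from .faers_io import RawTableSet, TABLE_NAMES

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate",
    "expected_cells",
    "implied_ror",
    "write_dataset",
    "paper_mimic_config",
]

_FILLER_DRUGS = (
    "ASPIRIN", "METFORMIN", "ATORVASTATIN", "OMEPRAZOLE", "LISINOPRIL",
    "AMLODIPINE", "LEVOTHYROXINE", "SIMVASTATIN", "IBUPROFEN", "WARFARIN",
    "GABAPENTIN", "SERTRALINE", "PREDNISONE", "FUROSEMIDE", "INSULIN GLARGINE",
    "CLOPIDOGREL", "PANTOPRAZOLE", "RAMIPRIL", "RIVAROXABAN", "DULOXETINE",
)
_FILLER_PTS = (
    "Nausea", "Headache", "Fatigue", "Rash", "Diarrhoea", "Pyrexia",
    "Dizziness", "Vomiting", "Pruritus", "Dyspnoea", "Arthralgia", "Anaemia",
    "Insomnia", "Cough", "Oedema peripheral", "Constipation", "Hypotension",
    "Renal impairment", "Hepatotoxicity", "Myalgia", "Tremor", "Alopecia",
    "Hyperglycaemia", "Hyponatraemia", "Weight decreased", "Abdominal pain",
    "Palpitations", "Confusional state", "Dry mouth", "Epistaxis",
)
_ICI_INDICATIONS = ("Malignant melanoma", "Non-small cell lung cancer",
                    "Renal cell carcinoma", "Gastric cancer",
                    "Hepatocellular carcinoma")
_OTHER_INDICATIONS = ("Hypertension", "Pain", "Diabetes mellitus")


@dataclass
class SyntheticConfig:
    """Full generative specification of one synthetic quarter."""

    n_reports: int = 50_000
    exposure_probs: dict[str, float] = field(
        default_factory=lambda: {"nivolumab": 0.05})
    combo_fraction: float = 0.0
    background_event_prob: float = 0.001
    signal_rhos: dict[str, float] = field(default_factory=dict)
    event_term: str = "Pemphigoid"
    tto_specs: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "PD-1i": (295.85, 0.83),
            "PD-L1i": (137.83, 0.69),
            "CTLA-4i": (76.24, 0.48),
            "background": (264.3, 0.78),
        })
    tto_valid_fraction: float = 1.0
    sex_probs: tuple[float, float, float] = (0.678, 0.220, 0.102)
    age_band_probs: dict[str, float] = field(
        default_factory=lambda: {"<18": 0.0012, "18-60": 0.1235,
                                 ">60": 0.7012, "missing": 0.1741})
    country_probs: dict[str, float] = field(
        default_factory=lambda: {"JP": 0.294, "US": 0.267, "FR": 0.162,
                                 "DE": 0.10, "IT": 0.09, "ES": 0.087})
    reporter_probs: tuple[float, float, float] = (0.866, 0.132, 0.002)
    outcome_probs: dict[str, float] = field(
        default_factory=lambda: {"HO": 0.361, "LT": 0.028, "DS": 0.016,
                                 "DE": 0.06, "OT": 0.50})
    duplicate_rate: float = 0.0
    fda_tie_fraction: float = 0.0
    quarter: str = "2024Q1"
    seed: int = 0

    def validate(self) -> list[str]:
        problems = []
        if self.n_reports < 0:
            problems.append("n_reports must be nonnegative")
        for agent in self.exposure_probs:
            if agent not in _cohort.AGENT_CLASS:
                problems.append(f"unknown agent '{agent}'")
        total_exp = sum(self.exposure_probs.values())
        if not 0 <= total_exp <= 1:
            problems.append("exposure probabilities must sum into [0, 1]")
        p0 = self.background_event_prob
        if not 0 < p0 < 1:
            problems.append("background_event_prob must lie in (0, 1)")
        for label, rho in self.signal_rhos.items():
            if rho < 1:
                problems.append(f"rho for '{label}' must be >= 1")
            if rho * p0 > 1:
                problems.append(f"rho * p0 > 1 for '{label}'")
        for frac_name in ("combo_fraction", "tto_valid_fraction",
                          "duplicate_rate", "fda_tie_fraction"):
            v = getattr(self, frac_name)
            if not 0 <= v <= 1:
                problems.append(f"{frac_name} out of [0, 1]")
        for probs, name in ((self.sex_probs, "sex_probs"),
                            (tuple(self.age_band_probs.values()), "age_band_probs"),
                            (tuple(self.country_probs.values()), "country_probs"),
                            (self.reporter_probs, "reporter_probs")):
            if abs(sum(probs) - 1.0) > 1e-6:
                problems.append(f"{name} must sum to 1")
        return problems

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["tto_specs"] = {k: list(v) for k, v in self.tto_specs.items()}
        data["sex_probs"] = list(self.sex_probs)
        data["reporter_probs"] = list(self.reporter_probs)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["tto_specs"] = {k: tuple(v) for k, v in data["tto_specs"].items()}
        data["sex_probs"] = tuple(data["sex_probs"])
        data["reporter_probs"] = tuple(data["reporter_probs"])
        return cls(**data)


@dataclass
class GroundTruth:
    """Latent truth of a generated quarter, for oracle-style tests."""

    expected_cells: dict[str, tuple[float, float, float, float]]
    weibull: dict[str, tuple[float, float]]
    reports: pd.DataFrame  # pid, exposure_label, planted_event, duplicate_of
    n_duplicates: int

    def to_json(self) -> str:
        return json.dumps({
            "expected_cells": {k: list(v) for k, v in self.expected_cells.items()},
            "weibull": {k: list(v) for k, v in self.weibull.items()},
            "n_duplicates": self.n_duplicates,
        }, indent=2, sort_keys=True)


@dataclass
class SyntheticDataset:
    tables: dict[str, pd.DataFrame]
    ground_truth: GroundTruth
    config: SyntheticConfig


# ---------------------------------------------------------------------------
# closed-form expectations


def _strata(config: SyntheticConfig):
    """Mutually exclusive report strata: (label, ps_agent or None, prob,
    event_prob).  Combination strata are ordered by which agent is primary
    suspect; their printed label is the canonical unordered one."""
    p0 = config.background_event_prob
    rho = config.signal_rhos
    agents = list(config.exposure_probs)
    cf = config.combo_fraction
    out = []
    for i, agent in enumerate(agents):
        p_i = config.exposure_probs[agent]
        out.append((agent, agent, p_i * (1 - cf),
                    p0 * rho.get(agent, 1.0)))
        if cf > 0:
            partners = [a for a in _cohort.AGENTS if a != agent]
            for partner in partners:
                pair = tuple(sorted({agent, partner}, key=_cohort.AGENTS.index))
                label = "+".join(_cohort.AGENT_ABBREV[x] for x in pair)
                out.append((label, agent, p_i * cf / len(partners),
                            p0 * rho.get(label, 1.0)))
    p_none = 1.0 - sum(config.exposure_probs.values())
    out.append(("__none__", None, p_none, p0))
    return out


def _stratum_in_exposure(label: str, ps_agent: str | None, exposure: str) -> bool:
    if ps_agent is None:
        return False
    if exposure == "all":
        return True
    if exposure in _cohort.CLASSES:
        return _cohort.AGENT_CLASS[ps_agent] == exposure
    if "+" in exposure:
        return label == exposure
    return label == exposure  # monotherapy stratum labelled by agent


def expected_cells(config: SyntheticConfig, exposure: str):
    """Pre-duplication expectations of (a, b, c, d) for one exposure.

    Exact under the generative model; the implied asymptotic odds ratio is
    (a*d)/(b*c) of these four numbers.
    """
    known = {s[0] for s in _strata(config)} | set(_cohort.CLASSES) | {"all"}
    if exposure not in known:
        raise ValueError(f"exposure '{exposure}' not present in config")
    n = config.n_reports
    a = b = c = d = 0.0
    for label, ps_agent, prob, pe in _strata(config):
        if _stratum_in_exposure(label, ps_agent, exposure):
            a += n * prob * pe
            b += n * prob * (1 - pe)
        else:
            c += n * prob * pe
            d += n * prob * (1 - pe)
    return a, b, c, d


def implied_ror(config: SyntheticConfig, exposure: str) -> float:
    a, b, c, d = expected_cells(config, exposure)
    return (a * d) / (b * c)


# ---------------------------------------------------------------------------
# generation


def _quarter_bounds(quarter: str):
    year, qn = int(quarter[:4]), int(quarter[5])
    start = np.datetime64(f"{year}-{3 * (qn - 1) + 1:02d}-01")
    if qn == 4:
        end = np.datetime64(f"{year + 1}-01-01")
    else:
        end = np.datetime64(f"{year}-{3 * qn + 1:02d}-01")
    return start, end


def _fmt_dates(days: np.ndarray) -> np.ndarray:
    """numpy datetime64[D] -> FAERS 8-digit strings."""
    if days.size == 0:
        return np.empty(0, dtype=object)
    iso = np.datetime_as_string(days, unit="D")
    return np.char.replace(iso, "-", "")


def generate(config: SyntheticConfig,
             out_dir: str | Path | None = None) -> SyntheticDataset:
    """Draw one synthetic quarter; optionally write it to ``out_dir``.

    Deterministic for a fixed config (all randomness flows from
    ``config.seed``).  Returns the in-memory tables plus ground truth;
    when ``out_dir`` is given the six ASCII tables and a
    ``ground_truth.json`` are written there as well.
    """
    problems = config.validate()
    if problems:
        raise ValueError("invalid synthetic config: " + "; ".join(problems))
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    agents = list(config.exposure_probs)
    probs = np.array([config.exposure_probs[a] for a in agents])
    p_none = 1.0 - probs.sum()
    choice = rng.choice(len(agents) + 1, size=n,
                        p=np.append(probs, p_none))
    exposed = choice < len(agents)
    primary_agent = np.array([agents[i] if i < len(agents) else ""
                              for i in choice], dtype=object)

    # combinations: a fraction of exposed reports carries a second ICI (SS)
    second_agent = np.full(n, "", dtype=object)
    labels = primary_agent.copy()
    labels[~exposed] = "__none__"
    if config.combo_fraction > 0:
        is_combo = exposed & (rng.random(n) < config.combo_fraction)
        for i in np.flatnonzero(is_combo):
            partners = [a for a in _cohort.AGENTS if a != primary_agent[i]]
            second_agent[i] = partners[rng.integers(0, len(partners))]
            pair = tuple(sorted({primary_agent[i], second_agent[i]},
                                key=_cohort.AGENTS.index))
            labels[i] = "+".join(_cohort.AGENT_ABBREV[x] for x in pair)
    else:
        is_combo = np.zeros(n, dtype=bool)

    p0 = config.background_event_prob
    rho_per_report = pd.Series(labels).map(config.signal_rhos).fillna(1.0)
    pe = np.where(exposed, p0 * rho_per_report.to_numpy(), p0)
    event = rng.random(n) < pe

    # onset times per primary-suspect class (background for unexposed)
    classes = np.array([
        _cohort.AGENT_CLASS.get(a, "background") if a else "background"
        for a in primary_agent
    ], dtype=object)
    tto = np.ones(n)
    for cls, (scale, shape) in config.tto_specs.items():
        mask = classes == cls
        if mask.any():
            tto[mask] = scale * rng.weibull(shape, size=int(mask.sum()))
    tto_days = np.maximum(1, np.ceil(tto)).astype("int64")

    qstart, qend = _quarter_bounds(config.quarter)
    span = int((qend - qstart) / np.timedelta64(1, "D"))
    event_day = qstart + rng.integers(0, span, size=n).astype("timedelta64[D]")
    start_day = event_day - tto_days.astype("timedelta64[D]")
    fda_day = event_day + rng.integers(7, 97, size=n).astype("timedelta64[D]")

    event_str = _fmt_dates(event_day).astype(object)
    start_str = _fmt_dates(start_day).astype(object)
    # degrade a (1 - valid) share of dates to partial/missing forms
    degraded = rng.random(n) >= config.tto_valid_fraction
    mode = rng.integers(0, 5, size=n)
    s = pd.Series(start_str, dtype=object)
    e = pd.Series(event_str, dtype=object)
    s[degraded & (mode == 0)] = s[degraded & (mode == 0)].str[:6]
    s[degraded & (mode == 1)] = s[degraded & (mode == 1)].str[:4]
    s[degraded & (mode == 2)] = ""
    e[degraded & (mode == 3)] = e[degraded & (mode == 3)].str[:6]
    e[degraded & (mode == 4)] = ""
    start_str = s.to_numpy(dtype=object)
    event_str = e.to_numpy(dtype=object)

    pid = (np.arange(n, dtype="int64") + 1) * 10
    caseid = np.array([f"C{i + 1:08d}" for i in range(n)], dtype=object)

    sex = rng.choice(["M", "F", "UNK"], size=n, p=list(config.sex_probs))
    band_names = list(config.age_band_probs)
    band = rng.choice(band_names, size=n,
                      p=list(config.age_band_probs.values()))
    age = np.empty(n, dtype=object)
    lo_hi = {"<18": (1, 18), "18-60": (18, 61), ">60": (61, 91)}
    for name, (lo, hi) in lo_hi.items():
        mask = band == name
        age[mask] = rng.integers(lo, hi, size=int(mask.sum())).astype(str)
    age[band == "missing"] = ""
    age_cod = np.where(age == "", "", "YR")
    country = rng.choice(list(config.country_probs), size=n,
                         p=list(config.country_probs.values()))
    occp = rng.choice(["MD", "CN", ""], size=n, p=list(config.reporter_probs))

    demo = pd.DataFrame({
        "PRIMARYID": pid.astype(str),
        "CASEID": caseid,
        "FDA_DT": _fmt_dates(fda_day),
        "EVENT_DT": event_str,
        "SEX": sex,
        "AGE": age,
        "AGE_COD": age_cod,
        "OCCR_COUNTRY": country,
        "OCCP_COD": occp,
    })

    # DRUG + THER: ICI rows (PS, optional SS partner) or one filler drug
    fancy = rng.random(n) < 0.2  # some names carry a formulation tail
    # Zipf-like background margins: spontaneous-report databases are skewed
    zipf_d = 1.0 / np.arange(1, len(_FILLER_DRUGS) + 1)
    filler = rng.choice(_FILLER_DRUGS, size=n, p=zipf_d / zipf_d.sum())
    spid = pid.astype(str)
    name = np.where(
        exposed,
        np.char.upper(primary_agent.astype(str)), filler).astype(object)
    name[exposed & fancy] = name[exposed & fancy] + " (INJECTION)"
    drug = pd.DataFrame({"PRIMARYID": spid, "DRUG_SEQ": "1",
                         "DRUGNAME": name, "ROLE_COD": "PS"})
    combo_idx = np.flatnonzero(second_agent != "")
    if combo_idx.size:
        extra = pd.DataFrame({
            "PRIMARYID": spid[combo_idx], "DRUG_SEQ": "2",
            "DRUGNAME": np.char.upper(second_agent[combo_idx].astype(str)),
            "ROLE_COD": "SS"})
        drug = pd.concat([drug, extra], ignore_index=True)
        drug = drug.sort_values(
            ["PRIMARYID", "DRUG_SEQ"],
            key=lambda s: s.astype("int64") if s.name == "PRIMARYID" else s,
            kind="mergesort").reset_index(drop=True)
    ther = pd.DataFrame({"PRIMARYID": spid, "DSG_DRUG_SEQ": "1",
                         "START_DT": start_str})
    indi = pd.DataFrame({
        "PRIMARYID": spid,
        "INDI_PT": np.where(exposed, rng.choice(_ICI_INDICATIONS, size=n),
                            rng.choice(_OTHER_INDICATIONS, size=n)),
    })

    # REAC: the planted event term for cases, one filler PT for the rest
    zipf_p = 1.0 / np.arange(1, len(_FILLER_PTS) + 1)
    pt = np.where(event, config.event_term,
                  rng.choice(_FILLER_PTS, size=n, p=zipf_p / zipf_p.sum()))
    reac = pd.DataFrame({"PRIMARYID": pid.astype(str), "PT": pt})

    # OUTC: independent per-category indicators
    outc_parts = []
    for code, p in config.outcome_probs.items():
        hit = np.flatnonzero(rng.random(n) < p)
        outc_parts.append(pd.DataFrame({"PRIMARYID": spid[hit],
                                        "OUTC_COD": code}))
    outc = (pd.concat(outc_parts, ignore_index=True)
            if outc_parts else
            pd.DataFrame(columns=["PRIMARYID", "OUTC_COD"]))
    if len(outc):
        outc = outc.sort_values(
            "PRIMARYID", key=lambda sr: sr.astype("int64"),
            kind="mergesort").reset_index(drop=True)

    tables = {"demo": demo, "drug": drug, "reac": reac, "ther": ther,
              "outc": outc, "indi": indi}

    # duplicates: a later report version of the same case; strictly later
    # FDA_DT unless the tie flag exercises the PRIMARYID tiebreak
    dup_map: dict[int, int] = {}
    dup_idx = np.flatnonzero(rng.random(n) < config.duplicate_rate)
    if dup_idx.size:
        tie = rng.random(dup_idx.size) < config.fda_tie_fraction
        dup_pid = pid[dup_idx] + 5
        dup_fda = fda_day[dup_idx] + np.where(
            tie, 0, rng.integers(1, 30, size=dup_idx.size)
        ).astype("timedelta64[D]")
        dup_demo = demo.iloc[dup_idx].copy()
        dup_demo["PRIMARYID"] = dup_pid.astype(str)
        dup_demo["FDA_DT"] = _fmt_dates(dup_fda)
        tables["demo"] = pd.concat([demo, dup_demo], ignore_index=True)
        old_new = dict(zip(pid[dup_idx].astype(str), dup_pid.astype(str)))
        for name in ("drug", "reac", "ther", "outc", "indi"):
            t = tables[name]
            extra = t[t["PRIMARYID"].isin(old_new)].copy()
            extra["PRIMARYID"] = extra["PRIMARYID"].map(old_new)
            tables[name] = pd.concat([t, extra], ignore_index=True)
        dup_map = {int(v): int(k) for k, v in old_new.items()}

    exposures = set(labels) - {"__none__"}
    exposures |= {"all"} | {
        _cohort.AGENT_CLASS[a] for a in agents
    }
    truth = GroundTruth(
        expected_cells={e: expected_cells(config, e) for e in sorted(exposures)},
        weibull=dict(config.tto_specs),
        reports=pd.DataFrame({
            "primaryid": pid,
            "exposure_label": labels,
            "planted_event": event,
            "tto_days": tto_days,
        }),
        n_duplicates=int(dup_idx.size),
    )
    dataset = SyntheticDataset(tables=tables, ground_truth=truth, config=config)
    if out_dir is not None:
        write_dataset(dataset, out_dir)
    return dataset


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path,
                  delimiter: str = "$") -> Path:
    """Write the six ASCII tables plus ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in TABLE_NAMES:
        frame = dataset.tables[name]
        path = out / f"{name.upper()}.txt"
        frame.to_csv(path, sep=delimiter, index=False, lineterminator="\n")
    (out / "ground_truth.json").write_text(dataset.ground_truth.to_json())
    return out


def as_tableset(dataset: SyntheticDataset) -> RawTableSet:
    """Wrap in-memory tables as a RawTableSet (skips the disk round trip)."""
    return RawTableSet(
        **{k: v.copy() for k, v in dataset.tables.items()},
        source_quarter=dataset.config.quarter,
    )


def paper_mimic_config(n_reports: int = 200_000, seed: int = 0) -> SyntheticConfig:
    """A configuration whose marginals mirror the published irBP reporting
    profile: per-agent reporting-rate ratios near the published RORs, agent
    exposure marginals chosen so expected case shares across the three ICI
    classes are 87.5 / 7.3 / 5.2 percent, male share 67.8%, valid-TTO share
    29.29%, and the published per-class Weibull onset parameters."""
    case_counts = {"nivolumab": 530, "pembrolizumab": 180, "cemiplimab": 24,
                   "tislelizumab": 10, "atezolizumab": 40, "avelumab": 3,
                   "durvalumab": 19, "ipilimumab": 44}
    rhos = {"nivolumab": 30.0, "pembrolizumab": 11.2, "cemiplimab": 38.0,
            "tislelizumab": 18.7, "atezolizumab": 6.4, "avelumab": 6.05,
            "durvalumab": 6.8, "ipilimumab": 8.8, "Nivo+Ipi": 12.7}
    weights = {a: case_counts[a] / rhos[a] for a in case_counts}
    # a small ICI share keeps the whole-database comparator essentially
    # free of the planted signals, as in the real database where ICI
    # reports are a sliver of all spontaneous reports
    total_ici = 0.01
    z = sum(weights.values())
    exposure_probs = {a: total_ici * w / z for a, w in weights.items()}
    return SyntheticConfig(
        n_reports=n_reports,
        exposure_probs=exposure_probs,
        combo_fraction=0.02,
        background_event_prob=0.005,
        signal_rhos=rhos,
        tto_valid_fraction=0.2929,
        duplicate_rate=0.05,
        seed=seed,
    )
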