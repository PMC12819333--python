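"""Cohort construction: drug-name mapping, event selection, regimens, Table-1
style demographic summaries.

Immune checkpoint inhibitors (ICIs) are grouped into three classes by
target: PD-1, PD-L1 and CTLA-4.  A report enters an exposure cohort only if
an ICI is its primary suspected drug (ROLE_COD = PS); monotherapy means a
single ICI on the report, combination means two or more ICIs with at least
one PS.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AGENTS",
    "AGENT_CLASS",
    "CLASSES",
    "DrugDictionary",
    "RegimenAssignment",
    "CohortSummary",
    "load_default_terms",
    "normalize_drug_name",
    "select_event_reports",
    "classify_regimen",
    "assign_regimens",
    "summarize_cohort",
]

#: canonical agent order (PD-1, then PD-L1, then CTLA-4 agents)
AGENTS = (
    "nivolumab", "pembrolizumab", "cemiplimab", "dostarlimab", "tislelizumab",
    "atezolizumab", "avelumab", "durvalumab",
    "ipilimumab", "tremelimumab",
)

AGENT_CLASS = {
    "nivolumab": "PD-1i", "pembrolizumab": "PD-1i", "cemiplimab": "PD-1i",
    "dostarlimab": "PD-1i", "tislelizumab": "PD-1i",
    "atezolizumab": "PD-L1i", "avelumab": "PD-L1i", "durvalumab": "PD-L1i",
    "ipilimumab": "CTLA-4i", "tremelimumab": "CTLA-4i",
}

CLASSES = ("PD-1i", "PD-L1i", "CTLA-4i")

#: short labels for combination regimens, e.g. "Nivo+Ipi"
AGENT_ABBREV = {
    "nivolumab": "Nivo", "pembrolizumab": "Pem", "cemiplimab": "Cemi",
    "dostarlimab": "Dost", "tislelizumab": "Tis",
    "atezolizumab": "Ate", "avelumab": "Ave", "durvalumab": "Dur",
    "ipilimumab": "Ipi", "tremelimumab": "Tre",
}

_AGE_BANDS = ("<18", "18-60", ">60", "missing")

_PUNCT_RE = re.compile(r"[^\w\s-]")
_WS_RE = re.compile(r"\s+")


def normalize_drug_name(raw: str) -> str:
    """Normalize a raw DRUGNAME for dictionary lookup: uppercase, cut any
    dosage/formulation tail after the first comma or parenthesis, collapse
    punctuation and whitespace."""
    s = str(raw).upper()
    for cut in (",", "("):
        idx = s.find(cut)
        if idx >= 0:
            s = s[:idx]
    s = _PUNCT_RE.sub("", s)
    return _WS_RE.sub(" ", s).strip()


class DrugDictionary:
    """Maps normalized raw drug names to (agent, class) pairs.

    The packaged default covers generic and brand synonyms of the ten ICI
    agents; users can extend it via a two-column TSV (raw_name<TAB>agent).
    """

    def __init__(self, entries: dict[str, str]):
        for agent in entries.values():
            if agent not in AGENT_CLASS:
                raise ValueError(f"unknown agent '{agent}' in drug dictionary")
        self._entries = {normalize_drug_name(k): v for k, v in entries.items()}

    @classmethod
    def default(cls) -> "DrugDictionary":
        ref = importlib.resources.files("pvsignal.data") / "drug_dictionary.tsv"
        return cls.from_file(ref)

    @classmethod
    def from_file(cls, path) -> "DrugDictionary":
        entries: dict[str, str] = {}
        for line in Path(str(path)).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            raw, agent = line.split("\t")
            entries[raw] = agent.strip()
        return cls(entries)

    def map_drug(self, raw_name: str) -> tuple[str, str] | None:
        """Return (agent, class) for an ICI drug name, else None."""
        agent = self._entries.get(normalize_drug_name(raw_name))
        if agent is None:
            return None
        return agent, AGENT_CLASS[agent]

    def map_series(self, names: pd.Series) -> pd.Series:
        """Vectorized agent lookup (agent name or NaN) for a DRUGNAME column."""
        uniq = names.dropna().unique()
        table = {u: (self.map_drug(u) or (None,))[0] for u in uniq}
        return names.map(table)


def load_default_terms() -> list[str]:
    """The packaged pemphigoid preferred-term list (flat stand-in for the
    MedDRA standardized query)."""
    ref = importlib.resources.files("pvsignal.data") / "pemphigoid_terms.txt"
    return load_terms(ref)


def load_terms(path) -> list[str]:
    terms = [t.strip() for t in Path(str(path)).read_text().splitlines() if t.strip()]
    return terms


def select_event_reports(reac: pd.DataFrame, term_list: list[str]) -> set[int]:
    """PRIMARYIDs of reports carrying any listed preferred term.

    Matching is case-insensitive after whitespace trimming.  An empty term
    list is a configuration error, not an empty cohort.
    """
    if not term_list:
        raise ValueError("event term list is empty")
    wanted = {t.strip().casefold() for t in term_list}
    hit = reac["PT"].str.strip().str.casefold().isin(wanted)
    pids = pd.to_numeric(reac.loc[hit, "PRIMARYID"], errors="coerce").dropna()
    return set(pids.astype("int64").tolist())


@dataclass(frozen=True)
class RegimenAssignment:
    primaryid: int
    agents_ps: tuple[str, ...]
    agents_any: tuple[str, ...]
    regimen: str  # monotherapy | combination | none
    combo_label: str | None = None


def _canon_sort(agents) -> tuple[str, ...]:
    return tuple(sorted(set(agents), key=AGENTS.index))


def _assign_one(pid: int, ps: tuple[str, ...], anyrole: tuple[str, ...]) -> RegimenAssignment:
    if not ps:
        return RegimenAssignment(pid, (), anyrole, "none")
    if len(anyrole) == 1:
        return RegimenAssignment(pid, ps, anyrole, "monotherapy")
    label = "+".join(AGENT_ABBREV[a] for a in anyrole)
    return RegimenAssignment(pid, ps, anyrole, "combination", label)


def classify_regimen(drug_rows: pd.DataFrame,
                     dictionary: DrugDictionary | None = None) -> RegimenAssignment:
    """Classify the therapy regimen of a single report's DRUG rows."""
    dictionary = dictionary or DrugDictionary.default()
    pid = int(drug_rows["PRIMARYID"].iloc[0]) if len(drug_rows) else 0
    ps, anyrole = [], []
    for row in drug_rows.itertuples():
        mapped = dictionary.map_drug(row.DRUGNAME)
        if mapped is None:
            continue
        agent = mapped[0]
        anyrole.append(agent)
        if str(row.ROLE_COD).strip().upper() == "PS":
            ps.append(agent)
    return _assign_one(pid, _canon_sort(ps), _canon_sort(anyrole))


def assign_regimens(drug: pd.DataFrame,
                    dictionary: DrugDictionary | None = None) -> pd.DataFrame:
    """Regimen assignment for every report in a DRUG table at once.

    Returns a frame indexed by primaryid with columns agents_ps, agents_any
    (canonically ordered tuples), regimen and combo_label.
    """
    dictionary = dictionary or DrugDictionary.default()
    work = drug[["PRIMARYID", "DRUGNAME", "ROLE_COD"]].copy()
    work["primaryid"] = pd.to_numeric(work["PRIMARYID"], errors="coerce")
    work = work.dropna(subset=["primaryid"])
    work["primaryid"] = work["primaryid"].astype("int64")
    work["agent"] = dictionary.map_series(work["DRUGNAME"])
    work = work.dropna(subset=["agent"])
    work["is_ps"] = work["ROLE_COD"].str.strip().str.upper() == "PS"

    # accumulate per-report agent sets with one pass over the (small)
    # ICI-row subset instead of a pandas group loop
    acc: dict[int, tuple[list, list]] = {}
    for pid, agent, is_ps in zip(work["primaryid"], work["agent"],
                                 work["is_ps"]):
        slot = acc.setdefault(int(pid), ([], []))
        slot[1].append(agent)
        if is_ps:
            slot[0].append(agent)
    rows = [
        _assign_one(pid, _canon_sort(ps), _canon_sort(anyrole))
        for pid, (ps, anyrole) in sorted(acc.items())
    ]
    frame = pd.DataFrame(
        {
            "agents_ps": [r.agents_ps for r in rows],
            "agents_any": [r.agents_any for r in rows],
            "regimen": [r.regimen for r in rows],
            "combo_label": [r.combo_label for r in rows],
        },
        index=pd.Index([r.primaryid for r in rows], name="primaryid"),
    )
    return frame


@dataclass
class CohortSummary:
    """Demographic breakdowns of a deduplicated report cohort.

    Sex, age-band, country and reporter counts each sum to ``n``; outcome
    counts are per report per category and may exceed ``n`` in total because
    a report can carry several outcomes.
    """

    n: int
    sex_counts: dict[str, int] = field(default_factory=dict)
    age_bands: dict[str, int] = field(default_factory=dict)
    median_age: float | None = None
    country_counts: dict[str, int] = field(default_factory=dict)
    reporter_counts: dict[str, int] = field(default_factory=dict)
    outcome_counts: dict[str, int] = field(default_factory=dict)
    indication_counts: dict[str, int] = field(default_factory=dict)


def _age_band(age: float | None) -> str:
    if age is None or (isinstance(age, float) and np.isnan(age)):
        return "missing"
    if age < 18:
        return "<18"
    if age <= 60:
        return "18-60"
    return ">60"


def _top_k(series: pd.Series, k: int) -> dict[str, int]:
    counts = series.dropna().value_counts()
    # ties broken alphabetically for determinism
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return dict(ordered[:k])


def summarize_cohort(reports: pd.DataFrame,
                     indications: pd.Series | None = None,
                     top_k_countries: int = 3,
                     top_k_indications: int = 5) -> CohortSummary:
    """Summarize a report-store cohort the way Table-1 style outputs do.

    Age bands are <18 / 18-60 / >60 with both band edges in the middle
    band; the median age is the standard sample median over non-missing
    ages.  An empty cohort yields a summary of zeros with median missing.
    """
    n = int(len(reports))
    summary = CohortSummary(n=n)
    summary.sex_counts = {
        cat: 0 for cat in ("male", "female", "unspecified")
    }
    summary.age_bands = {b: 0 for b in _AGE_BANDS}
    if n == 0:
        return summary

    for cat, cnt in reports["sex"].value_counts().items():
        summary.sex_counts[cat] = int(cnt)
    bands = reports["age_years"].map(_age_band)
    for band, cnt in bands.value_counts().items():
        summary.age_bands[band] = int(cnt)
    ages = reports["age_years"].dropna()
    summary.median_age = float(ages.median()) if len(ages) else None
    summary.country_counts = _top_k(reports["country"], top_k_countries)
    summary.reporter_counts = {
        k: int(v) for k, v in reports["reporter"].value_counts().items()
    }
    outcome_lists = reports["outcomes"].fillna("missing").str.split(",")
    summary.outcome_counts = {
        k: int(v) for k, v in outcome_lists.explode().value_counts().items()
    }
    if indications is not None:
        summary.indication_counts = _top_k(indications, top_k_indications)
    return summary


def indications_for(indi: pd.DataFrame, pids: set[int]) -> pd.Series:
    """All indication preferred terms attached to the given reports."""
    work = indi.copy()
    work["primaryid"] = pd.to_numeric(work["PRIMARYID"], errors="coerce")
    work = work.dropna(subset=["primaryid"])
    work = work[work["primaryid"].astype("int64").isin(pids)]
    return work["INDI_PT"].str.strip()
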