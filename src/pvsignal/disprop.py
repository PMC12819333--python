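"""Disproportionality signal detection on spontaneous-report 2x2 tables.

Four complementary estimators of over-reporting for a drug-event pair, each
with the positivity criterion conventional in pharmacovigilance:

* ROR  - reporting odds ratio ad/bc with a Woolf (log-normal) 95% CI;
         signal if ROR > 1, CI lower bound > 1 and a >= 3 reports.
* PRR  - proportional reporting ratio [a/(a+b)]/[c/(c+d)] with a Pearson
         chi-square on the 2x2; signal if PRR >= 2, chi2 >= 4 and a >= 3.
* BCPNN - Bayesian confidence propagation neural network information
         component IC = log2 P(x,y)/(P(x)P(y)) under Beta/Dirichlet priors,
         evaluated by the closed-form posterior approximation; signal if the
         2.5th posterior percentile IC025 > 0.
* MGPS - multi-item gamma Poisson shrinker: an empirical-Bayes mixture of
         two gamma priors on the relative reporting rate lambda, fitted by
         maximum marginal likelihood over the whole drug-event grid;
         EBGM = posterior geometric mean of lambda, EBGM05 its 5th posterior
         percentile; signal if EBGM05 > 2.

The unit of counting is always the deduplicated report: a = reports with
both exposure and event, b = exposure only, c = event only, d = neither.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from . import cohort as _cohort

__all__ = [
    "ContingencyTable",
    "SignalResult",
    "MgpsHyperparams",
    "BCPNN_PRIORS",
    "build_contingency",
    "build_pair_grid",
    "ror_stat",
    "prr_stat",
    "bcpnn_ic",
    "mgps_fit",
    "mgps_ebgm",
    "evaluate_criteria",
    "compute_signal",
]

#: z for two-sided 95% intervals (ROR CI and IC025); pinned in one place.
Z_95 = 1.96

#: BCPNN prior constants: joint cell gamma11, row/column alpha1, beta1 and
#: totals alpha, beta of the Dirichlet/Beta priors.
BCPNN_PRIORS = {"alpha1": 1.0, "beta1": 1.0, "alpha": 2.0, "beta": 2.0,
                "gamma11": 1.0}


@dataclass(frozen=True)
class ContingencyTable:
    """Whole-database 2x2 report counts for one exposure/event pair."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0:
                raise ValueError("negative cell count")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def haldane(self) -> "ContingencyTable":
        """Add 0.5 to every cell (zero-cell correction for ROR/PRR)."""
        return ContingencyTable(self.a + 0.5, self.b + 0.5,
                                self.c + 0.5, self.d + 0.5)

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


@dataclass
class MgpsHyperparams:
    """Fitted two-component gamma mixture prior for MGPS."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    mix_p: float
    loglik: float

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be positive")
        if not 0 < self.mix_p < 1:
            raise ValueError("mixture weight must lie in (0, 1)")


@dataclass
class SignalResult:
    exposure: str
    n_cases: int
    ror: float
    ror_low: float
    ror_high: float
    prr: float
    chi2: float
    ic_expect: float
    ic_var: float
    ic025: float
    ebgm: float | None
    ebgm05: float | None
    degenerate: bool
    flags: dict[str, bool]


def _exposure_mask(regimens: pd.DataFrame, exposure: str) -> pd.Series:
    """Boolean exposure membership per report, per the regimen rules."""
    if exposure == "all":
        return regimens["agents_ps"].map(bool)
    if exposure in _cohort.CLASSES:
        members = {a for a, c in _cohort.AGENT_CLASS.items() if c == exposure}
        return regimens["agents_ps"].map(lambda ps: bool(members & set(ps)))
    if "+" in exposure:
        return regimens["combo_label"] == exposure
    if exposure in _cohort.AGENT_CLASS:
        return (regimens["regimen"] == "monotherapy") & regimens[
            "agents_ps"].map(lambda ps: ps == (exposure,))
    raise ValueError(f"unknown exposure spec '{exposure}'")


def build_contingency(store: pd.DataFrame, regimens: pd.DataFrame,
                      event_pids: set[int], exposure: str) -> ContingencyTable:
    """Count the whole-store 2x2 table for one exposure specification.

    ``exposure`` may name a single agent (monotherapy reports of that
    agent), a class ("PD-1i", "PD-L1i", "CTLA-4i": any report whose primary
    suspect set intersects the class), a combination label ("Nivo+Ipi"), or
    "all" (any report with a primary-suspect ICI).
    """
    if store.empty:
        raise ValueError("empty report store")
    pids = store["primaryid"].astype("int64")
    reg = regimens.reindex(pids)
    reg["agents_ps"] = reg["agents_ps"].apply(
        lambda v: v if isinstance(v, tuple) else ())
    reg["regimen"] = reg["regimen"].fillna("none")
    exposed = _exposure_mask(reg, exposure).to_numpy()
    event = pids.isin(event_pids).to_numpy()
    a = int((exposed & event).sum())
    b = int((exposed & ~event).sum())
    c = int((~exposed & event).sum())
    d = int((~exposed & ~event).sum())
    return ContingencyTable(a, b, c, d)


def ror_stat(table: ContingencyTable) -> tuple[float, float, float]:
    """Reporting odds ratio with Woolf 95% CI (Haldane-corrected on zeros)."""
    t = table.haldane() if table.has_zero_cell else table
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return ror, ror * math.exp(-Z_95 * se), ror * math.exp(Z_95 * se)


def prr_stat(table: ContingencyTable, yates: bool = False) -> tuple[float, float]:
    """Proportional reporting ratio and the 2x2 Pearson chi-square.

    The chi-square is uncorrected by default; ``yates=True`` applies the
    continuity correction.  The Haldane rule is applied first when a cell
    is zero, matching the ROR treatment.
    """
    t = table.haldane() if table.has_zero_cell else table
    prr = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    obs = np.array([[t.a, t.b], [t.c, t.d]])
    chi2 = stats.chi2_contingency(obs, correction=yates).statistic
    return prr, float(chi2)


def bcpnn_ic(table: ContingencyTable) -> tuple[float, float, float]:
    """Closed-form BCPNN information component: (IC, Var[IC], IC025).

    Uses the standard closed-form posterior approximation with priors
    alpha1 = beta1 = gamma11 = 1 and alpha = beta = 2; IC025 is the normal
    lower bound IC - 1.96 sqrt(Var).  Defined for a = 0; no cell correction
    is applied.
    """
    p = BCPNN_PRIORS
    a, cx, cy, C = table.a, table.a + table.b, table.a + table.c, table.n
    if C <= 0:
        raise ValueError("empty table")
    g11 = p["gamma11"]
    gamma = g11 * (C + p["alpha"]) * (C + p["beta"]) / (
        (cx + p["alpha1"]) * (cy + p["beta1"]))
    ic = math.log2(
        (a + g11) * (C + p["alpha"]) * (C + p["beta"])
        / ((C + gamma) * (cx + p["alpha1"]) * (cy + p["beta1"]))
    )
    var = (1 / math.log(2) ** 2) * (
        (C - a + gamma - g11) / ((a + g11) * (1 + C + gamma))
        + (C - cx + p["alpha"] - p["alpha1"]) / ((cx + p["alpha1"]) * (1 + C + p["alpha"]))
        + (C - cy + p["beta"] - p["beta1"]) / ((cy + p["beta1"]) * (1 + C + p["beta"]))
    )
    return ic, var, ic - Z_95 * math.sqrt(var)


# ---------------------------------------------------------------------------
# MGPS


def build_pair_grid(drug: pd.DataFrame, reac: pd.DataFrame,
                    pids: set[int]) -> pd.DataFrame:
    """Full drug x event grid of report counts and null expectations.

    For every (drug name, preferred term) pair over the kept reports the
    observed report count a_ij is tallied; the expected count is the
    independence value E_ij = n_i. n_.j / N.  Zero cells are materialized:
    the MGPS prior is fitted to the complete grid.
    """
    d = drug.copy()
    d["primaryid"] = pd.to_numeric(d["PRIMARYID"], errors="coerce")
    d = d.dropna(subset=["primaryid"])
    d["primaryid"] = d["primaryid"].astype("int64")
    d = d[d["primaryid"].isin(pids)]
    d["item"] = d["DRUGNAME"].str.strip().str.upper()
    r = reac.copy()
    r["primaryid"] = pd.to_numeric(r["PRIMARYID"], errors="coerce")
    r = r.dropna(subset=["primaryid"])
    r["primaryid"] = r["primaryid"].astype("int64")
    r = r[r["primaryid"].isin(pids)]
    r["pt"] = r["PT"].str.strip().str.casefold()

    drug_sets = d.drop_duplicates(["primaryid", "item"])
    pt_sets = r.drop_duplicates(["primaryid", "pt"])
    pairs = drug_sets.merge(pt_sets, on="primaryid")
    a = pairs.groupby(["item", "pt"]).size()

    n_total = len(pids)
    row_tot = drug_sets.groupby("item").size()
    col_tot = pt_sets.groupby("pt").size()
    grid = pd.MultiIndex.from_product([row_tot.index, col_tot.index],
                                      names=["item", "pt"])
    out = pd.DataFrame(index=grid)
    out["a"] = a.reindex(grid, fill_value=0).astype("int64")
    out["E"] = (row_tot.reindex(grid, level="item").to_numpy()
                * col_tot.reindex(grid, level="pt").to_numpy()) / n_total
    return out.reset_index()


_MGPS_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


#: box for the log/logit-transformed hyperparameters; outside it the
#: negative-binomial pmf loses numerical meaning (hyperparameters up to
#: e^12 ~ 1.6e5 already approximate a point-mass prior arbitrarily well)
_MGPS_BOX = 12.0


def _mixture_loglik(params: np.ndarray, a: np.ndarray, E: np.ndarray) -> float:
    excess = np.abs(params) - _MGPS_BOX
    if np.any(excess > 0):
        return -1e12 * (1.0 + float(excess[excess > 0].sum()))
    a1, b1, a2, b2 = np.exp(params[:4])
    p = special.expit(params[4])
    lp1 = stats.nbinom.logpmf(a, a1, b1 / (b1 + E))
    lp2 = stats.nbinom.logpmf(a, a2, b2 / (b2 + E))
    return float(np.logaddexp(np.log(p) + lp1, np.log1p(-p) + lp2).sum())


def mgps_fit(a, E) -> MgpsHyperparams:
    """Fit the two-component gamma mixture prior by maximum marginal
    likelihood over the whole grid.

    The marginal of a Poisson(lambda E) count under a Gamma(alpha, beta)
    rate prior is negative binomial with size alpha and success probability
    beta/(beta+E); the mixture log-likelihood is maximized by Nelder-Mead
    in log/logit-transformed coordinates from the conventional start
    (0.2, 0.1, 2.0, 4.0, 1/3).
    """
    a = np.asarray(a, dtype=float)
    E = np.asarray(E, dtype=float)
    if a.size < 10:
        raise ValueError("need at least 10 grid cells to fit the MGPS prior")
    if np.any(E <= 0):
        raise ValueError("expected counts must be positive")
    # canonical cell order: the summed log-likelihood (and therefore the
    # whole optimization path) becomes invariant to input permutation
    order = np.lexsort((a, E))
    a, E = a[order], E[order]
    x0 = np.array([math.log(v) for v in _MGPS_START[:4]]
                  + [special.logit(_MGPS_START[4])])
    nll = lambda q: -_mixture_loglik(q, a, E)  # noqa: E731
    # Powell handles the ridged 5-parameter surface far better than a
    # simplex here; a Nelder-Mead polish from Powell's solution follows,
    # and the better of the two stages wins
    res = optimize.minimize(nll, x0, method="Powell",
                            options={"maxiter": 8000})
    polish = optimize.minimize(nll, res.x, method="Nelder-Mead",
                               options={"maxiter": 4000, "xatol": 1e-8,
                                        "fatol": 1e-10})
    if polish.fun < res.fun:
        res = polish
    a1, b1, a2, b2 = np.exp(res.x[:4])
    p = float(special.expit(res.x[4]))
    return MgpsHyperparams(float(a1), float(b1), float(a2), float(b2),
                           p, float(-res.fun))


def mgps_ebgm(a: float, E: float, hyper: MgpsHyperparams) -> tuple[float, float]:
    """Posterior EBGM (geometric mean of lambda) and EBGM05 for one cell.

    The posterior is the gamma mixture Q Gamma(alpha1+a, beta1+E) +
    (1-Q) Gamma(alpha2+a, beta2+E) with Q the posterior component weight.
    EBGM = exp(E[ln lambda]) via the digamma function; EBGM05 is found by
    root-finding on the mixture CDF to 1e-8 absolute tolerance.
    """
    if E <= 0:
        raise ValueError("E must be positive")
    lp1 = stats.nbinom.logpmf(a, hyper.alpha1, hyper.beta1 / (hyper.beta1 + E))
    lp2 = stats.nbinom.logpmf(a, hyper.alpha2, hyper.beta2 / (hyper.beta2 + E))
    w1 = math.log(hyper.mix_p) + lp1
    w2 = math.log1p(-hyper.mix_p) + lp2
    q = float(special.expit(w1 - w2))

    s1, r1 = hyper.alpha1 + a, hyper.beta1 + E
    s2, r2 = hyper.alpha2 + a, hyper.beta2 + E
    mean_log = q * (special.digamma(s1) - math.log(r1)) \
        + (1 - q) * (special.digamma(s2) - math.log(r2))
    ebgm = math.exp(mean_log)

    def cdf(x: float) -> float:
        return (q * stats.gamma.cdf(x, s1, scale=1 / r1)
                + (1 - q) * stats.gamma.cdf(x, s2, scale=1 / r2))

    q1 = stats.gamma.ppf(0.05, s1, scale=1 / r1)
    q2 = stats.gamma.ppf(0.05, s2, scale=1 / r2)
    # the mixture 5% quantile lies between the component quantiles; pad the
    # bracket so float round-off at a degenerate weight cannot break it
    lo, hi = 0.5 * min(q1, q2), 2.0 * max(q1, q2)
    while cdf(lo) > 0.05:
        lo *= 0.5
    while cdf(hi) < 0.05:
        hi *= 2.0
    ebgm05 = optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi, xtol=1e-8)
    return ebgm, float(ebgm05)


def evaluate_criteria(n_cases: int, ror: float, ror_low: float, prr: float,
                      chi2: float, ic025: float,
                      ebgm05: float | None) -> dict[str, bool]:
    """Positivity flags for the four methods.

    An exposure with fewer than three cases is flagged negative on every
    method (reported as "False" in tabular output).  Thresholds printed as
    strict (">") are strict here: exact-threshold inputs are negative.
    """
    if n_cases < 3:
        return {"ror_pos": False, "prr_pos": False,
                "bcpnn_pos": False, "mgps_pos": False}
    return {
        "ror_pos": bool(ror > 1 and ror_low > 1),
        "prr_pos": bool(prr >= 2 and chi2 >= 4),
        "bcpnn_pos": bool(ic025 > 0),
        "mgps_pos": bool(ebgm05 is not None and ebgm05 > 2),
    }


def compute_signal(table: ContingencyTable, exposure: str = "",
                   hyper: MgpsHyperparams | None = None,
                   yates: bool = False) -> SignalResult:
    """All four statistics plus flags for one contingency table.

    MGPS values require fitted hyperparameters (``hyper``); without them
    EBGM/EBGM05 are reported as missing and the MGPS flag is negative.  The
    pair expectation for MGPS is the table's own E = (a+b)(a+c)/N.
    """
    ror, lo, hi = ror_stat(table)
    prr, chi2 = prr_stat(table, yates=yates)
    ic, icv, ic025 = bcpnn_ic(table)
    ebgm = ebgm05 = None
    if hyper is not None:
        E = (table.a + table.b) * (table.a + table.c) / table.n
        if E > 0:
            ebgm, ebgm05 = mgps_ebgm(table.a, E, hyper)
    flags = evaluate_criteria(int(table.a), ror, lo, prr, chi2, ic025, ebgm05)
    return SignalResult(
        exposure=exposure, n_cases=int(table.a),
        ror=ror, ror_low=lo, ror_high=hi,
        prr=prr, chi2=chi2,
        ic_expect=ic, ic_var=icv, ic025=ic025,
        ebgm=ebgm, ebgm05=ebgm05,
        degenerate=table.has_zero_cell,
        flags=flags,
    )
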