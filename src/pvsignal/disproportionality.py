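"""Disproportionality statistics for spontaneous-report signal detection.

For a drug–event 2x2 table (a, b, c, d) with N = a+b+c+d and null-expected
count E = (a+b)(a+c)/N, this module implements the four classical measures:

* ROR, the reporting odds ratio ``ad/bc`` with a Wald CI on the log scale,
  ``exp(ln ROR ± 1.96 sqrt(1/a + 1/b + 1/c + 1/d))``;
* PRR, the proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` with Wald
  CI ``exp(ln PRR ± 1.96 sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)))`` and the
  uncorrected Pearson chi-square of the table;
* the BCPNN information component, using the gamma-posterior formulation
  ``lambda | a ~ Gamma(a + 1/2, E + 1/2)`` so that
  ``IC = log2((a+0.5)/(E+0.5))`` and IC025 is the posterior 2.5th
  percentile on the log2 scale;
* MGPS/EBGM, the multi-item gamma-Poisson shrinker: a two-component gamma
  mixture prior on the relative reporting rate, fitted by maximizing the
  negative-binomial marginal likelihood over all database (a, E) pairs, with
  EBGM the posterior geometric mean ``2^{E[log2 lambda | a]}`` and EBGM05
  its 5th posterior percentile.

Zero cells yield NaN ("undefined-signal") results rather than continuity
corrections by default; a Haldane 0.5 correction is available by flag.
Signal screening applies the detection rule (>= 3 reports and ROR lower 95%
bound > 1), per-algorithm concordance thresholds, important-medical-event
flagging, exclusion lists, and Benjamini–Hochberg FDR over the preferred
terms of one system organ class, producing volcano-plot-shaped output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .cohort import AnalyticData, ContingencyTable, SubgroupKey, contingency_all_pts

__all__ = [
    "RatioResult",
    "PrrResult",
    "IcResult",
    "EbgmResult",
    "SignalStats",
    "MgpsPrior",
    "SignalCriteria",
    "ror",
    "prr",
    "chi2_stat",
    "ic_bcpnn",
    "ic_from_ae",
    "fit_mgps_prior",
    "ebgm_mgps",
    "ebgm_from_ae",
    "compute_signal_stats",
    "evaluate_signal",
    "signal_table",
    "screen_soc",
    "flag_ime",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


def _cells(table) -> tuple[float, float, float, float]:
    if isinstance(table, ContingencyTable):
        return float(table.a), float(table.b), float(table.c), float(table.d)
    a, b, c, d = table
    return float(a), float(b), float(c), float(d)


@dataclass(frozen=True)
class RatioResult:
    estimate: float
    lo95: float
    hi95: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.estimate)


@dataclass(frozen=True)
class PrrResult(RatioResult):
    chi2: float = float("nan")


@dataclass(frozen=True)
class IcResult:
    ic: float
    ic025: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.ic)


@dataclass(frozen=True)
class EbgmResult:
    ebgm: float
    ebgm05: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.ebgm)


_UNDEF = float("nan")


def ror(table, haldane: bool = False) -> RatioResult:
    """Reporting odds ratio with 95% Wald CI.

    Any zero cell makes the estimate undefined (NaN) unless ``haldane``
    adds 0.5 to every cell.
    """
    a, b, c, d = _cells(table)
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) <= 0:
        return RatioResult(_UNDEF, _UNDEF, _UNDEF)
    log_ror = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return RatioResult(
        math.exp(log_ror), math.exp(log_ror - _Z95 * se), math.exp(log_ror + _Z95 * se)
    )


def chi2_stat(table, yates: bool = False) -> float:
    """Pearson chi-square of the 2x2 table, uncorrected by default."""
    a, b, c, d = _cells(table)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom <= 0:
        return _UNDEF
    dev = abs(a * d - b * c)
    if yates:
        dev = max(dev - n / 2, 0.0)
    return n * dev * dev / denom


def prr(table, yates: bool = False) -> PrrResult:
    """Proportional reporting ratio with 95% Wald CI and Pearson chi-square.

    Undefined when the comparator has no reports of the event (c = 0) or
    when either drug margin is empty.
    """
    a, b, c, d = _cells(table)
    if a <= 0 or c <= 0 or (a + b) <= 0 or (c + d) <= 0:
        return PrrResult(_UNDEF, _UNDEF, _UNDEF, chi2_stat(table, yates=yates))
    est = (a / (a + b)) / (c / (c + d))
    var = 1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)
    se = math.sqrt(max(var, 0.0))
    log_prr = math.log(est)
    return PrrResult(
        est,
        math.exp(log_prr - _Z95 * se),
        math.exp(log_prr + _Z95 * se),
        chi2_stat(table, yates=yates),
    )


def ic_bcpnn(table) -> IcResult:
    """BCPNN information component and its lower 95% credible bound.

    Posterior: ``lambda | a ~ Gamma(shape=a+0.5, rate=E+0.5)``;
    ``IC = log2((a+0.5)/(E+0.5))`` and ``IC025 = log2`` of the posterior
    2.5th percentile.
    """
    if isinstance(table, ContingencyTable):
        a, e = float(table.a), table.expected
    else:
        a, b, c, d = _cells(table)
        n = a + b + c + d
        e = (a + b) * (a + c) / n if n > 0 else 0.0
        a = float(a)
    return ic_from_ae(a, e)


def ic_from_ae(a: float, e: float) -> IcResult:
    """Information component directly from the observed and expected counts."""
    if not e > 0:
        return IcResult(_UNDEF, _UNDEF)
    ic = math.log2((a + 0.5) / (e + 0.5))
    q025 = stats.gamma.ppf(0.025, a + 0.5, scale=1.0 / (e + 0.5))
    return IcResult(ic, math.log2(q025))


# ---------------------------------------------------------------------------
# MGPS / EBGM


@dataclass(frozen=True)
class MgpsPrior:
    """Hyperparameters of the two-component gamma mixture prior on the
    relative reporting rate lambda: with probability ``p_mix``,
    ``lambda ~ Gamma(alpha1, beta1)``, else ``Gamma(alpha2, beta2)``
    (shape/rate convention)."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p_mix: float
    converged: bool = True
    loglik: float = float("nan")

    def validate(self) -> None:
        vals = (self.alpha1, self.beta1, self.alpha2, self.beta2)
        if not all(np.isfinite(v) and v > 0 for v in vals):
            raise ValueError(f"invalid MGPS prior parameters {vals}")
        if not 0 < self.p_mix < 1:
            raise ValueError(f"p_mix {self.p_mix} not in (0,1)")

    def canonical(self) -> "MgpsPrior":
        """Component order fixed by descending prior mean alpha/beta."""
        if self.alpha1 / self.beta1 >= self.alpha2 / self.beta2:
            return self
        return MgpsPrior(
            self.alpha2, self.beta2, self.alpha1, self.beta1, 1.0 - self.p_mix,
            self.converged, self.loglik,
        )


#: DuMouchel's published prior, used as the anchor start for fitting
_CANONICAL_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


def _nb_logpmf(a: np.ndarray, e: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """log P(a) for the negative-binomial marginal of Poisson(lambda*E) with
    lambda ~ Gamma(alpha, beta)."""
    return (
        special.gammaln(alpha + a)
        - special.gammaln(alpha)
        - special.gammaln(a + 1.0)
        + alpha * (np.log(beta) - np.log(beta + e))
        + a * (np.log(e) - np.log(beta + e))
    )


def _mixture_nll(theta: np.ndarray, a: np.ndarray, e: np.ndarray) -> float:
    # clip the unconstrained parameters so line-search excursions cannot
    # overflow exp(); the optimum lies far inside these bounds
    la1, lb1, la2, lb2, logit_p = np.clip(theta, -30.0, 30.0)
    alpha1, beta1 = math.exp(la1), math.exp(lb1)
    alpha2, beta2 = math.exp(la2), math.exp(lb2)
    p = 1.0 / (1.0 + math.exp(-logit_p))
    l1 = _nb_logpmf(a, e, alpha1, beta1) + math.log(p)
    l2 = _nb_logpmf(a, e, alpha2, beta2) + math.log1p(-p)
    ll = np.logaddexp(l1, l2)
    total = float(np.sum(ll))
    return -total if np.isfinite(total) else 1e300


def fit_mgps_prior(
    a: np.ndarray,
    e: np.ndarray,
    n_starts: int = 6,
    seed: int = 0,
) -> MgpsPrior:
    """Fit the two-gamma mixture prior by marginal maximum likelihood.

    Multi-start quasi-Newton optimization on unconstrained transforms
    (log alpha, log beta, logit p) from DuMouchel's canonical values plus
    seeded random perturbations; the best converged optimum wins.  Raises
    ``RuntimeError`` (carrying the best incumbent in ``args``) if no start
    converges.
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    if a.shape != e.shape or a.size < 2:
        raise ValueError("need at least 2 (a, E) pairs of equal length")
    if np.any(e <= 0):
        raise ValueError("all expected counts E must be positive")

    rng = np.random.default_rng(seed)
    a1, b1, a2, b2, p = _CANONICAL_START
    base = np.array([math.log(a1), math.log(b1), math.log(a2), math.log(b2),
                     math.log(p / (1 - p))])
    starts = [base]
    for _ in range(n_starts - 1):
        starts.append(base + rng.normal(0.0, 1.0, size=5))

    best = None
    best_converged = False
    for x0 in starts:
        res = optimize.minimize(
            _mixture_nll,
            x0,
            args=(a, e),
            method="L-BFGS-B",
            options={"maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
            best_converged = bool(res.success)
        elif res.success and not best_converged and res.fun <= best.fun + 1e-6:
            best = res
            best_converged = True

    la1, lb1, la2, lb2, logit_p = np.clip(best.x, -30.0, 30.0)
    prior = MgpsPrior(
        alpha1=math.exp(la1),
        beta1=math.exp(lb1),
        alpha2=math.exp(la2),
        beta2=math.exp(lb2),
        p_mix=1.0 / (1.0 + math.exp(-logit_p)),
        converged=best_converged,
        loglik=-float(best.fun),
    ).canonical()
    if not best_converged:
        raise RuntimeError("MGPS prior fit did not converge", prior)
    return prior


def _posterior_mixture(a: float, e: float, prior: MgpsPrior):
    """Posterior component parameters and weights given observed count a."""
    shapes = np.array([prior.alpha1 + a, prior.alpha2 + a])
    rates = np.array([prior.beta1 + e, prior.beta2 + e])
    log_w = np.array(
        [
            math.log(prior.p_mix) + float(_nb_logpmf(np.array(a), np.array(e), prior.alpha1, prior.beta1)),
            math.log1p(-prior.p_mix) + float(_nb_logpmf(np.array(a), np.array(e), prior.alpha2, prior.beta2)),
        ]
    )
    w = np.exp(log_w - special.logsumexp(log_w))
    return shapes, rates, w


def ebgm_mgps(table, prior: MgpsPrior) -> EbgmResult:
    """Empirical-Bayes geometric mean and 5th posterior percentile.

    The posterior of lambda is a two-component gamma mixture with components
    ``Gamma(alpha_j + a, beta_j + E)``; ``EBGM = 2^{E[log2 lambda]}`` via the
    digamma closed form per component, and EBGM05 is root-found on the
    mixture CDF.
    """
    prior.validate()
    if isinstance(table, ContingencyTable):
        a, e = float(table.a), table.expected
    else:
        a, b, c, d = _cells(table)
        n = a + b + c + d
        e = (a + b) * (a + c) / n if n > 0 else 0.0
    return ebgm_from_ae(a, e, prior)


def ebgm_from_ae(a: float, e: float, prior: MgpsPrior) -> EbgmResult:
    """EBGM and EBGM05 directly from the observed and expected counts."""
    prior.validate()
    if not e > 0:
        return EbgmResult(_UNDEF, _UNDEF)
    shapes, rates, w = _posterior_mixture(a, e, prior)
    mean_log = float(np.dot(w, special.digamma(shapes) - np.log(rates)))
    ebgm = math.exp(mean_log)

    def cdf(x: float) -> float:
        return float(np.dot(w, stats.gamma.cdf(x, shapes, scale=1.0 / rates)))

    lo = float(min(stats.gamma.ppf(0.05, shapes, scale=1.0 / rates)))
    hi = float(max(stats.gamma.ppf(0.05, shapes, scale=1.0 / rates)))
    if hi <= lo:
        ebgm05 = lo
    else:
        ebgm05 = optimize.brentq(lambda x: cdf(x) - 0.05, lo * 0.999999, hi * 1.000001,
                                 xtol=1e-12, rtol=1e-12)
    return EbgmResult(ebgm, float(ebgm05))


# ---------------------------------------------------------------------------
# signal evaluation


@dataclass(frozen=True)
class SignalStats:
    """All four algorithms' point and interval estimates for one pair."""

    drug: str
    pt: str
    n: int
    expected: float
    ror: float
    ror_lo95: float
    ror_hi95: float
    prr: float
    prr_lo95: float
    prr_hi95: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    p_value: float = float("nan")
    p_fdr: float = float("nan")


@dataclass(frozen=True)
class SignalCriteria:
    """Detection rule and per-algorithm concordance thresholds.

    The primary rule is >= ``min_reports`` reports with ROR lower 95% bound
    above ``ror_lower_bound``; the concordance set uses the standard
    literature thresholds (PRR >= 2 with chi2 >= 4 and n >= 3; IC025 > 0;
    EBGM05 >= 2), all overridable.
    """

    min_reports: int = 3
    ror_lower_bound: float = 1.0
    prr_threshold: float = 2.0
    chi2_threshold: float = 4.0
    ic025_threshold: float = 0.0
    ebgm05_threshold: float = 2.0


def compute_signal_stats(
    table: ContingencyTable, prior: MgpsPrior | None = None
) -> SignalStats:
    """Evaluate all four disproportionality algorithms on one 2x2 table."""
    r = ror(table)
    p = prr(table)
    ic = ic_bcpnn(table)
    eb = ebgm_mgps(table, prior) if prior is not None else EbgmResult(_UNDEF, _UNDEF)
    return SignalStats(
        drug=table.drug,
        pt=table.pt,
        n=table.a,
        expected=table.expected,
        ror=r.estimate,
        ror_lo95=r.lo95,
        ror_hi95=r.hi95,
        prr=p.estimate,
        prr_lo95=p.lo95,
        prr_hi95=p.hi95,
        chi2=p.chi2,
        ic=ic.ic,
        ic025=ic.ic025,
        ebgm=eb.ebgm,
        ebgm05=eb.ebgm05,
    )


def evaluate_signal(
    stats_: SignalStats, criteria: SignalCriteria = SignalCriteria()
) -> tuple[bool, frozenset[str]]:
    """Apply the detection rule and the four-algorithm concordance.

    Undefined (NaN) statistics fail their rule.  Returns
    ``(is_signal, algorithms_met)`` where the set is a subset of
    {"ROR", "PRR", "BCPNN", "MGPS"}.
    """
    met = set()
    n_ok = stats_.n >= criteria.min_reports
    if n_ok and stats_.ror_lo95 > criteria.ror_lower_bound:
        met.add("ROR")
    if (
        n_ok
        and stats_.prr >= criteria.prr_threshold
        and stats_.chi2 >= criteria.chi2_threshold
    ):
        met.add("PRR")
    if stats_.ic025 > criteria.ic025_threshold:
        met.add("BCPNN")
    if stats_.ebgm05 >= criteria.ebgm05_threshold:
        met.add("MGPS")
    is_signal = "ROR" in met
    return is_signal, frozenset(met)


def flag_ime(pt: str, ime_terms) -> bool:
    """Case-insensitive exact match of a PT against an IME term list."""
    folded = {str(t).casefold() for t in ime_terms}
    return str(pt).casefold() in folded


# ---------------------------------------------------------------------------
# per-SOC screening


def _pair_pvalue(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square when all expected cells >= 5, else Fisher exact."""
    tbl = np.array([[a, b], [c, d]], dtype=float)
    n = tbl.sum()
    if n == 0:
        return float("nan")
    expected = np.outer(tbl.sum(axis=1), tbl.sum(axis=0)) / n
    if (expected >= 5).all():
        _, p, _, _ = stats.chi2_contingency(tbl, correction=False)
    else:
        _, p = stats.fisher_exact(tbl.astype(int), alternative="two-sided")
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def signal_table(
    analytic: AnalyticData,
    drug: str,
    pts: list[str] | None = None,
    stratum: SubgroupKey = SubgroupKey(),
    prior: MgpsPrior | None = None,
    criteria: SignalCriteria = SignalCriteria(),
    ime_terms=(),
) -> pd.DataFrame:
    """Full four-algorithm statistics per PT for one drug and stratum.

    Returns one row per PT (restricted to ``pts`` when given) with counts,
    all interval estimates, the IME flag, the algorithms met, and the
    detection-rule verdict; sorted by n descending.
    """
    counts = contingency_all_pts(analytic, drug, stratum)
    if pts is not None:
        wanted = {str(p).casefold() for p in pts}
        counts = counts.loc[[p for p in counts.index if str(p).casefold() in wanted]]
    rows = []
    for pt, row in counts.iterrows():
        tbl = ContingencyTable(
            a=int(row["a"]), b=int(row["b"]), c=int(row["c"]), d=int(row["d"]),
            drug=drug, pt=str(pt), stratum=stratum,
        )
        s = compute_signal_stats(tbl, prior)
        is_sig, met = evaluate_signal(s, criteria)
        rows.append(
            {
                "pt": str(pt),
                "n": s.n,
                "expected": s.expected,
                "ror": s.ror,
                "ror_lo95": s.ror_lo95,
                "ror_hi95": s.ror_hi95,
                "prr": s.prr,
                "prr_lo95": s.prr_lo95,
                "prr_hi95": s.prr_hi95,
                "chi2": s.chi2,
                "ic": s.ic,
                "ic025": s.ic025,
                "ebgm": s.ebgm,
                "ebgm05": s.ebgm05,
                "ime": flag_ime(str(pt), ime_terms),
                "is_signal": is_sig,
                "algorithms_met": ",".join(sorted(met)),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return df.sort_values(["n", "pt"], ascending=[False, True], kind="mergesort").reset_index(drop=True)


def screen_soc(
    analytic: AnalyticData,
    drug: str,
    soc_pt_map: dict[str, str],
    soc: str | None = None,
    exclusions=(),
    stratum: SubgroupKey = SubgroupKey(),
    prior: MgpsPrior | None = None,
    criteria: SignalCriteria = SignalCriteria(),
    ime_terms=(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Volcano + signal tables for the PTs of one system organ class.

    ``soc_pt_map`` maps PT -> SOC (case-insensitive keys); when ``soc`` is
    given only PTs assigned to it are screened, otherwise every mapped PT.
    The volcano table carries one row per PT observed for the drug (n,
    log2 ROR, raw p from chi-square/Fisher, BH-FDR p across the SOC's PTs);
    the signal table keeps rows passing the detection rule minus the
    ``exclusions`` list (which stays visible in the volcano rows).
    """
    folded_map = {str(k).casefold(): v for k, v in soc_pt_map.items()}
    if soc is not None:
        wanted = [k for k, v in folded_map.items() if v == soc]
    else:
        wanted = list(folded_map)
    table = signal_table(
        analytic, drug, pts=wanted, stratum=stratum, prior=prior,
        criteria=criteria, ime_terms=ime_terms,
    )
    if table.empty:
        return table, table
    counts = contingency_all_pts(analytic, drug, stratum)
    pvals = []
    for pt in table["pt"]:
        r = counts.loc[pt]
        pvals.append(_pair_pvalue(int(r["a"]), int(r["b"]), int(r["c"]), int(r["d"])))
    volcano = table[["pt", "n", "ror", "is_signal"]].copy()
    volcano["log2_ror"] = np.log2(volcano["ror"])
    volcano["p"] = pvals
    volcano["p_fdr"] = _bh_adjust(volcano["p"].to_numpy())
    volcano = volcano[["pt", "n", "log2_ror", "p", "p_fdr", "is_signal"]]

    excluded = {str(t).casefold() for t in exclusions}
    signals = table.loc[
        table["is_signal"] & ~table["pt"].str.casefold().isin(excluded)
    ].reset_index(drop=True)
    return volcano.reset_index(drop=True), signals
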