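"""Census counting, Kaplan-Meier, log-rank, and parametric lifespan models.

Census counts from short video clips feed a human-in-the-loop curation
ledger; curated counts convert to per-animal event records (each unit
decrease between censuses is a death at the later census date, survivors
at study end are right-censored).  Records feed the product-limit
estimator, the two-group log-rank test, and maximum-likelihood fits of
seven lifespan families: exponential, Weibull, gamma, generalized gamma,
log-logistic, log-normal and Gompertz, ranked by AIC.

Parameterizations (documented because conventions vary):

- Gompertz hazard ``h(t) = a * exp(b t)``, a > 0, b > 0.
- gamma with shape ``k`` and *rate* ``r`` (mean ``k / r``).
- generalized gamma in the (mu, sigma, Q) form: ``log T = mu + (sigma/Q)
  * log(Q**2 * G)`` with ``G ~ Gamma(Q**-2)``; Q -> 0 recovers the
  log-normal(mu, sigma) and Q = 1 the Weibull(shape 1/sigma, scale
  exp(mu)).

The Kaplan-Meier estimator and five of the parametric fitters come from
lifelines; the Gompertz fitter is a lifelines extension defined here and
the censored gamma likelihood is maximized directly (lifelines ships
neither).  The log-rank statistic is computed in closed form here and is
cross-checked against lifelines in the test suite.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np
import pandas as pd
from lifelines import (
    ExponentialFitter,
    GeneralizedGammaFitter,
    KaplanMeierFitter,
    LogLogisticFitter,
    LogNormalFitter,
    WeibullFitter,
)
from lifelines.fitters import ParametricUnivariateFitter
from scipy import optimize, special, stats

__all__ = [
    "SURVIVAL_FAMILIES", "CensusCount", "ParametricFit", "KMEstimate",
    "sample_lifetimes", "count_frame", "apply_curation", "counts_to_records",
    "km_estimate", "logrank", "fit_parametric", "select_model",
    "LifespanModel", "LifespanResults", "GompertzFitter",
]

SURVIVAL_FAMILIES = (
    "exponential", "weibull", "gamma", "generalized_gamma",
    "log_logistic", "log_normal", "gompertz",
)

_N_PARAMS = {
    "exponential": 1, "weibull": 2, "gamma": 2, "generalized_gamma": 3,
    "log_logistic": 2, "log_normal": 2, "gompertz": 2,
}


# ---------------------------------------------------------------------------
# sampling

def sample_lifetimes(family: str, params: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. event times (days) from a lifespan family."""
    if family == "exponential":
        return rng.exponential(1.0 / params["rate"], size=n)
    if family == "weibull":
        return params["scale"] * rng.weibull(params["shape"], size=n)
    if family == "gamma":
        return rng.gamma(params["shape"], 1.0 / params["rate"], size=n)
    if family == "gompertz":
        a, b = params["a"], params["b"]
        # inverse CDF of S(t) = exp(-(a/b)(e^{bt}-1))
        u = rng.random(n)
        return np.log1p(-b / a * np.log(u)) / b
    if family == "log_normal":
        return np.exp(rng.normal(params["mu"], params["sigma"], size=n))
    if family == "log_logistic":
        u = rng.random(n)
        return params["alpha"] * (u / (1.0 - u)) ** (1.0 / params["beta"])
    if family == "generalized_gamma":
        mu, sigma, q = params["mu"], params["sigma"], params["Q"]
        if abs(q) < 1e-12:
            return np.exp(rng.normal(mu, sigma, size=n))
        g = rng.gamma(q**-2, 1.0, size=n)
        return np.exp(mu + (sigma / q) * np.log(q**2 * g))
    raise ValueError(f"unknown survival family {family!r}; expected one of {SURVIVAL_FAMILIES}")


def family_median(family: str, params: dict) -> float:
    """Closed-form median lifespan of a family (for calibration checks)."""
    ln2 = math.log(2.0)
    if family == "exponential":
        return ln2 / params["rate"]
    if family == "weibull":
        return params["scale"] * ln2 ** (1.0 / params["shape"])
    if family == "gompertz":
        a, b = params["a"], params["b"]
        return math.log1p(b / a * ln2) / b
    if family == "gamma":
        return float(stats.gamma.median(params["shape"], scale=1.0 / params["rate"]))
    if family == "log_normal":
        return math.exp(params["mu"])
    if family == "log_logistic":
        return params["alpha"]
    if family == "generalized_gamma":
        mu, sigma, q = params["mu"], params["sigma"], params["Q"]
        if abs(q) < 1e-12:
            return math.exp(mu)
        g_med = stats.gamma.median(q**-2)
        return math.exp(mu + (sigma / q) * math.log(q**2 * g_med))
    raise ValueError(f"unknown survival family {family!r}")


# ---------------------------------------------------------------------------
# census counting and curation

@dataclass
class CensusCount:
    """One census observation: automatic count plus optional curation."""

    day: float
    auto_count: int
    curated_count: int | None = None
    flag_overlap: bool = False
    note: str = ""

    @property
    def count(self) -> int:
        return self.auto_count if self.curated_count is None else self.curated_count


def count_frame(detections_per_frame, day: float = 0.0, expected_max: int | None = None) -> CensusCount:
    """Consensus animal count over a short clip.

    ``detections_per_frame`` is a sequence of per-frame detection lists
    (or plain counts).  The count is the median across frames; frame-to-
    frame disagreement raises the overlap-suspected flag, signalling the
    observation for manual curation.
    """
    counts = np.array([c if np.isscalar(c) else len(c) for c in detections_per_frame], dtype=float)
    if counts.size == 0:
        return CensusCount(day=day, auto_count=0, flag_overlap=False)
    if (counts < 0).any():
        raise ValueError("counts must be >= 0")
    med = int(round(float(np.median(counts))))
    flag = bool(counts.max() != counts.min())
    if expected_max is not None and med > expected_max:
        med, flag = expected_max, True
    return CensusCount(day=day, auto_count=med, flag_overlap=flag)


def census_to_frame(census: list[CensusCount]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "day": [c.day for c in census],
            "auto_count": [c.auto_count for c in census],
            "curated_count": [np.nan if c.curated_count is None else c.curated_count for c in census],
            "flag_overlap": [c.flag_overlap for c in census],
            "note": [c.note for c in census],
        }
    )


def apply_curation(census: list[CensusCount], ledger: pd.DataFrame) -> list[CensusCount]:
    """Override automatic counts with curated values from a ledger.

    The ledger has columns ``day``, ``curated_count`` and optional
    ``note``; every ledger row must reference an existing census day.
    Provenance (original auto count, curation note) is retained.
    """
    by_day = {float(c.day): c for c in census}
    unknown = [d for d in ledger["day"] if float(d) not in by_day]
    if unknown:
        raise ValueError(f"curation ledger references unknown census days: {unknown}")
    out = [CensusCount(c.day, c.auto_count, c.curated_count, c.flag_overlap, c.note) for c in census]
    idx = {float(c.day): i for i, c in enumerate(out)}
    for row in ledger.itertuples(index=False):
        i = idx[float(row.day)]
        out[i].curated_count = int(row.curated_count)
        out[i].note = str(getattr(row, "note", ""))
    return out


def counts_to_records(census: pd.DataFrame | list[CensusCount], cohort_size: int | None = None) -> pd.DataFrame:
    """Convert a census series to per-animal survival records.

    Each unit decrease between consecutive censuses emits a death at the
    later census day (right-endpoint convention); animals alive at the
    final census are censored there.  Deaths + censored always equals
    the initial cohort size.  Increasing counts are rejected with the
    offending days listed.
    """
    if isinstance(census, list):
        df = census_to_frame(census)
        counts = np.array([c.count for c in census], dtype=int)
        days = df["day"].to_numpy(dtype=float)
    else:
        days = census["day"].to_numpy(dtype=float)
        col = "count" if "count" in census.columns else "auto_count"
        counts = census[col].to_numpy(dtype=int)
    order = np.argsort(days)
    days, counts = days[order], counts[order]
    if len(days) == 0:
        raise ValueError("empty census series")
    rising = np.where(np.diff(counts) > 0)[0]
    if rising.size:
        bad = ", ".join(f"day {days[i]} -> day {days[i + 1]} ({counts[i]} -> {counts[i + 1]})" for i in rising)
        raise ValueError(f"census counts increase between censuses: {bad}")
    if cohort_size is None:
        cohort_size = int(counts[0])
    if counts[0] > cohort_size:
        raise ValueError(f"first census count {counts[0]} exceeds cohort size {cohort_size}")

    times, events = [], []
    prev = cohort_size
    for day, cnt in zip(days, counts):
        for _ in range(prev - cnt):
            times.append(day)
            events.append(1)
        prev = cnt
    for _ in range(int(counts[-1])):
        times.append(days[-1])
        events.append(0)
    return pd.DataFrame({"id": np.arange(len(times)), "time": times, "event": events})


# ---------------------------------------------------------------------------
# nonparametric estimation

@dataclass
class KMEstimate:
    """Product-limit survival curve with its median."""

    survival: pd.DataFrame      # columns: time, S
    median: float | None        # smallest t with S(t) <= 0.5; None if never reached
    n: int
    n_events: int
    fitter: KaplanMeierFitter = field(repr=False, default=None)


def km_estimate(records: pd.DataFrame) -> KMEstimate:
    """Kaplan-Meier estimate of the survival function.

    The median is the smallest observed time with S(t) <= 0.5 and is
    reported as None (undefined) when the curve never reaches 0.5,
    e.g. with heavy censoring.
    """
    t = records["time"].to_numpy(dtype=float)
    e = records["event"].to_numpy(dtype=int)
    if len(t) == 0:
        raise ValueError("no records")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    surv = kmf.survival_function_.reset_index()
    surv.columns = ["time", "S"]
    med = kmf.median_survival_time_
    median = None if not np.isfinite(med) else float(med)
    return KMEstimate(survival=surv, median=median, n=len(t), n_events=int(e.sum()), fitter=kmf)


def logrank(records_a: pd.DataFrame, records_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test (1 df); returns (chi-square, p-value).

    Closed-form observed-vs-expected computation with the hypergeometric
    variance; symmetric in the two groups.
    """
    for name, rec in (("A", records_a), ("B", records_b)):
        if len(rec) == 0:
            raise ValueError(f"group {name} is empty")
        if int(rec["event"].sum()) == 0:
            raise ValueError(f"group {name} contains no events")
    ta, ea = records_a["time"].to_numpy(float), records_a["event"].to_numpy(int)
    tb, eb = records_b["time"].to_numpy(float), records_b["event"].to_numpy(int)
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    group = np.concatenate([np.zeros(len(ta), int), np.ones(len(tb), int)])

    event_times = np.unique(times[events == 1])
    o_a = e_a = var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & (group == 0)).sum()
        dying = (times == t) & (events == 1)
        d = dying.sum()
        d_a = (dying & (group == 0)).sum()
        o_a += d_a
        e_a += d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0, 1.0
    chi2 = (o_a - e_a) ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# parametric fitting

class GompertzFitter(ParametricUnivariateFitter):
    """Gompertz lifespan model, hazard h(t) = a * exp(b t)."""

    _fitted_parameter_names = ["a_", "b_"]
    _bounds = [(1e-12, None), (1e-12, None)]

    def _cumulative_hazard(self, params, times):
        a, b = params
        return (a / b) * anp.expm1(b * times)

    def _create_initial_point(self, Ts, E, entry, weights):
        t = np.asarray(Ts[0] if isinstance(Ts, (tuple, list)) else Ts, dtype=float)
        crude = max(np.asarray(E).sum() / max(t.sum(), 1e-9), 1e-6)
        return np.array([crude / 2.0, 0.05])


def _gamma_negloglik(logp: np.ndarray, t: np.ndarray, e: np.ndarray) -> float:
    k, r = np.exp(logp)
    with np.errstate(over="ignore", invalid="ignore"):
        ll_event = k * np.log(r) + (k - 1.0) * np.log(t) - r * t - special.gammaln(k)
        sf = special.gammaincc(k, r * t)
        ll_cens = np.log(np.clip(sf, 1e-300, None))
    ll = np.where(e == 1, ll_event, ll_cens).sum()
    return -ll if np.isfinite(ll) else 1e12


def _numeric_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps * max(abs(x[i]), 1.0)
            ej = np.zeros(n); ej[j] = eps * max(abs(x[j]), 1.0)
            fpp = f(x + ei + ej); fpm = f(x + ei - ej)
            fmp = f(x - ei + ej); fmm = f(x - ei - ej)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * ei[i] * ej[j])
    return h


@dataclass
class ParametricFit:
    """A converged maximum-likelihood lifespan fit."""

    family: str
    params: dict[str, float]
    ses: dict[str, float]
    loglik: float
    n: int
    n_events: int
    data_hash: str
    fitter: object = field(repr=False, default=None)

    @property
    def k(self) -> int:
        return _N_PARAMS[self.family]

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    @property
    def bic(self) -> float:
        return self.k * math.log(self.n) - 2.0 * self.loglik


def _hash_records(t: np.ndarray, e: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(t, dtype=np.float64).tobytes())
    h.update(np.ascontiguousarray(e, dtype=np.int64).tobytes())
    return h.hexdigest()[:16]


def _fit_gamma(t: np.ndarray, e: np.ndarray) -> tuple[dict, dict, float]:
    mean, var = t[e == 1].mean(), max(t[e == 1].var(), 1e-6)
    x0 = np.log([max(mean**2 / var, 0.1), max(mean / var, 1e-4)])
    res = optimize.minimize(_gamma_negloglik, x0, args=(t, e), method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 4000})
    res2 = optimize.minimize(_gamma_negloglik, res.x, args=(t, e), method="BFGS")
    best = res2 if res2.fun <= res.fun else res
    if not np.isfinite(best.fun):
        raise RuntimeError("gamma fit failed to converge")
    logp = best.x
    # delta method: cov on natural scale from Hessian in log-parameters
    hess = _numeric_hessian(lambda lp: _gamma_negloglik(lp, t, e), logp)
    try:
        cov_log = np.linalg.inv(hess)
        p = np.exp(logp)
        jac = np.diag(p)
        cov = jac @ cov_log @ jac
        ses = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        ses = np.array([np.nan, np.nan])
    k, r = np.exp(logp)
    return {"shape": float(k), "rate": float(r)}, {"shape": float(ses[0]), "rate": float(ses[1])}, float(-best.fun)


def _fit_generalized_gamma(t: np.ndarray, e: np.ndarray) -> tuple[dict, dict, float, object]:
    """GG fit warm-started from its nested families.

    The (mu, sigma, Q) likelihood surface is multimodal; starting from
    the fitted Weibull (Q = 1) and log-normal (Q -> 0) guarantees the
    returned log-likelihood is at least that of the nested optima.
    """
    starts = []
    try:
        wf = WeibullFitter().fit(t, e)
        starts.append(np.array([math.log(wf.lambda_), math.log(1.0 / wf.rho_), 1.0]))
    except Exception:
        pass
    try:
        lf = LogNormalFitter().fit(t, e)
        starts.append(np.array([lf.mu_, math.log(lf.sigma_), 0.01]))
    except Exception:
        pass
    starts.append(None)  # lifelines' own initial point
    best = None
    for s in starts:
        try:
            f = GeneralizedGammaFitter()
            f.fit(t, e, initial_point=s)
            if np.isfinite(f.log_likelihood_) and (best is None or f.log_likelihood_ > best.log_likelihood_):
                best = f
        except Exception:
            continue
    if best is None:
        raise RuntimeError("generalized gamma fit failed to converge from all starting points")
    se = best.summary["se(coef)"]
    sigma = math.exp(best.ln_sigma_)
    params = {"mu": float(best.mu_), "sigma": float(sigma), "Q": float(best.lambda_)}
    ses = {
        "mu": float(se["mu_"]),
        "sigma": float(sigma * se["ln_sigma_"]),
        "Q": float(se["lambda_"]),
    }
    return params, ses, float(best.log_likelihood_), best


def fit_parametric(records: pd.DataFrame, family: str) -> ParametricFit:
    """Maximum-likelihood fit of one lifespan family with right-censoring.

    Raises on unknown family, on too few events (need k+1 events for a
    k-parameter family) and on non-convergence; never returns silently
    bad estimates.
    """
    if family not in SURVIVAL_FAMILIES:
        raise ValueError(f"unknown survival family {family!r}; expected one of {SURVIVAL_FAMILIES}")
    t = records["time"].to_numpy(dtype=float)
    e = records["event"].to_numpy(dtype=int)
    k = _N_PARAMS[family]
    if int(e.sum()) < k + 1:
        raise ValueError(f"{family} fit needs at least {k + 1} events, got {int(e.sum())}")
    data_hash = _hash_records(t, e)

    if family == "gamma":
        params, ses, ll = _fit_gamma(t, e)
        fitter = None
    elif family == "generalized_gamma":
        params, ses, ll, fitter = _fit_generalized_gamma(t, e)
    elif family == "gompertz":
        fitter = GompertzFitter().fit(t, e)
        se = fitter.summary["se(coef)"]
        params = {"a": float(fitter.a_), "b": float(fitter.b_)}
        ses = {"a": float(se["a_"]), "b": float(se["b_"])}
        ll = float(fitter.log_likelihood_)
    elif family == "exponential":
        fitter = ExponentialFitter().fit(t, e)
        lam = float(fitter.lambda_)  # lifelines scale = mean lifetime
        se_lam = float(fitter.summary["se(coef)"]["lambda_"])
        params = {"rate": 1.0 / lam}
        ses = {"rate": se_lam / lam**2}
        ll = float(fitter.log_likelihood_)
    elif family == "weibull":
        fitter = WeibullFitter().fit(t, e)
        se = fitter.summary["se(coef)"]
        params = {"shape": float(fitter.rho_), "scale": float(fitter.lambda_)}
        ses = {"shape": float(se["rho_"]), "scale": float(se["lambda_"])}
        ll = float(fitter.log_likelihood_)
    elif family == "log_normal":
        fitter = LogNormalFitter().fit(t, e)
        se = fitter.summary["se(coef)"]
        params = {"mu": float(fitter.mu_), "sigma": float(fitter.sigma_)}
        ses = {"mu": float(se["mu_"]), "sigma": float(se["sigma_"])}
        ll = float(fitter.log_likelihood_)
    elif family == "log_logistic":
        fitter = LogLogisticFitter().fit(t, e)
        se = fitter.summary["se(coef)"]
        params = {"alpha": float(fitter.alpha_), "beta": float(fitter.beta_)}
        ses = {"alpha": float(se["alpha_"]), "beta": float(se["beta_"])}
        ll = float(fitter.log_likelihood_)
    else:  # pragma: no cover
        raise AssertionError(family)

    if not np.isfinite(ll) or any(not np.isfinite(v) for v in params.values()):
        raise RuntimeError(f"{family} fit did not converge (loglik={ll}, params={params})")
    return ParametricFit(
        family=family, params=params, ses=ses, loglik=ll,
        n=len(t), n_events=int(e.sum()), data_hash=data_hash, fitter=fitter,
    )


def select_model(fits: list[ParametricFit]) -> pd.DataFrame:
    """Rank fits of the *same data* by ascending AIC (ties by family name)."""
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to rank")
    hashes = {f.data_hash for f in fits}
    if len(hashes) > 1:
        raise ValueError("fits were computed on different datasets; refusing to rank")
    rows = sorted(
        ({"family": f.family, "k": f.k, "loglik": f.loglik, "aic": f.aic, "bic": f.bic} for f in fits),
        key=lambda r: (r["aic"], r["family"]),
    )
    out = pd.DataFrame(rows)
    out["delta_aic"] = out["aic"] - out["aic"].iloc[0]
    return out


# ---------------------------------------------------------------------------
# model/results facade

class LifespanModel:
    """Cohort lifespan model built from per-animal survival records.

    ``fit()`` estimates the Kaplan-Meier curve and the requested
    parametric families and returns a :class:`LifespanResults`.
    """

    def __init__(self, records: pd.DataFrame):
        if not {"time", "event"}.issubset(records.columns):
            raise ValueError("records need 'time' and 'event' columns")
        if (records["time"] <= 0).any():
            raise ValueError("event times must be positive")
        self.records = records.reset_index(drop=True)

    @classmethod
    def from_census(cls, census, cohort_size: int | None = None) -> "LifespanModel":
        return cls(counts_to_records(census, cohort_size))

    def fit(self, families=SURVIVAL_FAMILIES) -> "LifespanResults":
        km = km_estimate(self.records)
        fits, failures = {}, {}
        for fam in families:
            try:
                fits[fam] = fit_parametric(self.records, fam)
            except (ValueError, RuntimeError) as exc:
                failures[fam] = str(exc)
        ranking = select_model(list(fits.values())) if len(fits) >= 2 else None
        return LifespanResults(records=self.records, km=km, fits=fits, ranking=ranking, failures=failures)


@dataclass
class LifespanResults:
    records: pd.DataFrame
    km: KMEstimate
    fits: dict[str, ParametricFit]
    ranking: pd.DataFrame | None
    failures: dict[str, str]

    @property
    def best_family(self) -> str | None:
        return None if self.ranking is None else str(self.ranking["family"].iloc[0])

    def summary(self) -> str:
        med = "undefined" if self.km.median is None else f"{self.km.median:.2f} d"
        lines = [
            f"Lifespan model: n={self.km.n}, events={self.km.n_events}, KM median={med}",
            f"{'family':<18}{'loglik':>12}{'AIC':>12}{'dAIC':>10}",
        ]
        if self.ranking is not None:
            for r in self.ranking.itertuples(index=False):
                lines.append(f"{r.family:<18}{r.loglik:>12.2f}{r.aic:>12.2f}{r.delta_aic:>10.2f}")
        for fam, msg in self.failures.items():
            lines.append(f"{fam:<18} FAILED: {msg}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """KM step curve with the best parametric survival overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.step(self.km.survival["time"], self.km.survival["S"], where="post", label="Kaplan-Meier")
        best = self.best_family
        if best is not None and self.fits[best].fitter is not None:
            grid = np.linspace(0, self.records["time"].max(), 200)
            sf = self.fits[best].fitter.survival_function_at_times(grid)
            ax.plot(grid, np.asarray(sf), label=f"best fit: {best}")
        ax.set_xlabel("age (days)")
        ax.set_ylabel("S(t)")
        ax.legend()
        return ax
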