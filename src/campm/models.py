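"""Sex-stratified Gamma exposure models with repeated-measures correlation.

The exposure contrast of interest is the multiplicative effect of a visual
concept on short-term (5-minute) personal PM2.5.  The model is a log-link
Gamma regression of the 5-minute mean on concept presence proportions, with
within-participant-day dependence from two sources: a participant-day random
intercept (exchangeable component) and lag-1 autoregressive decay in
observation order.  Effects are reported as percent change,
``(exp(beta) - 1) * 100``, with Wald intervals transformed from the log scale
so the asymmetry of multiplicative effects is preserved.

Estimation is by generalized estimating equations: Fisher scoring of the
Gamma/log quasi-score under a working within-cluster correlation

    R[j, k] = tau + psi * rho**|t_j - t_k|     (j != k),

whose parameters are moment-estimated from Pearson residual autocovariances
between outer iterations.  ``tau`` absorbs the random-intercept component and
``psi * rho**d`` the autoregressive one; gaps in the interval sequence
advance the lag.  Standard errors are cluster-robust (sandwich), so the
reported intervals are valid for the marginal log-linear effects even if the
working correlation is misspecified.  The hourly self-report variant uses a
nested-exchangeable working correlation (participant and participant-day
components) with sleeping as the reference activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .concepts import ConceptVocabulary, DEFAULT_VOCABULARY

__all__ = [
    "ModelSpec",
    "ModelResult",
    "ConvergenceError",
    "build_design",
    "fit_gamma_repeated",
    "fit_hourly_selfreport",
    "percent_change",
]


class ConvergenceError(RuntimeError):
    """Estimation failed to converge; carries diagnostic state."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


def percent_change(beta: float, se: float = 0.0, level: float = 0.95):
    """Percent change in the response mean for a unit predictor change.

    Point estimate ``(exp(beta) - 1) * 100``; the confidence interval
    transforms the Wald endpoints ``beta +/- z * se``, preserving asymmetry.
    """
    if se < 0:
        raise ValueError("se must be nonnegative")
    z = stats.norm.ppf(0.5 + level / 2)
    point = (math.exp(beta) - 1.0) * 100.0
    lo = (math.exp(beta - z * se) - 1.0) * 100.0
    hi = (math.exp(beta + z * se) - 1.0) * 100.0
    return point, lo, hi


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(
    fused_intervals: pd.DataFrame,
    photo_counts: pd.Series | dict,
    photo_threshold: int = 100,
    response: str = "pm_mean_5min",
    vocabulary: ConceptVocabulary = DEFAULT_VOCABULARY,
    location_concepts: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Model-ready table plus an exclusion report.

    Drops location concepts (collinear with activities), concepts flagged in
    fewer than ``photo_threshold`` photographs, and concepts never present in
    the intervals; drops rows with missing response.  Each exclusion is
    reported with its reason.
    """
    counts = pd.Series(photo_counts)
    if location_concepts is None:
        location_concepts = vocabulary.location_concepts
    candidates = [c for c in fused_intervals.columns if c in vocabulary.concepts]
    exclusions: list[dict] = []
    kept = []
    for c in candidates:
        if c in location_concepts:
            exclusions.append({"concept": c, "reason": "location/collinearity"})
        elif int(counts.get(c, 0)) < photo_threshold:
            exclusions.append({
                "concept": c, "reason": "infrequent",
                "n_photos": int(counts.get(c, 0))})
        elif not (fused_intervals[c] > 0).any():
            exclusions.append({"concept": c, "reason": "absent from intervals"})
        else:
            kept.append(c)
    if not kept:
        raise ValueError("all candidate predictors were excluded")
    n0 = len(fused_intervals)
    keep_cols = [col for col in ("participant_day", "participant_id", "sex",
                                 "interval_index", response) if col in fused_intervals]
    design = fused_intervals[keep_cols + kept].dropna(subset=[response]).reset_index(drop=True)
    if len(design) < n0:
        exclusions.append({"concept": "(rows)", "reason": "missing response",
                           "n_rows": n0 - len(design)})
    return design, exclusions


# ---------------------------------------------------------------------------
# working correlation models
# ---------------------------------------------------------------------------

class _Independence:
    name = "independence"

    def estimate(self, clusters) -> bool:
        return False

    def matrix(self, cluster) -> np.ndarray | None:
        return None  # identity

    def params(self) -> dict:
        return {}


class _ExchangeableAR1:
    """R = tau + psi * rho**distance off-diagonal; moment-updated."""

    name = "exchangeable+ar1"

    def __init__(self, max_lag: int = 10, fixed: dict | None = None):
        self.tau = 0.0
        self.psi = 0.0
        self.rho = 0.0
        self.max_lag = max_lag
        self.fixed = fixed

    def params(self) -> dict:
        return {"tau": self.tau, "psi": self.psi, "rho": self.rho}

    def estimate(self, clusters) -> bool:
        if self.fixed is not None:
            self.tau = self.fixed.get("tau", 0.0)
            self.psi = self.fixed.get("psi", 0.0)
            self.rho = self.fixed.get("rho", 0.0)
            return False
        v_num = v_den = 0.0
        lags = np.arange(1, self.max_lag + 1)
        sums = np.zeros(len(lags))
        counts = np.zeros(len(lags))
        for cl in clusters:
            r, t = cl.resid, cl.time
            v_num += float(r @ r)
            v_den += len(r)
            span = int(t.max()) + 1 if len(t) else 0
            arr = np.full(span, np.nan)
            arr[t] = r
            for i, k in enumerate(lags):
                if span <= k:
                    continue
                a, b = arr[:-k], arr[k:]
                ok = ~(np.isnan(a) | np.isnan(b))
                sums[i] += float(np.nansum(a[ok] * b[ok]))
                counts[i] += int(ok.sum())
        v = v_num / max(v_den, 1)
        ok = counts > 0
        if v <= 0 or ok.sum() < 3:
            changed = (self.tau, self.psi, self.rho) != (0.0, 0.0, 0.0)
            self.tau = self.psi = self.rho = 0.0
            return changed
        c = sums[ok] / counts[ok] / v
        k = lags[ok].astype(float)
        w = counts[ok]

        def _lsq(rho: float):
            design = np.column_stack([np.ones_like(k), rho**k])
            wd = design * w[:, None]
            coef, *_ = np.linalg.lstsq(wd.T @ design, wd.T @ c, rcond=None)
            resid = c - design @ coef
            return float(w @ resid**2), coef

        res = minimize_scalar(lambda r: _lsq(r)[0], bounds=(1e-4, 0.99), method="bounded")
        rho = float(res.x)
        _, (tau, psi) = _lsq(rho)
        tau = float(np.clip(tau, 0.0, 0.99))
        psi = float(np.clip(psi, 0.0, 0.99))
        if tau + psi > 0.99:
            s = 0.99 / (tau + psi)
            tau *= s
            psi *= s
        if psi < 1e-6:
            rho = 0.0
        old = (self.tau, self.psi, self.rho)
        self.tau, self.psi, self.rho = tau, psi, rho
        return max(abs(a - b) for a, b in zip(old, (tau, psi, rho))) > 1e-4

    def matrix(self, cluster) -> np.ndarray | None:
        if self.tau == 0.0 and self.psi == 0.0:
            return None
        t = cluster.time.astype(int)
        d = np.abs(t[:, None] - t[None, :])
        # integer lags: look powers up instead of computing float powers
        powers = self.rho ** np.arange(int(d.max()) + 1, dtype=float)
        R = self.tau + self.psi * powers[d]
        np.fill_diagonal(R, 1.0)
        return R


class _NestedExchangeable:
    """R = tau_outer + tau_inner * [same subcluster] off-diagonal."""

    name = "nested-exchangeable"

    def __init__(self, fixed: dict | None = None):
        self.tau_outer = 0.0
        self.tau_inner = 0.0
        self.fixed = fixed

    def params(self) -> dict:
        return {"tau_outer": self.tau_outer, "tau_inner": self.tau_inner}

    def estimate(self, clusters) -> bool:
        if self.fixed is not None:
            self.tau_outer = self.fixed.get("tau_outer", 0.0)
            self.tau_inner = self.fixed.get("tau_inner", 0.0)
            return False
        v_num = v_den = 0.0
        w_sum = w_cnt = 0.0  # same subcluster pairs
        b_sum = b_cnt = 0.0  # same cluster, different subcluster
        for cl in clusters:
            r, sub = cl.resid, cl.sub
            v_num += float(r @ r)
            v_den += len(r)
            S, Q = float(r.sum()), float(r @ r)
            tot_sum, tot_cnt = (S * S - Q) / 2, len(r) * (len(r) - 1) / 2
            ws = wc = 0.0
            for s in np.unique(sub):
                rs = r[sub == s]
                Ss, Qs = float(rs.sum()), float(rs @ rs)
                ws += (Ss * Ss - Qs) / 2
                wc += len(rs) * (len(rs) - 1) / 2
            w_sum += ws
            w_cnt += wc
            b_sum += tot_sum - ws
            b_cnt += tot_cnt - wc
        v = v_num / max(v_den, 1)
        if v <= 0:
            return False
        within = w_sum / w_cnt / v if w_cnt else 0.0
        between = b_sum / b_cnt / v if b_cnt else 0.0
        tau_o = float(np.clip(between, 0.0, 0.99))
        tau_i = float(np.clip(within - tau_o, 0.0, 0.99))
        if tau_o + tau_i > 0.99:
            s = 0.99 / (tau_o + tau_i)
            tau_o *= s
            tau_i *= s
        old = (self.tau_outer, self.tau_inner)
        self.tau_outer, self.tau_inner = tau_o, tau_i
        return max(abs(a - b) for a, b in zip(old, (tau_o, tau_i))) > 1e-4


    def matrix(self, cluster) -> np.ndarray | None:
        if self.tau_outer == 0.0 and self.tau_inner == 0.0:
            return None
        sub = cluster.sub
        same = sub[:, None] == sub[None, :]
        R = np.where(same, self.tau_outer + self.tau_inner, self.tau_outer)
        np.fill_diagonal(R, 1.0)
        return R


# ---------------------------------------------------------------------------
# GEE solver
# ---------------------------------------------------------------------------

@dataclass
class _Cluster:
    X: np.ndarray
    y: np.ndarray
    time: np.ndarray
    sub: np.ndarray | None = None
    resid: np.ndarray | None = None
    _chol: object = None
    Xr: np.ndarray | None = None


@dataclass
class ModelSpec:
    """What to fit: response, predictors, clustering and correlation contract."""

    response: str = "pm_mean_5min"
    predictors: tuple[str, ...] = ()
    group: str = "participant_day"
    time: str | None = "interval_index"
    subgroup: str | None = None  # for nested correlation (hourly model)
    correlation: str = "ar1"  # "ar1" | "independence" | "nested"
    stratum: str | None = None
    level: float = 0.95
    max_outer: int = 15
    max_inner: int = 100
    tol: float = 1e-10
    fixed_corr: dict | None = None


@dataclass
class ModelResult:
    """Fitted exposure model: log-scale coefficients and percent changes."""

    terms: pd.DataFrame
    alpha_hat: float
    alpha_se: float
    exp_alpha: float  # baseline response mean when no concept is present
    rho_hat: float
    sigma_u_hat: float
    corr_params: dict
    scale: float
    n_obs: int
    n_clusters: int
    algorithm: str
    converged: bool
    n_outer: int
    stratum: str | None = None
    exclusions: list = field(default_factory=list)

    def term(self, name: str) -> pd.Series:
        return self.terms.set_index("term").loc[name]

    def summary_frame(self) -> pd.DataFrame:
        out = self.terms.copy()
        out.insert(0, "stratum", self.stratum or "all")
        out["n_obs"] = self.n_obs
        out["n_clusters"] = self.n_clusters
        return out


def _split_clusters(design, spec: ModelSpec, predictors) -> list[_Cluster]:
    clusters = []
    if spec.time is not None and spec.time in design:
        design = design.sort_values([spec.group, spec.time], kind="stable")
    for _, g in design.groupby(spec.group, sort=True):
        if spec.time is not None and spec.time in g:
            t = g[spec.time].to_numpy()
            t = (t - t.min()).astype(int)
        else:
            t = np.arange(len(g))
        X = np.column_stack([np.ones(len(g))] +
                            [g[p].to_numpy(float) for p in predictors])
        y = g[spec.response].to_numpy(float)
        sub = g[spec.subgroup].to_numpy() if spec.subgroup else None
        clusters.append(_Cluster(X=X, y=y, time=t, sub=sub))
    return clusters


def _gee_fit(clusters: list[_Cluster], corr, spec: ModelSpec):
    """Fisher-scoring GEE for Gamma/log.  Returns (beta, cov, scale, n_outer)."""
    p = clusters[0].X.shape[1]
    N = sum(len(cl.y) for cl in clusters)

    # initialize from a log-scale least-squares fit; Newton refines from there
    X_all = np.vstack([cl.X for cl in clusters])
    y_all = np.concatenate([cl.y for cl in clusters])
    beta, *_ = np.linalg.lstsq(X_all, np.log(y_all), rcond=None)

    def _newton(beta):
        """Solve the estimating equations for fixed working correlation."""
        for cl in clusters:
            R = corr.matrix(cl)
            if R is None:
                cl._chol = None
                cl.Xr = cl.X
            else:
                cl._chol = cho_factor(R)
                cl.Xr = cho_solve(cl._chol, cl.X)
        M = sum(cl.X.T @ cl.Xr for cl in clusters)
        try:
            Mf = cho_factor(M)
        except np.linalg.LinAlgError as e:
            raise ConvergenceError(f"singular information matrix: {e}") from e
        for it in range(spec.max_inner):
            g = np.zeros(p)
            for cl in clusters:
                mu = np.exp(np.clip(cl.X @ beta, -30, 30))
                z = (cl.y - mu) / mu
                g += cl.Xr.T @ z
            step = cho_solve(Mf, g)
            nrm = float(np.max(np.abs(step)))
            if not np.isfinite(nrm):
                raise ConvergenceError("non-finite Newton step",
                                       {"beta": beta.tolist()})
            if nrm > 2.0:
                step *= 2.0 / nrm
            beta = beta + step
            if nrm < spec.tol:
                break
        else:
            raise ConvergenceError("inner Newton loop failed to converge",
                                   {"last_step": nrm, "beta": beta.tolist()})
        return beta, Mf

    beta, Mf = _newton(beta)
    n_outer = 0
    for n_outer in range(1, spec.max_outer + 1):
        for cl in clusters:
            mu = np.exp(cl.X @ beta)
            cl.resid = (cl.y - mu) / mu
        changed = corr.estimate(clusters)
        if not changed and n_outer > 1:
            break
        beta, Mf = _newton(beta)
        if not changed:
            break

    # sandwich covariance (phi cancels between bread and meat)
    B = np.zeros((p, p))
    for cl in clusters:
        mu = np.exp(cl.X @ beta)
        cl.resid = (cl.y - mu) / mu
        u = cl.Xr.T @ cl.resid
        B += np.outer(u, u)
    Minv = cho_solve(Mf, np.eye(p))
    cov = Minv @ B @ Minv
    scale = sum(float(cl.resid @ cl.resid) for cl in clusters) / max(N - p, 1)
    return beta, cov, scale, n_outer


def _package_result(beta, cov, scale, corr, spec, predictors, n_obs, n_clusters,
                    n_outer, exclusions=None) -> ModelResult:
    se = np.sqrt(np.diag(cov))
    rows = []
    for i, name in enumerate(predictors):
        b, s = float(beta[i + 1]), float(se[i + 1])
        pct, lo, hi = percent_change(b, s, spec.level)
        z = b / s if s > 0 else np.inf
        rows.append({
            "term": name, "beta": b, "se": s, "z": z,
            "pvalue": float(2 * stats.norm.sf(abs(z))),
            "percent_change": pct, "ci_low": lo, "ci_high": hi,
        })
    terms = pd.DataFrame(rows)
    params = corr.params()
    tau = params.get("tau", params.get("tau_outer", 0.0) + params.get("tau_inner", 0.0))
    return ModelResult(
        terms=terms,
        alpha_hat=float(beta[0]),
        alpha_se=float(se[0]),
        exp_alpha=float(np.exp(beta[0])),
        rho_hat=float(params.get("rho", 0.0)),
        sigma_u_hat=float(math.sqrt(max(tau, 0.0) * scale)),
        corr_params=params,
        scale=float(scale),
        n_obs=n_obs,
        n_clusters=n_clusters,
        algorithm=f"GEE Gamma/log, working correlation: {corr.name}, "
                  "cluster-robust (sandwich) SEs",
        converged=True,
        n_outer=n_outer,
        stratum=spec.stratum,
        exclusions=exclusions or [],
    )


def fit_gamma_repeated(design: pd.DataFrame, spec: ModelSpec,
                       exclusions: list | None = None) -> ModelResult:
    """Fit the log-link Gamma exposure model with repeated-measures correlation.

    ``design`` holds the response, predictor proportions in [0, 1], the
    cluster column (participant-day) and, for the AR component, an integer
    interval index whose gaps advance the lag.  Coefficients estimate the
    marginal log-linear concept effects; the intercept is the log 5-minute
    mean when no concept is present (plus the lognormal lift of the random
    effects, absorbed there by construction).
    """
    predictors = list(spec.predictors)  # empty -> intercept-only model
    missing = [p for p in predictors if p not in design.columns]
    if missing:
        raise ValueError(f"predictors not in design: {missing}")
    y = design[spec.response]
    if y.isna().any():
        raise ValueError("design contains missing responses; filter them first")
    bad = design.index[y <= 0]
    if len(bad):
        raise ValueError(
            f"non-positive response in rows {bad.tolist()[:10]} "
            f"({len(bad)} total); Gamma/log requires positive responses")
    n_clusters = design[spec.group].nunique()
    if n_clusters < 2:
        raise ValueError("need at least 2 participant-days")

    if spec.correlation == "independence":
        corr = _Independence()
    elif spec.correlation == "ar1":
        corr = _ExchangeableAR1(fixed=spec.fixed_corr)
    elif spec.correlation == "nested":
        if not spec.subgroup:
            raise ValueError("nested correlation requires spec.subgroup")
        corr = _NestedExchangeable(fixed=spec.fixed_corr)
    else:
        raise ValueError(f"unknown correlation structure {spec.correlation!r}")

    clusters = _split_clusters(design, spec, predictors)
    beta, cov, scale, n_outer = _gee_fit(clusters, corr, spec)
    return _package_result(beta, cov, scale, corr, spec, predictors,
                           len(design), n_clusters, n_outer, exclusions)


# ---------------------------------------------------------------------------
# hourly self-report model
# ---------------------------------------------------------------------------

def build_hourly_design(
    diary: pd.DataFrame,
    hourly_pm: pd.DataFrame | None = None,
    reference_activity: str = "sleeping",
    encoding: str = "split",
) -> tuple[pd.DataFrame, list[str]]:
    """Activity-indicator design from 1-2 activities per hour.

    ``encoding="split"`` weights each of two reported activities 0.5 (the
    diary records no within-hour proportions); ``"duplicate"`` emits one row
    per activity with full weight instead.  Returns the design and the
    non-reference activity list.
    """
    if encoding not in ("split", "duplicate"):
        raise ValueError("encoding must be 'split' or 'duplicate'")
    d = diary.copy()
    if hourly_pm is not None:
        d = d.merge(hourly_pm, on=[c for c in ("participant_day", "hour", "hour_start")
                                   if c in d.columns and c in hourly_pm.columns],
                    how="inner")
    a1 = d["activity1"].astype(str)
    a2 = d["activity2"].fillna("").astype(str) if "activity2" in d else pd.Series("", index=d.index)
    activities = sorted(set(a1[a1 != ""]) | set(a2[a2 != ""]))
    if reference_activity not in activities:
        raise ValueError(f"reference activity {reference_activity!r} not present in diary")
    non_ref = [a for a in activities if a != reference_activity]
    if encoding == "duplicate":
        rows1 = d.assign(_activity=a1, _w=1.0)
        rows2 = d.loc[a2 != ""].assign(_activity=a2[a2 != ""], _w=1.0)
        d = pd.concat([rows1, rows2], ignore_index=True)
        for a in non_ref:
            d[a] = (d["_activity"] == a).astype(float)
        d = d.drop(columns=["_activity", "_w"])
    else:
        for a in non_ref:
            w = (a1 == a).astype(float) + (a2 == a).astype(float)
            has2 = (a2 != "").astype(float)
            d[a] = w / (1.0 + has2)
    return d, non_ref


def fit_hourly_selfreport(
    diary: pd.DataFrame,
    hourly_pm: pd.DataFrame | None = None,
    reference_activity: str = "sleeping",
    response: str = "pm_hourly",
    encoding: str = "split",
    stratum: str | None = None,
) -> ModelResult:
    """Hourly Gamma/log model of PM on self-reported activities.

    Sleeping is the reference: the intercept is the log hourly mean while
    sleeping.  Dependence uses nested exchangeable working correlation with
    participant and participant-day components and cluster-robust SEs.
    """
    design, non_ref = build_hourly_design(diary, hourly_pm, reference_activity, encoding)
    spec = ModelSpec(
        response=response,
        predictors=tuple(non_ref),
        group="participant_id",
        subgroup="participant_day",
        time=None,
        correlation="nested",
        stratum=stratum,
    )
    return fit_gamma_repeated(design, spec)
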