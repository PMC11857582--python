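"""Maximum-likelihood ACE/ADE/AE/CE/E variance-component models for twin pairs.

Each pair contributes a bivariate-normal log-density with member means
``intercept + beta_age * age + beta_sex * [sex == M]`` and a zygosity-specific
covariance built from squared path coefficients:

    var      = a^2 + c^2 + d^2 + e^2
    cov(MZ)  = a^2 + c^2 + d^2
    cov(DZ)  = a^2 / 2 + c^2 + d^2 / 4

The outer optimization runs over unconstrained path coefficients (squares
guarantee nonnegative variances); the mean model is profiled out exactly by
generalized least squares inside every likelihood evaluation, and the data
enter only through per-zygosity sufficient statistics, so an evaluation costs
O(p^2) regardless of the number of pairs.  Reported components are the
standardized proportions (each squared path over the total variance).

Model comparison uses likelihood-ratio tests against the naive chi-squared
reference (the 50:50 chi2_0/chi2_1 boundary mixture is available behind a
flag and is the less conservative choice for variance components on the
boundary); confidence intervals are 95% profile-likelihood intervals on the
standardized proportions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    ValidationError,
)
from .io import TwinPairRecord

__all__ = [
    "MeanModel",
    "VarianceComponents",
    "ModelFit",
    "ModelSelectionResult",
    "fit_twin_model",
    "likelihood_ratio_test",
    "lrt_from_logliks",
    "select_model",
    "component_ci",
]

MODELS = ("ACE", "ADE", "AE", "CE", "E")
# free variance parameters per model (used for LRT degrees of freedom)
N_VARIANCE_PARAMS = {"ACE": 3, "ADE": 3, "AE": 2, "CE": 2, "E": 1}
# path labels per model, in optimization order
_PATHS = {"ACE": ("a", "c", "e"), "ADE": ("a", "d", "e"), "AE": ("a", "e"), "CE": ("c", "e"), "E": ("e",)}
_NESTED = {
    ("ACE", "AE"), ("ACE", "CE"), ("ACE", "E"),
    ("ADE", "AE"), ("ADE", "E"),
    ("AE", "E"), ("CE", "E"),
}
_BIG = 1e12


@dataclass(frozen=True)
class MeanModel:
    intercept: float
    beta_age: float
    beta_sex: float


@dataclass(frozen=True)
class VarianceComponents:
    a2: float
    c2: float = 0.0
    d2: float = 0.0
    e2: float = 0.0

    def __post_init__(self) -> None:
        total = self.a2 + self.c2 + self.d2 + self.e2
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"standardized components must sum to 1, got {total}")
        if self.c2 > 1e-12 and self.d2 > 1e-12:
            raise ValidationError("c2 and d2 cannot both be nonzero (not jointly identifiable)")


@dataclass
class ModelFit:
    model: str
    components: VarianceComponents
    mean_model: MeanModel
    total_sd: float
    loglik: float
    n_pairs: tuple[int, int]  # (MZ, DZ)
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    converged: bool = True
    _stats: "_SuffStats | None" = field(default=None, repr=False, compare=False)


@dataclass(frozen=True)
class ModelSelectionResult:
    chosen: str
    lrt_vs_full: tuple[float, int, float]  # (statistic, df, p) for the chosen reduction
    rationale: str  # negligible_C | negligible_A | both_significant
    lrt_pvalues: Mapping[str, float] = field(default_factory=dict)


class _GroupStats:
    """Sufficient statistics for one zygosity group (on scaled data)."""

    def __init__(self, y: np.ndarray, X1: np.ndarray, X2: np.ndarray):
        self.n = y.shape[0]
        y1, y2 = y[:, 0], y[:, 1]
        self.XtX = X1.T @ X1 + X2.T @ X2
        self.C12 = X1.T @ X2 + X2.T @ X1
        self.Xty = X1.T @ y1 + X2.T @ y2
        self.Xtyc = X1.T @ y2 + X2.T @ y1
        self.s_yy = float(y1 @ y1 + y2 @ y2)
        self.s_y12 = float(y1 @ y2)


class _SuffStats:
    """Scaled, age-centered data summary shared by all model fits on one dataset."""

    def __init__(self, pairs_mz: Sequence[TwinPairRecord], pairs_dz: Sequence[TwinPairRecord]):
        if len(pairs_mz) < 3 or len(pairs_dz) < 3:
            raise InsufficientDataError(
                f"need >=3 pairs per zygosity group, got MZ={len(pairs_mz)}, DZ={len(pairs_dz)}"
            )

        def arrays(pairs):
            y = np.array([p.values for p in pairs], dtype=float)
            age = np.array([p.ages for p in pairs], dtype=float)
            sex = np.array([[1.0 if s == "M" else 0.0 for s in p.sexes] for p in pairs])
            return y, age, sex

        y_mz, age_mz, sex_mz = arrays(pairs_mz)
        y_dz, age_dz, sex_dz = arrays(pairs_dz)
        all_y = np.concatenate([y_mz.ravel(), y_dz.ravel()])
        if np.ptp(all_y) == 0:
            raise DegenerateDataError("trait is constant; variance cannot be decomposed")
        self.scale = float(all_y.std(ddof=1))
        if self.scale == 0:
            raise DegenerateDataError("trait has zero variance")
        self.mean_age = float(np.concatenate([age_mz.ravel(), age_dz.ravel()]).mean())
        self.n_mz, self.n_dz = y_mz.shape[0], y_dz.shape[0]
        self.n_subjects = 2 * (self.n_mz + self.n_dz)
        self.fingerprint = hashlib.md5(
            np.ascontiguousarray(all_y).tobytes()
            + np.ascontiguousarray(age_mz).tobytes()
            + np.ascontiguousarray(age_dz).tobytes()
        ).hexdigest()

        def design(age, sex):
            n = age.shape[0]
            X1 = np.column_stack([np.ones(n), age[:, 0] - self.mean_age, sex[:, 0]])
            X2 = np.column_stack([np.ones(n), age[:, 1] - self.mean_age, sex[:, 1]])
            return X1, X2

        self.groups = {
            "MZ": _GroupStats(y_mz / self.scale, *design(age_mz, sex_mz)),
            "DZ": _GroupStats(y_dz / self.scale, *design(age_dz, sex_dz)),
        }

    def loglik_profiled(self, v: float, k_mz: float, k_dz: float) -> tuple[float, np.ndarray]:
        """Log-likelihood (scaled data) at covariance (v, k_z), with GLS-profiled betas."""
        ks = {"MZ": k_mz, "DZ": k_dz}
        dets = {z: v * v - ks[z] * ks[z] for z in ks}
        if v <= 1e-12 or any(d <= 1e-12 for d in dets.values()):
            return -_BIG, np.zeros(3)
        A = np.zeros((3, 3))
        b = np.zeros(3)
        for z, g in self.groups.items():
            w = 1.0 / dets[z]
            A += w * (v * g.XtX - ks[z] * g.C12)
            b += w * (v * g.Xty - ks[z] * g.Xtyc)
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            beta, *_ = np.linalg.lstsq(A, b, rcond=None)
        ll = 0.0
        for z, g in self.groups.items():
            k = ks[z]
            rss = g.s_yy - 2.0 * beta @ g.Xty + beta @ g.XtX @ beta
            rcp = g.s_y12 - beta @ g.Xtyc + 0.5 * beta @ g.C12 @ beta
            Q = (v * rss - 2.0 * k * rcp) / dets[z]
            ll += -g.n * np.log(2.0 * np.pi) - 0.5 * g.n * np.log(dets[z]) - 0.5 * Q
        return float(ll), beta

    def loglik_correlation(self, r_mz: float, r_dz: float) -> float:
        """Profile log-likelihood (scaled data) at within-pair correlations
        (r_mz, r_dz), with the total variance and betas both profiled out."""
        rs = {"MZ": r_mz, "DZ": r_dz}
        if any(abs(r) >= 1.0 - 1e-12 for r in rs.values()):
            return -_BIG
        A = np.zeros((3, 3))
        b = np.zeros(3)
        for z, g in self.groups.items():
            w = 1.0 / (1.0 - rs[z] ** 2)
            A += w * (g.XtX - rs[z] * g.C12)
            b += w * (g.Xty - rs[z] * g.Xtyc)
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            beta, *_ = np.linalg.lstsq(A, b, rcond=None)
        Q = 0.0
        logdet = 0.0
        for z, g in self.groups.items():
            r = rs[z]
            det = 1.0 - r * r
            rss = g.s_yy - 2.0 * beta @ g.Xty + beta @ g.XtX @ beta
            rcp = g.s_y12 - beta @ g.Xtyc + 0.5 * beta @ g.C12 @ beta
            Q += (rss - 2.0 * r * rcp) / det
            logdet += g.n * np.log(det)
        if Q <= 0:
            return -_BIG
        v_hat = Q / self.n_subjects
        N = self.n_subjects
        return float(-0.5 * N * (np.log(2.0 * np.pi) + np.log(v_hat) + 1.0) - 0.5 * logdet)


def _covariance(model: str, paths: np.ndarray) -> tuple[float, float, float]:
    """(var, cov_MZ, cov_DZ) from path coefficients in `_PATHS[model]` order."""
    sq = paths * paths
    comp = dict(zip(_PATHS[model], sq))
    a2 = comp.get("a", 0.0)
    c2 = comp.get("c", 0.0)
    d2 = comp.get("d", 0.0)
    e2 = comp.get("e", 0.0)
    v = a2 + c2 + d2 + e2
    return v, a2 + c2 + d2, 0.5 * a2 + c2 + 0.25 * d2


def _start_proportions(model: str, st: _SuffStats) -> np.ndarray:
    """Falconer-informed starting proportions from identity-weighted residuals."""
    ll0, beta0 = st.loglik_profiled(1.0, 0.0, 0.0)
    rs = {}
    v_tot = 0.0
    for z, g in st.groups.items():
        rss = g.s_yy - 2.0 * beta0 @ g.Xty + beta0 @ g.XtX @ beta0
        rcp = g.s_y12 - beta0 @ g.Xtyc + 0.5 * beta0 @ g.C12 @ beta0
        var = rss / (2.0 * g.n)
        rs[z] = float(np.clip(rcp / g.n / var, -0.95, 0.95)) if var > 0 else 0.0
        v_tot += rss
    v_tot /= st.n_subjects
    r_mz, r_dz = rs["MZ"], rs["DZ"]
    lo, hi = 0.05, 0.90
    if model == "ACE":
        p = np.array([2 * (r_mz - r_dz), 2 * r_dz - r_mz, 1 - r_mz])
    elif model == "ADE":
        p = np.array([4 * r_dz - r_mz, 2 * r_mz - 4 * r_dz, 1 - r_mz])
    elif model == "AE":
        p = np.array([r_mz, 1 - r_mz])
    elif model == "CE":
        p = np.array([0.5 * (r_mz + r_dz), 1 - 0.5 * (r_mz + r_dz)])
    else:  # E
        p = np.array([1.0])
    p = np.clip(p, lo, hi)
    p = p / p.sum()
    return np.sqrt(p * max(v_tot, 1e-8))


def _fit_e_only(st: _SuffStats) -> tuple[np.ndarray, float, np.ndarray]:
    """Closed-form E-only fit: OLS betas, e^2 = RSS/N (scaled data)."""
    _, beta = st.loglik_profiled(1.0, 0.0, 0.0)
    rss = 0.0
    for g in st.groups.values():
        rss += g.s_yy - 2.0 * beta @ g.Xty + beta @ g.XtX @ beta
    e2 = rss / st.n_subjects
    N = st.n_subjects
    ll = -0.5 * N * (np.log(2.0 * np.pi) + np.log(e2) + 1.0)
    return np.array([np.sqrt(e2)]), float(ll), beta


def fit_twin_model(
    pairs_mz: Sequence[TwinPairRecord],
    pairs_dz: Sequence[TwinPairRecord],
    model: str = "ACE",
    *,
    n_starts: int = 5,
    seed: int = 0,
    compute_ci: bool = False,
) -> ModelFit:
    """Fit a twin variance-component model by maximum likelihood.

    Runs ``n_starts`` optimizations (a Falconer-informed start plus jittered
    copies, jitter seeded by ``seed``) of the profiled likelihood over
    unconstrained path coefficients and keeps the best.  ``compute_ci``
    additionally fills 95% profile-likelihood intervals for every free
    standardized component.
    """
    if model not in MODELS:
        raise ValidationError(f"unknown model {model!r}; choose from {MODELS}")
    st = _SuffStats(pairs_mz, pairs_dz)

    if model == "E":
        paths, ll_scaled, beta = _fit_e_only(st)
        converged = True
    else:
        def neg_ll(x: np.ndarray) -> float:
            v, k_mz, k_dz = _covariance(model, x)
            ll, _ = st.loglik_profiled(v, k_mz, k_dz)
            return -ll

        x0 = _start_proportions(model, st)
        rng = np.random.default_rng(seed)
        starts = [x0] + [x0 * np.exp(0.25 * rng.standard_normal(x0.size)) for _ in range(n_starts - 1)]
        best = None
        for s0 in starts:
            res = optimize.minimize(
                neg_ll, s0, method="L-BFGS-B",
                options={"gtol": 1e-8, "ftol": 1e-14, "maxiter": 1000},
            )
            if best is None:
                best = res
                continue
            # prefer cleanly terminated runs when objective values tie within
            # floating-point noise of the objective's magnitude
            tie = abs(res.fun - best.fun) <= 1e-10 * max(1.0, abs(best.fun))
            if (tie and res.success and not best.success) or (not tie and res.fun < best.fun):
                best = res
        # gradient-free polish: finite-difference noise can make L-BFGS-B end a
        # run "abnormally" at the optimum; Nelder-Mead certifies stationarity
        polish = optimize.minimize(
            neg_ll, best.x, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-11 * max(1.0, abs(best.fun)),
                     "maxiter": 4000},
        )
        x_hat = polish.x if polish.fun <= best.fun else best.x
        converged = bool(best.success or polish.success)
        paths = np.abs(x_hat)
        v, k_mz, k_dz = _covariance(model, paths)
        ll_scaled, beta = st.loglik_profiled(v, k_mz, k_dz)
        converged = converged and np.isfinite(ll_scaled)

    sq = paths * paths
    total = float(sq.sum())
    props = {lbl: float(s / total) for lbl, s in zip(_PATHS[model], sq)}
    components = VarianceComponents(
        a2=props.get("a", 0.0), c2=props.get("c", 0.0),
        d2=props.get("d", 0.0), e2=props.get("e", 0.0),
    )
    s = st.scale
    mean_model = MeanModel(
        intercept=float(s * beta[0] - s * beta[1] * st.mean_age),
        beta_age=float(s * beta[1]),
        beta_sex=float(s * beta[2]),
    )
    fit = ModelFit(
        model=model,
        components=components,
        mean_model=mean_model,
        total_sd=float(np.sqrt(total) * s),
        loglik=float(ll_scaled - st.n_subjects * np.log(s)),
        n_pairs=(st.n_mz, st.n_dz),
        converged=converged,
        _stats=st,
    )
    if compute_ci:
        for comp in _PATHS[model]:
            name = comp + "2"
            fit.ci95[name] = component_ci(fit, name)
    return fit


def lrt_from_logliks(ll_full: float, ll_reduced: float, df: int) -> tuple[float, int, float]:
    """Likelihood-ratio statistic 2*(ll_full - ll_reduced), floored at 0,
    against the chi-squared reference with ``df`` degrees of freedom."""
    stat = max(0.0, 2.0 * (ll_full - ll_reduced))
    if df <= 0:
        return stat, df, 1.0
    return stat, df, float(stats.chi2.sf(stat, df))


def likelihood_ratio_test(
    full: ModelFit, reduced: ModelFit, *, boundary_mixture: bool = False
) -> tuple[float, int, float]:
    """LRT of a reduced twin model against the full model on the same data.

    Uses the naive chi-squared reference by default (conservative for a
    variance component on its boundary); ``boundary_mixture=True`` switches
    to the 50:50 chi2_0/chi2_1 mixture for single-parameter reductions.
    """
    if full.model != reduced.model and (full.model, reduced.model) not in _NESTED:
        raise ValidationError(f"{reduced.model} is not nested in {full.model}")
    if full._stats is not None and reduced._stats is not None:
        if full._stats.fingerprint != reduced._stats.fingerprint:
            raise ValidationError("fits were computed on different data")
    df = N_VARIANCE_PARAMS[full.model] - N_VARIANCE_PARAMS[reduced.model]
    stat, df, p = lrt_from_logliks(full.loglik, reduced.loglik, df)
    if boundary_mixture and df == 1:
        p = float(0.5 * stats.chi2.sf(stat, 1)) if stat > 0 else 1.0
    return stat, df, p


def select_model(
    fits: Mapping[str, ModelFit], alpha: float = 0.05
) -> ModelSelectionResult:
    """Choose among ACE/AE/CE by the likelihood-ratio parsimony rule.

    A reduction is adopted when its LRT against ACE is non-significant
    (p > alpha) while the competing reduction is rejected; if both reductions
    are non-significant the one with the higher log-likelihood wins (ties go
    to AE); if both are rejected the full ACE model is retained.
    """
    for m in ("ACE", "AE", "CE"):
        if m not in fits:
            raise ValidationError(f"select_model requires an {m} fit")
    lrt_ae = likelihood_ratio_test(fits["ACE"], fits["AE"])
    lrt_ce = likelihood_ratio_test(fits["ACE"], fits["CE"])
    pvals = {"AE": lrt_ae[2], "CE": lrt_ce[2]}
    ae_ok, ce_ok = lrt_ae[2] > alpha, lrt_ce[2] > alpha
    if ae_ok and not ce_ok:
        return ModelSelectionResult("AE", lrt_ae, "negligible_C", pvals)
    if ce_ok and not ae_ok:
        return ModelSelectionResult("CE", lrt_ce, "negligible_A", pvals)
    if ae_ok and ce_ok:
        if fits["CE"].loglik > fits["AE"].loglik:
            return ModelSelectionResult("CE", lrt_ce, "negligible_A", pvals)
        return ModelSelectionResult("AE", lrt_ae, "negligible_C", pvals)
    return ModelSelectionResult("ACE", (0.0, 0, 1.0), "both_significant", pvals)


def _implied_correlations(model: str, props: dict[str, float]) -> tuple[float, float]:
    a2 = props.get("a2", 0.0)
    c2 = props.get("c2", 0.0)
    d2 = props.get("d2", 0.0)
    return a2 + c2 + d2, 0.5 * a2 + c2 + 0.25 * d2


def component_ci(
    fit: ModelFit, component: str, level: float = 0.95
) -> tuple[float, float]:
    """Profile-likelihood confidence interval for one standardized component.

    The interval is the set of proportion values whose profile log-likelihood
    (all other parameters re-maximized, total variance and mean model profiled
    in closed form) lies within ``chi2.ppf(level, 1)/2`` of the maximum,
    intersected with [0, 1].
    """
    if not fit.converged:
        raise ValidationError("cannot compute a profile CI from a non-converged fit")
    st = fit._stats
    if st is None:
        raise ValidationError("fit does not retain its data; refit to compute CIs")
    free = [p + "2" for p in _PATHS[fit.model]]
    if component not in free:
        raise ValidationError(f"component {component!r} is not free in the {fit.model} model")
    others = [c for c in free if c != component]

    def profile(t: float) -> float:
        rest = 1.0 - t
        if len(others) == 1:
            props = {component: t, others[0]: rest}
            return st.loglik_correlation(*_implied_correlations(fit.model, props))
        # two remaining components: maximize over their split of the mass
        def nll(u: float) -> float:
            props = {component: t, others[0]: u * rest, others[1]: (1.0 - u) * rest}
            return -st.loglik_correlation(*_implied_correlations(fit.model, props))
        res = optimize.minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                                       options={"xatol": 1e-7})
        return -float(res.fun)

    t_hat = float(np.clip(getattr(fit.components, component), 0.0, 1.0))
    ll_hat = fit.loglik + st.n_subjects * np.log(st.scale)  # back to scaled-data units
    ll_hat = max(ll_hat, profile(t_hat))
    crit = float(stats.chi2.ppf(level, 1)) / 2.0
    eps = 1e-7

    def g(t: float) -> float:
        return profile(t) - (ll_hat - crit)

    t_in = float(np.clip(t_hat, eps, 1.0 - eps))
    if g(eps) >= 0:
        lo = 0.0
    else:
        lo = float(optimize.brentq(g, eps, t_in, xtol=1e-6))
    if g(1.0 - eps) >= 0:
        hi = 1.0
    else:
        hi = float(optimize.brentq(g, t_in, 1.0 - eps, xtol=1e-6))
    return lo, hi
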