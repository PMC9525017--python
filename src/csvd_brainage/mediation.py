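"""Single-level three-variable mediation with BCa bootstrap inference.

The model asks whether a mediator M (here: regional brain-age gap) carries
part of the effect of a binary exposure X (CSVD status) on an outcome Y
(a cognitive score).  Three least-squares regressions, each including the
same confounders Z (age, age², sex, education years, EFC, TIV), define the
paths::

    M = a  X + Z g1 + e_m          (path a)
    Y = c  X + Z g2 + e_y          (total effect, path c)
    Y = b  M + c' X + Z g3 + e'_y  (paths b and c')

The indirect effect is a*b, and for nested least squares with a shared
covariate set the decomposition c = c' + a*b holds exactly; it is asserted
at fit time.  The proportion mediated is 100 * a*b / c.

Inference on a, b and a*b uses case resampling of whole rows with
bias-corrected-and-accelerated (BCa) confidence intervals: the bias
constant z0 is the normal quantile of the fraction of bootstrap statistics
below the point estimate, and the acceleration is the jackknife skewness
coefficient.  Two-sided p-values are obtained by inverting the BCa
interval — the smallest level at which the interval excludes zero.
Setting ``accelerated=False`` drops the acceleration term (plain
bias-corrected percentile intervals).

The bootstrap loop is vectorised: all resampled regressions are solved as
batched normal equations, which keeps 10 000 resamples at cohort scale in
the seconds range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "MediationInput",
    "PathCoefficients",
    "MediationResult",
    "fit_mediation_paths",
    "bootstrap_mediation",
    "proportion_mediated",
    "mediation_screen",
    "bca_interval",
    "bias_constant",
    "jackknife_acceleration",
]

IDENTITY_TOL = 1e-10


@dataclass
class MediationInput:
    """Aligned (X, M, Y, covariates) arrays for one mediation model."""

    x: np.ndarray
    m: np.ndarray
    y: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.x)
        if len(self.m) != n or len(self.y) != n:
            raise ValueError("x, m, y must have equal length")
        if self.covariates is not None and len(self.covariates) != n:
            raise ValueError("covariates misaligned with x")
        if np.ptp(self.x) == 0:
            raise ValueError("exposure x is constant")
        for nm, v in (("x", self.x), ("m", self.m), ("y", self.y)):
            if np.isnan(v).any():
                raise ValueError(f"missing values in {nm}")

    @property
    def n(self) -> int:
        return len(self.x)

    def designs(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(D1, D3, names): D1 = [x, 1, Z] for models 1-2, D3 adds m.

        Covariate columns are z-scored here: with an intercept present this
        leaves the x and m coefficients (and hence all paths) unchanged
        while keeping the normal equations well conditioned even with an
        age-squared column in the design.
        """
        n = self.n
        if self.covariates is not None:
            Z = self.covariates.to_numpy(dtype=float)
            mu = Z.mean(axis=0)
            sd = Z.std(axis=0)
            sd[sd == 0] = 1.0
            Z = (Z - mu) / sd
            znames = list(self.covariates.columns)
        else:
            Z = np.empty((n, 0))
            znames = []
        D1 = np.column_stack([self.x, np.ones(n), Z])
        D3 = np.column_stack([self.x, self.m, np.ones(n), Z])
        names = ["x", "m", "const", *znames]
        return D1, D3, names


@dataclass
class PathCoefficients:
    """Least-squares path estimates with classical standard errors."""

    a: float
    b: float
    c: float
    cprime: float
    se_a: float
    se_b: float
    se_c: float
    se_cprime: float
    n: int
    residuals_m: np.ndarray = field(repr=False)
    residuals_y: np.ndarray = field(repr=False)
    residuals_y_full: np.ndarray = field(repr=False)

    @property
    def ab(self) -> float:
        return self.a * self.b


@dataclass
class MediationResult:
    """Point estimates, BCa intervals and p-values for one model."""

    paths: PathCoefficients
    p_a: float
    p_b: float
    p_ab: float
    ci: dict[str, tuple[float, float]]
    proportion_mediated: float
    proportion_defined: bool
    B: int
    seed: int | None
    alpha: float
    accelerated: bool

    @property
    def significant(self) -> bool:
        """All three relevant paths below alpha (the default decision rule)."""
        return max(self.p_a, self.p_b, self.p_ab) < self.alpha


def _ols(X: np.ndarray, y: np.ndarray, names: list[str]):
    """Coefficients, residuals and classical SEs; errors name rank problems."""
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        r = 0
        for j in range(p):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                raise ValueError(
                    f"rank-deficient design: column {names[j]!r} is collinear"
                )
            r = rj
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - p
    if dof <= 0:
        raise ValueError(f"not enough rows ({n}) for {p} parameters")
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    return coef, resid, se


def fit_mediation_paths(inp: MediationInput) -> PathCoefficients:
    """Fit the three path regressions and check c = c' + a*b."""
    D1, D3, names = inp.designs()
    n1 = [names[0], names[2]] + names[3:]
    coef1, res_m, se1 = _ols(D1, inp.m, n1)
    coef2, res_y, se2 = _ols(D1, inp.y, n1)
    coef3, res_yf, se3 = _ols(D3, inp.y, names)
    paths = PathCoefficients(
        a=float(coef1[0]), b=float(coef3[1]),
        c=float(coef2[0]), cprime=float(coef3[0]),
        se_a=float(se1[0]), se_b=float(se3[1]),
        se_c=float(se2[0]), se_cprime=float(se3[0]),
        n=inp.n,
        residuals_m=res_m, residuals_y=res_y, residuals_y_full=res_yf,
    )
    scale = max(1.0, abs(paths.c))
    gap = abs(paths.c - (paths.cprime + paths.ab))
    if gap > IDENTITY_TOL * scale:
        raise AssertionError(
            f"mediation identity violated: |c - (c' + a*b)| = {gap:.3e}"
        )
    return paths


# ----------------------------------------------------------- BCa machinery

def bias_constant(samples: np.ndarray, theta_hat: float, B: int | None = None) -> float:
    """z0 = Phi^-1( #{theta* < theta_hat} / B ), clamped away from 0 and 1."""
    samples = np.asarray(samples, dtype=float)
    B = B or len(samples)
    prop = np.count_nonzero(samples < theta_hat) / B
    lo = 1.0 / (2 * B)
    if prop <= 0 or prop >= 1:
        warnings.warn("bootstrap distribution entirely on one side of the "
                      "estimate; bias constant clamped", RuntimeWarning,
                      stacklevel=2)
    prop = min(max(prop, lo), 1 - lo)
    return float(norm.ppf(prop))


def jackknife_acceleration(jack_thetas: np.ndarray) -> float:
    """Acceleration a-hat from leave-one-out estimates (skewness formula)."""
    t = np.asarray(jack_thetas, dtype=float)
    d = t.mean() - t
    denom = 6.0 * (np.sum(d**2) ** 1.5)
    if denom == 0:
        return 0.0
    return float(np.sum(d**3) / denom)


def bca_interval(samples, theta_hat: float, alpha: float,
                 z0: float, ahat: float) -> tuple[float, float]:
    """BCa (1 - alpha) interval; with z0 = ahat = 0 it is the percentile
    interval exactly."""
    samples = np.asarray(samples, dtype=float)
    levels = []
    for z in (norm.ppf(alpha / 2), norm.ppf(1 - alpha / 2)):
        u = z0 + z
        denom = 1.0 - ahat * u
        adj = z0 + (u / denom if denom > 0 else np.sign(u) * np.inf)
        levels.append(float(norm.cdf(adj)))
    lo, hi = np.quantile(samples, np.clip(levels, 0.0, 1.0))
    return float(lo), float(hi)


def _bca_pvalue(samples: np.ndarray, z0: float, ahat: float) -> float:
    """Two-sided p by inversion: smallest alpha whose BCa interval excludes 0."""
    B = len(samples)
    lo = 1.0 / (2 * B)
    q = (np.count_nonzero(samples < 0) + 0.5 * np.count_nonzero(samples == 0)) / B
    q = min(max(q, lo), 1 - lo)
    w = norm.ppf(q) - z0
    denom = 1.0 + ahat * w
    if denom <= 0:
        return float(2 * lo)
    z = w / denom - z0
    p = 2.0 * min(norm.cdf(z), 1.0 - norm.cdf(z))
    return float(min(1.0, max(p, 2 * lo)))


def _batched_coefs(D: np.ndarray, yv: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Solve OLS for each resample (row-index matrix) via normal equations."""
    A = D[idx]  # (nb, n, p)
    t = yv[idx]  # (nb, n)
    XtX = np.matmul(A.transpose(0, 2, 1), A)
    Xty = np.matmul(A.transpose(0, 2, 1), t[..., None])
    try:
        return np.linalg.solve(XtX, Xty)[..., 0]
    except np.linalg.LinAlgError:
        out = np.empty((len(idx), D.shape[1]))
        for i in range(len(idx)):
            out[i], *_ = np.linalg.lstsq(A[i], t[i], rcond=None)
        return out


def bootstrap_mediation(
    inp: MediationInput,
    B: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
    accelerated: bool = True,
    chunk: int = 1000,
    max_redraws: int = 100,
) -> MediationResult:
    """Case-resampling bootstrap of the mediation paths with BCa inference.

    Whole rows (X, M, Y, Z) are resampled with replacement B times;
    resamples with a constant exposure or mediator are redrawn (up to
    ``max_redraws`` attempts, then an error).  For each statistic in
    {a, b, a*b} the bias constant, jackknife acceleration, BCa interval at
    level 1 - alpha and the inversion p-value are computed.  A BCa interval
    for the proportion mediated is included when the total effect is
    bounded away from zero.
    """
    if B < 100:
        raise ValueError(f"B must be >= 100, got {B}")
    paths = fit_mediation_paths(inp)
    D1, D3, _ = inp.designs()
    n = inp.n
    rng = np.random.default_rng(seed)

    a_s = np.empty(B)
    b_s = np.empty(B)
    c_s = np.empty(B)
    cp_s = np.empty(B)
    done = 0
    while done < B:
        nb = min(chunk, B - done)
        idx = rng.integers(0, n, size=(nb, n))
        for _ in range(max_redraws):
            xs = inp.x[idx]
            ms = inp.m[idx]
            bad = (np.ptp(xs, axis=1) == 0) | (np.ptp(ms, axis=1) == 0)
            if not bad.any():
                break
            idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
        else:
            raise RuntimeError(
                "degenerate bootstrap resamples persisted after "
                f"{max_redraws} redraws"
            )
        c1 = _batched_coefs(D1, inp.m, idx)
        c2 = _batched_coefs(D1, inp.y, idx)
        c3 = _batched_coefs(D3, inp.y, idx)
        a_s[done:done + nb] = c1[:, 0]
        c_s[done:done + nb] = c2[:, 0]
        cp_s[done:done + nb] = c3[:, 0]
        b_s[done:done + nb] = c3[:, 1]
        done += nb
    ab_s = a_s * b_s

    # jackknife (leave-one-out) estimates for the acceleration
    if accelerated:
        all_idx = np.arange(n)
        jk_idx = np.stack([np.delete(all_idx, i) for i in range(n)])
        j1 = _batched_coefs(D1, inp.m, jk_idx)
        j2 = _batched_coefs(D1, inp.y, jk_idx)
        j3 = _batched_coefs(D3, inp.y, jk_idx)
        jack = {
            "a": j1[:, 0],
            "b": j3[:, 1],
            "ab": j1[:, 0] * j3[:, 1],
            "proportion": 100.0 * j1[:, 0] * j3[:, 1] / j2[:, 0],
        }
    else:
        jack = {}

    stats = {"a": (a_s, paths.a), "b": (b_s, paths.b), "ab": (ab_s, paths.ab)}
    ci: dict[str, tuple[float, float]] = {}
    pvals: dict[str, float] = {}
    for name, (samples, point) in stats.items():
        z0 = bias_constant(samples, point, B)
        ah = jackknife_acceleration(jack[name]) if accelerated else 0.0
        ci[name] = bca_interval(samples, point, alpha, z0, ah)
        pvals[name] = _bca_pvalue(samples, z0, ah)

    prop, defined = proportion_mediated(paths.ab, paths.c, as_percent=True)
    if defined and np.all(np.sign(c_s) == np.sign(paths.c)):
        pm_s = 100.0 * ab_s / c_s
        z0 = bias_constant(pm_s, prop, B)
        ah = jackknife_acceleration(jack["proportion"]) if accelerated else 0.0
        ci["proportion"] = bca_interval(pm_s, prop, alpha, z0, ah)

    return MediationResult(
        paths=paths,
        p_a=pvals["a"], p_b=pvals["b"], p_ab=pvals["ab"],
        ci=ci,
        proportion_mediated=prop,
        proportion_defined=defined,
        B=B, seed=seed, alpha=alpha, accelerated=accelerated,
    )


def proportion_mediated(ab: float, c: float, tol: float = 1e-8,
                        as_percent: bool = True):
    """100 * ab / c (percent); flagged undefined when |c| < tol.

    Returns ``(value, defined)``; the value is NaN when undefined.  Values
    outside [0, 100] are reported raw (suppression or sign reversal), not
    truncated.
    """
    if abs(c) < tol:
        return float("nan"), False
    v = ab / c * (100.0 if as_percent else 1.0)
    return float(v), True


def mediation_screen(
    bag,
    subjects: pd.DataFrame,
    group,
    regions: list[str] | None = None,
    outcomes=("mmse",),
    covariates: pd.DataFrame | None = None,
    B: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    fwer: bool = False,
    accelerated: bool = True,
    require_paths: tuple[str, ...] = ("a", "b", "ab"),
) -> pd.DataFrame:
    """One mediation model per (region, outcome) pair.

    ``bag`` is a BagResult (``scope == region_id`` rows supply the
    mediator); ``group`` the 0/1 CSVD flags indexed by subject_id.
    A pair is flagged significant when every path named in
    ``require_paths`` has p < alpha; with ``fwer=True`` an additional
    column applies a Bonferroni threshold over all screened models.
    Per-model seeds are spawned deterministically from ``seed``.
    """
    from .group_stats import MEDIATION_COVARIATES, build_covariates

    ids = subjects["subject_id"].to_numpy()
    g = pd.Series(group).loc[ids].to_numpy(dtype=float)
    covs = covariates if covariates is not None else build_covariates(
        subjects, include=MEDIATION_COVARIATES)
    wide = bag.wide("bag").loc[ids]
    if regions is None:
        regions = [s for s in bag.scopes if s != "global"]
    missing_r = [r for r in regions if r not in wide.columns]
    if missing_r:
        raise ValueError(f"BAG table has no scope for regions: {missing_r}")
    missing_o = [o for o in outcomes if o not in subjects.columns]
    if missing_o:
        raise ValueError(f"unknown outcome columns: {missing_o}")
    bad = [p for p in require_paths if p not in ("a", "b", "ab")]
    if bad:
        raise ValueError(f"require_paths entries must be in {{a, b, ab}}: {bad}")

    n_models = len(regions) * len(outcomes)
    fwer_threshold = alpha / n_models if n_models else alpha
    rows = []
    k = 0
    for outcome in outcomes:
        yv = subjects[outcome].to_numpy(dtype=float)
        for rid in regions:
            child_seed = int(np.random.SeedSequence((seed, k)).generate_state(1)[0]
                             % (2**31))
            k += 1
            inp = MediationInput(x=g, m=wide[rid].to_numpy(dtype=float),
                                 y=yv, covariates=covs)
            res = bootstrap_mediation(inp, B=B, seed=child_seed, alpha=alpha,
                                      accelerated=accelerated)
            pv = {"a": res.p_a, "b": res.p_b, "ab": res.p_ab}
            sig = all(pv[p] < alpha for p in require_paths)
            row = {
                "region_id": rid, "outcome": outcome,
                "a": res.paths.a, "b": res.paths.b,
                "c": res.paths.c, "cprime": res.paths.cprime,
                "ab": res.paths.ab,
                "se_a": res.paths.se_a, "se_b": res.paths.se_b,
                "se_c": res.paths.se_c, "se_cprime": res.paths.se_cprime,
                "p_a": res.p_a, "p_b": res.p_b, "p_ab": res.p_ab,
                "ab_ci_low": res.ci["ab"][0], "ab_ci_high": res.ci["ab"][1],
                "proportion_mediated_pct": res.proportion_mediated,
                "proportion_defined": res.proportion_defined,
                "significant": sig,
            }
            if "proportion" in res.ci:
                row["proportion_ci_low"] = res.ci["proportion"][0]
                row["proportion_ci_high"] = res.ci["proportion"][1]
            if fwer:
                row["significant_fwer"] = all(pv[p] < fwer_threshold
                                              for p in require_paths)
            rows.append(row)
    return pd.DataFrame(rows)
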