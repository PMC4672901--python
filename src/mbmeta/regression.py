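"""Hierarchical precision-weighted meta-regression.

The model for a per-experiment effect y (raw or percentage change) is

    y = X beta + b_study + eps,   b_study ~ N(0, tau^2),

with residual covariance Sigma having per-record variances
sigma^2 / weight (weight = 1 / Var(y) from the primary experiment) and a
single correlation rho between residuals inside each shared-control
block, zero elsewhere (block compound symmetry).

Estimation is maximum likelihood: beta and sigma^2 are profiled out in
closed form at each value of the variance-ratio parameters
(lambda = tau^2 / sigma^2 and rho), which are optimised numerically with
jittered multi-starts. When a spec carries no cluster term (or no
multi-record block), the corresponding parameter is fixed at zero and
the fit collapses to (generalised) weighted least squares exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import linalg, optimize, stats

from .corpus import Dataset
from .effects import Z_95, effect_from_record

__all__ = [
    "GLMMSpec",
    "GLMMFit",
    "ModelFrame",
    "DriverEffect",
    "DesignError",
    "build_frame",
    "glmm_loglik",
    "fit_glmm",
    "generalized_r2",
    "bootstrap_generalized_r2",
    "residual_driver_effects",
    "cellcount_regression",
    "per_cell_model",
]

COVARIATES = (
    "TIME",
    "BENZALDEHYDE",
    "TEMPERATURE",
    "VOLTAGE",
    "AC_DC",
    "RH",
    "DRIVER",
    "LOBE_CATEGORY",
    "CELL_COUNT",
)

RHO_MAX = 0.99


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class GLMMSpec:
    """Model specification for the hierarchical weighted regression."""

    response: str = "percent_change"  # or "raw_change"
    covariates: tuple[str, ...] = ("TIME", "BENZALDEHYDE")
    cluster: bool = True  # study-level random effect
    residual_structure: str = "diagonal"  # or "block_compound_symmetry"
    # default is ML so that likelihood ratios between nested fixed-effect
    # structures (generalised R^2) are valid; REML gives less biased
    # variance components for recovery studies
    reml: bool = False

    def __post_init__(self):
        for c in self.covariates:
            if c not in COVARIATES:
                raise ValueError(f"unknown covariate {c!r}")
        if self.response not in ("percent_change", "raw_change"):
            raise ValueError(f"unknown response {self.response!r}")
        if self.residual_structure not in ("diagonal", "block_compound_symmetry"):
            raise ValueError(f"unknown residual structure {self.residual_structure!r}")


@dataclass
class ModelFrame:
    """Numeric arrays extracted from a dataset for one model spec."""

    y: np.ndarray
    X: np.ndarray
    columns: list[str]
    weights: np.ndarray
    clusters: np.ndarray  # integer study index, -1 if clustering disabled
    blocks: np.ndarray  # integer shared-control block index, -1 if unblocked
    records: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.y.size


def _record_value(r, cov: str, cell_counts: Optional[dict]):
    if cov == "TIME":
        return r.delay_min
    if cov == "BENZALDEHYDE":
        return 1.0 if r.benzaldehyde else 0.0
    if cov == "TEMPERATURE":
        return r.temperature_c
    if cov == "VOLTAGE":
        return r.shock_v
    if cov == "RH":
        return r.rh_pct
    if cov == "CELL_COUNT":
        if cell_counts is None or r.driver not in cell_counts:
            return None
        return float(cell_counts[r.driver])
    raise KeyError(cov)


def build_frame(
    spec: GLMMSpec,
    ds: Dataset,
    cell_counts: Optional[dict] = None,
) -> ModelFrame:
    """Compute effects, weights and the design matrix for a dataset.

    Records missing a required covariate value are dropped with a warning.
    Categorical covariates (AC_DC, DRIVER, LOBE_CATEGORY) are dummy-coded
    against the first level seen.
    """
    kept = []
    for r in ds.records:
        es = effect_from_record(r, scale=spec.response)
        if es.se <= 0:
            warnings.warn(
                f"dropping {r.study_id}/{r.figure_panel}: zero effect SE "
                f"gives an infinite precision weight"
            )
            continue
        row = {}
        ok = True
        for cov in spec.covariates:
            if cov in ("AC_DC", "DRIVER", "LOBE_CATEGORY"):
                row[cov] = {
                    "AC_DC": r.current_type,
                    "DRIVER": r.driver,
                    "LOBE_CATEGORY": r.lobe_category,
                }[cov]
                if row[cov] is None:
                    ok = False
            else:
                row[cov] = _record_value(r, cov, cell_counts)
                if row[cov] is None:
                    ok = False
        if not ok:
            warnings.warn(
                f"dropping {r.study_id}/{r.figure_panel}: missing covariate value"
            )
            continue
        kept.append((r, es, row))
    if not kept:
        raise DesignError("no usable records for this model spec")

    columns = ["Intercept"]
    design_cols: list[list[float]] = [[1.0] * len(kept)]
    for cov in spec.covariates:
        values = [row[cov] for _, _, row in kept]
        if cov in ("AC_DC", "DRIVER", "LOBE_CATEGORY"):
            levels = sorted(set(values))
            for level in levels[1:]:
                columns.append(f"{cov}[{level}]")
                design_cols.append([1.0 if v == level else 0.0 for v in values])
        else:
            columns.append(cov)
            design_cols.append([float(v) for v in values])
    X = np.column_stack(design_cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError(
            f"rank-deficient design matrix ({X.shape[1]} columns, "
            f"rank {np.linalg.matrix_rank(X)})"
        )

    y = np.array([es.estimate for _, es, _ in kept])
    weights = np.array([1.0 / es.variance for _, es, _ in kept])

    if spec.cluster:
        study_ids = {r.study_id for r, _, _ in kept}
        index = {s: i for i, s in enumerate(sorted(study_ids))}
        clusters = np.array([index[r.study_id] for r, _, _ in kept])
    else:
        clusters = np.full(len(kept), -1)

    if spec.residual_structure == "block_compound_symmetry":
        block_ids = [r.shared_control_id for r, _, _ in kept]
        index = {}
        blocks = np.empty(len(kept), dtype=int)
        for i, b in enumerate(block_ids):
            if b is None:
                blocks[i] = -1
            else:
                blocks[i] = index.setdefault(b, len(index))
        if not index:
            raise DesignError(
                "block_compound_symmetry requires at least one record with "
                "a shared_control_id"
            )
    else:
        blocks = np.full(len(kept), -1)

    return ModelFrame(
        y=y,
        X=X,
        columns=columns,
        weights=weights,
        clusters=clusters,
        blocks=blocks,
        records=[r for r, _, _ in kept],
    )


def _cluster_outer(clusters: np.ndarray) -> np.ndarray:
    """Z Z^T indicator matrix for the study random effect."""
    n = clusters.size
    zz = np.zeros((n, n))
    for c in np.unique(clusters):
        if c < 0:
            continue
        idx = np.flatnonzero(clusters == c)
        zz[np.ix_(idx, idx)] = 1.0
    return zz


def _block_correlation(blocks: np.ndarray, weights: np.ndarray, rho: float) -> np.ndarray:
    """C(rho): diag(1/w) plus rho off-diagonals inside shared-control blocks."""
    s = 1.0 / np.sqrt(weights)
    c = np.diag(s**2)
    if rho != 0.0:
        for b in np.unique(blocks):
            if b < 0:
                continue
            idx = np.flatnonzero(blocks == b)
            for i in idx:
                for j in idx:
                    if i != j:
                        c[i, j] = rho * s[i] * s[j]
    return c


def _scaled_cov(frame: ModelFrame, lam: float, rho: float) -> np.ndarray:
    """W = V / sigma^2 = lambda Z Z^T + C(rho)."""
    w = _block_correlation(frame.blocks, frame.weights, rho)
    if lam > 0:
        w = w + lam * _cluster_outer(frame.clusters)
    return w


def glmm_loglik(params: dict, frame: ModelFrame) -> float:
    """Gaussian log-likelihood at explicit parameter values.

    ``params`` carries ``beta`` (array matching frame.columns), ``tau2``,
    ``rho`` and ``sigma2``.
    """
    beta = np.asarray(params["beta"], dtype=float)
    tau2 = float(params["tau2"])
    rho = float(params["rho"])
    sigma2 = float(params["sigma2"])
    if sigma2 <= 0 or tau2 < 0 or not 0.0 <= rho < 1.0:
        raise ValueError("parameters outside their domains")
    v = sigma2 * _scaled_cov(frame, tau2 / sigma2, rho)
    try:
        cho = linalg.cho_factor(v, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError(f"residual covariance not positive definite: {exc}") from exc
    r = frame.y - frame.X @ beta
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    quad = float(r @ linalg.cho_solve(cho, r))
    n = frame.n
    return -0.5 * (n * math.log(2.0 * math.pi) + logdet + quad)


@dataclass
class GLMMFit:
    spec: GLMMSpec
    frame: ModelFrame
    beta: np.ndarray
    beta_se: np.ndarray
    tau2: float
    rho: float
    sigma2: float
    loglik: float
    residuals: np.ndarray
    converged: bool

    @property
    def n(self) -> int:
        return self.frame.n

    def coef_table(self) -> dict:
        return {
            name: {"estimate": float(b), "se": float(s)}
            for name, b, s in zip(self.frame.columns, self.beta, self.beta_se)
        }


def _profile(frame: ModelFrame, lam: float, rho: float, reml: bool = False):
    """GLS beta-hat, profiled sigma2-hat and profile loglik at (lambda, rho).

    With ``reml=True`` sigma^2 uses the n - p divisor and the objective is
    the restricted likelihood (including the log|X' W^-1 X| term).
    """
    w = _scaled_cov(frame, lam, rho)
    cho = linalg.cho_factor(w, lower=True)
    wx = linalg.cho_solve(cho, frame.X)
    wy = linalg.cho_solve(cho, frame.y)
    xtwx = frame.X.T @ wx
    beta = np.linalg.solve(xtwx, frame.X.T @ wy)
    r = frame.y - frame.X @ beta
    quad = float(r @ linalg.cho_solve(cho, r))
    n = frame.n
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    if reml:
        p = frame.X.shape[1]
        sigma2 = quad / (n - p)
        sign, logdet_x = np.linalg.slogdet(xtwx)
        ll = -0.5 * (
            (n - p) * (math.log(2.0 * math.pi) + math.log(sigma2) + 1.0)
            + logdet
            + logdet_x
        )
    else:
        sigma2 = quad / n
        ll = -0.5 * (n * math.log(2.0 * math.pi) + n * math.log(sigma2) + logdet + n)
    return beta, sigma2, ll, xtwx, r


def fit_glmm(
    spec: GLMMSpec,
    ds_or_frame,
    cell_counts: Optional[dict] = None,
    n_restarts: int = 5,
    seed: int = 0,
) -> GLMMFit:
    """Maximum-likelihood fit of the hierarchical weighted model.

    The variance-ratio parameters are optimised by bounded quasi-Newton
    with jittered restarts; beta and sigma^2 are profiled out in closed
    form, so fits with both variance parameters fixed reduce exactly to
    weighted least squares.
    """
    frame = (
        ds_or_frame
        if isinstance(ds_or_frame, ModelFrame)
        else build_frame(spec, ds_or_frame, cell_counts=cell_counts)
    )
    fit_lam = spec.cluster and len(np.unique(frame.clusters[frame.clusters >= 0])) >= 2
    if spec.cluster and not fit_lam:
        warnings.warn("fewer than 2 study clusters: tau^2 fixed at 0")
    block_sizes = [np.sum(frame.blocks == b) for b in np.unique(frame.blocks) if b >= 0]
    fit_rho = spec.residual_structure == "block_compound_symmetry" and any(
        s >= 2 for s in block_sizes
    )
    if spec.residual_structure == "block_compound_symmetry" and not fit_rho:
        warnings.warn("no multi-record shared-control block: rho fixed at 0")

    def unpack(u: np.ndarray) -> tuple[float, float]:
        i = 0
        lam = rho = 0.0
        if fit_lam:
            lam = math.exp(u[i])
            i += 1
        if fit_rho:
            rho = RHO_MAX / (1.0 + math.exp(-u[i]))
        return lam, rho

    n_free = int(fit_lam) + int(fit_rho)
    if n_free == 0:
        beta, sigma2, ll, xtwx, r = _profile(frame, 0.0, 0.0, reml=spec.reml)
        cov = sigma2 * np.linalg.inv(xtwx)
        return GLMMFit(
            spec, frame, beta, np.sqrt(np.diag(cov)),
            tau2=0.0, rho=0.0, sigma2=sigma2, loglik=ll,
            residuals=r, converged=True,
        )

    def negloglik(u: np.ndarray) -> float:
        lam, rho = unpack(u)
        try:
            return -_profile(frame, lam, rho, reml=spec.reml)[2]
        except linalg.LinAlgError:
            return 1e12

    rng = np.random.default_rng(seed)
    starts = [np.zeros(n_free)]
    starts += [rng.normal(scale=2.0, size=n_free) for _ in range(n_restarts - 1)]
    bounds = []
    if fit_lam:
        bounds.append((-25.0, 25.0))
    if fit_rho:
        bounds.append((-15.0, 15.0))
    best = None
    any_converged = False
    for u0 in starts:
        res = optimize.minimize(
            negloglik, u0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-10},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    lam, rho = unpack(best.x)
    # snap a boundary-small lambda to exactly zero when it fits as well
    if fit_lam and lam < 1e-8:
        lam = 0.0
    beta, sigma2, ll, xtwx, r = _profile(frame, lam, rho, reml=spec.reml)
    cov = sigma2 * np.linalg.inv(xtwx)
    return GLMMFit(
        spec, frame, beta, np.sqrt(np.diag(cov)),
        tau2=lam * sigma2, rho=rho, sigma2=sigma2, loglik=ll,
        residuals=r, converged=any_converged,
    )


def generalized_r2(full: GLMMFit, null: GLMMFit) -> float:
    """Likelihood-ratio generalised R^2 = 1 - exp(-(2/n)(l_full - l_null))."""
    if full.n != null.n:
        raise ValueError(f"fits use different n ({full.n} vs {null.n})")
    if not set(null.frame.columns) <= set(full.frame.columns):
        raise ValueError("null model is not nested in the full model")
    lr = full.loglik - null.loglik
    return float(min(1.0, max(0.0, 1.0 - math.exp(-2.0 * lr / full.n))))


def bootstrap_generalized_r2(
    spec_full: GLMMSpec,
    spec_null: GLMMSpec,
    ds: Dataset,
    cell_counts: Optional[dict] = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Point estimate and nonparametric bootstrap CI for generalised R^2.

    Experiments are resampled with replacement and both models refitted
    on each resample; the CI is the 2.5/97.5 percentile interval.
    """
    full = fit_glmm(spec_full, ds, cell_counts=cell_counts, seed=seed)
    null = fit_glmm(spec_null, ds, cell_counts=cell_counts, seed=seed)
    point = generalized_r2(full, null)
    rng = np.random.default_rng(seed)
    values = []
    records = ds.records
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_boot):
            idx = rng.integers(0, len(records), size=len(records))
            boot_records = [records[i] for i in idx]
            # duplicate record keys are legal in a bootstrap resample;
            # bypass Dataset's duplicate check with a bare namespace
            boot = Dataset.__new__(Dataset)
            boot.records = boot_records
            boot.provenance = "bootstrap"
            try:
                f = fit_glmm(spec_full, boot, cell_counts=cell_counts, seed=seed)
                g = fit_glmm(spec_null, boot, cell_counts=cell_counts, seed=seed)
                values.append(generalized_r2(f, g))
            except (DesignError, np.linalg.LinAlgError, linalg.LinAlgError):
                continue
    lo, hi = np.percentile(values, [2.5, 97.5]) if values else (math.nan, math.nan)
    return {"r2": point, "ci_low": float(lo), "ci_high": float(hi), "n_boot": len(values)}


@dataclass
class DriverEffect:
    """Residual learning effect for one driver line."""

    driver: str
    effect: float  # percent, reference-rescaled
    se: float
    n_experiments: int
    lobe_category: str
    cell_count: Optional[int] = None

    @property
    def per_cell_effect(self) -> float:
        if not self.cell_count:
            raise ValueError(f"driver {self.driver} has no cell count")
        return self.effect / self.cell_count

    @property
    def per_cell_se(self) -> float:
        if not self.cell_count:
            raise ValueError(f"driver {self.driver} has no cell count")
        return self.se / self.cell_count


def residual_driver_effects(
    fit: GLMMFit,
    reference: float,
    cell_counts: Optional[dict] = None,
    mode: str = "fitted_plus_residual",
) -> list[DriverEffect]:
    """Summarise model residuals per driver on the rescaled learning scale.

    With ``mode="fitted_plus_residual"`` (default) each record
    contributes its response minus the non-intercept covariate
    contribution (intercept + residual); with ``mode="residual_only"``
    only the raw residual is used. Per-driver means are shifted to the
    learning scale (+100 for a percentage-change response) and the
    wild-type reference level is subtracted.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; refusing to summarise residuals")
    if mode not in ("fitted_plus_residual", "residual_only"):
        raise ValueError(f"unknown mode {mode!r}")
    adj = fit.frame.y - fit.frame.X[:, 1:] @ fit.beta[1:]
    values = adj if mode == "fitted_plus_residual" else fit.residuals
    shift = 100.0 if fit.spec.response == "percent_change" else 0.0

    per_driver: dict[str, list[float]] = {}
    lobes: dict[str, str] = {}
    for v, r in zip(values, fit.frame.records):
        if r.driver is None:
            continue
        per_driver.setdefault(r.driver, []).append(float(v))
        lobes[r.driver] = r.lobe_category
    if not per_driver:
        warnings.warn("no records carry a driver label")
    out = []
    for driver, vals in per_driver.items():
        n = len(vals)
        mean = float(np.mean(vals))
        if n >= 2:
            se = float(np.std(vals, ddof=1) / math.sqrt(n))
        else:
            # single contributing experiment: fall back to its own
            # model-implied residual standard deviation
            idx = [i for i, r in enumerate(fit.frame.records) if r.driver == driver]
            se = float(math.sqrt(fit.sigma2 / fit.frame.weights[idx[0]]))
        out.append(
            DriverEffect(
                driver=driver,
                effect=mean + shift - reference,
                se=se,
                n_experiments=n,
                lobe_category=lobes[driver],
                cell_count=None if cell_counts is None else cell_counts.get(driver),
            )
        )
    return out


def cellcount_regression(effects: Sequence[DriverEffect]) -> dict:
    """Weighted linear regression of driver effects on their cell counts.

    Weights are the number of contributing experiments; the slope CI and
    p-value use the t-distribution with n - 2 degrees of freedom. The
    returned R^2 is the likelihood-ratio generalised R^2 against the
    intercept-only weighted fit.
    """
    import statsmodels.api as sm

    usable = [e for e in effects if e.cell_count is not None]
    if len(usable) < 3:
        raise ValueError(f"need >= 3 drivers with cell counts, got {len(usable)}")
    x = np.array([float(e.cell_count) for e in usable])
    if np.allclose(x, x[0]):
        raise ValueError("all cell counts equal: slope is unidentifiable")
    y = np.array([e.effect for e in usable])
    w = np.array([float(e.n_experiments) for e in usable])
    model = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    null = sm.WLS(y, np.ones_like(y), weights=w).fit()
    n = len(usable)
    r2_gen = float(min(1.0, max(0.0, 1.0 - math.exp(-2.0 * (model.llf - null.llf) / n))))
    tcrit = stats.t.ppf(0.975, df=n - 2)
    slope, slope_se = model.params[1], model.bse[1]
    return {
        "slope": float(slope),
        "slope_se": float(slope_se),
        "slope_ci": (float(slope - tcrit * slope_se), float(slope + tcrit * slope_se)),
        "intercept": float(model.params[0]),
        "r2_generalized": r2_gen,
        "p": float(model.pvalues[1]),
        "n_drivers": n,
    }


def per_cell_model(effects: Sequence[DriverEffect]) -> dict:
    """Per-lobe-category synthesis of per-cell driver effects.

    Each driver's effect and SE are divided by its cell count, then
    categories are pooled by inverse-variance weighting. Returns one
    estimate + CI per category and all pairwise category differences.
    """
    usable = []
    for e in effects:
        if not e.cell_count:
            warnings.warn(f"driver {e.driver} has no cell count; excluded")
            continue
        usable.append(e)
    if not usable:
        raise ValueError("no drivers with positive cell counts")
    groups: dict[str, list[DriverEffect]] = {}
    for e in usable:
        groups.setdefault(e.lobe_category, []).append(e)
    categories = {}
    for cat, members in groups.items():
        est = np.array([e.per_cell_effect for e in members])
        se = np.array([e.per_cell_se for e in members])
        if np.all(se > 0):
            w = 1.0 / se**2
        else:  # degenerate SEs: weight by contributing experiments
            w = np.array([float(e.n_experiments) for e in members])
        mean = float(np.sum(w * est) / np.sum(w))
        pooled_se = float(1.0 / math.sqrt(np.sum(1.0 / se**2))) if np.all(se > 0) else 0.0
        categories[cat] = {
            "estimate": mean,
            "se": pooled_se,
            "ci_low": mean - Z_95 * pooled_se,
            "ci_high": mean + Z_95 * pooled_se,
            "k": len(members),
        }
    differences = {}
    cats = sorted(categories)
    for i, a in enumerate(cats):
        for b in cats[i + 1 :]:
            d = categories[a]["estimate"] - categories[b]["estimate"]
            se_d = math.hypot(categories[a]["se"], categories[b]["se"])
            differences[f"{a} - {b}"] = {
                "estimate": d,
                "se": se_d,
                "ci_low": d - Z_95 * se_d,
                "ci_high": d + Z_95 * se_d,
            }
    return {"categories": categories, "differences": differences}
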