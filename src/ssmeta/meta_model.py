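"""Multilevel random-effects meta-regression fitted by REML.

The model for the vector of observed effect sizes y with known sampling
variances v is

    y = X beta + sum_l Z_l u_l + e,      u_l ~ N(0, sigma2_l I),
                                         e   ~ N(0, diag(v)),

where each random level l (study, fitness component, taxon, or the
observation level itself) contributes a variance component sigma2_l.
Variance components are estimated by maximising the restricted
log-likelihood

    l_R = -1/2 [ ln|V| + ln|X' V^-1 X| + (y - X b)' V^-1 (y - X b) ]

with V = diag(v) + sum_l sigma2_l Z_l Z_l' and b the GLS estimate.
Optimisation is quasi-Newton over log(sigma2_l) with analytic
gradients and multiple restarts; fixed-effect inference is Wald-type
with normal (z) reference distributions, matching standard
meta-analytic practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .errors import DesignError

#: Reference levels for treatment coding of the standard moderators.
REFERENCE_LEVELS = {"sex": "male", "environment": "benign"}

#: Mapping from random-level names to dataset columns.
LEVEL_COLUMNS = {"study": "study_id", "trait": "trait", "taxon": "taxon"}

SIGMA2_FLOOR = 1e-10
SIGMA2_CEIL = 1e4
#: Estimates within this distance of the floor are reported as exactly 0.
SIGMA2_ZERO_TOL = 1e-8

Z_95 = 1.959963984540054


@dataclass(frozen=True)
class ModelSpec:
    """Moderator formula plus the set of random levels.

    ``moderators`` is either ``"1"`` (intercept only), a single
    categorical column name (e.g. ``"fitness_class"``), or
    ``"a*b"`` for two crossed categoricals with interaction
    (e.g. ``"sex*environment"``).
    """

    moderators: str = "1"
    random_levels: tuple[str, ...] = ("study", "trait", "taxon")

    def __post_init__(self) -> None:
        if not self.random_levels:
            raise ValueError("random_levels must be non-empty")


@dataclass
class Design:
    """A realised fixed-effect design with its coding metadata."""

    X: np.ndarray
    columns: list[str]
    terms: list[str]                       # e.g. ["sex", "environment", "sex:environment"]
    level_maps: dict[str, list[str]]       # moderator -> non-reference levels
    references: dict[str, str]             # moderator -> reference level


def _categories(frame: pd.DataFrame, col: str) -> tuple[str, list[str]]:
    if col not in frame.columns:
        raise DesignError(f"moderator column {col!r} not in data")
    levels = sorted(frame[col].astype(str).unique())
    ref = REFERENCE_LEVELS.get(col)
    if ref is None or ref not in levels:
        ref = levels[0]
    others = [l for l in levels if l != ref]
    return ref, others


def build_design(frame: pd.DataFrame, spec: ModelSpec) -> Design:
    """Build a treatment-coded fixed-effect design matrix.

    Reference levels are ``male`` for sex and ``benign`` for environment
    (first alphabetical level otherwise), so the ``sex*environment``
    design has six columns: intercept, both-sexes and female-sex main
    effects, stressed-environment main effect and the two interactions.
    """
    k = len(frame)
    formula = spec.moderators.replace(" ", "")
    cols: list[np.ndarray] = [np.ones(k)]
    names: list[str] = ["intercept"]
    terms: list[str] = ["1"]
    level_maps: dict[str, list[str]] = {}
    references: dict[str, str] = {}

    if formula == "1":
        factors: list[str] = []
        interaction = False
    elif "*" in formula:
        factors = formula.split("*")
        if len(factors) != 2:
            raise DesignError("only two-way crossed designs are supported")
        interaction = True
    else:
        factors = [formula]
        interaction = False

    indicators: dict[str, dict[str, np.ndarray]] = {}
    for col in factors:
        ref, others = _categories(frame, col)
        references[col] = ref
        level_maps[col] = others
        indicators[col] = {}
        terms.append(col)
        values = frame[col].astype(str).to_numpy()
        for lev in others:
            ind = (values == lev).astype(float)
            indicators[col][lev] = ind
            cols.append(ind)
            names.append(f"{col}[{lev}]")
    if interaction:
        a, b = factors
        terms.append(f"{a}:{b}")
        for lb in level_maps[b]:
            for la in level_maps[a]:
                cols.append(indicators[a][la] * indicators[b][lb])
                names.append(f"{a}[{la}]:{b}[{lb}]")

    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = _aliased_columns(X, names)
        raise DesignError(
            "rank-deficient design; aliased columns: " + ", ".join(aliased)
        )
    return Design(X=X, columns=names, terms=terms, level_maps=level_maps,
                  references=references)


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Greedy scan for columns linearly dependent on their predecessors."""
    aliased = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
        else:
            aliased.append(names[j])
    return aliased


def grouping_matrix(labels: Sequence) -> np.ndarray:
    """k x q indicator matrix mapping observations to groups."""
    labels = np.asarray(labels)
    uniq, codes = np.unique(labels, return_inverse=True)
    Z = np.zeros((len(labels), len(uniq)))
    Z[np.arange(len(labels)), codes] = 1.0
    return Z


def level_matrices(
    frame: pd.DataFrame, random_levels: Sequence[str]
) -> dict[str, np.ndarray]:
    """Build Z_l for each requested random level.

    The special level ``"effect"`` assigns each observation its own
    group (observation-level / residual heterogeneity).
    """
    out: dict[str, np.ndarray] = {}
    k = len(frame)
    for level in random_levels:
        if level == "effect":
            out[level] = np.eye(k)
        else:
            col = LEVEL_COLUMNS.get(level, level)
            if col not in frame.columns:
                raise DesignError(f"random level {level!r}: column {col!r} missing")
            out[level] = grouping_matrix(frame[col].astype(str).to_numpy())
    return out


@dataclass
class FitResult:
    """REML estimates for one multilevel meta-regression."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: dict[str, float]
    loglik_reml: float
    k: int
    p: int
    converged: bool
    beta_names: list[str] = field(default_factory=list)
    design: Optional[Design] = None
    message: str = ""

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))

    def summary_frame(self) -> pd.DataFrame:
        """Wald table: estimate, SE, z, two-sided p, 95% CI."""
        se = self.se
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, self.beta / se, np.nan)
        p = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "parameter": self.beta_names or [f"b{i}" for i in range(self.p)],
                "estimate": self.beta,
                "se": se,
                "z": z,
                "p": p,
                "lci": self.beta - Z_95 * se,
                "uci": self.beta + Z_95 * se,
            }
        )


@dataclass(frozen=True)
class ContrastResult:
    """A linear combination L'beta with Wald inference."""

    L: np.ndarray
    estimate: float
    se: float
    z: float
    p_two_sided: float
    ci95: tuple[float, float]
    label: str = ""


def _reml_nll_grad(
    log_s2: np.ndarray,
    y: np.ndarray,
    v: np.ndarray,
    X: np.ndarray,
    Zs: list[np.ndarray],
    Gs: list[np.ndarray],
) -> tuple[float, np.ndarray]:
    """Negative restricted log-likelihood (up to a constant) and gradient
    with respect to log(sigma2).

    Gradient terms use the thin Z_l matrices: with P the REML projector,
    tr(P Z Z') = ||L^-1 Z||_F^2 - tr(A^-1 (Z' V^-1 X)' (Z' V^-1 X)),
    avoiding any k x k inverse.
    """
    s2 = np.exp(log_s2)
    V = np.diag(v).astype(float)
    for sj, G in zip(s2, Gs):
        V += sj * G
    try:
        c, low = cho_factor(V, lower=True, check_finite=False)
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        return np.inf, np.zeros_like(log_s2)
    L = np.tril(c)
    logdet_v = 2.0 * np.sum(np.log(np.diag(L)))
    VinvX = cho_solve((c, low), X, check_finite=False)
    A = X.T @ VinvX
    cA, lowA = cho_factor(A, lower=True)
    logdet_a = 2.0 * np.sum(np.log(np.diag(np.tril(cA))))
    Vinv_y = cho_solve((c, low), y, check_finite=False)
    beta = cho_solve((cA, lowA), X.T @ Vinv_y)
    r = y - X @ beta
    Vinv_r = cho_solve((c, low), r, check_finite=False)
    quad = float(r @ Vinv_r)
    nll = 0.5 * (logdet_v + logdet_a + quad)
    grad = np.empty_like(s2)
    for j, Z in enumerate(Zs):
        W = solve_triangular(L, Z, lower=True, check_finite=False)
        tr_vg = float(np.sum(W * W))
        C = Z.T @ VinvX  # q x p
        D = cho_solve((cA, lowA), C.T)
        tr_xg = float(np.sum(C.T * D))
        zr = Z.T @ Vinv_r
        quad_g = float(zr @ zr)
        grad[j] = 0.5 * (tr_vg - tr_xg - quad_g) * s2[j]  # log-scale chain rule
    return nll, grad


def profile_beta(
    y: np.ndarray,
    v: np.ndarray,
    X: np.ndarray,
    Gs: list[np.ndarray],
    s2: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """GLS fixed effects and covariance at fixed variance components.

    With all components at zero this is exactly the inverse-variance
    weighted (fixed-effect) least-squares fit.
    """
    k = len(y)
    V = np.diag(v).astype(float)
    for sj, G in zip(s2, Gs):
        V += sj * G
    c, low = cho_factor(V, lower=True)
    Vinv = cho_solve((c, low), np.eye(k))
    A = X.T @ Vinv @ X
    cov = np.linalg.inv(A)
    beta = cov @ (X.T @ (Vinv @ y))
    return beta, cov


def _moment_start(y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    """DerSimonian-Laird-style method-of-moments total tau^2 start."""
    w = 1.0 / v
    Xw = X * w[:, None]
    A = X.T @ Xw
    beta = np.linalg.solve(A, Xw.T @ y)
    r = y - X @ beta
    q = float(r @ (w * r))
    k, p = X.shape
    # trace term of the DL estimator generalised to meta-regression
    H = Xw @ np.linalg.solve(A, Xw.T)
    denom = float(np.sum(w) - np.sum(w * np.diag(H))) if k > p else 1.0
    denom = max(denom, 1e-12)
    tau2 = (q - (k - p)) / denom
    return max(tau2, 1e-4)


def reml_fit(
    y: np.ndarray,
    v: np.ndarray,
    X: np.ndarray,
    z_matrices: dict[str, np.ndarray],
    beta_names: Optional[list[str]] = None,
    design: Optional[Design] = None,
) -> FitResult:
    """Fit the multilevel model by REML.

    Parameters
    ----------
    y, v
        Effect sizes and their (strictly positive) sampling variances.
    X
        Fixed-effect design matrix, full column rank, k > p.
    z_matrices
        Mapping level name -> k x q_l group indicator matrix.

    Returns
    -------
    FitResult with GLS fixed effects, their covariance, per-level
    variance components (exact zeros at the boundary), the restricted
    log-likelihood and a convergence flag.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    k, p = X.shape
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be > 0")
    if k <= p:
        raise ValueError(f"need more effects (k={k}) than fixed parameters (p={p})")

    names = list(z_matrices.keys())
    Zs = list(z_matrices.values())
    Gs = [Z @ Z.T for Z in Zs]
    nlev = len(Gs)

    mom = _moment_start(y, v, X)
    starts = [
        np.full(nlev, 1e-3),
        np.full(nlev, max(0.1 * mom / nlev, SIGMA2_FLOOR * 10)),
        np.full(nlev, max(mom / nlev, SIGMA2_FLOOR * 10)),
    ]
    bounds = [(math.log(SIGMA2_FLOOR), math.log(SIGMA2_CEIL))] * nlev

    best = None
    for s0 in starts:
        res = optimize.minimize(
            _reml_nll_grad,
            np.log(s0),
            args=(y, v, X, Zs, Gs),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-13, "gtol": 1e-8, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res

    s2_hat = np.exp(best.x)
    # Boundary tie-break: values indistinguishable from the floor are 0.
    s2_report = np.where(s2_hat <= SIGMA2_ZERO_TOL, 0.0, s2_hat)
    beta, cov = profile_beta(y, v, X, Gs, s2_report)
    nll, grad = _reml_nll_grad(
        np.log(np.maximum(s2_report, SIGMA2_FLOOR)), y, v, X, Zs, Gs
    )
    at_bound = s2_report == 0.0
    grad_ok = bool(np.all(np.abs(grad[~at_bound]) < 1e-4)) if np.any(~at_bound) else True
    converged = bool(best.success) and grad_ok
    return FitResult(
        beta=beta,
        cov_beta=cov,
        sigma2={n: float(s) for n, s in zip(names, s2_report)},
        loglik_reml=-float(nll),
        k=k,
        p=p,
        converged=converged,
        beta_names=beta_names or [f"b{i}" for i in range(p)],
        design=design,
        message=str(best.message),
    )


def fit_model(frame: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Convenience wrapper: build design + Z matrices from an analysis
    frame (columns ``value``, ``variance`` plus moderators/levels) and
    run :func:`reml_fit`."""
    design = build_design(frame, spec)
    zs = level_matrices(frame, spec.random_levels)
    return reml_fit(
        frame["value"].to_numpy(dtype=float),
        frame["variance"].to_numpy(dtype=float),
        design.X,
        zs,
        beta_names=design.columns,
        design=design,
    )


def contrast(fit: FitResult, L: Sequence[float], label: str = "") -> ContrastResult:
    """Evaluate the linear contrast L'beta with a Wald z test."""
    L = np.asarray(L, dtype=float)
    if L.shape != (fit.p,):
        raise ValueError(f"contrast length {L.shape} does not match p={fit.p}")
    est = float(L @ fit.beta)
    var = float(L @ fit.cov_beta @ L)
    se = math.sqrt(max(var, 0.0))
    if se > 0:
        z = est / se
        pval = 2.0 * stats.norm.sf(abs(z))
    else:
        z = float("nan")
        pval = float("nan")
    return ContrastResult(
        L=L,
        estimate=est,
        se=se,
        z=z,
        p_two_sided=pval,
        ci95=(est - Z_95 * se, est + Z_95 * se),
        label=label,
    )


def predict_levels(fit: FitResult, moderator: str) -> pd.DataFrame:
    """Per-level predicted means with Wald 95% CIs.

    Builds, for each level of ``moderator`` (including the reference),
    the design row with every other moderator at its reference and
    evaluates the corresponding linear combination of fixed effects.
    """
    if fit.design is None:
        raise ValueError("fit carries no design metadata")
    d = fit.design
    if moderator in ("1", None) and not d.level_maps:
        # intercept-only model: the single "level" is the grand mean
        c = contrast(fit, np.eye(fit.p)[0], label="overall")
        return pd.DataFrame(
            [{"level": "overall", "estimate": c.estimate, "se": c.se,
              "lci": c.ci95[0], "uci": c.ci95[1]}]
        )
    if moderator not in d.level_maps:
        raise DesignError(f"moderator {moderator!r} was not in the model")
    levels = [d.references[moderator]] + d.level_maps[moderator]
    rows = []
    for lev in levels:
        L = np.zeros(fit.p)
        L[d.columns.index("intercept")] = 1.0
        col = f"{moderator}[{lev}]"
        if col in d.columns:
            L[d.columns.index(col)] = 1.0
        elif lev != d.references[moderator]:
            raise DesignError(f"unknown level {lev!r} for {moderator!r}")
        c = contrast(fit, L, label=lev)
        rows.append(
            {
                "level": lev,
                "estimate": c.estimate,
                "se": c.se,
                "lci": c.ci95[0],
                "uci": c.ci95[1],
            }
        )
    return pd.DataFrame(rows)


def cell_mean_contrast(
    fit: FitResult, sex: str, environment: str
) -> np.ndarray:
    """Design row (as a contrast vector) for one sex-by-environment cell."""
    if fit.design is None:
        raise ValueError("fit carries no design metadata")
    d = fit.design
    L = np.zeros(fit.p)
    L[d.columns.index("intercept")] = 1.0
    for col in (
        f"sex[{sex}]",
        f"environment[{environment}]",
        f"sex[{sex}]:environment[{environment}]",
    ):
        if col in d.columns:
            L[d.columns.index(col)] = 1.0
    return L


def per_trait_models(
    frame: pd.DataFrame, min_effects: int = 3
) -> tuple[dict[str, FitResult], list[str]]:
    """Separate intercept-only meta-analyses per fitness component.

    Each trait contributing more than ``min_effects`` effect sizes gets
    its own intercept-only REML fit with study and taxon random levels;
    the remaining traits are returned as skipped.
    """
    fits: dict[str, FitResult] = {}
    skipped: list[str] = []
    for trait, sub in frame.groupby("trait", sort=True):
        if len(sub) <= min_effects:
            skipped.append(str(trait))
            continue
        spec = ModelSpec(moderators="1", random_levels=("study", "taxon"))
        fits[str(trait)] = fit_model(sub.reset_index(drop=True), spec)
    return fits, skipped
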