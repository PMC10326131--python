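"""Bayesian models: trivariate-outcome regression and circular tilt regression.

Two models summarise how age, gender and skin configuration affect the
ellipse-derived outcomes.

**Multivariate linear model.**  The outcome vector
(log eccentricity, area/1000, semi-minor axis) follows

    y_i = alpha + B x_i + eps_i,   eps_i ~ N_3(0, Sigma),

with x_i = (age, gender, configuration).  Priors are weakly informative
and conjugate: matrix-normal N(0, tau^2 I (x) Sigma) on the stacked
(alpha, B) with a large scale tau (default 100), and inverse-Wishart
(nu = 4, I_3) on Sigma.  Conjugacy gives exact Gibbs conditionals:

    Gamma | Sigma, Y ~ MatrixNormal(M_n, V_n, Sigma),
        V_n = (X'X + tau^-2 I)^-1,  M_n = V_n X'Y
    Sigma | Gamma, Y ~ InvWishart(nu + n + p, I + E'E + tau^-2 Gamma'Gamma)

A covariate is declared significant for an outcome when 0 lies outside the
0.95 highest-posterior-density interval (HPDI) of its coefficient.

**Circular model.**  The ellipse tilt is axial (period 180°); angles are
doubled onto the full circle, where the projected-normal regression

    theta_i ~ PN(mu_i, I),   mu_i = gamma_0 + gamma_1 * config_i

is fitted by Gibbs sampling with latent-length augmentation: writing the
latent point as u_i = r_i (cos theta_i, sin theta_i), the conditional
density of r_i is proportional to r exp(-(r - b_i)^2 / 2) on r > 0, which
after introducing w_i | r_i ~ Uniform(0, r_i) reduces to a truncated
normal — every conditional is exact.  Posterior circular means per
configuration are compared through their HPDIs on the circle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats

OUTCOME_LABELS = ("log_ecc", "area_scaled", "semi_minor")
COVARIATE_LABELS = ("intercept", "age", "gender", "config")

DEFAULT_PRIOR_SCALE = 100.0
DEFAULT_PRIOR_DF = 4.0


@dataclass(frozen=True)
class McmcSettings:
    n_chains: int = 4
    n_iter: int = 2000  # per chain, including warm-up
    warmup_frac: float = 0.5
    seed: int = 0

    @property
    def n_kept(self) -> int:
        return self.n_iter - int(self.n_iter * self.warmup_frac)


@dataclass
class MvRegPosterior:
    """Posterior draws for the trivariate regression.

    ``coef`` has shape (chains, draws, p, 3): stacked (intercept; B') rows
    by outcome columns.  ``sigma`` has shape (chains, draws, 3, 3).
    """

    coef: np.ndarray
    sigma: np.ndarray
    covariate_labels: tuple[str, ...]
    outcome_labels: tuple[str, ...]
    rhat: pd.DataFrame
    ess: pd.DataFrame
    converged: bool
    warnings: list[str] = field(default_factory=list)

    def coef_draws(self, covariate: str, outcome: str) -> np.ndarray:
        i = self.covariate_labels.index(covariate)
        j = self.outcome_labels.index(outcome)
        return self.coef[..., i, j].ravel()


@dataclass(frozen=True)
class PosteriorSummary:
    label: str
    mean: float
    hpdi_low: float
    hpdi_high: float
    significant: bool


def hpdi(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``level`` of the draws.

    Scans every window of ceil(level * n) consecutive sorted draws and
    returns the narrowest — the sample HPDI for a unimodal posterior.
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise ValueError(f"need at least 100 draws for an HPDI, got {n}")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    k = int(np.ceil(level * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


def _design(covariates: pd.DataFrame) -> np.ndarray:
    X = np.column_stack(
        [np.ones(len(covariates))]
        + [covariates[c].to_numpy(dtype=float) for c in ("age", "gender", "config")]
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by leave-one-out rank
        bad = [
            COVARIATE_LABELS[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")
    return X


def fit_mvreg(
    data: pd.DataFrame,
    settings: McmcSettings | None = None,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
    prior_df: float = DEFAULT_PRIOR_DF,
    fixed_sigma: np.ndarray | None = None,
) -> MvRegPosterior:
    """Gibbs sampler for the trivariate-outcome linear model.

    ``data`` needs columns age, gender, config and the three outcomes.
    ``fixed_sigma`` holds the error covariance constant (no inverse-Wishart
    step), exposing the closed-form ridge posterior for validation.
    Convergence (split-R-hat < 1.01 and bulk ESS > 400 for every
    coefficient) is flagged, never silently ignored.
    """
    settings = settings or McmcSettings()
    if len(data) < 10:
        raise ValueError("need at least 10 rows")
    Y = data[list(OUTCOME_LABELS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(Y)):
        raise ValueError("outcomes must be finite")
    X = _design(data)
    n, p = X.shape
    q = Y.shape[1]

    lam = prior_scale**-2
    xtx = X.T @ X
    xty = X.T @ Y
    v_n = np.linalg.inv(xtx + lam * np.eye(p))
    m_n = v_n @ xty
    chol_vn = np.linalg.cholesky(v_n)
    s0 = np.eye(q)

    n_chains, n_iter = settings.n_chains, settings.n_iter
    n_warm = int(n_iter * settings.warmup_frac)
    coef_out = np.empty((n_chains, n_iter - n_warm, p, q))
    sigma_out = np.empty((n_chains, n_iter - n_warm, q, q))
    root = np.random.SeedSequence(settings.seed)
    for chain, ss in enumerate(root.spawn(n_chains)):
        rng = np.random.default_rng(ss)
        sigma = np.eye(q) if fixed_sigma is None else np.asarray(fixed_sigma, float)
        chol_sigma = np.linalg.cholesky(sigma)
        for it in range(n_iter):
            z = rng.standard_normal((p, q))
            gamma = m_n + chol_vn @ z @ chol_sigma.T
            if fixed_sigma is None:
                resid = Y - X @ gamma
                scale = s0 + resid.T @ resid + lam * (gamma.T @ gamma)
                sigma = stats.invwishart.rvs(
                    df=prior_df + n + p, scale=scale, random_state=rng
                )
                chol_sigma = np.linalg.cholesky(sigma)
            if it >= n_warm:
                coef_out[chain, it - n_warm] = gamma
                sigma_out[chain, it - n_warm] = sigma

    ds = az.convert_to_dataset(coef_out)
    rhat_arr = np.asarray(az.rhat(ds)["x"])
    ess_arr = np.asarray(az.ess(ds)["x"])
    idx = [
        {"covariate": cov, "outcome": out}
        for cov in COVARIATE_LABELS
        for out in OUTCOME_LABELS
    ]
    rhat_df = pd.DataFrame(idx).assign(rhat=rhat_arr.ravel())
    ess_df = pd.DataFrame(idx).assign(ess=ess_arr.ravel())
    warn_msgs: list[str] = []
    converged = True
    if n_chains >= 2:
        if (rhat_df["rhat"] > 1.01).any():
            converged = False
            warn_msgs.append("split R-hat exceeds 1.01 for some coefficients")
        if (ess_df["ess"] < 400).any():
            warn_msgs.append("bulk ESS below 400 for some coefficients")
    else:
        warn_msgs.append("convergence diagnostics require >= 2 chains")
    for m in warn_msgs:
        warnings.warn(m, stacklevel=2)
    return MvRegPosterior(
        coef=coef_out,
        sigma=sigma_out,
        covariate_labels=COVARIATE_LABELS,
        outcome_labels=OUTCOME_LABELS,
        rhat=rhat_df,
        ess=ess_df,
        converged=converged,
        warnings=warn_msgs,
    )


def significance_table(posterior: MvRegPosterior, level: float = 0.95) -> pd.DataFrame:
    """Posterior mean, HPDI and the 0-outside-HPDI significance flag.

    One row per (covariate, outcome) pair including intercepts: 12 rows for
    the default model (intercept + 3 covariates, 3 outcomes each).
    """
    rows = []
    for cov in posterior.covariate_labels:
        for out in posterior.outcome_labels:
            draws = posterior.coef_draws(cov, out)
            lo, hi = hpdi(draws, level)
            rows.append(
                {
                    "covariate": cov,
                    "outcome": out,
                    "mean": float(draws.mean()),
                    "hpdi_low": lo,
                    "hpdi_high": hi,
                    "significant": not (lo <= 0.0 <= hi),
                }
            )
    return pd.DataFrame(rows)


def interval_excludes_zero(lo: float, hi: float) -> bool:
    """The study's significance rule: 0 outside the HPDI."""
    return not (lo <= 0.0 <= hi)


# ---------------------------------------------------------------------------
# projected-normal circular regression


@dataclass
class CircularPosterior:
    """Posterior for the tilt-angle model, reported on the axial scale.

    ``circular_mean_draws`` maps configuration label -> draws of the
    posterior circular mean direction in degrees in [0, 180).
    ``hpdi_axial`` maps configuration -> (low, high) arc on [0, 180); the
    arc may wrap (low > high).
    """

    beta0: np.ndarray  # (chains, draws, 2) latent intercept
    beta1: np.ndarray | None  # (chains, draws, 2) configuration shift
    circular_mean_draws: dict[int, np.ndarray]
    hpdi_axial: dict[int, tuple[float, float]]
    degenerate: bool = False


def _circular_mean_deg(angles_deg: np.ndarray) -> float:
    a = np.deg2rad(angles_deg)
    return float(np.degrees(np.arctan2(np.sin(a).mean(), np.cos(a).mean())) % 360.0)


def circular_hpdi(draws_deg: np.ndarray, level: float = 0.95, period: float = 360.0) -> tuple[float, float]:
    """HPDI of angular draws on a circle of the given period.

    Draws are unwrapped around their circular mean so the shortest-window
    search runs on a line, then mapped back; the returned arc may wrap
    (low > high).
    """
    x = np.asarray(draws_deg, dtype=float) % period
    center = _circular_mean_deg(x * (360.0 / period)) * (period / 360.0)
    centered = (x - center + period / 2.0) % period - period / 2.0
    lo, hi = hpdi(centered, level)
    return (lo + center) % period, (hi + center) % period


def arcs_overlap(a: tuple[float, float], b: tuple[float, float], period: float = 360.0) -> bool:
    """Whether two circular arcs (possibly wrapping) intersect."""

    def segments(arc):
        lo, hi = arc[0] % period, arc[1] % period
        if lo <= hi:
            return [(lo, hi)]
        return [(lo, period), (0.0, hi)]

    return any(
        s1[0] <= s2[1] and s2[0] <= s1[1]
        for s1 in segments(a)
        for s2 in segments(b)
    )


def hpdi_overlap(a: tuple[float, float], b: tuple[float, float], period: float = 360.0) -> bool:
    """The study's rule for the circular model: overlapping HPDIs mean no
    significant configuration effect on the tilt."""
    return arcs_overlap(a, b, period)


def fit_circular(
    angles_deg: np.ndarray,
    config: np.ndarray,
    settings: McmcSettings | None = None,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
    axial: bool = True,
) -> CircularPosterior:
    """Projected-normal circular regression of tilt on configuration.

    ``angles_deg``: tilt angles, axial in [0, 180) by default (doubled
    internally).  ``config``: 0/1 indicator per angle.  Requires at least
    10 angles in every configuration present; with a single configuration
    the shift is dropped and only the baseline mean is estimated.
    """
    settings = settings or McmcSettings()
    theta_axial = np.asarray(angles_deg, dtype=float)
    cfg = np.asarray(config, dtype=float)
    if theta_axial.shape != cfg.shape:
        raise ValueError("angles and config must align")
    levels = sorted(set(int(c) for c in cfg))
    for lev in levels:
        if (cfg == lev).sum() < 10:
            raise ValueError(f"need >= 10 angles per configuration (config {lev})")
    two_groups = len(levels) == 2
    if not two_groups and levels != [0]:
        raise ValueError("single-configuration fit requires config == 0")

    period = 180.0 if axial else 360.0
    theta = np.deg2rad(theta_axial * (360.0 / period))  # doubled if axial
    u = np.column_stack((np.cos(theta), np.sin(theta)))
    if np.allclose(theta_axial, theta_axial[0]):
        warnings.warn("all angles identical; posterior is degenerate", stacklevel=2)
        degenerate = True
    else:
        degenerate = False

    X = np.column_stack((np.ones_like(cfg), cfg)) if two_groups else np.ones((cfg.size, 1))
    n, p = X.shape
    lam = prior_scale**-2
    v_n = np.linalg.inv(X.T @ X + lam * np.eye(p))
    chol_vn = np.linalg.cholesky(v_n)

    n_chains, n_iter = settings.n_chains, settings.n_iter
    n_warm = int(n_iter * settings.warmup_frac)
    beta_out = np.empty((n_chains, n_iter - n_warm, p, 2))
    root = np.random.SeedSequence(settings.seed)
    for chain, ss in enumerate(root.spawn(n_chains)):
        rng = np.random.default_rng(ss)
        r = np.ones(n)
        for it in range(n_iter):
            # beta | r: two independent normal regressions on u * r
            target = u * r[:, None]
            m = v_n @ (X.T @ target)
            beta = m + chol_vn @ rng.standard_normal((p, 2))
            # r | beta via uniform augmentation: w ~ U(0, r), then
            # r ~ N(b, 1) truncated to (w, inf)
            b = np.einsum("ij,ij->i", X @ beta, u)
            w = rng.uniform(0.0, r)
            lo = (w - b)  # standardized lower bound
            r = b + stats.truncnorm.rvs(lo, np.inf, random_state=rng, size=n)
            if it >= n_warm:
                beta_out[chain, it - n_warm] = beta

    beta0 = beta_out[:, :, 0, :]
    beta1 = beta_out[:, :, 1, :] if two_groups else None
    circ_draws: dict[int, np.ndarray] = {}
    hp: dict[int, tuple[float, float]] = {}
    for lev in levels:
        mu = beta0 + (beta1 * lev if beta1 is not None else 0.0)
        ang = np.degrees(np.arctan2(mu[..., 1], mu[..., 0])).ravel() % 360.0
        ang_axial = ang * (period / 360.0)
        circ_draws[lev] = ang_axial
        hp[lev] = circular_hpdi(ang_axial, period=period)
    return CircularPosterior(
        beta0=beta0,
        beta1=beta1,
        circular_mean_draws=circ_draws,
        hpdi_axial=hp,
        degenerate=degenerate,
    )


def configuration_shift(posterior: CircularPosterior) -> float:
    """Posterior-mean difference of circular means (config 1 minus 0),
    on the axial scale, in (-90, 90]."""
    if posterior.beta1 is None:
        raise ValueError("shift undefined: posterior was fitted on one configuration")
    m0 = _circular_mean_deg(posterior.circular_mean_draws[0] * 2.0) / 2.0
    m1 = _circular_mean_deg(posterior.circular_mean_draws[1] * 2.0) / 2.0
    d = (m1 - m0 + 90.0) % 180.0 - 90.0
    return float(d)
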