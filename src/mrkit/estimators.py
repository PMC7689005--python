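"""Causal-effect estimators for two-sample Mendelian randomization.

Given k harmonized instruments with exposure effects beta_X (SE sigma_X)
and outcome effects beta_Y (SE sigma_Y), the per-SNP causal estimate is the
Wald ratio beta_Y/beta_X with first-order SE sigma_Y/|beta_X|.  The pooled
inverse-variance-weighted (IVW) estimate is

    beta_IVW = sum(beta_X * beta_Y / sigma_Y^2) / sum(beta_X^2 / sigma_Y^2)
    se_IVW   = sqrt(1 / sum(beta_X^2 / sigma_Y^2))          (fixed effect)

which is algebraically the slope of a zero-intercept weighted regression of
beta_Y on beta_X with weights 1/sigma_Y^2.  The random-effect variant uses a
multiplicative overdispersion model: the fixed SE is inflated by
sqrt(Q/(k-1)) when Cochran's Q exceeds its degrees of freedom.  The weighted
median estimator is consistent when instruments carrying more than half of
the weight are valid; MR-Egger adds a free intercept whose deviation from
zero measures directional horizontal pleiotropy, with the slope giving a
pleiotropy-adjusted effect under the InSiDE assumption.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientInstrumentsError, SingularDesignError, ValidationError
from .summary_data import HarmonizedInstrument, usable_instruments

METHOD_LABELS = (
    "wald",
    "ivw_fixed",
    "ivw_random",
    "weighted_median",
    "egger_slope",
    "egger_intercept",
)


@dataclass(frozen=True)
class MrEstimate:
    """A causal-effect (or intercept) estimate with its uncertainty.

    ``beta`` is in SD-outcome per SD-exposure units except for
    ``egger_intercept``, which is in SD-outcome units per allele.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int

    def __post_init__(self) -> None:
        if self.method not in METHOD_LABELS:
            raise ValidationError(f"unknown method label {self.method!r}")
        if not self.se > 0:
            raise ValidationError(f"{self.method}: se must be > 0")
        if not self.ci_low < self.ci_high:
            raise ValidationError(f"{self.method}: empty confidence interval")


def _extract(insts: Sequence[HarmonizedInstrument]):
    insts = usable_instruments(insts)
    bx = np.array([i.beta_exposure for i in insts])
    by = np.array([i.beta_outcome for i in insts])
    sy = np.array([i.se_outcome for i in insts])
    return insts, bx, by, sy


def _normal_estimate(method: str, beta: float, se: float, k: int, alpha: float) -> MrEstimate:
    z = stats.norm.ppf(1 - alpha / 2)
    pval = float(2 * stats.norm.sf(abs(beta / se)))
    return MrEstimate(method, float(beta), float(se), float(beta - z * se),
                      float(beta + z * se), pval, k)


def _t_estimate(method: str, beta: float, se: float, k: int, df: int, alpha: float) -> MrEstimate:
    tq = stats.t.ppf(1 - alpha / 2, df)
    pval = float(2 * stats.t.sf(abs(beta / se), df))
    return MrEstimate(method, float(beta), float(se), float(beta - tq * se),
                      float(beta + tq * se), pval, k)


def wald_ratio(inst: HarmonizedInstrument, alpha: float = 0.05) -> MrEstimate:
    """Single-SNP causal estimate beta_Y/beta_X, SE = sigma_Y/|beta_X|."""
    if inst.beta_exposure == 0:
        raise ValidationError(f"{inst.rsid}: Wald ratio undefined (beta_exposure = 0)")
    beta = inst.beta_outcome / inst.beta_exposure
    se = inst.se_outcome / abs(inst.beta_exposure)
    return _normal_estimate("wald", beta, se, 1, alpha)


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray):
    w = sy ** -2.0
    denom = np.sum(bx ** 2 * w)
    beta = np.sum(bx * by * w) / denom
    se_fixed = np.sqrt(1.0 / denom)
    return beta, se_fixed


def cochran_q_components(bx: np.ndarray, by: np.ndarray, sy: np.ndarray):
    """Q = sum of w_k (r_k - beta_IVW)^2 with r_k the Wald ratios and
    w_k = (beta_X/sigma_Y)^2; returns (Q, per-SNP contributions)."""
    beta_ivw, _ = _ivw_core(bx, by, sy)
    ratios = by / bx
    weights = (bx / sy) ** 2
    contrib = weights * (ratios - beta_ivw) ** 2
    return float(np.sum(contrib)), contrib


def ivw(
    insts: Sequence[HarmonizedInstrument],
    effect_model: str = "fixed",
    alpha: float = 0.05,
) -> MrEstimate:
    """Inverse-variance-weighted pooled estimate over >= 2 instruments.

    ``effect_model="fixed"`` uses the analytic IVW SE; ``"random"`` applies
    multiplicative overdispersion, inflating the SE by
    ``max(1, sqrt(Q/(k-1)))``.  P-values are standard normal.
    """
    if effect_model not in ("fixed", "random"):
        raise ValidationError(f"effect_model must be 'fixed' or 'random', got {effect_model!r}")
    insts, bx, by, sy = _extract(insts)
    k = len(insts)
    min_k = 1 if effect_model == "fixed" else 2
    if k < min_k:
        raise InsufficientInstrumentsError(
            f"IVW ({effect_model}) requires >= {min_k} instruments, got {k}"
        )
    if np.any(bx == 0):
        raise ValidationError("IVW undefined with a zero exposure beta")
    beta, se = _ivw_core(bx, by, sy)
    method = "ivw_fixed"
    if effect_model == "random":
        q, _ = cochran_q_components(bx, by, sy)
        se = se * max(1.0, np.sqrt(q / (k - 1)))
        method = "ivw_random"
    return _normal_estimate(method, beta, se, k, alpha)


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    # cumulative weight at each ratio, centred on its own mass
    s = np.cumsum(w) - w / 2
    return float(np.interp(0.5, s, r))


def weighted_median(
    insts: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> MrEstimate:
    """Weighted median of Wald ratios; robust to <50% invalid weight.

    Weights are ``(beta_X/sigma_Y)^2`` normalized to sum 1; the estimate
    linearly interpolates the ratio at cumulative weight 0.5.  The SE comes
    from a parametric bootstrap (``n_boot`` replicates resampling each
    beta_X and beta_Y from normal distributions at their observed values and
    SEs); ``seed`` makes it reproducible and is required.
    """
    if seed is None:
        raise ValidationError("weighted_median requires an explicit seed for the bootstrap")
    insts, bx, by, sy = _extract(insts)
    sx = np.array([i.se_exposure for i in insts])
    k = len(insts)
    if k < 3:
        raise InsufficientInstrumentsError(f"weighted median requires >= 3 instruments, got {k}")
    beta = _weighted_median(by / bx, (bx / sy) ** 2)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        boot[b] = _weighted_median(by_b / bx_b, (bx_b / sy) ** 2)
    se = float(np.std(boot, ddof=1))
    if se == 0:
        se = np.finfo(float).tiny  # degenerate bootstrap (all ratios identical)
    return _normal_estimate("weighted_median", beta, se, k, alpha)


def mr_egger(
    insts: Sequence[HarmonizedInstrument], alpha: float = 0.05
) -> tuple[MrEstimate, MrEstimate]:
    """MR-Egger regression: returns (slope, intercept) estimates.

    Instruments are oriented so beta_X >= 0 (joint sign-flip leaves the Wald
    ratio unchanged), then beta_Y is regressed on beta_X with weights
    1/sigma_Y^2 and a free intercept.  SEs use multiplicative overdispersion
    floored at 1; inference is t with k-2 degrees of freedom.
    """
    import statsmodels.api as sm

    insts, bx, by, sy = _extract(insts)
    k = len(insts)
    if k < 3:
        raise InsufficientInstrumentsError(f"MR-Egger requires >= 3 instruments, got {k}")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    if np.ptp(bx) == 0:
        raise SingularDesignError("all exposure betas equal; Egger design is singular")
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=sy ** -2.0).fit()
    # statsmodels scales bse by the residual sd; rebuild from the unscaled
    # covariance with the overdispersion floored at 1, so under-dispersed
    # (or exactly-fitting) data cannot shrink the SEs below the analytic ones.
    resid_sd = float(np.sqrt(fit.scale))
    unit_se = np.sqrt(np.diag(fit.normalized_cov_params))
    inter_se, slope_se = unit_se * max(1.0, resid_sd)
    inter, slope = fit.params
    df = k - 2
    slope_est = _t_estimate("egger_slope", slope, slope_se, k, df, alpha)
    inter_est = _t_estimate("egger_intercept", inter, inter_se, k, df, alpha)
    return slope_est, inter_est


def estimate_all(
    insts: Sequence[HarmonizedInstrument],
    methods: Sequence[str] = ("ivw_fixed", "ivw_random", "weighted_median", "egger_slope"),
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> list[MrEstimate]:
    """Run the requested methods and return one estimate per label.

    Requesting ``egger_slope`` (or ``egger_intercept``) runs the Egger
    regression once and emits both rows.
    """
    results: list[MrEstimate] = []
    egger_done = False
    for m in methods:
        if m == "ivw_fixed":
            results.append(ivw(insts, "fixed", alpha))
        elif m == "ivw_random":
            results.append(ivw(insts, "random", alpha))
        elif m == "weighted_median":
            results.append(weighted_median(insts, n_boot=n_boot, seed=seed, alpha=alpha))
        elif m in ("egger_slope", "egger_intercept"):
            if not egger_done:
                results.extend(mr_egger(insts, alpha))
                egger_done = True
        elif m == "wald":
            usable = usable_instruments(insts)
            if len(usable) != 1:
                raise ValidationError("wald method applies to a single instrument")
            results.append(wald_ratio(usable[0], alpha))
        else:
            raise ValidationError(f"unknown method {m!r}")
    return results
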