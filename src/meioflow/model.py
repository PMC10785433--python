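"""Misclassification-adjusted multinomial estimation of spike-in proportions.

A spiked sample is a mixture: a fraction ``s`` of its cells are truly RFP
(the spike) and ``1 - s`` are truly GFP/RFP (the background genotype).
Gating assigns each cell to one of three categories — RFP, GFP+GFP_RFP, WT —
but imperfectly: a truly-RFP cell lands in category ``j`` with probability
``p_j`` and a background cell with probability ``q_j``.  The probability that
a cell of a sample with spike-in ``s`` is observed in category ``j`` is
therefore

    pi_j(s) = p_j * s + q_j * (1 - s).

An experiment contributes ``L`` samples with category counts ``y_{lj}``:
one control with ``s = 0`` exactly (pure background, so its off-category
counts are pure misclassification), one reference with ``s = 1`` exactly
(pure RFP cells), and spiked samples with unknown interior ``s``.  The
combined log-likelihood

    l(p, q, s) = sum_l sum_j y_{lj} * log(p_j s_l + q_j (1 - s_l))

is maximized jointly over the two probability triples and the unknown
spike-ins.  ``p`` and ``q`` are parameterized through a softmax map (two free
parameters per triple) and each unknown ``s`` through log-odds, so the
optimization is smooth and unconstrained.  Standard errors come from the
inverse observed information at the optimum, delta-method-transformed back
to the probability scale.

Detectability of a spike is assessed with a Wald test of H0: s = 0, either
model-based (``s_hat / SE``) or, as a cross-check, as a classical two-sample
test on raw RFP fractions against the control.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .errors import ConvergenceError
from .gating import ClassCounts

__all__ = [
    "MisclassParams",
    "SampleRole",
    "ExperimentSeries",
    "OptimizerConfig",
    "FitResult",
    "WaldResult",
    "category_probs",
    "log_likelihood",
    "fit_experiment",
    "wald_test",
    "proportion_wald_test",
]

_SIMPLEX_TOL = 1e-10
_BOUNDARY_TOL = 1e-6


@dataclass(frozen=True)
class MisclassParams:
    """Classification probability triples for the two true cell types.

    ``p`` is (P(classified RFP), P(classified GFP+GFP_RFP), P(classified WT))
    for a truly RFP cell; ``q`` is the same triple for a truly GFP or
    GFP/RFP cell.  Each triple is nonnegative and sums to one.
    """

    p: tuple[float, float, float]
    q: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name, triple in (("p", self.p), ("q", self.q)):
            arr = np.asarray(triple, dtype=float)
            if arr.shape != (3,) or np.any(arr < 0):
                raise ValueError(f"{name} must be three nonnegative probabilities")
            if abs(arr.sum() - 1.0) > _SIMPLEX_TOL:
                raise ValueError(f"{name} must sum to 1 (got {arr.sum():.2e} off)")

    @property
    def p_arr(self) -> np.ndarray:
        return np.asarray(self.p, dtype=float)

    @property
    def q_arr(self) -> np.ndarray:
        return np.asarray(self.q, dtype=float)


class SampleRole(str, enum.Enum):
    """Role of a sample inside an experiment series."""

    CONTROL_ZERO = "control_zero"  # pure background, s fixed at 0
    PURE_ONE = "pure_one"          # pure RFP cells, s fixed at 1
    UNKNOWN = "unknown"            # spiked sample, s estimated


@dataclass(frozen=True)
class ExperimentSeries:
    """All samples of one experiment, with their spike-in roles.

    Requires at least one ``CONTROL_ZERO`` and one ``PURE_ONE`` sample; the
    spike-ins of ``UNKNOWN`` samples are what the fit estimates.
    """

    experiment_id: str
    samples: tuple[tuple[ClassCounts, SampleRole], ...]

    def __post_init__(self) -> None:
        roles = [r for _, r in self.samples]
        if SampleRole.CONTROL_ZERO not in roles or SampleRole.PURE_ONE not in roles:
            raise ValueError("series needs at least one control (s=0) and one pure (s=1) sample")

    @property
    def counts(self) -> np.ndarray:
        """(L, 3) count matrix in sample order."""
        return np.array([c.as_array() for c, _ in self.samples])

    @property
    def roles(self) -> list[SampleRole]:
        return [r for _, r in self.samples]

    @property
    def unknown_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r is SampleRole.UNKNOWN]

    @property
    def sample_ids(self) -> list[str]:
        return [c.sample_id for c, _ in self.samples]


@dataclass(frozen=True)
class OptimizerConfig:
    """Settings for the multi-start maximum-likelihood optimization.

    ``n_starts`` dispersed starting points are tried (the first is a
    closed-form moment start, the rest random); the best log-likelihood
    wins, ties broken by smallest parameter norm.
    """

    n_starts: int = 10
    seed: int = 0
    gtol: float = 1e-6
    ftol: float = 1e-10
    max_iter: int = 1000


@dataclass
class FitResult:
    """Maximum-likelihood fit of one experiment series."""

    params: MisclassParams
    s_hat: np.ndarray            # one per unknown sample, in series order
    se_s: np.ndarray             # nan where s_hat sits on the boundary
    loglik: float
    covariance: np.ndarray       # over free parameters, unconstrained scale
    free_names: list[str]
    converged: bool
    boundary: np.ndarray         # per unknown sample
    sample_ids: list[str] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class WaldResult:
    statistic: float
    p_value: float
    comparison: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# Probability model
# ---------------------------------------------------------------------------


def category_probs(params: MisclassParams, s: float) -> np.ndarray:
    """Category probabilities ``p*s + q*(1-s)`` for spike-in proportion ``s``.

    At ``s = 0`` this is exactly ``q`` (pure background) and at ``s = 1``
    exactly ``p`` (pure RFP); components always sum to one.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"spike-in proportion must be in [0, 1], got {s}")
    return params.p_arr * s + params.q_arr * (1.0 - s)


def _full_s_vector(series: ExperimentSeries, s_values: Sequence[float]) -> np.ndarray:
    unknown = series.unknown_indices
    if len(s_values) != len(unknown):
        raise ValueError(f"expected {len(unknown)} spike-in values, got {len(s_values)}")
    s = np.zeros(len(series.samples))
    for i, role in enumerate(series.roles):
        if role is SampleRole.PURE_ONE:
            s[i] = 1.0
    s[unknown] = np.asarray(s_values, dtype=float)
    return s


def log_likelihood(
    series: ExperimentSeries,
    params: MisclassParams,
    s_values: Sequence[float] = (),
) -> float:
    """Combined multinomial log-likelihood of a series.

    ``s_values`` supplies one spike-in per UNKNOWN sample, in series order;
    controls and pure samples enter with s fixed at 0 and 1.  A category with
    zero probability but a positive count makes the data impossible and
    returns ``-inf`` (reported, never silently floored).
    """
    s = _full_s_vector(series, s_values)
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("spike-in proportions must be in [0, 1]")
    y = series.counts
    pi = np.outer(s, params.p_arr) + np.outer(1.0 - s, params.q_arr)
    pos = y > 0
    if np.any(pi[pos] <= 0):
        return -np.inf
    out = 0.0
    if pos.any():
        out = float(np.sum(y[pos] * np.log(pi[pos])))
    return out


# ---------------------------------------------------------------------------
# Maximum likelihood
# ---------------------------------------------------------------------------


def _softmax3(a1: float, a2: float) -> np.ndarray:
    z = np.array([a1, a2, 0.0])
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def _inv_softmax3(triple: np.ndarray, eps: float = 1e-9) -> tuple[float, float]:
    t = np.clip(np.asarray(triple, dtype=float), eps, None)
    return float(np.log(t[0] / t[2])), float(np.log(t[1] / t[2]))


def _unpack(theta: np.ndarray, n_unknown: int):
    p = _softmax3(theta[0], theta[1])
    q = _softmax3(theta[2], theta[3])
    t = theta[4 : 4 + n_unknown]
    s_unknown = special.expit(t)
    return p, q, s_unknown


def _negloglik_and_grad(theta: np.ndarray, y: np.ndarray, s_fixed: np.ndarray,
                        unknown: np.ndarray) -> tuple[float, np.ndarray]:
    """Negative log-likelihood with analytic gradient on the free scale.

    Probabilities are floored at 1e-300 inside the logs so the optimizer can
    traverse degenerate corners; the reported likelihood is recomputed
    without the floor after convergence.
    """
    n_unknown = len(unknown)
    p, q, s_unknown = _unpack(theta, n_unknown)
    s = s_fixed.copy()
    s[unknown] = s_unknown
    pi = np.outer(s, p) + np.outer(1.0 - s, q)
    pi_safe = np.maximum(pi, 1e-300)
    nll = -float(np.sum(y * np.log(pi_safe)))

    w = y / pi_safe                                   # (L, 3)
    gp = w.T @ s                                      # dl/dp_j
    gq = w.T @ (1.0 - s)                              # dl/dq_j
    ga = p * (gp - float(gp @ p))                     # softmax chain rule
    gb = q * (gq - float(gq @ q))
    grad = np.empty_like(theta)
    grad[0], grad[1] = -ga[0], -ga[1]
    grad[2], grad[3] = -gb[0], -gb[1]
    if n_unknown:
        dl_ds = (w * (p - q)).sum(axis=1)             # per sample
        grad[4:] = -(dl_ds[unknown] * s_unknown * (1.0 - s_unknown))
    return nll, grad


def _moment_start(y: np.ndarray, roles: list[SampleRole], unknown: list[int]) -> np.ndarray:
    """Closed-form start: empirical proportions of the pure/control samples,
    and a method-of-moments spike-in from the RFP fraction."""
    tot = y.sum(axis=1, keepdims=True)
    props = np.where(tot > 0, y / np.maximum(tot, 1), 1 / 3)
    ctrl = [i for i, r in enumerate(roles) if r is SampleRole.CONTROL_ZERO]
    pure = [i for i, r in enumerate(roles) if r is SampleRole.PURE_ONE]
    q0 = props[ctrl].mean(axis=0)
    p0 = props[pure].mean(axis=0)
    theta = list(_inv_softmax3(p0) + _inv_softmax3(q0))
    denom = p0[0] - q0[0]
    for i in unknown:
        s0 = (props[i, 0] - q0[0]) / denom if abs(denom) > 1e-9 else 0.01
        s0 = float(np.clip(s0, 1e-4, 1 - 1e-4))
        theta.append(float(special.logit(s0)))
    return np.array(theta)


def fit_experiment(series: ExperimentSeries, config: OptimizerConfig | None = None) -> FitResult:
    """Maximize the combined log-likelihood of one experiment series.

    Returns the fitted probability triples, the spike-in estimate and
    standard error for every UNKNOWN sample, and the covariance of the free
    parameters from the inverse observed information.  An estimate pinned to
    0 or 1 is flagged as a boundary optimum and its SE reported as ``nan``.
    """
    config = config or OptimizerConfig()
    y = series.counts
    if np.any(y.sum(axis=1) <= 0):
        raise ValueError("every sample must contain at least one event")
    roles = series.roles
    unknown = np.array(series.unknown_indices, dtype=int)
    n_unknown = len(unknown)
    s_fixed = np.array([1.0 if r is SampleRole.PURE_ONE else 0.0 for r in roles])

    rng = np.random.default_rng(config.seed)
    starts = [_moment_start(y, roles, list(unknown))]
    for _ in range(max(0, config.n_starts - 1)):
        theta0 = np.concatenate([
            rng.normal(0.0, 2.0, size=4),
            special.logit(rng.uniform(0.005, 0.5, size=n_unknown)) if n_unknown else [],
        ])
        starts.append(theta0)

    bounds = [(-30.0, 30.0)] * 4 + [(-16.0, 16.0)] * n_unknown
    best = None
    n_ok = 0
    for theta0 in starts:
        res = optimize.minimize(
            _negloglik_and_grad,
            theta0,
            args=(y, s_fixed, unknown),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": config.max_iter, "ftol": config.ftol, "gtol": config.gtol},
        )
        n_ok += bool(res.success)
        key = (-res.fun, -float(np.linalg.norm(res.x)))  # highest ll, then smallest norm
        if best is None or key > best[0]:
            best = (key, res)
    assert best is not None
    res = best[1]
    theta = res.x
    p, q, s_unknown = _unpack(theta, n_unknown)
    params = MisclassParams(tuple(p / p.sum()), tuple(q / q.sum()))
    converged = n_ok > 0

    boundary = (s_unknown < _BOUNDARY_TOL) | (s_unknown > 1 - _BOUNDARY_TOL)
    cov, se_s = _covariance(theta, y, s_fixed, unknown, s_unknown, boundary)
    loglik = log_likelihood(series, params, s_unknown)

    free_names = ["p_logit1", "p_logit2", "q_logit1", "q_logit2"] + [
        f"s_logodds[{series.sample_ids[i]}]" for i in unknown
    ]
    if not converged:
        diagnostics = {"message": str(res.message), "n_starts": len(starts)}
    else:
        diagnostics = {"n_starts": len(starts), "n_converged": n_ok}
    return FitResult(
        params=params,
        s_hat=s_unknown,
        se_s=se_s,
        loglik=loglik,
        covariance=cov,
        free_names=free_names,
        converged=converged,
        boundary=boundary,
        sample_ids=[series.sample_ids[i] for i in unknown],
        diagnostics=diagnostics,
    )


def _covariance(theta, y, s_fixed, unknown, s_unknown, boundary):
    """Observed-information covariance and delta-method SEs for the spike-ins."""
    k = len(theta)
    eps = 1e-5 * np.maximum(1.0, np.abs(theta))
    H = np.zeros((k, k))
    for j in range(k):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += eps[j]
        tm[j] -= eps[j]
        _, gp = _negloglik_and_grad(tp, y, s_fixed, unknown)
        _, gm = _negloglik_and_grad(tm, y, s_fixed, unknown)
        H[:, j] = (gp - gm) / (2 * eps[j])
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.pinv(H)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
    se_s = np.full(len(unknown), np.nan)
    for m in range(len(unknown)):
        if boundary[m]:
            continue
        var_t = cov[4 + m, 4 + m]
        if var_t > 0:
            # delta method through s = expit(t): ds/dt = s(1-s)
            se_s[m] = s_unknown[m] * (1.0 - s_unknown[m]) * np.sqrt(var_t)
    return cov, se_s


# ---------------------------------------------------------------------------
# Wald tests
# ---------------------------------------------------------------------------


def wald_test(fit: FitResult, sample_index: int = 0, alternative: str = "greater") -> WaldResult:
    """Model-based Wald test of H0: s = 0 for one unknown sample.

    The statistic is ``z = s_hat / SE(s_hat)`` against a standard normal,
    one-sided by default (a spike can only add RFP cells).  A degenerate
    estimate at the zero boundary gives ``z = 0`` (one-sided p = 0.5).  If
    the SE is unavailable away from zero, use :func:`proportion_wald_test`.
    """
    if not fit.converged:
        raise ConvergenceError("fit did not converge; Wald test unavailable")
    s = float(fit.s_hat[sample_index])
    se = float(fit.se_s[sample_index])
    null = f"H0: s=0 for sample {fit.sample_ids[sample_index]!r} (model-based)"
    if s < _BOUNDARY_TOL:
        z = 0.0
    elif not np.isfinite(se) or se <= 0:
        raise ConvergenceError(
            "standard error unavailable (boundary optimum); "
            "use proportion_wald_test for a model-free comparison"
        )
    else:
        z = s / se
    if alternative == "greater":
        p = float(stats.norm.sf(z))
    elif alternative == "two-sided":
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    return WaldResult(statistic=z, p_value=p, comparison=null)


def proportion_wald_test(
    spiked: ClassCounts, control: ClassCounts, alternative: str = "greater"
) -> WaldResult:
    """Two-sample Wald test on raw RFP fractions (spiked vs control).

    Cross-check mode: compares the classified-RFP fraction of a spiked
    sample with the control's, unpooled normal approximation.
    """
    n1, n0 = spiked.n_total, control.n_total
    if n1 == 0 or n0 == 0:
        raise ValueError("both samples need events")
    f1, f0 = spiked.y1 / n1, control.y1 / n0
    var = f1 * (1 - f1) / n1 + f0 * (1 - f0) / n0
    z = (f1 - f0) / np.sqrt(var) if var > 0 else 0.0
    if alternative == "greater":
        p = float(stats.norm.sf(z))
    elif alternative == "two-sided":
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    return WaldResult(
        statistic=float(z),
        p_value=p,
        comparison=f"H0: RFP fraction equal in {spiked.sample_id!r} and control {control.sample_id!r}",
    )
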