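"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route deliberately different from the
implementation under test: explicit per-event loops for gating, an
EM-profiled grid search for the spike-in MLE, and leave-one-out coefficient
shifts for Cook's distance.
"""

from __future__ import annotations

import numpy as np


def brute_force_tally(events: np.ndarray, channels: list[str]) -> tuple[int, int, int]:
    """Loop-based three-category tally using the published cuts directly."""
    fitc = channels.index("FITC.A")
    pe = channels.index("PE.CF594.A")
    y1 = y2 = y3 = 0
    for row in events:
        gfp = 560 < row[fitc] < 10_000
        rfp = 1_000 < row[pe] < 10_000
        if rfp and not gfp:
            y1 += 1
        elif gfp:
            y2 += 1
        else:
            y3 += 1
    return y1, y2, y3


def brute_force_quality(events: np.ndarray, channels: list[str]) -> np.ndarray:
    """Per-event re-check of the quality bounds, one comparison at a time."""
    idx = {c: channels.index(c) for c in ("FSC.H", "FSC.A", "SSC.H", "BV605.A", "BV510.A")}
    keep = []
    for row in events:
        ok = (
            row[idx["FSC.H"]] > 55_000
            and row[idx["FSC.A"]] < 200_000
            and 450 < row[idx["SSC.H"]] < 3_500
            and row[idx["BV605.A"]] > 800
            and row[idx["BV510.A"]] > 800
        )
        keep.append(ok)
    return np.array(keep, dtype=bool)


def profile_pq_em(y: np.ndarray, s: np.ndarray, n_iter: int = 500, tol: float = 1e-12):
    """Profile MLE of (p, q) at fixed spike-ins via EM over the latent true
    type of each counted cell; returns (p, q, log-likelihood)."""
    tot = y.sum(axis=1, keepdims=True)
    props = y / np.maximum(tot, 1)
    p = props[np.argmax(s)].copy() + 1e-6
    q = props[np.argmin(s)].copy() + 1e-6
    p /= p.sum()
    q /= q.sum()
    ll_old = -np.inf
    for _ in range(n_iter):
        pi = np.outer(s, p) + np.outer(1 - s, q)
        pi = np.maximum(pi, 1e-300)
        w = (s[:, None] * p[None, :]) / pi
        Np = (y * w).sum(axis=0) + 1e-300
        Nq = (y * (1 - w)).sum(axis=0) + 1e-300
        p = Np / Np.sum()
        q = Nq / Nq.sum()
        mask = y > 0
        ll = float((y[mask] * np.log(pi[mask])).sum())
        if abs(ll - ll_old) < tol * max(1.0, abs(ll)):
            break
        ll_old = ll
    return p, q, ll


def grid_search_s(y: np.ndarray, s_fixed: np.ndarray, unknown_index: int,
                  coarse: float = 1e-2, fine: float = 1e-4) -> float:
    """Dense grid-search MLE of one unknown spike-in with (p, q) profiled out
    by EM at every grid point (coarse pass, then a fine pass at resolution
    ``fine`` around the coarse optimum)."""

    def profile_ll(s_val: float) -> float:
        s = s_fixed.copy()
        s[unknown_index] = s_val
        return profile_pq_em(y, s)[2]

    coarse_grid = np.arange(0.0, 1.0 + coarse / 2, coarse)
    lls = [profile_ll(v) for v in coarse_grid]
    center = coarse_grid[int(np.argmax(lls))]
    lo = max(0.0, center - 1.5 * coarse)
    hi = min(1.0, center + 1.5 * coarse)
    fine_grid = np.arange(lo, hi + fine / 2, fine)
    lls = [profile_ll(v) for v in fine_grid]
    return float(fine_grid[int(np.argmax(lls))])


def cooks_via_refit(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Cook's distance from explicit leave-one-out coefficient shifts:
    D_i = (b - b_(i))' X'X (b - b_(i)) / (k * s^2)."""
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    b, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ b
    s2 = resid @ resid / (n - 2)
    XtX = X.T @ X
    out = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        bi, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
        d = b - bi
        out[i] = d @ XtX @ d / (2 * s2)
    return out
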