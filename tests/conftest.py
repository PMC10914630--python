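import numpy as np
import pytest

from circasyn import SimulationConfig, simulate_cohort, simulate_paired_preparations


@pytest.fixture(scope="session")
def small_cohort():
    """A modest null-free cohort reused by read-only tests."""
    cfg = SimulationConfig(n_per_group=15, n_proteins=200, n_modules=2,
                           module_size=40, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def paired_cohort():
    cfg = SimulationConfig(n_per_group=12, n_proteins=150, n_modules=0,
                           module_size=0, seed=7)
    return simulate_paired_preparations(cfg)


# ---------------------------------------------------------------------------
# independent oracles (deliberately brute-force; no reuse of package internals)
# ---------------------------------------------------------------------------

def ols_oracle(y, X):
    """Per-protein least squares via explicit normal equations."""
    XtX = np.zeros((X.shape[1], X.shape[1]))
    Xty = np.zeros(X.shape[1])
    for i in range(X.shape[0]):
        XtX += np.outer(X[i], X[i])
        Xty += X[i] * y[i]
    beta = np.linalg.solve(XtX, Xty)
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    s2 = float(resid @ resid) / df
    cov = np.linalg.inv(XtX) * s2
    return beta, np.sqrt(np.diag(cov)), df


def cosinor_grid_oracle(y, zt, coarse_step=0.01):
    """Brute-force SSE minimization over phase with profiled (mesor, amplitude).

    For each candidate phase the model y = M + A*cos(2*pi*(t - phi)/24) is
    linear in (M, A); the best phase on a fine grid is refined by golden
    search.  Returns (mesor, amplitude, peak_zt, r2).
    """
    from scipy.optimize import minimize_scalar

    y = np.asarray(y, float)
    zt = np.asarray(zt, float)
    w = 2 * np.pi / 24.0

    def sse_at(phi):
        c = np.cos(w * (zt - phi))
        X = np.column_stack([np.ones_like(c), c])
        coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        return float(r @ r), coef

    phis = np.arange(0.0, 24.0, coarse_step)
    sses = np.array([sse_at(p)[0] for p in phis])
    best = phis[int(np.argmin(sses))]
    res = minimize_scalar(lambda p: sse_at(p)[0],
                          bounds=(best - 2 * coarse_step, best + 2 * coarse_step),
                          method="bounded", options={"xatol": 1e-10})
    phi = float(res.x)
    sse, (mesor, amp) = sse_at(phi)
    if amp < 0:
        amp, phi = -amp, (phi + 12.0) % 24.0
    phi %= 24.0
    sst = float(np.sum((y - y.mean()) ** 2))
    return float(mesor), float(amp), phi, 1.0 - sse / sst


def hypergeom_tail_oracle(k, N, K, n):
    """P[X >= k] for X ~ Hypergeom(N, K, n) by direct enumeration."""
    from math import comb

    total = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x)
               for x in range(k, min(K, n) + 1)) / total


def fisher_two_sided_oracle(table):
    """Two-sided Fisher exact p by enumerating tables with fixed margins."""
    from math import comb

    (a, b), (c, d) = table
    row1, col1, N = a + b, a + c, a + b + c + d

    def prob(x):
        return comb(col1, x) * comb(N - col1, row1 - x) / comb(N, row1)

    p_obs = prob(a)
    lo, hi = max(0, row1 + col1 - N), min(row1, col1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12))
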