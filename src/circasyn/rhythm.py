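"""Diurnal rhythmicity from time-of-death expression snapshots.

Each postmortem subject contributes a single circadian time point: the
clock time of death converted to Zeitgeber time (ZT; hours relative to
sunrise on the day of death, negative before sunrise).  A fixed-period
24-h sinusoid (single-harmonic cosinor)

    y = M + A * cos(2*pi*(t - phi) / 24)

is fitted per protein by least squares, using the linearization
``y = M + b1*cos(wt) + b2*sin(wt)`` which attains the exact nonlinear
optimum for a fixed period.  Goodness of fit is summarized by R^2 and
significance by an empirical p-value from refitting on ZT-permuted data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Dataset

logger = logging.getLogger(__name__)

_OMEGA = 2.0 * np.pi / 24.0
_STREAM_RHYTHM = 11


def tod_to_zt(tod_clock, sunrise, sunset=None):
    """Convert clock time of death to Zeitgeber time.

    ZT0 is sunrise; the result is ``tod_clock - sunrise`` wrapped into
    ``[-6, 18)`` so deaths shortly before sunrise carry negative ZT.
    ``sunset`` is accepted (and validated) for interface symmetry but does
    not enter the default conversion; see :func:`tod_to_zt_rescaled` for a
    daylength-rescaled variant.
    """
    tod_clock = np.asarray(tod_clock, dtype=float)
    sunrise = np.asarray(sunrise, dtype=float)
    for name, v in (("tod_clock", tod_clock), ("sunrise", sunrise)):
        if np.any((v < 0.0) | (v >= 24.0)):
            raise ValueError(f"{name} outside [0, 24)")
    if sunset is not None:
        sunset = np.asarray(sunset, dtype=float)
        if np.any((sunset < 0.0) | (sunset >= 24.0)):
            raise ValueError("sunset outside [0, 24)")
    zt = np.mod(tod_clock - sunrise + 6.0, 24.0) - 6.0
    if zt.ndim == 0:
        return float(zt)
    return zt


def tod_to_zt_rescaled(tod_clock, sunrise, sunset):
    """Daylength-rescaled ZT: sunrise maps to ZT0 and sunset to ZT12.

    Daytime hours are scaled by ``12 / daylength`` and nighttime hours by
    ``12 / (24 - daylength)``, then wrapped into ``[-6, 18)``.
    """
    tod_clock = np.asarray(tod_clock, dtype=float)
    sunrise = np.asarray(sunrise, dtype=float)
    sunset = np.asarray(sunset, dtype=float)
    raw = np.mod(tod_clock - sunrise, 24.0)           # hours since sunrise, [0, 24)
    daylength = np.mod(sunset - sunrise, 24.0)
    night = 24.0 - daylength
    scaled = np.where(
        raw < daylength,
        raw * 12.0 / daylength,
        12.0 + (raw - daylength) * 12.0 / night,
    )
    out = np.mod(scaled + 6.0, 24.0) - 6.0
    if out.ndim == 0:
        return float(out)
    return out


def zt_for_dataset(ds: Dataset, rescale_daylength: bool = False) -> np.ndarray:
    meta = ds.metadata_frame()
    fn = tod_to_zt_rescaled if rescale_daylength else tod_to_zt
    return np.asarray(
        fn(meta["tod"].to_numpy(), meta["sunrise"].to_numpy(), meta["sunset"].to_numpy())
    )


# ---------------------------------------------------------------------------
# cosinor fitting
# ---------------------------------------------------------------------------

@dataclass
class CosinorResults:
    """Fitted single-harmonic cosinor for one series."""

    mesor: float
    amplitude: float
    peak_zt: float
    r2: float
    beta_cos: float
    beta_sin: float
    nobs: int
    p_emp: float = np.nan

    def predict(self, zt) -> np.ndarray:
        zt = np.asarray(zt, dtype=float)
        return self.mesor + self.beta_cos * np.cos(_OMEGA * zt) + self.beta_sin * np.sin(_OMEGA * zt)

    def summary(self) -> str:
        lines = [
            "Cosinor fit (period fixed at 24 h)",
            f"  nobs      {self.nobs}",
            f"  mesor     {self.mesor:.4f}",
            f"  amplitude {self.amplitude:.4f}",
            f"  peak ZT   {self.peak_zt:.4f}",
            f"  R^2       {self.r2:.4f}",
        ]
        if np.isfinite(self.p_emp):
            lines.append(f"  empirical p {self.p_emp:.4g}")
        return "\n".join(lines)


class CosinorModel:
    """Fixed-period sinusoid model of one expression series over ZT.

    Parameters
    ----------
    endog
        Expression values (log2), one per sample.
    zt
        Zeitgeber times in hours, same length.
    """

    def __init__(self, endog, zt):
        self.endog = np.asarray(endog, dtype=float)
        self.zt = np.asarray(zt, dtype=float)
        if self.endog.shape != self.zt.shape or self.endog.ndim != 1:
            raise ValueError("endog and zt must be 1-D arrays of equal length")
        if len(self.endog) < 6:
            raise ValueError("cosinor fit requires at least 6 samples")
        if np.allclose(self.zt, self.zt[0]):
            raise ValueError("zt values are all identical")

    def fit(self) -> CosinorResults:
        mesor, b1, b2, r2 = _cosinor_coefs(self.endog, self.zt)
        amplitude = float(np.hypot(b1, b2))
        peak = float(np.mod(np.arctan2(b2, b1) / _OMEGA, 24.0))
        if amplitude == 0.0:
            peak = 0.0
        return CosinorResults(
            mesor=float(mesor), amplitude=amplitude, peak_zt=peak, r2=float(r2),
            beta_cos=float(b1), beta_sin=float(b2), nobs=len(self.endog),
        )


def _cosinor_coefs(y, zt):
    c = np.cos(_OMEGA * zt)
    s = np.sin(_OMEGA * zt)
    X = np.column_stack([np.ones_like(c), c, s])
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        warnings.warn("constant series: R^2 defined as 0, amplitude 0")
        return y.mean(), 0.0, 0.0, 0.0
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    r2 = 1.0 - float(np.sum(resid ** 2)) / sst
    return coef[0], coef[1], coef[2], min(max(r2, 0.0), 1.0)


def fit_cosinor(values, zt) -> CosinorResults:
    """Functional wrapper: least-squares cosinor fit of one series."""
    return CosinorModel(values, zt).fit()


def fit_cosinor_matrix(Y: np.ndarray, zt: np.ndarray) -> pd.DataFrame:
    """Vectorized cosinor fit for a proteins-by-samples matrix.

    Returns a DataFrame with columns mesor, amplitude, peak_zt, r2,
    beta_cos, beta_sin (row order follows ``Y``).
    """
    Y = np.asarray(Y, dtype=float)
    zt = np.asarray(zt, dtype=float)
    n = len(zt)
    c = np.cos(_OMEGA * zt)
    s = np.sin(_OMEGA * zt)
    X = np.column_stack([np.ones(n), c, s])
    G = np.linalg.inv(X.T @ X)
    B = Y @ X @ G.T                                   # (p, 3) coefficients
    fitted_ss = np.einsum("pi,ij,pj->p", B, X.T @ X, B)
    ybar = Y.mean(axis=1)
    sst = np.sum(Y ** 2, axis=1) - n * ybar ** 2
    ssr = fitted_ss - n * ybar ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(sst > 0, ssr / sst, 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    amp = np.hypot(B[:, 1], B[:, 2])
    peak = np.mod(np.arctan2(B[:, 2], B[:, 1]) / _OMEGA, 24.0)
    peak = np.where(amp == 0.0, 0.0, peak)
    amp = np.where(sst > 0, amp, 0.0)
    return pd.DataFrame(
        dict(mesor=B[:, 0], amplitude=amp, peak_zt=peak, r2=r2,
             beta_cos=B[:, 1], beta_sin=B[:, 2])
    )


# ---------------------------------------------------------------------------
# permutation empirical p-values
# ---------------------------------------------------------------------------

def _perm_r2(y, c, s, G, perm_idx):
    """R^2 for many permuted pairings of one series with the ZT basis.

    ``perm_idx`` is (n_perm, n): row p pairs sample i with basis value
    index perm_idx[p, i].  X'X is permutation-invariant, so only X'y
    changes per permutation.
    """
    n = len(y)
    sy = float(y.sum())
    xty = np.empty((perm_idx.shape[0], 3))
    xty[:, 0] = sy
    xty[:, 1] = (c[perm_idx] * y[None, :]).sum(axis=1)
    xty[:, 2] = (s[perm_idx] * y[None, :]).sum(axis=1)
    V = xty @ G
    ssr = np.einsum("pi,pi->p", V, xty)
    ybar = sy / n
    sst = float(np.sum(y ** 2)) - n * ybar ** 2
    if sst <= 0:
        return np.zeros(perm_idx.shape[0])
    return np.clip((ssr - n * ybar ** 2) / sst, 0.0, 1.0)


def _basis(zt):
    c = np.cos(_OMEGA * zt)
    s = np.sin(_OMEGA * zt)
    X = np.column_stack([np.ones(len(zt)), c, s])
    return c, s, np.linalg.inv(X.T @ X)


def _protein_rng(seed: int, index: int) -> np.random.Generator:
    # one substream per protein index: results do not depend on evaluation order
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAM_RHYTHM, index)))


def empirical_p(values, zt, n_perm: int = 1000, seed: int = 0,
                protein_index: int = 0) -> float:
    """Empirical rhythmicity p-value from ZT-randomized refits.

    The ZT vector is permuted ``n_perm`` times, the cosinor refitted, and

        p = (1 + #{R^2_null >= R^2_obs}) / (n_perm + 1)

    (add-one estimator, so p >= 1/(n_perm+1)).  Pure function of ``seed``
    and ``protein_index``.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d gives coarse p-value resolution", n_perm)
    y = np.asarray(values, dtype=float)
    res = fit_cosinor(y, zt)
    rng = _protein_rng(seed, protein_index)
    c, s, G = _basis(np.asarray(zt, dtype=float))
    perm_idx = _permutation_indices(rng, n_perm, len(y))
    null_r2 = _perm_r2(y, c, s, G, perm_idx)
    return float((1 + np.sum(null_r2 >= res.r2)) / (n_perm + 1))


def _permutation_indices(rng, n_perm, n):
    idx = np.tile(np.arange(n), (n_perm, 1))
    return rng.permuted(idx, axis=1)


def rhythm_fits(ds: Dataset, group: str, n_perm: int = 1000, seed: int = 0,
                rescale_daylength: bool = False) -> pd.DataFrame:
    """Per-protein cosinor fits with empirical p-values for one group.

    Returns a DataFrame with columns protein_id, group, mesor, amplitude,
    peak_zt, r2, p_emp.  Permutation streams are keyed by protein index so
    results are reproducible regardless of evaluation order.
    """
    sub = ds.select_group(group)
    zt = zt_for_dataset(sub, rescale_daylength)
    Y = sub.expr.values
    fits = fit_cosinor_matrix(Y, zt)
    c, s, G = _basis(zt)
    n = len(zt)
    p_emp = np.empty(len(fits))
    for i in range(Y.shape[0]):
        rng = _protein_rng(seed, i)
        perm_idx = _permutation_indices(rng, n_perm, n)
        null_r2 = _perm_r2(Y[i], c, s, G, perm_idx)
        p_emp[i] = (1 + np.sum(null_r2 >= fits["r2"].iloc[i])) / (n_perm + 1)
    out = fits.copy()
    out.insert(0, "protein_id", ds.protein_ids)
    out.insert(1, "group", group)
    out["p_emp"] = p_emp
    return out


def rhythmic_set(fits: pd.DataFrame, alpha: float = 0.05) -> set:
    """Proteins with empirical p below ``alpha``."""
    return set(fits.loc[fits["p_emp"] < alpha, "protein_id"])


# ---------------------------------------------------------------------------
# phase-ordered heatmap matrices
# ---------------------------------------------------------------------------

def phase_ordered_matrix(ds: Dataset, fits: pd.DataFrame, top_n: int = 200,
                         group: str | None = None,
                         row_order: list | None = None,
                         rescale_daylength: bool = False):
    """Z-scored expression of top rhythmic proteins, phase- and ZT-ordered.

    Proteins are the ``top_n`` by ascending empirical p (ties broken by
    descending R^2, then id), rows Z-transformed and sorted by peak ZT,
    columns sorted by subject ZT.  Passing ``row_order`` (e.g. the ordering
    derived in the unaffected group) keeps rows fixed while Z-scores are
    recomputed within the plotted group.

    Returns ``(matrix DataFrame, row_order, column_order)``.
    """
    sub = ds.select_group(group) if group is not None else ds
    if row_order is None:
        ranked = fits.sort_values(
            ["p_emp", "r2", "protein_id"], ascending=[True, False, True]
        )
        if len(ranked) < top_n:
            logger.info("only %d proteins available for top_n=%d", len(ranked), top_n)
        chosen = ranked.head(top_n)
        chosen = chosen.sort_values(["peak_zt", "protein_id"])
        row_order = list(chosen["protein_id"])
    zt = zt_for_dataset(sub, rescale_daylength)
    col_idx = np.argsort(zt, kind="stable")
    col_order = [sub.sample_ids[i] for i in col_idx]
    mat = sub.expr.select_proteins(row_order).select_samples(col_order).values
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (mat - mean) / sd
    return pd.DataFrame(z, index=row_order, columns=col_order), row_order, col_order
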