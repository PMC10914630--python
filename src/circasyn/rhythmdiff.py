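"""Differential rhythmicity between diagnosis groups.

The statistic is the change in cosinor goodness of fit,

    dR2 = R2_unaffected - R2_OUD,

evaluated for proteins significantly rhythmic in at least one group.  The
null distribution is built by permuting ZT assignments independently
within the unaffected samples and within the OUD samples and refitting
both cosinor models; the tail is chosen by the sign of the observed dR2
(positive -> candidate rhythm loss in OUD, negative -> gain).  Differences
in phase, amplitude and mesor are reported for proteins rhythmic in both
groups.  The Fisher-exact overlap test compares the rhythmic sets over a
shared background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import Dataset
from .rhythm import _basis, _perm_r2, _permutation_indices, zt_for_dataset

logger = logging.getLogger(__name__)

_STREAM_DRHYTHM = 12


def _group_arrays(ds: Dataset, rescale_daylength: bool = False):
    out = {}
    for g in ("unaffected", "OUD"):
        sub = ds.select_group(g)
        zt = zt_for_dataset(sub, rescale_daylength)
        out[g] = (sub.expr.values, zt)
    return out


def delta_r2_table(ds: Dataset, fits_u: pd.DataFrame, fits_o: pd.DataFrame,
                   alpha: float = 0.05, n_perm: int = 1000, seed: int = 0,
                   rescale_daylength: bool = False) -> pd.DataFrame:
    """dR2 permutation test for every protein rhythmic in either group.

    ``fits_u``/``fits_o`` are per-group tables from
    :func:`circasyn.rhythm.rhythm_fits` (need columns protein_id, r2,
    p_emp).  Proteins rhythmic (p_emp < alpha) in neither group are
    skipped with a log entry.  Returns columns protein_id, r2_unaffected,
    r2_oud, delta_r2, p_change, change_class.
    """
    arrays = _group_arrays(ds, rescale_daylength)
    (Yu, zt_u), (Yo, zt_o) = arrays["unaffected"], arrays["OUD"]
    cu, su, Gu = _basis(zt_u)
    co, so, Go = _basis(zt_o)
    pu = fits_u.set_index("protein_id")
    po = fits_o.set_index("protein_id")
    pos = {p: i for i, p in enumerate(ds.protein_ids)}
    eligible = [
        p for p in ds.protein_ids
        if (p in pu.index and pu.loc[p, "p_emp"] < alpha)
        or (p in po.index and po.loc[p, "p_emp"] < alpha)
    ]
    n_skipped = len(ds.protein_ids) - len(eligible)
    if n_skipped:
        logger.info("delta_r2: %d protein(s) rhythmic in neither group skipped", n_skipped)
    rows = []
    for p in eligible:
        i = pos[p]
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(_STREAM_DRHYTHM, i))
        )
        r2u = float(pu.loc[p, "r2"])
        r2o = float(po.loc[p, "r2"])
        delta = r2u - r2o
        idx_u = _permutation_indices(rng, n_perm, len(zt_u))
        idx_o = _permutation_indices(rng, n_perm, len(zt_o))
        null_u = _perm_r2(Yu[i], cu, su, Gu, idx_u)
        null_o = _perm_r2(Yo[i], co, so, Go, idx_o)
        null_delta = null_u - null_o
        if delta > 0:
            p_change = (1 + np.sum(null_delta >= delta)) / (n_perm + 1)
            candidate = "loss"
        elif delta < 0:
            p_change = (1 + np.sum(null_delta <= delta)) / (n_perm + 1)
            candidate = "gain"
        else:
            p_change, candidate = 1.0, "none"
        change_class = candidate if (p_change < alpha and candidate != "none") else "none"
        rows.append((p, r2u, r2o, delta, float(p_change), change_class))
    return pd.DataFrame(
        rows, columns=["protein_id", "r2_unaffected", "r2_oud", "delta_r2",
                       "p_change", "change_class"]
    )


def delta_r2_test(ds: Dataset, protein_id: str, fits_u: pd.DataFrame,
                  fits_o: pd.DataFrame, alpha: float = 0.05, n_perm: int = 1000,
                  seed: int = 0) -> pd.Series:
    """dR2 test for a single protein (must be rhythmic in at least one group)."""
    if protein_id not in set(ds.protein_ids):
        raise KeyError(f"protein {protein_id!r} not in dataset")
    sub_u = fits_u[fits_u["protein_id"] == protein_id]
    sub_o = fits_o[fits_o["protein_id"] == protein_id]
    if sub_u.empty or sub_o.empty:
        raise KeyError(f"protein {protein_id!r} missing from the fit tables")
    if not (float(sub_u["p_emp"].iloc[0]) < alpha or float(sub_o["p_emp"].iloc[0]) < alpha):
        raise ValueError(f"protein {protein_id!r} is rhythmic in neither group")
    table = delta_r2_table(
        ds.select_proteins(ds.protein_ids), sub_u, sub_o,
        alpha=alpha, n_perm=n_perm, seed=seed,
    )
    return table.set_index("protein_id").loc[protein_id]


def rhythm_param_diff(fit_u, fit_o) -> tuple:
    """(phase_diff, amplitude_diff, base_diff), OUD minus unaffected.

    Only defined for proteins rhythmic in both groups.  The phase
    difference is circular, mapped to ``(-12, 12]`` hours; amplitude and
    mesor differences are plain.
    """
    phase = circular_phase_diff(_get(fit_o, "peak_zt") - _get(fit_u, "peak_zt"))
    amplitude = _get(fit_o, "amplitude") - _get(fit_u, "amplitude")
    base = _get(fit_o, "mesor") - _get(fit_u, "mesor")
    return phase, amplitude, base


def circular_phase_diff(x: float) -> float:
    """Wrap an hour difference into ``(-12, 12]`` (so 23 vs 1 gives +2)."""
    return float(12.0 - np.mod(12.0 - x, 24.0))


def _get(fit, key):
    if isinstance(fit, pd.Series):
        return float(fit[key])
    return float(getattr(fit, key))


def rhythm_param_diff_table(fits_u: pd.DataFrame, fits_o: pd.DataFrame,
                            alpha: float = 0.05) -> pd.DataFrame:
    """Rhythm-parameter differences for proteins rhythmic in both groups."""
    pu = fits_u.set_index("protein_id")
    po = fits_o.set_index("protein_id")
    both = [p for p in pu.index if p in po.index
            and pu.loc[p, "p_emp"] < alpha and po.loc[p, "p_emp"] < alpha]
    rows = []
    for p in both:
        ph, am, ba = rhythm_param_diff(pu.loc[p], po.loc[p])
        rows.append((p, ph, am, ba))
    return pd.DataFrame(rows, columns=["protein_id", "phase_diff", "amplitude_diff",
                                       "base_diff"])


@dataclass
class OverlapTestResult:
    """Fisher-exact comparison of two rhythmic sets over a background."""

    table_counts: np.ndarray     # [[both, u_only], [o_only, neither]]
    odds_ratio: float
    p_fisher: float


def rhythmic_overlap_test(set_u, set_o, background) -> OverlapTestResult:
    """Two-sided Fisher exact test of overlap between group rhythmic sets."""
    background = set(background)
    if not background:
        raise ValueError("empty background")
    set_u, set_o = set(set_u) & background, set(set_o) & background
    both = len(set_u & set_o)
    u_only = len(set_u - set_o)
    o_only = len(set_o - set_u)
    neither = len(background) - both - u_only - o_only
    table = np.array([[both, u_only], [o_only, neither]])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return OverlapTestResult(table_counts=table, odds_ratio=float(odds), p_fisher=float(p))


def gain_loss_by_set_difference(set_u, set_o) -> dict:
    """Complementary bookkeeping: rhythmic-call set differences.

    Proteins rhythmic only in unaffected subjects ("lost" in OUD) and only
    in OUD ("gained"), reported alongside the dR2 permutation test which
    may call a different (usually smaller) set.
    """
    set_u, set_o = set(set_u), set(set_o)
    return {"lost": sorted(set_u - set_o), "gained": sorted(set_o - set_u),
            "shared": sorted(set_u & set_o)}
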