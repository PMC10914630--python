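"""Covariate-adjusted differential expression between OUD and unaffected subjects.

Per protein, log2 expression is regressed on a group indicator plus
technical/demographic covariates (TMT plex, sex, age, PMI, optional
user-supplied per-sample columns).  Residual variances are shrunk toward a
pooled prior by an empirical-Bayes squeeze (moderated t with augmented
degrees of freedom); hyperparameters are estimated by closed-form moment
matching on log residual variances.  A protein is called differentially
expressed when the unadjusted p-value and the absolute log2 fold-change
both clear their thresholds (defaults 0.05 and 0.26, i.e. a 20% change);
a BH-adjusted FDR column is emitted for information.

Cross-comparison utilities: rank-rank hypergeometric overlap (RRHO)
concordance grids and directional Venn overlap counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .data import Dataset

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("plex", "sex", "age", "pmi")
P_MAX_DEFAULT = 0.05
LFC_MIN_DEFAULT = 0.26

_CATEGORICAL = {"plex", "sex"}


class CollinearityError(ValueError):
    """A covariate is collinear with the group indicator or the rest of the design."""


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _design_matrix(ds: Dataset, covariates, extra: pd.DataFrame | None):
    meta = ds.metadata_frame()
    cols = [np.ones(len(meta)), (meta["group"] == "OUD").to_numpy(dtype=float)]
    names = ["intercept", "group"]
    blocks = {}
    for cov in covariates:
        if extra is not None and cov in extra.columns:
            vals = extra.loc[meta["sample_id"], cov].to_numpy(dtype=float)
            blocks[cov] = [(cov, vals)]
        elif cov in _CATEGORICAL:
            levels = sorted(meta[cov].unique())
            blocks[cov] = [
                (f"{cov}[{lev}]", (meta[cov] == lev).to_numpy(dtype=float))
                for lev in levels[1:]
            ]
        elif cov in ("age", "pmi"):
            blocks[cov] = [(cov, meta[cov].to_numpy(dtype=float))]
        else:
            raise ValueError(
                f"covariate {cov!r} is not a metadata field and no extra column supplies it"
            )
    for cov, entries in blocks.items():
        for name, vals in entries:
            cols.append(vals)
            names.append(name)
    X = np.column_stack(cols)
    _check_collinearity(X, names, blocks)
    return X, names


def _check_collinearity(X, names, blocks, cond_max: float = 1e8):
    # scale columns to unit norm so the condition number reflects geometry only
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    cond = np.linalg.cond(X / norms)
    if cond <= cond_max:
        return
    # identify the offending covariate block: removing it must restore conditioning
    for cov in blocks:
        keep = [i for i, n in enumerate(names)
                if n == "intercept" or n == "group" or not _in_block(n, cov)]
        Xr = X[:, keep]
        nr = np.linalg.norm(Xr, axis=0)
        nr[nr == 0] = 1.0
        if np.linalg.cond(Xr / nr) <= cond_max:
            raise CollinearityError(
                f"covariate {cov!r} is collinear with the group indicator or other covariates "
                f"(design condition number {cond:.3g})"
            )
    raise CollinearityError(f"design matrix is ill-conditioned (condition number {cond:.3g})")


def _in_block(name, cov):
    return name == cov or name.startswith(f"{cov}[")


# ---------------------------------------------------------------------------
# empirical Bayes variance squeeze
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def squeeze_variances(s2: np.ndarray, df: float):
    """Moment-matching estimate of the scaled inverse-chi-square variance prior.

    Returns ``(prior_df, prior_var, posterior_var)`` with

        posterior_var = (prior_df * prior_var + df * s2) / (prior_df + df).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) if len(e) > 1 else 0.0
    resid_var = e_var - float(special.polygamma(1, df / 2.0))
    if resid_var > 0:
        d0 = 2.0 * _trigamma_inverse(resid_var)
        s0 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0 = float(np.exp(e_mean))
    post = _posterior_var(s2, df, d0, s0)
    return d0, s0, post


def _posterior_var(s2, df, d0, s0):
    if np.isinf(d0):
        return np.full_like(np.asarray(s2, dtype=float), s0)
    if d0 == 0:
        return np.asarray(s2, dtype=float)
    return (d0 * s0 + df * s2) / (d0 + df)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class DEResults:
    """Per-protein differential-expression table plus fit metadata."""

    table: pd.DataFrame
    design_names: list
    prior_df: float
    prior_var: float
    residual_df: float

    def classify(self, p_max: float = P_MAX_DEFAULT, lfc_min: float = LFC_MIN_DEFAULT) -> pd.DataFrame:
        self.table = classify_de(self.table, p_max=p_max, lfc_min=lfc_min)
        return self.table

    @property
    def de_up(self) -> set:
        t = self.table
        return set(t.loc[t["de_flag"] == "up", "protein_id"])

    @property
    def de_down(self) -> set:
        t = self.table
        return set(t.loc[t["de_flag"] == "down", "protein_id"])

    def summary(self) -> str:
        t = self.table
        n_up = int((t["de_flag"] == "up").sum())
        n_down = int((t["de_flag"] == "down").sum())
        return "\n".join([
            "Differential expression (OUD - unaffected)",
            f"  proteins tested   {len(t)}",
            f"  design columns    {', '.join(self.design_names)}",
            f"  residual df       {self.residual_df:g}",
            f"  prior df          {self.prior_df:g}",
            f"  prior variance    {self.prior_var:.4g}",
            f"  DE up / down      {n_up} / {n_down}",
        ])


class DifferentialExpressionModel:
    """OLS of protein expression on group + covariates with a moderated t.

    Parameters
    ----------
    dataset
        Aligned :class:`~circasyn.data.Dataset` containing both groups.
    covariates
        Metadata fields to adjust for (``plex``/``sex`` expand to dummy
        columns); names present in ``extra_covariates`` resolve there.
    extra_covariates
        Optional per-sample numeric columns indexed by sample_id (e.g. a
        measured total peptide signal).
    """

    def __init__(self, dataset: Dataset, covariates=DEFAULT_COVARIATES,
                 extra_covariates: pd.DataFrame | None = None):
        groups = dataset.groups
        for g in ("unaffected", "OUD"):
            if (groups == g).sum() < 3:
                raise ValueError(f"fewer than 3 samples in group {g!r}")
        self.dataset = dataset
        self.covariates = tuple(covariates)
        self.X, self.design_names = _design_matrix(dataset, self.covariates, extra_covariates)

    def fit(self, moderate: bool = True, prior_df: float | None = None,
            prior_var: float | None = None) -> DEResults:
        """Fit all proteins; ``moderate=False`` reports the ordinary t-test.

        ``prior_df``/``prior_var`` override the moment-matching estimates
        (``prior_df=0`` reproduces the unmoderated test, ``inf`` the
        pooled-variance test).
        """
        Y = self.dataset.expr.values
        if np.isnan(Y).any():
            raise ValueError("expression contains missing values; apply drop_incomplete first")
        X = self.X
        n, k = X.shape
        df = n - k
        if df < 1:
            raise ValueError("no residual degrees of freedom")
        G = np.linalg.inv(X.T @ X)
        B = Y @ X @ G                       # (p, k)
        resid = Y - B @ X.T
        s2 = np.sum(resid ** 2, axis=1) / df
        logfc = B[:, 1]
        se_unit = np.sqrt(G[1, 1])

        if not moderate:
            d0, s0 = 0.0, float(np.mean(s2))
            post = s2
        elif prior_df is not None:
            d0 = float(prior_df)
            s0 = float(prior_var) if prior_var is not None else float(np.exp(np.mean(np.log(s2[s2 > 0]))))
            post = _posterior_var(s2, df, d0, s0)
        else:
            d0, s0, post = squeeze_variances(s2, df)

        df_total = df + d0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = logfc / (np.sqrt(post) * se_unit)
        p = 2.0 * stats.t.sf(np.abs(t), df_total if np.isfinite(df_total) else 1e12)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        fdr = multipletests(p, method="fdr_bh")[1]
        table = pd.DataFrame(
            dict(protein_id=self.dataset.protein_ids, logfc=logfc, t_mod=t, p=p,
                 fdr=fdr, df_total=df_total)
        )
        table = classify_de(table)
        return DEResults(table=table, design_names=list(self.design_names),
                         prior_df=d0, prior_var=s0, residual_df=df)


def fit_de(ds: Dataset, covariates=DEFAULT_COVARIATES, moderate: bool = True,
           extra_covariates: pd.DataFrame | None = None,
           prior_df: float | None = None, prior_var: float | None = None) -> pd.DataFrame:
    """Functional wrapper returning the per-protein DE table."""
    model = DifferentialExpressionModel(ds, covariates, extra_covariates)
    return model.fit(moderate=moderate, prior_df=prior_df, prior_var=prior_var).table


def classify_de(records: pd.DataFrame, p_max: float = P_MAX_DEFAULT,
                lfc_min: float = LFC_MIN_DEFAULT) -> pd.DataFrame:
    """Flag proteins as up/down/none at the p and |log2FC| thresholds.

    Both thresholds are inclusive: p <= p_max and |logfc| >= lfc_min.
    """
    records = records.copy()
    sig = records["p"] <= p_max
    up = sig & (records["logfc"] >= lfc_min)
    down = sig & (records["logfc"] <= -lfc_min)
    records["de_flag"] = np.select([up, down], ["up", "down"], default="none")
    return records


# ---------------------------------------------------------------------------
# RRHO and overlap counts
# ---------------------------------------------------------------------------

@dataclass
class RRHOMap:
    """Grids of -log10 hypergeometric overlap p-values over rank thresholds.

    ``grid`` holds the concordance map (top-i of A vs top-j of B).  A pure
    top-vs-top upper-tail map cannot register anti-concordance: when one
    ranking reverses the other, every top-set overlap sits at its support
    minimum and the map is identically zero.  ``grid_discordant`` therefore
    holds the complementary hypermat computed against the reversed B
    ranking (top-i of A vs bottom-j of B), the standard way the RRHO
    procedure surfaces discordant signal.
    """

    grid: pd.DataFrame            # rows: thresholds in A, cols: thresholds in B
    grid_discordant: pd.DataFrame
    step: int
    n_proteins: int

    def max_cell(self):
        """Location and value of the global maximum over both maps.

        Returns ``(row_rank, col_rank, value, kind)`` with ranks counted
        from the top of each descending ranking; for a discordant maximum
        the column coordinate is the starting rank of the bottom set, so
        anti-concordant signal reports far-corner (off-diagonal)
        coordinates.
        """
        a = self.grid.to_numpy()
        d = self.grid_discordant.to_numpy()
        if a.max() >= d.max():
            i, j = np.unravel_index(np.argmax(a), a.shape)
            return int(self.grid.index[i]), int(self.grid.columns[j]), float(a[i, j]), "concordant"
        i, j = np.unravel_index(np.argmax(d), d.shape)
        col = self.n_proteins - int(self.grid_discordant.columns[j]) + 1
        return int(self.grid_discordant.index[i]), col, float(d[i, j]), "discordant"


def _rrho_ranks(records: pd.DataFrame) -> pd.Series:
    score = -np.log10(records["p"].to_numpy()) * np.sign(records["logfc"].to_numpy())
    order = records.assign(_score=score).sort_values(
        ["_score", "protein_id"], ascending=[False, True]
    )
    return pd.Series(np.arange(1, len(order) + 1), index=order["protein_id"].to_numpy())


def rrho_map(records_a: pd.DataFrame, records_b: pd.DataFrame, step: int = 50) -> RRHOMap:
    """Rank-rank hypergeometric overlap of two signed DE rankings.

    Proteins are ranked by ``-log10(p) * sign(logfc)`` (most upregulated
    first; ties broken by id).  For every pair of rank thresholds
    ``(i*step, j*step)`` the grid holds ``-log10`` of the hypergeometric
    upper-tail probability of the observed overlap of the two top sets.
    """
    shared = sorted(set(records_a["protein_id"]) & set(records_b["protein_id"]))
    n_dropped = (len(records_a) - len(shared)) + (len(records_b) - len(shared))
    if n_dropped:
        logger.info("rrho_map restricted to %d shared proteins (%d dropped)",
                    len(shared), n_dropped)
    N = len(shared)
    if N < 2 * step:
        raise ValueError(f"need at least {2 * step} shared proteins, got {N}")
    ra = _rrho_ranks(records_a[records_a["protein_id"].isin(shared)])
    rb = _rrho_ranks(records_b[records_b["protein_id"].isin(shared)])
    rank_a = ra.loc[shared].to_numpy()
    rank_b = rb.loc[shared].to_numpy()
    thresholds = np.arange(step, N + 1, step)
    if thresholds[-1] != N:                          # partial final stratum
        thresholds = np.append(thresholds, N)

    def _hypermat(rb):
        edges = np.concatenate([[0.5], thresholds + 0.5])
        hist, _, _ = np.histogram2d(rank_a, rb, bins=[edges, edges])
        counts = hist.cumsum(axis=0).cumsum(axis=1)  # overlap of top-i and top-j
        ti = thresholds[:, None]
        tj = thresholds[None, :]
        p = stats.hypergeom.sf(counts - 1, N, ti, tj)
        grid = -np.log10(np.clip(p, np.finfo(float).tiny, 1.0))
        return pd.DataFrame(grid, index=thresholds, columns=thresholds)

    concordant = _hypermat(rank_b)
    discordant = _hypermat(N + 1 - rank_b)           # B reversed: bottom-j sets
    return RRHOMap(grid=concordant, grid_discordant=discordant,
                   step=step, n_proteins=N)


def overlap_counts(flags_a: pd.DataFrame, flags_b: pd.DataFrame) -> dict:
    """Directional Venn counts of DE calls between two analyses."""
    out = {}
    for direction in ("up", "down"):
        a = set(flags_a.loc[flags_a["de_flag"] == direction, "protein_id"])
        b = set(flags_b.loc[flags_b["de_flag"] == direction, "protein_id"])
        out[direction] = {
            "shared": len(a & b),
            "a_only": len(a - b),
            "b_only": len(b - a),
        }
    return out
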