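"""Synapse-enrichment classification from paired homogenate/synaptosome data.

Within a diagnosis group, each subject contributes a paired homogenate and
synaptosome measurement per protein.  A protein is classified as
synapse-enriched when its synaptosome abundance significantly exceeds its
homogenate abundance (one-sided paired t, Bonferroni-corrected p < 0.05)
by at least a 1.25-fold linear ratio.  All other proteins are non-enriched.
Downstream synaptosome differential expression is restricted to the
enriched set (by default the union of the group-specific enriched sets).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .data import Dataset

logger = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.05
FOLD_MIN_DEFAULT = 1.25


def compute_enrichment(hom: Dataset, syn: Dataset, group: str,
                       paired: bool = True) -> pd.DataFrame:
    """Per-protein synaptosome-over-homogenate enrichment within one group.

    Pairs the two preparations on subject_id; subjects lacking either
    preparation are excluded (logged).  The test is one-sided (mean paired
    log2 difference > 0) with Bonferroni correction over proteins tested.
    Set ``paired=False`` for an unpaired Welch fallback.

    Returns a table with columns protein_id, log2_ratio, fold, p_raw,
    p_bonf, enriched.
    """
    hom_g = hom.select_group(group)
    syn_g = syn.select_group(group)
    proteins = [p for p in hom_g.protein_ids if p in set(syn_g.protein_ids)]
    if not proteins:
        raise ValueError("homogenate and synaptosome protein universes are disjoint")
    hom_subj = {s.subject_id: s.sample_id for s in hom_g.subjects}
    syn_subj = {s.subject_id: s.sample_id for s in syn_g.subjects}
    shared_subjects = [s for s in hom_subj if s in syn_subj]
    n_unpaired = (len(hom_subj) - len(shared_subjects)) + (len(syn_subj) - len(shared_subjects))
    if n_unpaired:
        logger.info("excluding %d unpaired sample(s) from enrichment analysis", n_unpaired)
    if paired:
        if len(shared_subjects) < 3:
            raise ValueError(
                f"fewer than 3 paired subjects in group {group!r} "
                f"({len(shared_subjects)} shared)"
            )
        H = hom_g.expr.select_proteins(proteins).select_samples(
            [hom_subj[s] for s in shared_subjects]).values
        S = syn_g.expr.select_proteins(proteins).select_samples(
            [syn_subj[s] for s in shared_subjects]).values
        d = S - H
        n = d.shape[1]
        dbar = d.mean(axis=1)
        sd = d.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = dbar * np.sqrt(n) / sd
        t = np.where(sd == 0, np.where(dbar > 0, np.inf, np.where(dbar < 0, -np.inf, 0.0)), t)
        p_raw = stats.t.sf(t, n - 1)
        p_raw = np.where(np.isposinf(t), 0.0, np.where(np.isneginf(t), 1.0, p_raw))
        log2_ratio = dbar
    else:
        H = hom_g.expr.select_proteins(proteins).values
        S = syn_g.expr.select_proteins(proteins).values
        res = stats.ttest_ind(S, H, axis=1, equal_var=False, alternative="greater")
        p_raw = res.pvalue
        log2_ratio = S.mean(axis=1) - H.mean(axis=1)
    m = len(proteins)
    p_bonf = np.minimum(1.0, p_raw * m)
    table = pd.DataFrame(
        dict(protein_id=proteins, log2_ratio=log2_ratio,
             fold=np.exp2(log2_ratio), p_raw=p_raw, p_bonf=p_bonf)
    )
    return classify_enriched(table)


def classify_enriched(records: pd.DataFrame, alpha: float = ALPHA_DEFAULT,
                      fold_min: float = FOLD_MIN_DEFAULT) -> pd.DataFrame:
    """Set the ``enriched`` flag: Bonferroni p < alpha AND fold >= fold_min.

    The fold boundary is inclusive ("at least 1.25-fold"); the significance
    boundary is strict (p < 0.05).
    """
    records = records.copy()
    records["enriched"] = (records["p_bonf"] < alpha) & (records["fold"] >= fold_min)
    return records


def enriched_union(*record_tables: pd.DataFrame) -> set:
    """Union of enriched sets across groups (the default downstream universe)."""
    out: set = set()
    for t in record_tables:
        out |= set(t.loc[t["enriched"], "protein_id"])
    return out


def filter_to_enriched(syn: Dataset, records) -> Dataset:
    """Restrict a synaptosome dataset to the enriched proteins.

    ``records`` may be an enrichment table or a precomputed protein set
    (e.g. the union across groups).  Zero enriched proteins is an error.
    """
    if isinstance(records, pd.DataFrame):
        enriched = [p for p in records.loc[records["enriched"], "protein_id"]]
    else:
        enriched = list(records)
    keep = [p for p in syn.protein_ids if p in set(enriched)]
    if not keep:
        raise ValueError(
            "no synapse-enriched proteins to retain; review the enrichment thresholds"
        )
    logger.info("retaining %d synapse-enriched protein(s) of %d", len(keep), len(syn.protein_ids))
    return syn.select_proteins(keep)
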