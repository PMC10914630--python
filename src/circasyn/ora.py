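"""Generic over-representation analysis against GMT gene-set collections.

Each annotated set is intersected with the stated background (all
quantified proteins of the relevant preparation/region, not the genome)
and tested with an upper-tail hypergeometric p-value for overlap with the
query set, with Benjamini-Hochberg adjustment across tested sets.  The
reported enrichment score is the count of query hits divided by the count
of background proteins in the set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named protein sets loaded from a GMT file."""

    sets: dict           # name -> set of member ids
    source: str = ""

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")


def load_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name, description, tab-separated members).

    Duplicate members within a set are removed (logged); a line with fewer
    than 3 fields is an error naming the line number.
    """
    sets = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has fewer than 3 fields")
            name = fields[0]
            members = [m for m in fields[2:] if m]
            unique = set(members)
            if len(unique) < len(members):
                logger.info("set %r: removed %d duplicate member(s)",
                            name, len(members) - len(unique))
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r} at line {lineno}")
            sets[name] = unique
    return GeneSetCollection(sets=sets, source=str(path))


def run_ora(query, background, collection: GeneSetCollection,
            min_size: int = 3, max_size: int = 2000) -> pd.DataFrame:
    """Hypergeometric ORA of a query protein set over a background.

    Sets are intersected with the background before testing; sets smaller
    than ``min_size`` or larger than ``max_size`` after intersection are
    skipped.  Returns a table with columns set_name, n_query_hits,
    n_set_in_background, p_hyper, p_adj, enrichment_score.
    """
    query, background = set(query), set(background)
    if not query or not background:
        raise ValueError("query and background must be non-empty")
    stray = query - background
    if stray:
        logger.info("restricting query to background (%d identifier(s) dropped)", len(stray))
        query &= background
    N, n = len(background), len(query)
    rows = []
    for name in sorted(collection.sets):
        in_bg = collection.sets[name] & background
        K = len(in_bg)
        if K < min_size or K > max_size:
            continue
        k = len(in_bg & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, p, k / K))
    if not rows:
        return pd.DataFrame(columns=["set_name", "n_query_hits", "n_set_in_background",
                                     "p_hyper", "p_adj", "enrichment_score"])
    df = pd.DataFrame(rows, columns=["set_name", "n_query_hits", "n_set_in_background",
                                     "p_hyper", "enrichment_score"])
    df["p_adj"] = multipletests(df["p_hyper"].to_numpy(), method="fdr_bh")[1]
    return df[["set_name", "n_query_hits", "n_set_in_background", "p_hyper",
               "p_adj", "enrichment_score"]].sort_values("p_hyper", ignore_index=True)
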