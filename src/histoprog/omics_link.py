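"""Linking tile risk to molecular data.

Single-sample gene-set enrichment (ssGSEA) of hallmark-style gene
sets, marker-mean immune cell scores, Spearman correlation of set
scores with the tile risk score (BH-corrected across sets), and
mutation-group score comparisons via the Mann-Whitney U test.

Proteomic matrices flow through the same operations as transcriptomic
ones; there is no separate code path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .survival_stats import mann_whitney

__all__ = [
    "read_gmt",
    "write_gmt",
    "impute_median",
    "ssgsea",
    "immune_scores",
    "correlate_with_tirs",
    "compare_by_mutation",
    "MutationComparison",
]

log = logging.getLogger(__name__)


@dataclass
class MutationComparison:
    u: float
    p: float
    median_mut: float
    median_wt: float
    direction: str  # "higher_in_mutant" | "lower_in_mutant" | "equal"


# ---------------------------------------------------------------------------
# I/O and preprocessing
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def impute_median(expr: pd.DataFrame) -> pd.DataFrame:
    """Impute missing values with the per-gene median."""
    med = expr.median(axis=1)
    return expr.apply(lambda col: col.fillna(med))


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def ssgsea(expr: pd.DataFrame, sets: dict, alpha: float = 0.25,
           min_size: int = 1, max_size: int = 500) -> pd.DataFrame:
    """Single-sample gene-set enrichment scores.

    Per sample, genes are ranked by expression (descending; average
    ranks on ties). The raw set score is the sum over the ranked list
    of the difference between the weighted in-set ECDF (weight
    ``|rank value|^alpha``) and the unweighted out-of-set ECDF. Raw
    scores are rescaled by the global max-min spread across the whole
    score matrix. Sets with fewer than ``min_size`` or more than
    ``max_size`` matched genes are skipped.
    """
    if expr.index.has_duplicates:
        raise ValueError("duplicate gene names in expression matrix")
    genes = expr.index
    n_genes = len(genes)
    kept_sets = {}
    for name, members in sets.items():
        matched = [g for g in members if g in expr.index]
        if not (min_size <= len(matched) <= max_size):
            log.info("set %s skipped (%d matched genes)", name, len(matched))
            continue
        kept_sets[name] = matched
    if not kept_sets:
        raise ValueError("no gene set matched the expression matrix")
    values = expr.to_numpy(dtype=float)
    # descending ranks, average for ties: rank 1 = highest expression
    scores = np.zeros((len(kept_sets), values.shape[1]))
    member_masks = {
        name: genes.isin(m) for name, m in kept_sets.items()
    }
    for j in range(values.shape[1]):
        col = values[:, j]
        rank_desc = sps.rankdata(-col, method="average")
        order = np.argsort(rank_desc, kind="stable")  # best-ranked first
        weights = np.abs(rank_desc) ** alpha
        for i, name in enumerate(kept_sets):
            in_set = member_masks[name][order]
            w = weights[order]
            w_in = np.where(in_set, w, 0.0)
            cdf_in = np.cumsum(w_in)
            tot_in = cdf_in[-1]
            cdf_in = cdf_in / tot_in if tot_in > 0 else cdf_in
            out = (~in_set).astype(float)
            cdf_out = np.cumsum(out)
            tot_out = cdf_out[-1]
            cdf_out = cdf_out / tot_out if tot_out > 0 else cdf_out
            scores[i, j] = float(np.sum(cdf_in - cdf_out))
    spread = scores.max() - scores.min()
    if spread > 0:
        scores = scores / spread
    return pd.DataFrame(scores, index=list(kept_sets), columns=expr.columns)


# ---------------------------------------------------------------------------
# Immune scores
# ---------------------------------------------------------------------------

def immune_scores(expr: pd.DataFrame, marker_sets: dict) -> pd.DataFrame:
    """Marker-mean immune cell-type scores.

    Each cell type's score in a sample is the mean log-expression of
    its marker genes; cell types with no matched marker are skipped.
    """
    rows = {}
    for cell_type, markers in marker_sets.items():
        matched = [g for g in markers if g in expr.index]
        if not matched:
            log.info("cell type %s skipped: no markers matched", cell_type)
            continue
        rows[cell_type] = expr.loc[matched].mean(axis=0)
    if not rows:
        raise ValueError("no marker set matched the expression matrix")
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Correlation with TiRS
# ---------------------------------------------------------------------------

def correlate_with_tirs(score_matrix: pd.DataFrame, tirs: pd.Series
                        ) -> pd.DataFrame:
    """Spearman correlation of each set score with TiRS, BH-corrected.

    Samples are aligned by id; fewer than 3 paired samples is an error.
    Returns a table (set, rho, p, q) sorted by q then p.
    """
    tirs = pd.Series(tirs)
    common = [s for s in score_matrix.columns if s in tirs.index]
    if len(common) < 3:
        raise ValueError("need at least 3 paired samples")
    t = tirs.loc[common].to_numpy(dtype=float)
    rows = []
    for name in score_matrix.index:
        s = score_matrix.loc[name, common].to_numpy(dtype=float)
        rho, p = sps.spearmanr(s, t)
        rows.append({"set": name, "rho": float(rho), "p": float(p)})
    tab = pd.DataFrame(rows)
    tab["q"] = multipletests(tab["p"], method="fdr_bh")[1]
    return tab.sort_values(["q", "p"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Mutation comparison
# ---------------------------------------------------------------------------

def compare_by_mutation(tirs, mutated) -> MutationComparison:
    """Compare TiRS between mutated and wild-type samples.

    Delegates to the Mann-Whitney U test and reports the effect
    direction via group medians.
    """
    tirs = np.asarray(tirs, dtype=float)
    mutated = np.asarray(mutated, dtype=bool)
    x = tirs[mutated]
    y = tirs[~mutated]
    if x.size == 0 or y.size == 0:
        raise ValueError("both mutation groups must be non-empty")
    u, p = mann_whitney(x, y)
    mx, my = float(np.median(x)), float(np.median(y))
    direction = ("higher_in_mutant" if mx > my
                 else "lower_in_mutant" if mx < my else "equal")
    return MutationComparison(u=u, p=p, median_mut=mx, median_wt=my,
                              direction=direction)
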