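"""CLIP-style target selection and factor-vs-load correlation across tissues.

Given a per-gene binding-record count (an opaque nonnegative ranking score
from a CLIP database) and a gene x tissue TPM matrix containing the splicing
factor itself, select the factor's strongest targets and correlate the
factor's expression with the summed expression of those targets across
tissues.  A positive correlation is the signature of load-adaptive negative
autoregulation: tissues with more substrate demand maintain more factor.

Two selection modes mirror common practice:

* ``percentile`` — the genes in the top fraction (2% or 5%) of binding
  records;
* ``absolute`` — the record threshold (scanned from strictest down) at which
  the selected targets' share of the transcriptome falls inside a window
  (default 2-5%), making selections comparable across factors with very
  different record distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TargetTable",
    "SelectionError",
    "select_targets_percentile",
    "select_targets_absolute",
    "load_correlation",
    "permutation_null",
]


class SelectionError(ValueError):
    """Target selection is impossible on this table."""


@dataclass(frozen=True)
class TargetTable:
    """Per-gene binding records joined with a gene x tissue TPM matrix."""

    records: pd.Series  # index: gene, values: nonnegative counts
    tpm: pd.DataFrame   # index: gene, columns: tissues
    factor_gene: str

    def __post_init__(self) -> None:
        if len(self.tpm) == 0 or len(self.records) == 0:
            raise SelectionError("empty table")
        if self.factor_gene not in self.tpm.index:
            raise SelectionError(f"factor gene {self.factor_gene!r} not in TPM matrix")
        missing = self.records.index.difference(self.tpm.index)
        if len(missing):
            raise SelectionError(
                f"records refer to genes absent from TPM matrix: {list(missing)[:5]}")
        if (self.records < 0).any():
            raise SelectionError("binding records must be nonnegative")
        if (self.tpm.to_numpy() < 0).any():
            raise SelectionError("TPM values must be nonnegative")

    @property
    def candidate_genes(self) -> pd.Index:
        """Genes eligible as targets: everything except the factor itself."""
        return self.records.index.difference([self.factor_gene], sort=False)


def _ranked_candidates(table: TargetTable) -> pd.DataFrame:
    recs = table.records.loc[table.candidate_genes]
    # deterministic order: records descending, gene id ascending at ties
    idx = np.lexsort((recs.index.to_numpy(), -recs.to_numpy(dtype=float)))
    return recs.iloc[idx].rename("records").to_frame()


def select_targets_percentile(table: TargetTable, top_frac: float) -> list[str]:
    """The ceil(top_frac * n) candidate genes with the highest records.

    Ties at the cut are broken by lexicographic gene id; the factor itself is
    never selected.  Selections are nested in ``top_frac``.
    """
    if not 0.0 < top_frac < 1.0:
        raise ValueError("top_frac must be in (0, 1)")
    ranked = _ranked_candidates(table)
    n = math.ceil(top_frac * len(ranked))
    return list(ranked.index[:n])


def select_targets_absolute(table: TargetTable,
                            window: tuple[float, float] = (0.02, 0.05),
                            ) -> tuple[list[str], float]:
    """Record threshold whose selection's transcriptome share hits a window.

    For each candidate threshold (unique record values, scanned descending,
    i.e. strictest selection first), genes with records >= threshold are
    selected; the score is the across-tissue mean of
    (selected TPM sum) / (total transcriptome TPM).  Returns the first
    threshold whose score lies in ``[lo_frac, hi_frac]``, with its selection.
    """
    lo_frac, hi_frac = window
    if not 0.0 < lo_frac < hi_frac < 1.0:
        raise ValueError("window must satisfy 0 < lo < hi < 1")
    ranked = _ranked_candidates(table)
    totals = table.tpm.sum(axis=0)  # per-tissue transcriptome TPM
    if (totals <= 0).any():
        raise SelectionError("a tissue has zero total TPM")
    thresholds = np.unique(ranked["records"].to_numpy())[::-1]
    nearest = (None, np.inf)
    for thr in thresholds:
        sel = ranked.index[ranked["records"] >= thr]
        share = float((table.tpm.loc[sel].sum(axis=0) / totals).mean())
        if lo_frac <= share <= hi_frac:
            return list(sel), float(thr)
        gap = max(lo_frac - share, share - hi_frac)
        if gap < nearest[1]:
            nearest = (share, gap)
    raise SelectionError(
        f"no record threshold puts the selected share inside "
        f"[{lo_frac}, {hi_frac}]; nearest achievable share was {nearest[0]:.4g}")


def load_correlation(table: TargetTable, gene_set, *,
                     method: str = "pearson") -> tuple[float, pd.Series]:
    """Correlation of factor expression with summed target expression.

    Per tissue, load = sum of TPM over ``gene_set``; the statistic is the
    Pearson (default) or Spearman correlation of log1p(factor TPM) against
    log1p(load) across tissues.  Returns (coefficient, per-tissue load).
    """
    genes = list(gene_set)
    if len(genes) == 0:
        raise ValueError("gene_set is empty")
    if table.tpm.shape[1] < 3:
        raise ValueError("need >= 3 tissues")
    missing = set(genes) - set(table.tpm.index)
    if missing:
        raise KeyError(f"genes not in TPM matrix: {sorted(missing)[:5]}")
    load = table.tpm.loc[genes].sum(axis=0)
    factor = table.tpm.loc[table.factor_gene]
    x = np.log1p(factor.to_numpy(dtype=float))
    y = np.log1p(load.to_numpy(dtype=float))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant factor or load vector: correlation undefined")
    if method == "pearson":
        rho = stats.pearsonr(x, y).statistic
    elif method == "spearman":
        rho = stats.spearmanr(x, y).statistic
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(rho), load


def permutation_null(table: TargetTable, gene_set, *, n_perm: int = 10_000,
                     seed: int = 0, method: str = "pearson") -> np.ndarray:
    """Null distribution of the load correlation under tissue permutation.

    Shuffles the factor vector across tissues, leaving the load vector
    fixed; returns the permuted coefficients.
    """
    _, load = load_correlation(table, gene_set, method=method)
    rng = np.random.default_rng(seed)
    x = np.log1p(table.tpm.loc[table.factor_gene].to_numpy(dtype=float))
    y = np.log1p(load.to_numpy(dtype=float))
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    ys = (y - y.mean()) / y.std()
    out = np.empty(n_perm)
    for i in range(n_perm):
        xp = rng.permutation(x)
        xs = (xp - xp.mean()) / xp.std()
        out[i] = float(np.mean(xs * ys))
    return out
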