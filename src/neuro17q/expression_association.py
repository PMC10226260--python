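"""Rank-correlation machinery for expression signatures and motif scanning.

Covers four analyses used when relating an RNA-binding protein (anchor,
e.g. IGF2BP1) to transcription factors in tumor expression data:

* Spearman correlation with tie correction (thin wrapper over scipy);
* correlation-of-correlations: similarity of two genes' genome-wide
  co-expression signatures, the statistic behind anchor-vs-TF signature
  comparisons (e.g. IGF2BP1 vs MYCN rho ~ 0.93 in tumor cohorts);
* knockdown log-fold-change concordance between two perturbations;
* adrenergic-vs-mesenchymal (ADRN/MES) signature scoring as a difference
  of mean per-gene z-scores;
* E-box motif (CANNTG) scanning; the motif is its own reverse complement,
  so scanning one strand finds all double-stranded occurrences.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)


class AssociationError(ValueError):
    pass


@dataclass
class CorrelationProfile:
    """Genome-wide Spearman coefficients of one anchor gene."""

    anchor: str
    rho: pd.Series       # per-gene coefficient, anchor excluded
    n_samples: int


def spearman(x, y) -> float:
    """Tie-corrected Spearman rho; NaN (with warning) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AssociationError("inputs must be equal-length 1-d vectors")
    if x.size < 3:
        raise AssociationError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant vector: Spearman rho undefined")
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def _expression_filter(expr: ExpressionMatrix, min_sum: float) -> pd.DataFrame:
    """Drop genes whose summed (linear-scale) expression is below min_sum."""
    vals = expr.values
    linear = np.exp2(vals) if expr.is_log_scale else vals
    keep = linear.sum(axis=1) >= min_sum
    dropped = int((~keep).sum())
    if dropped:
        logger.info("expression filter dropped %d genes (sum < %g)",
                    dropped, min_sum)
    return vals.loc[keep]


def correlation_profile(expr: ExpressionMatrix, anchor: str,
                        min_sum: float | None = 1.0) -> CorrelationProfile:
    """Spearman coefficients of one gene against all other genes."""
    if anchor not in expr.values.index:
        raise AssociationError(f"anchor gene {anchor!r} not in matrix")
    vals = _expression_filter(expr, min_sum) if min_sum is not None \
        else expr.values
    if anchor not in vals.index:  # anchor itself must survive filtering
        vals = pd.concat([vals, expr.values.loc[[anchor]]])
    variances = vals.var(axis=1)
    constant = variances == 0
    if constant.any():
        logger.info("dropping %d zero-variance genes", int(constant.sum()))
        vals = vals.loc[~constant]
    anchor_vec = expr.values.loc[anchor].to_numpy(dtype=float)
    others = vals.drop(index=anchor, errors="ignore")
    # rank once, then correlate against the anchor's ranks (vectorized)
    ranked = others.rank(axis=1).to_numpy(dtype=float)
    ra = stats.rankdata(anchor_vec)
    ranked = (ranked - ranked.mean(axis=1, keepdims=True))
    ra = ra - ra.mean()
    num = ranked @ ra
    den = np.sqrt((ranked ** 2).sum(axis=1) * (ra ** 2).sum())
    rho = pd.Series(num / den, index=others.index, name=anchor)
    return CorrelationProfile(anchor, rho, n_samples=vals.shape[1])


def correlation_of_correlations(expr: ExpressionMatrix, anchor: str,
                                tf: str, min_sum: float | None = 1.0,
                                exclude_self: bool = True
                                ) -> tuple[float, CorrelationProfile,
                                           CorrelationProfile]:
    """Spearman correlation between two genes' co-expression signatures.

    Computes genome-wide Spearman profiles for ``anchor`` and ``tf`` and
    correlates them over the shared gene universe. With ``exclude_self``
    (default) both the anchor and the TF are excluded from that universe so
    their trivial self-correlations of 1 cannot inflate the result.
    """
    for g in (anchor, tf):
        if g not in expr.values.index:
            raise AssociationError(f"gene {g!r} not in matrix")
    prof_a = correlation_profile(expr, anchor, min_sum=min_sum)
    prof_t = correlation_profile(expr, tf, min_sum=min_sum)
    shared = prof_a.rho.index.intersection(prof_t.rho.index)
    if exclude_self:
        shared = shared.difference([anchor, tf])
    rho = spearman(prof_a.rho.loc[shared], prof_t.rho.loc[shared])
    return rho, prof_a, prof_t


def knockdown_concordance(logfc_a: pd.Series, logfc_b: pd.Series
                          ) -> tuple[float, int]:
    """Spearman concordance of two knockdown log-fold-change profiles.

    Returns (rho, n shared genes)."""
    shared = logfc_a.index.intersection(logfc_b.index)
    if len(shared) < 3:
        raise AssociationError(
            f"only {len(shared)} shared genes; need >= 3")
    return spearman(logfc_a.loc[shared], logfc_b.loc[shared]), len(shared)


def signature_score_ratio(expr: ExpressionMatrix, set_a, set_b
                          ) -> pd.Series:
    """Per-sample ADRN-minus-MES style signature score.

    Score = mean per-gene z-score over ``set_a`` minus mean over ``set_b``,
    z-scoring each gene across samples on the log2 scale (linear-scale input
    is log2(x+1)-transformed first). Missing genes are logged; a set with no
    genes present is an error.
    """
    vals = expr.values if expr.is_log_scale else np.log2(expr.values + 1.0)
    scores = {}
    for name, gene_set in (("a", set_a), ("b", set_b)):
        present = [g for g in gene_set if g in vals.index]
        missing = len(list(gene_set)) - len(present)
        if not present:
            raise AssociationError(f"no genes of set_{name} in the matrix")
        if missing:
            logger.warning("%d genes of set_%s absent from matrix",
                           missing, name)
        sub = vals.loc[present]
        sd = sub.std(axis=1, ddof=0)
        sd = sd.replace(0.0, np.nan)  # constant genes contribute nothing
        z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
        scores[name] = z.mean(axis=0, skipna=True)
    return (scores["a"] - scores["b"]).rename("adrn_minus_mes")


_EBOX = re.compile(r"(?=CA..TG)")
_VALID = re.compile(r"[ACGTN]*")


def ebox_scan(sequence: str) -> list[int]:
    """0-based start positions of all (possibly overlapping) E-box motifs.

    The E-box CANNTG is self-reverse-complementary, so single-strand
    scanning covers both strands. N in the sequence matches nothing (an
    ambiguous base never asserts a motif).
    """
    seq = sequence.upper()
    bad = _VALID.match(seq).end()
    if bad != len(seq):
        raise AssociationError(
            f"invalid nucleotide {seq[bad]!r} at offset {bad}")
    hits = []
    for m in _EBOX.finditer(seq):
        window = seq[m.start() + 2: m.start() + 4]
        if "N" not in window:  # CA/TG already literal; reject ambiguous core
            hits.append(m.start())
    return hits
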