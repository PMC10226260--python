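"""Multi-evidence oncogene prioritization over candidate 17q genes.

Assembles a genes x criteria evidence matrix — dependency scores, tumor
fold changes by clinical subgroup, hazard ratios, co-expression with the
driver genes, knockdown responses, promoter ChIP and transcript CLIP
scores — and produces heatmap-ready scaled rows plus a composite ranking.

Each criterion declares a scaling mode (unit [0, 1] for occupancy-style
scores such as ChIP/CLIP; symmetric [-1, 1] for everything else) and an
orientation stating whether larger values argue for oncogenicity. After
scaling, lower-is-oncogenic criteria are negated so that larger always
means more oncogenic, and the composite score is the mean of the oriented
scaled values over a gene's non-missing criteria. Missing evidence is
excluded from the mean rather than scored as zero: absence of a CLIP peak
table entry means "no data", not "no binding".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HIGHER_IS_ONCOGENIC = "higher_is_oncogenic"
LOWER_IS_ONCOGENIC = "lower_is_oncogenic"
UNIT = "unit"
SYMMETRIC = "symmetric"


class RankingError(ValueError):
    pass


@dataclass(frozen=True)
class Criterion:
    """One evidence class: its orientation and row-scaling mode."""

    name: str
    orientation: str = HIGHER_IS_ONCOGENIC
    scaling: str = SYMMETRIC

    def __post_init__(self):
        if self.orientation not in (HIGHER_IS_ONCOGENIC, LOWER_IS_ONCOGENIC):
            raise RankingError(f"bad orientation {self.orientation!r}")
        if self.scaling not in (UNIT, SYMMETRIC):
            raise RankingError(f"bad scaling {self.scaling!r}")


@dataclass
class EvidenceMatrix:
    """Genes x criteria evidence values with per-criterion metadata."""

    values: pd.DataFrame            # genes x criterion-name columns
    criteria: list[Criterion]

    def __post_init__(self):
        names = [c.name for c in self.criteria]
        if len(set(names)) != len(names):
            raise RankingError("duplicate criterion names")
        missing = [n for n in names if n not in self.values.columns]
        if missing:
            raise RankingError(f"criteria without a value column: {missing}")
        for c in self.criteria:
            if self.values[c.name].isna().all():
                raise RankingError(f"criterion {c.name!r} has no data")


def scale_row(values, scaling: str = UNIT) -> np.ndarray:
    """Min-max scale one criterion's values to [0, 1] or [-1, 1].

    NaN passes through as missing; a constant row maps to all zeros (there
    is no information to spread, and zero is neutral in both modes).
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if not finite.any():
        raise RankingError("all values missing")
    lo, hi = v[finite].min(), v[finite].max()
    out = np.full_like(v, np.nan)
    if hi == lo:
        out[finite] = 0.0
        return out
    unit = (v[finite] - lo) / (hi - lo)
    out[finite] = unit if scaling == UNIT else 2.0 * unit - 1.0
    return out


def scaled_matrix(matrix: EvidenceMatrix) -> pd.DataFrame:
    """Heatmap-ready frame: every criterion scaled per its declared mode."""
    out = {}
    for c in matrix.criteria:
        out[c.name] = scale_row(matrix.values[c.name], c.scaling)
    return pd.DataFrame(out, index=matrix.values.index)


def composite_rank(matrix: EvidenceMatrix) -> pd.DataFrame:
    """Composite oncogene ranking across all evidence classes.

    Scales each criterion, orients it so larger = more oncogenic, and
    averages over non-missing criteria per gene. Returns a frame sorted by
    descending composite score (ties broken by gene id) with the per-gene
    criterion coverage. Genes with no evidence at all are excluded.
    """
    scaled = scaled_matrix(matrix)
    for c in matrix.criteria:
        if c.orientation == LOWER_IS_ONCOGENIC:
            scaled[c.name] = -scaled[c.name]
    coverage = scaled.notna().sum(axis=1)
    composite = scaled.mean(axis=1, skipna=True)
    keep = coverage > 0
    if (~keep).any():
        import logging
        logging.getLogger(__name__).warning(
            "%d genes with no non-missing criteria excluded",
            int((~keep).sum()))
    out = pd.DataFrame({"composite": composite[keep],
                        "n_criteria": coverage[keep]})
    out = out.sort_values(["composite", "n_criteria"],
                          ascending=[False, False])
    # stable lexicographic tie-break on gene id
    out = out.iloc[np.lexsort((out.index.to_numpy(), -out["composite"]))]
    out["rank"] = np.arange(1, len(out) + 1)
    return out
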