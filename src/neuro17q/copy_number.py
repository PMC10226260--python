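"""Copy-number state calling and the chromosome-17q balance classifier.

Tumors with extra 17q copies fall into two clinically distinct classes:
*balanced* gains (whole chromosome 17, p and q rise together) and
*unbalanced* gains, where only the distal 17q segment — from the IGF2BP1
locus to the q terminus ("IMP1-ter") — exceeds the 17p level. The balance
value

    bv = -median(IMP1-ter) + median(17p) + 0.2

computed on per-bin log2 ratios separates the two: bv <= 0 calls the sample
unbalanced, bv > 0 balanced. Gain/loss states use the conventional shallow
whole-genome-sequencing log2-ratio thresholds of +0.3 and -0.4; MYCN
amplification (MNA) is called when the copy number at the MYCN locus
exceeds 4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Input violated a copy-number invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a chromosome."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError(
                f"interval end ({self.end}) <= start ({self.start})")

    def contains(self, position: float) -> bool:
        return self.start <= position < self.end


@dataclass(frozen=True)
class Thresholds:
    """Calling thresholds on the log2-ratio / copy-number scale."""

    loss_log2: float = -0.4
    gain_log2: float = 0.3
    mna_cn: float = 4.0
    balance_offset: float = 0.2

    def __post_init__(self):
        if not self.loss_log2 < 0 < self.gain_log2:
            raise ValidationError("need loss_log2 < 0 < gain_log2")


@dataclass
class CNProfile:
    """One sample's ordered genomic bins with log2 ratios and optional CN.

    ``bins`` columns: chromosome, start, end, log2_ratio, cn (NaN allowed in
    cn only). Bins must be sorted and non-overlapping within a chromosome.
    """

    sample_id: str
    bins: pd.DataFrame

    def __post_init__(self):
        required = ["chromosome", "start", "end", "log2_ratio"]
        missing = [c for c in required if c not in self.bins.columns]
        if missing:
            raise ValidationError(f"{self.sample_id}: bins missing {missing}")
        if "cn" not in self.bins.columns:
            self.bins = self.bins.assign(cn=np.nan)
        if not np.isfinite(self.bins["log2_ratio"]).all():
            raise ValidationError(f"{self.sample_id}: non-finite log2 ratio")
        self.bins = (self.bins.sort_values(["chromosome", "start"], kind="stable")
                     .reset_index(drop=True))
        for chrom, grp in self.bins.groupby("chromosome", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if (ends <= starts).any():
                raise ValidationError(f"{self.sample_id}: empty bin on {chrom}")
            if (starts[1:] < ends[:-1]).any():
                raise ValidationError(
                    f"{self.sample_id}: overlapping bins on {chrom}")

    def overlapping(self, region: GenomicInterval,
                    mode: str = "midpoint") -> pd.DataFrame:
        """Bins selected by ``region``.

        ``midpoint`` (default, used for arm-scale medians): bins whose
        midpoint falls inside the region. ``interval``: any overlap — the
        right rule for locus-scale regions smaller than a bin.
        """
        b = self.bins
        on_chrom = b["chromosome"] == region.chromosome
        if mode == "midpoint":
            mid = (b["start"] + b["end"]) / 2.0
            mask = on_chrom & (mid >= region.start) & (mid < region.end)
        elif mode == "interval":
            mask = on_chrom & (b["start"] < region.end) & \
                (b["end"] > region.start)
        else:
            raise ValidationError(f"unknown overlap mode {mode!r}")
        return b[mask]


@dataclass(frozen=True)
class BalanceCall:
    """Result of the 17q balance classification for one sample."""

    sample_id: str
    median_17p: float
    median_imp1_ter: float
    bv: float
    label: str  # "balanced" | "unbalanced"


def classify_log2(value: float, thresholds: Thresholds = Thresholds()) -> str:
    """Call gain / loss / neutral from a log2 ratio.

    Gain iff value >= gain threshold, loss iff value <= loss threshold
    (both inclusive), neutral otherwise.
    """
    if not math.isfinite(value):
        raise ValidationError(f"non-finite log2 ratio: {value}")
    if value >= thresholds.gain_log2:
        return "gain"
    if value <= thresholds.loss_log2:
        return "loss"
    return "neutral"


def region_median(profile: CNProfile, region: GenomicInterval,
                  column: str = "log2_ratio") -> float:
    """Unweighted median of per-bin values over bins with midpoint in region."""
    hits = profile.overlapping(region)
    if hits.empty:
        raise ValidationError(
            f"{profile.sample_id}: no bin overlaps "
            f"{region.chromosome}:{region.start}-{region.end}")
    values = hits[column]
    if values.isna().any():
        raise ValidationError(
            f"{profile.sample_id}: missing {column} in region")
    return float(values.median())


def balance_call(profile: CNProfile, region_17p: GenomicInterval,
                 region_imp1_ter: GenomicInterval,
                 thresholds: Thresholds = Thresholds()) -> BalanceCall:
    """Classify a sample as 17q balanced or unbalanced.

    bv = -median(IMP1-ter) + median(17p) + offset; the boundary bv = 0 is
    assigned to *unbalanced*.
    """
    m17p = region_median(profile, region_17p)
    mimp = region_median(profile, region_imp1_ter)
    bv = -mimp + m17p + thresholds.balance_offset
    label = "unbalanced" if bv <= 0 else "balanced"
    return BalanceCall(profile.sample_id, m17p, mimp, bv, label)


def mna_call(profile: CNProfile, mycn_region: GenomicInterval,
             thresholds: Thresholds = Thresholds()) -> tuple[bool, float]:
    """MYCN-amplification flag and the copy number at the locus.

    Uses the integer-CN column when present, otherwise derives CN from the
    log2 ratio as 2 * 2**log2. The flag is strict: CN > 4 at defaults.
    """
    hits = profile.overlapping(mycn_region, mode="interval")
    if hits.empty:
        raise ValidationError(
            f"{profile.sample_id}: MYCN region not covered by any bin")
    cn = hits["cn"]
    if cn.isna().any():
        cn = 2.0 * np.exp2(hits["log2_ratio"])
    cn_at_locus = float(cn.median())
    return cn_at_locus > thresholds.mna_cn, cn_at_locus


def _check_common_grid(profiles: Sequence[CNProfile]) -> pd.DataFrame:
    ref = profiles[0].bins[["chromosome", "start", "end"]]
    for p in profiles[1:]:
        grid = p.bins[["chromosome", "start", "end"]]
        if len(grid) != len(ref) or not grid.reset_index(drop=True).equals(
                ref.reset_index(drop=True)):
            merged = ref.merge(grid, how="outer", indicator=True)
            off = merged[merged["_merge"] != "both"]
            where = (f"{off.iloc[0].chromosome}:{off.iloc[0].start}"
                     if len(off) else "bin count")
            raise ValidationError(
                f"bin grid of {p.sample_id} differs from "
                f"{profiles[0].sample_id} (first mismatch: {where})")
    return ref.copy()


def cohort_aberration_frequencies(profiles: Sequence[CNProfile],
                                  thresholds: Thresholds = Thresholds()
                                  ) -> pd.DataFrame:
    """Per-bin gain and loss percentages across a cohort.

    All profiles must share an identical bin grid. Returns a frame with
    chromosome, start, end, gain_pct, loss_pct.
    """
    if not profiles:
        raise ValidationError("empty cohort")
    grid = _check_common_grid(profiles)
    ratios = np.vstack([p.bins["log2_ratio"].to_numpy() for p in profiles])
    n = len(profiles)
    grid["gain_pct"] = 100.0 * (ratios >= thresholds.gain_log2).sum(axis=0) / n
    grid["loss_pct"] = 100.0 * (ratios <= thresholds.loss_log2).sum(axis=0) / n
    return grid


def region_state(profile: CNProfile, region: GenomicInterval,
                 thresholds: Thresholds = Thresholds()) -> str:
    """Gain/loss/neutral call for a whole region via its median log2 ratio.

    This is how cohort-level region summaries (e.g. "7 gain", "11q loss"
    frequencies) are tabulated: a sample counts as gained/lost in a region
    iff the region median crosses the respective threshold.
    """
    return classify_log2(region_median(profile, region), thresholds)


def cohort_region_frequencies(profiles: Sequence[CNProfile],
                              regions: dict[str, GenomicInterval],
                              thresholds: Thresholds = Thresholds()
                              ) -> pd.DataFrame:
    """Fraction of samples with each region called gain / loss."""
    rows = []
    for name, region in regions.items():
        states = [region_state(p, region, thresholds) for p in profiles]
        n = len(states)
        rows.append({
            "region": name,
            "gain_pct": 100.0 * sum(s == "gain" for s in states) / n,
            "loss_pct": 100.0 * sum(s == "loss" for s in states) / n,
        })
    return pd.DataFrame(rows)
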