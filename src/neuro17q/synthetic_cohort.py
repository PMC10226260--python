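"""Seeded synthetic neuroblastoma cohorts and dependency screens.

Generates data with known ground truth so every downstream stage —
balance-value classification, MNA calling, aberration frequencies, the
essentiality screen, signature correlation and survival — can be tested
end to end without external accessions.

The emulated cohort mirrors the reference study conditions: ~100 tumors in
which 17q gain is the most frequent aberration (prevalence 0.79), 0.35 of
samples carry an *unbalanced* gain restricted to the IGF2BP1-to-q-terminus
segment, and 0.17 are MYCN-amplified. Copy-number bins carry Gaussian
log2-ratio noise around the planted event means (+log2(3/2) ~ 0.58 for one
extra copy on a diploid background). Expression for the two driver genes
and a co-regulated driver module loads on a shared latent Gaussian factor
achieving a target pairwise correlation. Survival is exponential with the
hazard multiplied for high-risk (MNA or unbalanced) samples and uniform
censoring of a configurable fraction.

The dependency screen emulates a pan-cancer CRISPR panel of 13 MNA vs 607
other cell lines: background genes score ~ Normal(0, sd) in both groups,
planted MNA-essential genes shift by a negative effect in the MNA group
only, and a held-out common-essential set scores strongly negative in both.

All randomness flows from a single seed split into per-component child
streams, so adding one component never perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .copy_number import CNProfile, GenomicInterval
from .essentiality_screen import DependencyScreen
from .io_formats import CohortMeta, ExpressionMatrix, GeneAnnotation

GAIN_LOG2 = math.log2(3 / 2)   # one extra copy on a diploid background
LOSS_LOG2 = math.log2(1 / 2)

# toy genome: three chromosomes suffice to exercise every region-dependent
# rule (17p vs IMP1-ter on chr17, MYCN on 2p, chr1 as neutral background)
DEFAULT_CHROM_LENGTHS = {"chr1": 248_000_000, "chr2": 242_000_000,
                         "chr17": 83_000_000}
DEFAULT_CENTROMERES = {"chr1": 123_400_000, "chr2": 93_900_000,
                       "chr17": 25_100_000}
IGF2BP1_LOCUS = GenomicInterval("chr17", 48_900_000, 49_000_000)
MYCN_LOCUS = GenomicInterval("chr2", 16_080_000, 16_090_000)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort and dependency screen."""

    seed: int = 0
    # cohort
    n_samples: int = 100
    n_bins_per_chrom: int = 40
    chrom_lengths: dict = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    centromeres: dict = field(
        default_factory=lambda: dict(DEFAULT_CENTROMERES))
    prevalence_17q_gain: float = 0.79
    prevalence_unbalanced: float = 0.35
    prevalence_mna: float = 0.17
    cn_noise_sd: float = 0.1
    # expression
    n_genes: int = 1000
    driver_corr: float = 0.8
    driver_module_size: int = 30
    # dependency screen
    n_cell_lines_group_a: int = 13
    n_cell_lines_group_b: int = 607
    n_planted_essential: int = 40
    n_common_essential: int = 50
    dependency_effect: float = -0.5
    dependency_noise_sd: float = 0.15
    unexpressed_fraction: float = 0.1
    # survival
    hazard_ratio_highrisk: float = 8.0
    baseline_median_days: float = 3650.0
    censor_rate: float = 0.6

    def __post_init__(self):
        for name in ("n_samples", "n_bins_per_chrom", "n_genes",
                     "n_cell_lines_group_a", "n_cell_lines_group_b",
                     "n_planted_essential", "n_common_essential",
                     "driver_module_size"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("prevalence_17q_gain", "prevalence_unbalanced",
                     "prevalence_mna", "censor_rate", "unexpressed_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.prevalence_unbalanced > self.prevalence_17q_gain:
            raise ConfigError(
                "unbalanced gains are a subset of 17q gains: "
                "prevalence_unbalanced must not exceed prevalence_17q_gain")
        if not -1 <= self.driver_corr <= 1:
            raise ConfigError("driver_corr must lie in [-1, 1]")
        if self.hazard_ratio_highrisk <= 0:
            raise ConfigError("hazard_ratio_highrisk must be positive")
        if self.n_planted_essential > self.n_genes:
            raise ConfigError("n_planted_essential exceeds n_genes")


@dataclass
class GroundTruth:
    """Planted labels the generators guarantee."""

    samples: pd.DataFrame | None = None   # sample_id, cn17_state,
    # balance_label, mna, risk_group
    planted_essential: list[str] = field(default_factory=list)
    common_essential: list[str] = field(default_factory=list)


def _rng(config: SimulationConfig, component: str) -> np.random.Generator:
    """Child RNG for a named component of the simulation."""
    key = int.from_bytes(component.encode(), "big") % (2 ** 31)
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(key,)))


def toy_regions(config: SimulationConfig) -> dict[str, GenomicInterval]:
    """The analysis regions of the toy genome."""
    len17 = config.chrom_lengths["chr17"]
    cen17 = config.centromeres["chr17"]
    return {
        "17p": GenomicInterval("chr17", 0, cen17),
        "17q": GenomicInterval("chr17", cen17, len17),
        "imp1_ter": GenomicInterval("chr17", IGF2BP1_LOCUS.start, len17),
        "mycn": MYCN_LOCUS,
    }


def _bin_grid(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for chrom, length in config.chrom_lengths.items():
        edges = np.linspace(0, length, config.n_bins_per_chrom + 1,
                            dtype=np.int64)
        for s, e in zip(edges[:-1], edges[1:]):
            rows.append((chrom, int(s), int(e)))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end"])


def _simulate_annotation(config: SimulationConfig,
                         rng: np.random.Generator) -> GeneAnnotation:
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    records = [("IGF2BP1", "IGF2BP1", "chr17", IGF2BP1_LOCUS.start,
                IGF2BP1_LOCUS.end, "+", "protein_coding"),
               ("MYCN", "MYCN", "chr2", MYCN_LOCUS.start, MYCN_LOCUS.end,
                "+", "protein_coding")]
    n_bg = config.n_genes - len(records)
    picks = rng.choice(len(chroms), size=n_bg, p=probs)
    for i in range(n_bg):
        chrom = chroms[picks[i]]
        start = int(rng.integers(0, config.chrom_lengths[chrom] - 10_000))
        biotype = "protein_coding" if rng.random() > 0.05 else "lncRNA"
        gid = f"GENE{i + 1:05d}"
        records.append((gid, gid, chrom, start, start + 10_000,
                        rng.choice(["+", "-"]), biotype))
    df = pd.DataFrame(records, columns=["gene_id", "symbol", "chromosome",
                                        "start", "end", "strand", "biotype"])
    cen = config.centromeres
    df["arm"] = ["p" if s < cen.get(c, np.inf) else "q"
                 for s, c in zip(df["start"], df["chromosome"])]
    return GeneAnnotation(df)


def _simulate_cn(config: SimulationConfig, truth: pd.DataFrame,
                 rng: np.random.Generator) -> list[CNProfile]:
    grid = _bin_grid(config)
    mid = (grid["start"] + grid["end"]) / 2.0
    regions = toy_regions(config)
    on17 = (grid["chromosome"] == "chr17").to_numpy()
    in_imp1 = on17 & (mid >= regions["imp1_ter"].start).to_numpy()
    # the MYCN locus falls in exactly one bin of the chr2 grid
    mycn_bin = np.zeros(len(grid), bool)
    chr2 = grid[grid["chromosome"] == "chr2"]
    idx = chr2.index[(chr2["start"] <= MYCN_LOCUS.start) &
                     (MYCN_LOCUS.start < chr2["end"])][0]
    mycn_bin[idx] = True

    profiles = []
    for row in truth.itertuples():
        mean = np.zeros(len(grid))
        if row.cn17_state == "whole_gain":
            mean[on17] = GAIN_LOG2
        elif row.cn17_state == "q_arm_gain":
            mean[in_imp1] = GAIN_LOG2
        log2 = rng.normal(mean, config.cn_noise_sd)
        cn = np.full(len(grid), np.nan)
        if row.mna:
            amp_cn = float(rng.integers(8, 31))
            cn[mycn_bin] = amp_cn
            log2[mycn_bin] = math.log2(amp_cn / 2.0) + \
                rng.normal(0, config.cn_noise_sd)
        else:
            cn[mycn_bin] = 2.0
        bins = grid.assign(log2_ratio=log2, cn=cn)
        profiles.append(CNProfile(sample_id=row.sample_id, bins=bins))
    return profiles


def _simulate_expression(config: SimulationConfig, truth: pd.DataFrame,
                         annotation: GeneAnnotation,
                         rng: np.random.Generator) -> ExpressionMatrix:
    genes = list(annotation.df["gene_id"])
    n_s = len(truth)
    base = rng.uniform(2.0, 10.0, size=len(genes))
    values = base[:, None] + rng.normal(0.0, 1.0, size=(len(genes), n_s))
    df = pd.DataFrame(values, index=genes, columns=truth["sample_id"])
    # drivers and module share a latent factor; loading sqrt(rho) gives
    # pairwise correlation rho between any two loaded genes
    rho = config.driver_corr
    lam = math.sqrt(abs(rho))
    factor = rng.standard_normal(n_s)
    module = [g for g in genes if g not in ("IGF2BP1", "MYCN")]
    module = module[: config.driver_module_size]
    for g in ["IGF2BP1", "MYCN"] + module:
        sign = -1.0 if (rho < 0 and g == "MYCN") else 1.0
        noise = rng.standard_normal(n_s)
        df.loc[g] = base[genes.index(g)] + sign * lam * factor + \
            math.sqrt(1 - abs(rho)) * noise
    return ExpressionMatrix(values=df, scale="log2TPM")


def _simulate_survival(config: SimulationConfig, truth: pd.DataFrame,
                       rng: np.random.Generator) -> CohortMeta:
    lam0 = math.log(2) / config.baseline_median_days
    hr = np.where(truth["risk_group"] == "high",
                  config.hazard_ratio_highrisk, 1.0)
    event_time = rng.exponential(1.0 / (lam0 * hr))
    censored = rng.random(len(truth)) < config.censor_rate
    time = np.where(censored, rng.uniform(0, event_time), event_time)
    meta = pd.DataFrame({
        "sample_id": truth["sample_id"],
        "inss_stage": np.where(truth["risk_group"] == "high", "4", "1"),
        "mna_status": truth["mna"].astype(int),
        "balance_17q": (truth["balance_label"] == "unbalanced").astype(int),
        "os_time": np.round(time, 1),
        "os_event": (~censored).astype(int),
    })
    return CohortMeta(meta)


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[GeneAnnotation, list[CNProfile],
                               ExpressionMatrix, CohortMeta, GroundTruth]:
    """Generate a full synthetic tumor cohort with known ground truth.

    Returns gene annotation, per-sample copy-number profiles, an expression
    matrix (log2 TPM), clinical metadata with survival, and the planted
    labels. Deterministic for a fixed config (seed included).
    """
    rng_labels = _rng(config, "labels")
    n = config.n_samples
    u = rng_labels.random(n)
    cn17 = np.where(u < config.prevalence_unbalanced, "q_arm_gain",
                    np.where(u < config.prevalence_17q_gain,
                             "whole_gain", "none"))
    mna = rng_labels.random(n) < config.prevalence_mna
    balance = np.where(cn17 == "q_arm_gain", "unbalanced", "balanced")
    truth_df = pd.DataFrame({
        "sample_id": [f"NB{i + 1:04d}" for i in range(n)],
        "cn17_state": cn17,
        "balance_label": balance,
        "mna": mna,
        "risk_group": np.where(mna | (balance == "unbalanced"),
                               "high", "low"),
    })
    annotation = _simulate_annotation(config, _rng(config, "annotation"))
    profiles = _simulate_cn(config, truth_df, _rng(config, "cn"))
    expr = _simulate_expression(config, truth_df, annotation,
                                _rng(config, "expression"))
    meta = _simulate_survival(config, truth_df, _rng(config, "survival"))
    return annotation, profiles, expr, meta, GroundTruth(samples=truth_df)


def simulate_dependency_screen(config: SimulationConfig
                               ) -> tuple[DependencyScreen, GroundTruth]:
    """Generate a pan-cancer style dependency screen with planted effects.

    Planted genes shift by ``dependency_effect`` in the MNA group only;
    common-essential genes score around -1 in both groups; an
    ``unexpressed_fraction`` of background genes sits near 0 log2 TPM to
    exercise the expression filter. Planted and common-essential genes are
    always expressed.
    """
    rng = _rng(config, "screen")
    n_g = config.n_genes
    genes = [f"GENE{i + 1:05d}" for i in range(n_g)]
    order = rng.permutation(n_g)
    planted = [genes[i] for i in order[: config.n_planted_essential]]
    common = [genes[i] for i in
              order[config.n_planted_essential:
                    config.n_planted_essential + config.n_common_essential]]
    n_a, n_b = config.n_cell_lines_group_a, config.n_cell_lines_group_b
    lines = [f"MNA{i + 1:03d}" for i in range(n_a)] + \
        [f"OTH{i + 1:03d}" for i in range(n_b)]
    group = pd.Series(["MNA"] * n_a + ["other"] * n_b, index=lines)

    dep = rng.normal(0.0, config.dependency_noise_sd, size=(n_g, n_a + n_b))
    dep = pd.DataFrame(dep, index=genes, columns=lines)
    dep.loc[planted, dep.columns[:n_a]] += config.dependency_effect
    dep.loc[common, :] += -1.0

    expressed = rng.random(n_g) >= config.unexpressed_fraction
    expr_mean = np.where(expressed, 4.0, 0.0)
    expr = rng.normal(expr_mean[:, None],
                      np.where(expressed, 1.0, 0.2)[:, None],
                      size=(n_g, n_a + n_b))
    expr = pd.DataFrame(np.clip(expr, 0.0, None), index=genes, columns=lines)
    forced = list(set(planted) | set(common))
    expr.loc[forced] = np.clip(
        rng.normal(4.0, 1.0, size=(len(forced), n_a + n_b)), 2.5, None)

    screen = DependencyScreen(dep=dep, expr=expr, group=group,
                              common_essential=frozenset(common))
    truth = GroundTruth(planted_essential=planted, common_essential=common)
    return screen, truth
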