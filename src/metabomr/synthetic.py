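"""Synthetic two-sample GWAS summary statistics with known truth.

The generator emulates the structure the estimators assume: each
instrument j has a true exposure effect xi_j, an optional direct
(pleiotropic) outcome effect alpha_j, and observed effects

    beta_X_j ~ N(xi_j,               se_X_j²)
    beta_Y_j ~ N(theta*xi_j + alpha_j, se_Y_j²)

with SEs following the standard 1/sqrt(2*maf*(1-maf)*n) approximation
for a standardized trait. True effects are drawn half-normal,
xi_j = |N(0, effect_sd²)| — instruments oriented to the trait-raising
allele — so that a constant directional alpha actually shifts the IVW
estimand rather than averaging out over signs. Null SNPs (xi = alpha =
0) and a block-diagonal LD structure exercise instrument selection and
clumping. Everything is a deterministic function of (config, seed).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, EstimationError
from .instruments import InstrumentSet, LDMatrix
from .sumstats_io import SummaryStatRecord
from . import estimators as est

PLEIOTROPY_MODES = ("none", "balanced", "directional")

#: non-palindromic allele pairs (effect, other); palindromic pairs A/T and
#: C/G are only drawn when a config explicitly asks for them.
_NON_PALINDROMIC = (
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
)
_PALINDROMIC = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))

_SPACING_BP = 100_000  # one synthetic chromosome, fixed 100 kb spacing


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for one synthetic exposure-outcome dataset.

    Defaults mirror the study the pipeline targets: a metabolite GWAS
    of 86,507 individuals against a cancer GWAS of 66,450
    (cases + controls), common variants (MAF 0.1-0.5), and instrument
    effects calibrated so the mean F-statistic sits around 60 —
    comfortably past the mean-F > 10 weak-instrument guard, as
    metabolite mQTLs typically are.
    """

    k_instruments: int = 30
    n_null_snps: int = 0
    theta: float = 0.0
    pleiotropy_mode: str = "none"
    mu_alpha: float = 0.0
    tau_alpha: float = 0.0
    pleiotropy_fraction: float = 1.0
    effect_sd: float = 0.042
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_exposure: int = 86_507
    n_outcome: int = 66_450
    ld_block_size: int = 1
    ld_within_r2: float = 0.0
    palindromic_alleles: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.k_instruments < 1:
            raise ConfigurationError("k_instruments must be >= 1")
        if self.n_null_snps < 0:
            raise ConfigurationError("n_null_snps must be >= 0")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ConfigurationError(
                f"pleiotropy_mode must be one of {PLEIOTROPY_MODES}"
            )
        if self.pleiotropy_mode == "balanced" and self.mu_alpha != 0:
            raise ConfigurationError("balanced pleiotropy requires mu_alpha = 0")
        if self.pleiotropy_mode == "none" and (self.tau_alpha != 0 or self.mu_alpha != 0):
            raise ConfigurationError("mode 'none' requires mu_alpha = tau_alpha = 0")
        if self.tau_alpha < 0:
            raise ConfigurationError("tau_alpha must be >= 0")
        if not (0.0 <= self.pleiotropy_fraction <= 1.0):
            raise ConfigurationError("pleiotropy_fraction must lie in [0,1]")
        if self.effect_sd <= 0:
            raise ConfigurationError("effect_sd must be > 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.n_exposure < 1 or self.n_outcome < 1:
            raise ConfigurationError("sample sizes must be positive")
        if self.ld_block_size < 1:
            raise ConfigurationError("ld_block_size must be >= 1")
        if not (0.0 <= self.ld_within_r2 < 1.0):
            raise ConfigurationError("ld_within_r2 must lie in [0,1)")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of a generated dataset, for parameter-recovery tests."""

    theta: float
    xi: tuple[float, ...]
    alpha: tuple[float, ...]
    instrument_ids: tuple[str, ...]
    seed: int


def derive_seed(base_seed: int, *labels) -> int:
    """Stable sub-stream seed from a base seed and labels (< 2**31)."""
    token = "|".join([str(base_seed), *map(str, labels)])
    return zlib.crc32(token.encode()) & 0x7FFFFFFF


def _gwas_se(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def simulate_sumstats(
    config: SimulationConfig,
) -> tuple[list[SummaryStatRecord], list[SummaryStatRecord], SimulationTruth]:
    """Generate matched exposure and outcome summary statistics.

    Instruments come first, then null SNPs, all on one synthetic
    chromosome at 100 kb spacing with shared alleles and frequencies
    across the two samples. P-values are two-sided normal.
    """
    rng = np.random.default_rng(config.seed)
    k, n_null = config.k_instruments, config.n_null_snps
    m = k + n_null
    maf = rng.uniform(*config.maf_range, size=m)
    se_x = _gwas_se(maf, config.n_exposure)
    se_y = _gwas_se(maf, config.n_outcome)

    xi = np.zeros(m)
    xi[:k] = np.abs(rng.normal(0.0, config.effect_sd, size=k))
    alpha = np.zeros(m)
    if config.pleiotropy_mode != "none":
        n_pleio = int(round(k * config.pleiotropy_fraction))
        which = rng.permutation(k)[:n_pleio]
        alpha[which] = rng.normal(config.mu_alpha, config.tau_alpha, size=n_pleio)

    beta_x = rng.normal(xi, se_x)
    beta_y = rng.normal(config.theta * xi + alpha, se_y)
    p_x = 2.0 * stats.norm.sf(np.abs(beta_x) / se_x)
    p_y = 2.0 * stats.norm.sf(np.abs(beta_y) / se_y)

    pairs = _NON_PALINDROMIC + (_PALINDROMIC if config.palindromic_alleles else ())
    allele_idx = rng.integers(0, len(pairs), size=m)

    ids = [f"rs{j + 1:06d}" for j in range(m)]
    exposure, outcome = [], []
    for j in range(m):
        ea, oa = pairs[allele_idx[j]]
        common = dict(
            snp_id=ids[j], effect_allele=ea, other_allele=oa,
            chrom="1", pos=_SPACING_BP * (j + 1), eaf=float(maf[j]),
        )
        exposure.append(
            SummaryStatRecord(
                beta=float(beta_x[j]), se=float(se_x[j]),
                pvalue=float(min(1.0, p_x[j])), n=config.n_exposure, **common,
            )
        )
        outcome.append(
            SummaryStatRecord(
                beta=float(beta_y[j]), se=float(se_y[j]),
                pvalue=float(min(1.0, p_y[j])), n=config.n_outcome, **common,
            )
        )
    truth = SimulationTruth(
        theta=config.theta,
        xi=tuple(float(v) for v in xi[:k]),
        alpha=tuple(float(v) for v in alpha[:k]),
        instrument_ids=tuple(ids[:k]),
        seed=config.seed,
    )
    return exposure, outcome, truth


def simulate_ld(config: SimulationConfig, n_snps: int | None = None) -> LDMatrix:
    """Block-diagonal LD: consecutive SNPs share r² = ld_within_r2.

    Blocks of ``ld_block_size`` consecutive SNPs, zero r² across blocks,
    unit diagonal; SNP ids match :func:`simulate_sumstats` output.
    """
    m = n_snps if n_snps is not None else config.k_instruments + config.n_null_snps
    ids = [f"rs{j + 1:06d}" for j in range(m)]
    r2 = np.zeros((m, m))
    b = config.ld_block_size
    for start in range(0, m, b):
        stop = min(start + b, m)
        r2[start:stop, start:stop] = config.ld_within_r2
    np.fill_diagonal(r2, 1.0)
    return LDMatrix(snp_ids=ids, r2=r2)


def instrument_set_from_truth(
    exposure: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
    truth: SimulationTruth,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> InstrumentSet:
    """Build the true-instrument set directly (no selection/harmonization).

    Used by recovery studies where the estimand, not the screening
    pipeline, is under test; alleles are already aligned by construction.
    """
    by_id_out = {r.snp_id: r for r in outcome}
    by_id_exp = {r.snp_id: r for r in exposure}
    return InstrumentSet.from_arrays(
        beta_exp=[by_id_exp[s].beta for s in truth.instrument_ids],
        se_exp=[by_id_exp[s].se for s in truth.instrument_ids],
        beta_out=[by_id_out[s].beta for s in truth.instrument_ids],
        se_out=[by_id_out[s].se for s in truth.instrument_ids],
        snp_ids=list(truth.instrument_ids),
        exposure_name=exposure_name,
        outcome_name=outcome_name,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo recovery harness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """One cell of a recovery grid: a config and the methods to score."""

    name: str
    config: SimulationConfig
    methods: tuple[str, ...] = (
        est.METHOD_IVW_FIXED, est.METHOD_IVW_RANDOM, est.METHOD_ML,
        est.METHOD_SIMPLE_MEDIAN, est.METHOD_WEIGHTED_MEDIAN, est.METHOD_EGGER,
    )


def _estimate_by_method(
    iset: InstrumentSet, method: str, seed: int, n_boot: int
) -> est.MREstimate:
    if method == est.METHOD_IVW_FIXED:
        return est.ivw(iset, "fixed")
    if method == est.METHOD_IVW_RANDOM:
        return est.ivw(iset, "random")
    if method == est.METHOD_ML:
        return est.maximum_likelihood(iset)
    if method == est.METHOD_SIMPLE_MEDIAN:
        return est.median_estimators(iset, "simple", n_boot=n_boot, seed=seed)
    if method == est.METHOD_WEIGHTED_MEDIAN:
        return est.median_estimators(iset, "weighted", n_boot=n_boot, seed=seed)
    if method == est.METHOD_EGGER:
        return est.mr_egger(iset)[0]
    raise EstimationError(f"unknown method {method!r}")


def recovery_suite(
    scenarios: Sequence[Scenario],
    replicates: int,
    seed: int,
    n_boot: int = 500,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Monte-Carlo estimator scorecard over a scenario grid.

    For every scenario x method: mean bias and RMSE of theta, coverage
    of the 95% CI at the true theta, and the rejection rate at
    ``alpha``. Deterministic given (scenarios, replicates, seed).
    """
    rows = []
    for sc in scenarios:
        thetas = {m: [] for m in sc.methods}
        covered = {m: 0 for m in sc.methods}
        rejected = {m: 0 for m in sc.methods}
        true_or = np.exp(sc.config.theta)
        for rep in range(replicates):
            cfg = replace(sc.config, seed=derive_seed(seed, sc.name, rep))
            exposure, outcome, truth = simulate_sumstats(cfg)
            iset = instrument_set_from_truth(exposure, outcome, truth)
            for m in sc.methods:
                e = _estimate_by_method(
                    iset, m, seed=derive_seed(seed, sc.name, rep, m), n_boot=n_boot
                )
                thetas[m].append(e.theta)
                covered[m] += int(e.ci_low < true_or < e.ci_high)
                rejected[m] += int(e.pvalue < alpha)
        for m in sc.methods:
            t = np.asarray(thetas[m])
            rows.append({
                "scenario": sc.name,
                "method": m,
                "replicates": replicates,
                "mean_bias": float(np.mean(t) - sc.config.theta),
                "rmse": float(np.sqrt(np.mean((t - sc.config.theta) ** 2))),
                "ci_coverage": covered[m] / replicates,
                "rejection_rate": rejected[m] / replicates,
            })
    return pd.DataFrame(rows)
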