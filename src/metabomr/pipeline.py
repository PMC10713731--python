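"""Batch orchestration: exposures x outcomes, reporting, volcano data.

One pair runs select -> clump -> harmonize -> F-check -> gated
estimators -> diagnostics and yields report rows matching the
conventional MR results layout (outcome, exposure, method, SNP count,
OR with 95% CI, p, heterogeneity p, pleiotropy p). A batch iterates a
manifest of pairs with per-pair seeds derived from the names, so
results never depend on manifest order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from . import estimators as est
from .diagnostics import cochran_q, leave_one_out, pleiotropy_test
from .exceptions import ConfigurationError, MRError
from .instruments import InstrumentSet, LDMatrix, clump, compute_f, select_by_pvalue
from .sumstats_io import AuditLog, ColumnMap, harmonize, read_sumstats
from .synthetic import derive_seed

logger = logging.getLogger("metabomr")


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and knobs of one analysis run.

    Defaults are the conventional choices: genome-wide significance
    5e-8, clumping at r² < 0.01 within 250 kb, mean-F guard at 10,
    1000 bootstrap replicates for the median SEs, two-sided alpha 0.05
    with no multiplicity correction for the significance flag (a BH
    column is emitted alongside for context, but never drives the flag).
    """

    p_threshold: float = 5e-8
    clump_r2: float = 0.01
    clump_window_kb: int = 250
    min_mean_f: float = 10.0
    n_boot: int = 1000
    seed: int = 0
    alpha: float = 0.05
    gating_mode: str = est.GATING_BY_COUNT
    palindromic_eaf_window: float = 0.42
    on_missing_ld: str = "error"

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError("alpha must lie in (0,1)")
        for name in ("p_threshold", "clump_r2", "min_mean_f"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls(**data)


@dataclass(frozen=True)
class ResultRow:
    """One method's row of the batch report."""

    outcome: str
    exposure: str
    method: str
    n_snp: int
    or_value: float
    ci_low: float
    ci_high: float
    pvalue: float
    p_heterogeneity: float | None = None
    p_pleiotropy: float | None = None
    significant: bool = False

    @property
    def theta(self) -> float:
        return float(np.log(self.or_value))


@dataclass
class PairResult:
    """Rows plus the per-pair diagnostics report and audit trail."""

    exposure: str
    outcome: str
    rows: list[ResultRow]
    diagnostics: dict
    audit: AuditLog
    skipped_reason: str | None = None


def _rows_from_estimates(
    estimates: Sequence[est.MREstimate],
    exposure: str,
    outcome: str,
    het_p: float | None,
    pleio_p: float | None,
    alpha: float,
) -> list[ResultRow]:
    rows = []
    for e in estimates:
        rows.append(
            ResultRow(
                outcome=outcome, exposure=exposure, method=e.method,
                n_snp=e.n_snp, or_value=e.or_value,
                ci_low=e.ci_low, ci_high=e.ci_high, pvalue=e.pvalue,
                p_heterogeneity=het_p if e.method == est.METHOD_IVW_FIXED else None,
                p_pleiotropy=pleio_p if e.method == est.METHOD_EGGER else None,
                significant=e.pvalue < alpha,
            )
        )
    return rows


def run_pair_records(
    exposure_records,
    outcome_records,
    config: AnalysisConfig,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    ld: LDMatrix | None = None,
    seed: int | None = None,
) -> PairResult:
    """Run the full per-pair analysis on already-parsed records."""
    audit = AuditLog()
    seed = config.seed if seed is None else seed
    selected = select_by_pvalue(exposure_records, config.p_threshold)
    if not selected:
        audit.record("select", "*", "no genome-wide-significant SNPs")
        return PairResult(exposure_name, outcome_name, [], {}, audit,
                          skipped_reason="no instruments after selection")
    clumped = clump(
        selected, ld=ld, r2_threshold=config.clump_r2,
        window_kb=config.clump_window_kb, on_missing_ld=config.on_missing_ld,
    )
    for r in selected:
        if r not in clumped:
            audit.record("clump", r.snp_id, "removed by a stronger SNP in LD/window")
    harm = harmonize(clumped, outcome_records, config.palindromic_eaf_window)
    for snp_id, reason in harm.dropped:
        audit.record("harmonize", snp_id, reason)
    if not harm.instruments:
        return PairResult(exposure_name, outcome_name, [], {}, audit,
                          skipped_reason="no instruments after harmonization")
    iset = InstrumentSet(exposure_name, outcome_name, harm.instruments)
    iset, strong = compute_f(iset, config.min_mean_f)
    if not strong:
        logger.warning(
            "%s vs %s: mean F %.2f <= %g, weak-instrument flag set",
            exposure_name, outcome_name, iset.mean_f, config.min_mean_f,
        )
    estimates = est.run_gated_methods(
        iset, seed=seed, gating_mode=config.gating_mode, n_boot=config.n_boot
    )
    k = iset.n_snp
    het = cochran_q(iset) if k >= 2 else None
    pleio = pleiotropy_test(iset) if k >= 3 else None
    loo = leave_one_out(iset) if k >= 2 else []
    rows = _rows_from_estimates(
        estimates, exposure_name, outcome_name,
        het.pvalue if het else None, pleio.pvalue if pleio else None,
        config.alpha,
    )
    diag = {
        "exposure": exposure_name,
        "outcome": outcome_name,
        "n_selected": len(selected),
        "n_clumped": len(clumped),
        "n_harmonized": k,
        "f_per_snp": [float(f) for f in iset.f_per_snp],
        "mean_f": iset.mean_f,
        "weak_instrument": not strong,
        "heterogeneity": asdict(het) if het else None,
        "pleiotropy": asdict(pleio) if pleio else None,
        "leave_one_out": [asdict(r) for r in loo],
    }
    return PairResult(exposure_name, outcome_name, rows, diag, audit)


def run_pair(
    exposure_path: str | Path,
    outcome_path: str | Path,
    config: AnalysisConfig,
    exposure_name: str | None = None,
    outcome_name: str | None = None,
    exposure_map: ColumnMap | None = None,
    outcome_map: ColumnMap | None = None,
    ld: LDMatrix | None = None,
    seed: int | None = None,
) -> PairResult:
    """Read one exposure and one outcome table and analyze the pair."""
    exposure_name = exposure_name or Path(exposure_path).stem
    outcome_name = outcome_name or Path(outcome_path).stem
    audit = AuditLog()
    exposure_records = read_sumstats(exposure_path, exposure_map, audit)
    outcome_records = read_sumstats(outcome_path, outcome_map, audit)
    result = run_pair_records(
        exposure_records, outcome_records, config,
        exposure_name, outcome_name, ld=ld, seed=seed,
    )
    result.audit.entries = audit.entries + result.audit.entries
    return result


@dataclass
class BatchResult:
    """All pair results plus the flattened, deterministic report."""

    pairs: list[PairResult]
    rows: list[ResultRow]
    failures: list[tuple[str, str, str]]  # (exposure, outcome, reason)

    def to_frame(self) -> pd.DataFrame:
        """Long results table with a BH-adjusted column per method.

        The BH column is contextual only; the ``significant`` flag
        stays on the raw two-sided p < alpha rule.
        """
        df = pd.DataFrame([asdict(r) for r in self.rows])
        if df.empty:
            return df
        df["pvalue_bh"] = np.nan
        for m, idx in df.groupby("method").groups.items():
            df.loc[idx, "pvalue_bh"] = multipletests(
                df.loc[idx, "pvalue"].to_numpy(), method="fdr_bh"
            )[1]
        return df

    def significance_summary(self, methods: tuple[str, ...] = (
        est.METHOD_WALD, est.METHOD_IVW_FIXED, est.METHOD_IVW_RANDOM,
    )) -> pd.DataFrame:
        """Exposures with any primary-method p < alpha, per outcome."""
        df = pd.DataFrame([asdict(r) for r in self.rows])
        if df.empty:
            return pd.DataFrame(columns=["outcome", "n_significant_exposures"])
        primary = df[df["method"].isin(methods) & df["significant"]]
        counts = (
            primary.groupby("outcome")["exposure"].nunique()
            .rename("n_significant_exposures").reset_index()
        )
        return counts


def _method_rank(method: str) -> int:
    return est.METHOD_ORDER.index(method)


def run_batch(
    manifest: Sequence[Mapping],
    config: AnalysisConfig,
    ld: LDMatrix | None = None,
) -> BatchResult:
    """Run every exposure-outcome pair in a manifest.

    Each manifest entry is a mapping with keys ``exposure``,
    ``outcome``, ``exposure_path``, ``outcome_path`` (and optionally
    per-entry column maps). Per-pair seeds derive from
    (config.seed, exposure, outcome), and the flattened rows are sorted
    by (outcome, exposure, method), so neither batch order nor batch
    composition changes any number. Individual pair failures are
    collected and the batch continues.
    """
    if not manifest:
        raise ConfigurationError("manifest is empty")
    pairs: list[PairResult] = []
    failures: list[tuple[str, str, str]] = []
    for entry in manifest:
        exp_name = str(entry["exposure"])
        out_name = str(entry["outcome"])
        pair_seed = derive_seed(config.seed, exp_name, out_name)
        try:
            result = run_pair(
                entry["exposure_path"], entry["outcome_path"], config,
                exposure_name=exp_name, outcome_name=out_name,
                exposure_map=entry.get("exposure_map"),
                outcome_map=entry.get("outcome_map"),
                ld=ld, seed=pair_seed,
            )
        except MRError as exc:
            logger.error("pair %s vs %s failed: %s", exp_name, out_name, exc)
            failures.append((exp_name, out_name, str(exc)))
            continue
        if result.skipped_reason:
            logger.info(
                "pair %s vs %s skipped: %s", exp_name, out_name,
                result.skipped_reason,
            )
        pairs.append(result)
    rows = [r for p in pairs for r in p.rows]
    rows.sort(key=lambda r: (r.outcome, r.exposure, _method_rank(r.method)))
    return BatchResult(pairs=pairs, rows=rows, failures=failures)


def volcano_table(
    rows: Sequence[ResultRow], method_filter: str = "ivw"
) -> pd.DataFrame:
    """Plot-ready volcano data: log OR vs -log10 p for one method.

    ``method_filter`` "ivw" selects the fixed-effects IVW row of each
    pair (the conventional volcano method); pairs lacking the method
    are omitted with a log note.
    """
    if not rows:
        raise ValueError("rows must be non-empty")
    method = est.METHOD_IVW_FIXED if method_filter == "ivw" else method_filter
    present = {}
    for r in rows:
        if r.method == method:
            present[(r.exposure, r.outcome)] = r
    all_pairs = {(r.exposure, r.outcome) for r in rows}
    for pair in sorted(all_pairs - set(present)):
        logger.info("volcano: pair %s lacks method %s; omitted", pair, method)
    data = [
        {
            "exposure": e, "outcome": o,
            "log_or": float(np.log(r.or_value)),
            "minus_log10_p": float(-np.log10(r.pvalue)),
        }
        for (e, o), r in sorted(present.items())
    ]
    return pd.DataFrame(data, columns=["exposure", "outcome", "log_or", "minus_log10_p"])


def write_diagnostics_report(pairs: Sequence[PairResult], path: str | Path) -> None:
    """Per-pair JSON diagnostics (Q, intercept, leave-one-out, audit)."""
    payload = [
        {
            "exposure": p.exposure, "outcome": p.outcome,
            "skipped_reason": p.skipped_reason,
            "diagnostics": p.diagnostics,
            "audit": p.audit.entries,
        }
        for p in pairs
    ]
    Path(path).write_text(json.dumps(payload, indent=1))
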