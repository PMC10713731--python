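"""Read, write and harmonize GWAS summary statistics.

Summary statistics arrive as delimited text whose headers differ between
consortia; a :class:`ColumnMap` translates any dialect onto the canonical
field names. Harmonization then aligns exposure and outcome records to a
shared effect allele so downstream estimators can consume per-SNP
``(beta_X, se_X, beta_Y, se_Y)`` pairs directly. Every record dropped at
any stage is accounted for, with a reason, in an :class:`AuditLog` or in
the :class:`HarmonizationResult` — nothing is silently discarded.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, HarmonizationError, NoRecordsError

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: fields a ColumnMap must provide; the rest are optional.
MANDATORY_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se")
CANONICAL_FIELDS = (
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
)

ACTION_UNCHANGED = "unchanged"
ACTION_SIGN_FLIPPED = "sign_flipped"
ACTION_STRAND_FLIPPED = "strand_flipped"
ACTION_STRAND_AND_SIGN = "strand_flipped_and_sign_flipped"


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association summary for a single trait.

    ``beta`` is a per-SD effect for a continuous exposure or a log-odds
    effect for a binary outcome; ``se`` must be positive; ``pvalue`` is
    the two-sided association p-value.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: int | None = None

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from canonical field names to source column headers.

    ``mapping`` must cover :data:`MANDATORY_FIELDS`; unmapped optional
    fields (chrom, pos, eaf, pvalue, n) are treated as absent. When the
    p-value column is absent it is recomputed from the Wald z-score.
    """

    mapping: Mapping[str, str]
    sep: str = "\t"
    na_tokens: tuple[str, ...] = ("", "NA", "NaN", "nan", ".")

    def __post_init__(self):
        missing = [f for f in MANDATORY_FIELDS if f not in self.mapping]
        if missing:
            raise ConfigurationError(
                f"column map is missing mandatory field(s): {', '.join(missing)}"
            )
        unknown = [f for f in self.mapping if f not in CANONICAL_FIELDS]
        if unknown:
            raise ConfigurationError(
                f"column map has unknown canonical field(s): {', '.join(unknown)}"
            )

    @classmethod
    def canonical(cls, sep: str = "\t") -> "ColumnMap":
        """The identity map: source headers already use canonical names."""
        return cls(mapping={f: f for f in CANONICAL_FIELDS}, sep=sep)


@dataclass
class AuditLog:
    """Accumulates per-record exclusion/adjustment decisions."""

    entries: list[dict] = field(default_factory=list)

    def record(self, stage: str, snp_id: str, reason: str) -> None:
        self.entries.append({"stage": stage, "snp_id": snp_id, "reason": reason})

    def __len__(self) -> int:
        return len(self.entries)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.entries, indent=1))


def _two_sided_p(beta: float, se: float) -> float:
    return float(min(1.0, 2.0 * stats.norm.sf(abs(beta) / se)))


def read_sumstats(
    path: str | Path,
    column_map: ColumnMap | None = None,
    audit: AuditLog | None = None,
) -> list[SummaryStatRecord]:
    """Parse a delimited summary-statistics table into records.

    Rows with a nonpositive or missing SE, a missing beta, or alleles
    outside A/C/G/T are dropped and logged in ``audit``. Gzip input is
    accepted transparently. Raises :class:`NoRecordsError` if no row
    survives, and :class:`ConfigurationError` if a mandatory column is
    absent from the file.
    """
    cm = column_map or ColumnMap.canonical()
    audit = audit if audit is not None else AuditLog()
    try:
        df = pd.read_csv(
            path, sep=cm.sep, dtype=str,
            na_values=list(cm.na_tokens), keep_default_na=True,
        )
    except pd.errors.EmptyDataError:
        raise NoRecordsError(f"no records in {path}: file is empty")

    missing_cols = [
        cm.mapping[f] for f in MANDATORY_FIELDS if cm.mapping[f] not in df.columns
    ]
    if missing_cols:
        raise ConfigurationError(
            f"{path}: mandatory column(s) not found: {', '.join(missing_cols)}"
        )

    def col(fieldname: str) -> pd.Series | None:
        src = cm.mapping.get(fieldname)
        if src is None or src not in df.columns:
            return None
        return df[src]

    records: list[SummaryStatRecord] = []
    n_rows = len(df)
    snp_ids = col("snp_id").astype(str).str.strip()
    eas = col("effect_allele").astype(str).str.strip().str.upper()
    oas = col("other_allele").astype(str).str.strip().str.upper()
    betas = pd.to_numeric(col("beta"), errors="coerce")
    ses = pd.to_numeric(col("se"), errors="coerce")
    pvals = col("pvalue")
    pvals = pd.to_numeric(pvals, errors="coerce") if pvals is not None else None
    eafs = col("eaf")
    eafs = pd.to_numeric(eafs, errors="coerce") if eafs is not None else None
    chroms = col("chrom")
    poss = col("pos")
    poss = pd.to_numeric(poss, errors="coerce") if poss is not None else None
    ns = col("n")
    ns = pd.to_numeric(ns, errors="coerce") if ns is not None else None

    for i in range(n_rows):
        sid = snp_ids.iloc[i]
        beta = betas.iloc[i]
        se = ses.iloc[i]
        ea, oa = eas.iloc[i], oas.iloc[i]
        if pd.isna(beta):
            audit.record("read", sid, "missing beta")
            continue
        if pd.isna(se):
            audit.record("read", sid, "missing SE")
            continue
        if se <= 0:
            audit.record("read", sid, "nonpositive SE")
            continue
        if ea not in VALID_ALLELES or oa not in VALID_ALLELES or ea == oa:
            audit.record("read", sid, "invalid alleles")
            continue
        p = None if pvals is None else pvals.iloc[i]
        if p is None or pd.isna(p):
            p = _two_sided_p(float(beta), float(se))
        eaf = None
        if eafs is not None and not pd.isna(eafs.iloc[i]):
            eaf = float(eafs.iloc[i])
            if not (0.0 < eaf < 1.0):
                audit.record("read", sid, "eaf outside (0,1), set missing")
                eaf = None
        pos = None
        if poss is not None and not pd.isna(poss.iloc[i]):
            pos = int(poss.iloc[i])
        chrom = None
        if chroms is not None and not pd.isna(chroms.iloc[i]):
            chrom = str(chroms.iloc[i]).strip()
        n_val = None
        if ns is not None and not pd.isna(ns.iloc[i]):
            n_val = int(ns.iloc[i])
        records.append(
            SummaryStatRecord(
                snp_id=sid, effect_allele=ea, other_allele=oa,
                beta=float(beta), se=float(se), pvalue=float(p),
                chrom=chrom, pos=pos, eaf=eaf, n=n_val,
            )
        )
    if not records:
        raise NoRecordsError(f"no records in {path}: all {n_rows} rows were dropped")
    return records


def write_sumstats(records: Sequence[SummaryStatRecord], path: str | Path) -> None:
    """Write records as a canonical-header tab-separated table."""
    rows = [asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=list(CANONICAL_FIELDS))
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HarmonizedInstrument:
    """One SNP's allele-aligned exposure and outcome effects."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None = None
    eaf_out: float | None = None
    action_taken: str = ACTION_UNCHANGED


@dataclass
class HarmonizationResult:
    """Retained instruments plus the fully accounted drop list."""

    instruments: list[HarmonizedInstrument]
    dropped: list[tuple[str, str]]  # (snp_id, reason)

    def __iter__(self) -> Iterator[HarmonizedInstrument]:
        return iter(self.instruments)

    def __len__(self) -> int:
        return len(self.instruments)


def _is_palindromic_pair(a1: str, a2: str) -> bool:
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def harmonize(
    exposure: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
    palindromic_eaf_window: float = 0.42,
) -> HarmonizationResult:
    """Align outcome effects onto each exposure SNP's effect allele.

    Rules, per exposure SNP found in the outcome:

    * identical alleles — keep as is;
    * effect/other swapped — negate ``beta_out``, flip ``eaf_out``;
    * alleles match only after A<->T / C<->G complement — apply the
      complement, then the two rules above (``strand_flipped`` actions);
    * palindromic pair (A/T or C/G) — strand cannot be resolved from the
      labels, so orientation is taken from allele-frequency agreement;
      dropped as ambiguous when either frequency is missing or closer to
      0.5 than ``palindromic_eaf_window`` allows
      (``min(eaf, 1-eaf) > window``);
    * irreconcilable alleles, or SNP absent from the outcome — dropped.

    ``|beta_out|`` and ``se_out`` are never altered, only signs and
    frequencies. Raises :class:`HarmonizationError` on duplicate
    exposure SNP ids.
    """
    ids = [r.snp_id for r in exposure]
    seen, dups = set(), []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise HarmonizationError(
            f"duplicate snp_id in exposure: {', '.join(sorted(set(dups)))}"
        )
    out_by_id: dict[str, SummaryStatRecord] = {}
    for r in outcome:
        out_by_id.setdefault(r.snp_id, r)

    kept: list[HarmonizedInstrument] = []
    dropped: list[tuple[str, str]] = []
    for exp in exposure:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            dropped.append((exp.snp_id, "absent from outcome"))
            continue
        e_ea, e_oa = exp.effect_allele, exp.other_allele
        o_ea, o_oa = out.effect_allele, out.other_allele

        if _is_palindromic_pair(e_ea, e_oa):
            if {o_ea, o_oa} != {e_ea, e_oa}:
                dropped.append((exp.snp_id, "irreconcilable alleles"))
                continue
            if exp.eaf is None or out.eaf is None:
                dropped.append((exp.snp_id, "ambiguous palindromic"))
                continue
            if (
                min(exp.eaf, 1 - exp.eaf) > palindromic_eaf_window
                or min(out.eaf, 1 - out.eaf) > palindromic_eaf_window
            ):
                dropped.append((exp.snp_id, "ambiguous palindromic"))
                continue
            # label-implied orientation, then frequency check
            if o_ea == e_ea:
                beta_out, eaf_out, action = out.beta, out.eaf, ACTION_UNCHANGED
            else:
                beta_out, eaf_out, action = -out.beta, 1 - out.eaf, ACTION_SIGN_FLIPPED
            if (exp.eaf < 0.5) != (eaf_out < 0.5):
                beta_out, eaf_out = -beta_out, 1 - eaf_out
                action = (
                    ACTION_SIGN_FLIPPED
                    if action == ACTION_UNCHANGED
                    else ACTION_UNCHANGED
                )
        else:
            eaf_out = out.eaf
            if o_ea == e_ea and o_oa == e_oa:
                beta_out, action = out.beta, ACTION_UNCHANGED
            elif o_ea == e_oa and o_oa == e_ea:
                beta_out, action = -out.beta, ACTION_SIGN_FLIPPED
                eaf_out = None if eaf_out is None else 1 - eaf_out
            elif COMPLEMENT[o_ea] == e_ea and COMPLEMENT[o_oa] == e_oa:
                beta_out, action = out.beta, ACTION_STRAND_FLIPPED
            elif COMPLEMENT[o_ea] == e_oa and COMPLEMENT[o_oa] == e_ea:
                beta_out, action = -out.beta, ACTION_STRAND_AND_SIGN
                eaf_out = None if eaf_out is None else 1 - eaf_out
            else:
                dropped.append((exp.snp_id, "irreconcilable alleles"))
                continue
        kept.append(
            HarmonizedInstrument(
                snp_id=exp.snp_id,
                beta_exp=exp.beta, se_exp=exp.se,
                beta_out=beta_out, se_out=out.se,
                eaf_exp=exp.eaf, eaf_out=eaf_out,
                action_taken=action,
            )
        )
    return HarmonizationResult(instruments=kept, dropped=dropped)


# ---------------------------------------------------------------------------
# Results tables
# ---------------------------------------------------------------------------

RESULTS_COLUMNS = (
    "outcome", "exposure", "method", "n_snp", "or", "ci_low", "ci_high",
    "pvalue", "p_heterogeneity", "p_pleiotropy",
)
NOT_ASSESSED = "/"


def _fmt(value, ndigits: int) -> str:
    if value is None:
        return NOT_ASSESSED
    return f"{value:.{ndigits}f}"


def companion_path(path: str | Path) -> Path:
    """Full-precision machine-readable sidecar for a rendered table."""
    return Path(path).with_suffix(".full.json")


def write_results_table(rows: Sequence, path: str | Path) -> Path:
    """Write a rendered results table plus a full-precision companion.

    The rendered file is tab-separated with ORs/CIs at 2 decimals and
    p-values at 3 (the precision the human-readable report uses);
    non-assessable diagnostics render as "/". Exact float values are
    preserved in a JSON companion next to the table; returns its path.
    """
    if not rows:
        raise ValueError("rows must be non-empty")
    path = Path(path)
    lines = ["\t".join(RESULTS_COLUMNS)]
    payload = []
    for r in rows:
        lines.append("\t".join([
            r.outcome, r.exposure, r.method, str(r.n_snp),
            _fmt(r.or_value, 2), _fmt(r.ci_low, 2), _fmt(r.ci_high, 2),
            _fmt(r.pvalue, 3), _fmt(r.p_heterogeneity, 3), _fmt(r.p_pleiotropy, 3),
        ]))
        payload.append({
            "outcome": r.outcome, "exposure": r.exposure, "method": r.method,
            "n_snp": r.n_snp, "or_value": r.or_value, "ci_low": r.ci_low,
            "ci_high": r.ci_high, "pvalue": r.pvalue,
            "p_heterogeneity": r.p_heterogeneity,
            "p_pleiotropy": r.p_pleiotropy,
            "significant": bool(r.significant),
        })
    path.write_text("\n".join(lines) + "\n")
    side = companion_path(path)
    side.write_text(json.dumps(payload, indent=1))
    return side


def read_results_table(companion: str | Path) -> list:
    """Read the full-precision companion back into ResultRow objects."""
    from .pipeline import ResultRow  # late import: pipeline imports this module

    payload = json.loads(Path(companion).read_text())
    return [ResultRow(**d) for d in payload]
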