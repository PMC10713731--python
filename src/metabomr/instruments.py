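"""Instrument selection: genome-wide significance, LD clumping, F-statistics.

Instruments for a metabolite exposure must be genome-wide significant
(P < 5e-8, strict), approximately independent (greedy clumping at
r² < 0.01 within 250 kb), and strong (mean F = mean((beta/se)²) > 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ClumpingError, ConfigurationError
from .sumstats_io import HarmonizedInstrument, SummaryStatRecord


@dataclass
class LDMatrix:
    """Square symmetric r² table over an ordered SNP panel."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ConfigurationError("LD matrix shape does not match snp_ids")
        if not np.allclose(self.r2, self.r2.T):
            raise ConfigurationError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ConfigurationError("LD matrix diagonal must be 1")
        if self.r2.min() < 0 or self.r2.max() > 1 + 1e-12:
            raise ConfigurationError("LD r2 values must lie in [0,1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def r2_between(self, a: str, b: str) -> float | None:
        """Pairwise r², or None when either SNP is absent from the panel."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])

    @classmethod
    def from_square_file(cls, path: str | Path, sep: str = "\t") -> "LDMatrix":
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls(snp_ids=list(df.index.astype(str)), r2=df.to_numpy(dtype=float))

    @classmethod
    def from_long(cls, pairs: pd.DataFrame) -> "LDMatrix":
        """Build from long format with columns snp_a, snp_b, r2."""
        ids = sorted(set(pairs["snp_a"]) | set(pairs["snp_b"]))
        idx = {s: i for i, s in enumerate(ids)}
        m = np.eye(len(ids))
        for a, b, v in pairs[["snp_a", "snp_b", "r2"]].itertuples(index=False):
            m[idx[a], idx[b]] = m[idx[b], idx[a]] = float(v)
        return cls(snp_ids=ids, r2=m)

    def to_square_file(self, path: str | Path, sep: str = "\t") -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(
            path, sep=sep
        )


@dataclass
class InstrumentSet:
    """A named exposure-outcome pair's harmonized instruments.

    Per-SNP F-statistics and their mean are filled by :func:`compute_f`.
    """

    exposure_name: str
    outcome_name: str
    instruments: list[HarmonizedInstrument]
    f_per_snp: np.ndarray | None = None
    mean_f: float | None = None

    def __post_init__(self):
        if not self.instruments:
            raise ValueError("InstrumentSet requires at least one instrument")

    def __len__(self) -> int:
        return len(self.instruments)

    @property
    def n_snp(self) -> int:
        return len(self.instruments)

    @property
    def snp_ids(self) -> list[str]:
        return [i.snp_id for i in self.instruments]

    def _arr(self, attr: str) -> np.ndarray:
        return np.array([getattr(i, attr) for i in self.instruments], dtype=float)

    @property
    def beta_exp(self) -> np.ndarray:
        return self._arr("beta_exp")

    @property
    def se_exp(self) -> np.ndarray:
        return self._arr("se_exp")

    @property
    def beta_out(self) -> np.ndarray:
        return self._arr("beta_out")

    @property
    def se_out(self) -> np.ndarray:
        return self._arr("se_out")

    def drop(self, index: int) -> "InstrumentSet":
        """A new set with instrument ``index`` removed (F left unset)."""
        kept = [x for j, x in enumerate(self.instruments) if j != index]
        return InstrumentSet(self.exposure_name, self.outcome_name, kept)

    @classmethod
    def from_arrays(
        cls,
        beta_exp,
        se_exp,
        beta_out,
        se_out,
        snp_ids: Sequence[str] | None = None,
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
    ) -> "InstrumentSet":
        beta_exp = np.asarray(beta_exp, dtype=float)
        if snp_ids is None:
            snp_ids = [f"snp{j + 1}" for j in range(len(beta_exp))]
        inst = [
            HarmonizedInstrument(
                snp_id=s, beta_exp=float(bx), se_exp=float(sx),
                beta_out=float(by), se_out=float(sy),
            )
            for s, bx, sx, by, sy in zip(snp_ids, beta_exp, se_exp, beta_out, se_out)
        ]
        return cls(exposure_name, outcome_name, inst)


def select_by_pvalue(
    records: Sequence[SummaryStatRecord], p_threshold: float = 5e-8
) -> list[SummaryStatRecord]:
    """Keep records with ``pvalue < p_threshold`` (strict), order preserved."""
    return [r for r in records if r.pvalue < p_threshold]


def clump(
    records: Sequence[SummaryStatRecord],
    ld: LDMatrix | None = None,
    r2_threshold: float = 0.01,
    window_kb: int = 250,
    on_missing_ld: str = "error",
) -> list[SummaryStatRecord]:
    """Greedy p-value clumping to an approximately independent set.

    SNPs are visited in ascending p-value order (ties broken by snp_id);
    each index SNP removes every remaining same-chromosome SNP within
    ``window_kb`` kilobases (inclusive) whose r² with it is >=
    ``r2_threshold``. Without an LD matrix, distance alone decides:
    everything inside the window is removed. A pair inside the window
    but absent from ``ld`` raises :class:`ClumpingError` when
    ``on_missing_ld="error"`` and is treated as r²=1 (removed) when
    ``on_missing_ld="conservative"``. Kept SNPs are returned in index
    (p-ascending) order.
    """
    if on_missing_ld not in ("error", "conservative"):
        raise ConfigurationError("on_missing_ld must be 'error' or 'conservative'")
    for r in records:
        if r.chrom is None or r.pos is None:
            raise ClumpingError(f"{r.snp_id}: clumping requires chrom and pos")
    order = sorted(records, key=lambda r: (r.pvalue, r.snp_id))
    window_bp = window_kb * 1000
    alive = list(order)
    kept: list[SummaryStatRecord] = []
    while alive:
        best = alive.pop(0)
        kept.append(best)
        survivors = []
        for r in alive:
            if r.chrom == best.chrom and abs(r.pos - best.pos) <= window_bp:
                if ld is None:
                    continue  # distance-only mode removes it
                r2 = ld.r2_between(best.snp_id, r.snp_id)
                if r2 is None:
                    if on_missing_ld == "error":
                        raise ClumpingError(
                            f"r2 for pair ({best.snp_id}, {r.snp_id}) missing "
                            "from LD matrix"
                        )
                    continue  # conservative: treat as r2=1, remove
                if r2 >= r2_threshold:
                    continue
            survivors.append(r)
        alive = survivors
    return kept


def compute_f(
    instrument_set: InstrumentSet, min_mean_f: float = 10.0
) -> tuple[InstrumentSet, bool]:
    """Annotate per-SNP F = (beta_exp/se_exp)² and the mean-F strength flag.

    The flag passes only when mean F is strictly greater than
    ``min_mean_f`` (a mean of exactly 10 fails).
    """
    f = (instrument_set.beta_exp / instrument_set.se_exp) ** 2
    mean_f = float(np.mean(f))
    annotated = InstrumentSet(
        exposure_name=instrument_set.exposure_name,
        outcome_name=instrument_set.outcome_name,
        instruments=list(instrument_set.instruments),
        f_per_snp=f,
        mean_f=mean_f,
    )
    return annotated, mean_f > min_mean_f
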