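"""Amp-seq fine mapping within the called chromosome.

Each amplicon carries one diagnostic SNP genotyped by deep sequencing in a
toxin-selected and a control pool of the male-informative backcross. After
quality control — amplicons with fewer than 500 reads in either pool, or a
control-pool allele frequency outside [0.125, 0.5] (nonspecific PCR
amplification), are excluded — each marker is tested for a selection-driven
increase in the resistant-allele frequency with a one-sided two-proportion
z-test, Benjamini-Hochberg adjusted across amplicons, with an effect-size
floor on ΔAF. The candidate interval spans the outermost significant SNP
positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .exceptions import InvalidParameterError, UndefinedAlleleFrequencyError

REQUIRED_COLUMNS = [
    "amplicon_id", "chrom", "pos",
    "sel_depth_R", "sel_depth_S", "ctrl_depth_R", "ctrl_depth_S",
]


def amplicon_frequencies(records: pd.DataFrame) -> pd.DataFrame:
    """Add sel_af, ctrl_af and delta_af columns (zero-depth rows -> error)."""
    sel_total = records["sel_depth_R"] + records["sel_depth_S"]
    ctrl_total = records["ctrl_depth_R"] + records["ctrl_depth_S"]
    if (sel_total == 0).any() or (ctrl_total == 0).any():
        raise UndefinedAlleleFrequencyError("amplicon with zero total reads in a pool")
    out = records.copy()
    out["sel_af"] = records["sel_depth_R"] / sel_total
    out["ctrl_af"] = records["ctrl_depth_R"] / ctrl_total
    out["delta_af"] = out["sel_af"] - out["ctrl_af"]
    return out


def delta_af(sel_af: float, ctrl_af: float) -> float:
    """Selection-induced allele-frequency change: selected AF - control AF."""
    for v in (sel_af, ctrl_af):
        if not np.isfinite(v):
            raise UndefinedAlleleFrequencyError("undefined allele frequency")
    return sel_af - ctrl_af


def qc_amplicons(records: pd.DataFrame, min_reads: int = 500,
                 ctrl_lower: float = 0.125, ctrl_upper: float = 0.5) -> pd.DataFrame:
    """Retain amplicons that pass read-depth and control-frequency QC.

    Keeps amplicons with >= ``min_reads`` total reads in both pools and a
    control-pool AF in [ctrl_lower, ctrl_upper] (inclusive); a control AF
    outside that band flags nonspecific PCR amplification. Order-preserving
    and idempotent.
    """
    if not (0.0 <= ctrl_lower < ctrl_upper <= 1.0):
        raise InvalidParameterError("need 0 <= ctrl_lower < ctrl_upper <= 1")
    sel_total = records["sel_depth_R"] + records["sel_depth_S"]
    ctrl_total = records["ctrl_depth_R"] + records["ctrl_depth_S"]
    deep = (sel_total >= min_reads) & (ctrl_total >= min_reads)
    records = records.loc[deep]
    records = amplicon_frequencies(records)
    return records.loc[(records["ctrl_af"] >= ctrl_lower) & (records["ctrl_af"] <= ctrl_upper)]


@dataclass(frozen=True)
class MarkerTestResult:
    amplicon_id: int
    delta_af: float
    p_raw: float
    p_adjusted: float = np.nan
    significant: bool = False


def test_marker(sel_depth_r: int, sel_total: int, ctrl_depth_r: int, ctrl_total: int) -> float:
    """One-sided two-proportion z-test p-value (selected AF > control AF).

    Pooled sequencing depths are large, so the normal approximation is
    appropriate; a zero pooled variance returns the one-sided null center 0.5.
    """
    if sel_total <= 0 or ctrl_total <= 0:
        raise UndefinedAlleleFrequencyError("zero total reads")
    pooled = (sel_depth_r + ctrl_depth_r) / (sel_total + ctrl_total)
    if pooled in (0.0, 1.0):
        return 0.5
    _, p = proportions_ztest(
        count=[sel_depth_r, ctrl_depth_r],
        nobs=[sel_total, ctrl_total],
        alternative="larger",
    )
    return float(p)


def test_markers(records: pd.DataFrame) -> pd.DataFrame:
    """Per-amplicon ΔAF and raw one-sided p-values for a QC-passed table."""
    records = amplicon_frequencies(records)
    p_raw = [
        test_marker(
            int(r.sel_depth_R), int(r.sel_depth_R + r.sel_depth_S),
            int(r.ctrl_depth_R), int(r.ctrl_depth_R + r.ctrl_depth_S),
        )
        for r in records.itertuples()
    ]
    out = records.copy()
    out["p_raw"] = p_raw
    return out


@dataclass(frozen=True)
class MappedInterval:
    """Candidate interval spanned by the significant marker SNPs (1-based, inclusive)."""

    chrom: str
    start: int
    end: int
    supporting_amplicons: tuple[int, ...] = ()

    def __post_init__(self):
        if self.start > self.end:
            raise InvalidParameterError("interval start must be <= end")

    @property
    def width_bp(self) -> int:
        return self.end - self.start

    @property
    def width_kb_display(self) -> str:
        return f"{round(self.width_bp / 1000)} kb"

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


def call_interval(results: pd.DataFrame, alpha: float = 0.01, min_delta: float = 0.1,
                  adjust: str = "BH") -> tuple[MappedInterval | None, pd.DataFrame, list[str]]:
    """Call the candidate interval from single-chromosome marker tests.

    ``results`` must carry ``amplicon_id, chrom, pos, delta_af, p_raw`` and be
    sorted by position. Significance requires adjusted p <= alpha AND
    delta_af >= min_delta; the interval spans the outermost significant SNP
    positions (no gap-bridging). Returns (interval-or-None, annotated table,
    warnings); isolated significant markers (non-significant on both sides)
    are flagged in the warnings list.
    """
    if results["chrom"].nunique() > 1:
        raise InvalidParameterError("call_interval expects markers from a single chromosome")
    pos = results["pos"].to_numpy()
    if np.any(np.diff(pos) < 0):
        raise InvalidParameterError("markers must be sorted by position")
    out = results.copy()
    if adjust == "BH":
        out["p_adjusted"] = multipletests(out["p_raw"], method="fdr_bh")[1] if len(out) else []
    elif adjust in (None, "none"):
        out["p_adjusted"] = out["p_raw"]
    else:
        raise InvalidParameterError(f"unknown adjustment {adjust!r}")
    out["significant"] = (out["p_adjusted"] <= alpha) & (out["delta_af"] >= min_delta)

    warnings: list[str] = []
    sig = out.loc[out["significant"]]
    if sig.empty:
        return None, out, warnings

    flags = out["significant"].to_numpy()
    for i in np.flatnonzero(flags):
        left_ok = i > 0 and flags[i - 1]
        right_ok = i < len(flags) - 1 and flags[i + 1]
        if not left_ok and not right_ok and flags.sum() > 1:
            row = out.iloc[i]
            warnings.append(
                f"isolated significant marker: amplicon {row['amplicon_id']} "
                f"at {row['chrom']}:{row['pos']}"
            )
    interval = MappedInterval(
        chrom=str(sig["chrom"].iloc[0]),
        start=int(sig["pos"].min()),
        end=int(sig["pos"].max()),
        supporting_amplicons=tuple(int(a) for a in sig["amplicon_id"]),
    )
    return interval, out, warnings


class FineMapping:
    """Amp-seq fine-mapping model over a paired-pool amplicon table.

    Parameters
    ----------
    amplicons : DataFrame
        Columns ``amplicon_id, chrom, pos, sel_depth_R, sel_depth_S,
        ctrl_depth_R, ctrl_depth_S`` for one chromosome.
    min_reads : int
        Minimum total reads per pool per amplicon.
    ctrl_bounds : (float, float)
        Admissible control-pool AF band (inclusive).
    alpha, min_delta : float
        Adjusted-p cutoff and ΔAF effect-size floor for significance.
    adjust : str
        Multiplicity adjustment across retained amplicons ('BH' or 'none').
    """

    def __init__(self, amplicons: pd.DataFrame, min_reads: int = 500,
                 ctrl_bounds: tuple[float, float] = (0.125, 0.5),
                 alpha: float = 0.01, min_delta: float = 0.1, adjust: str = "BH"):
        missing = [c for c in REQUIRED_COLUMNS if c not in amplicons.columns]
        if missing:
            raise InvalidParameterError(f"amplicon table missing columns: {missing}")
        self.amplicons = amplicons
        self.min_reads = int(min_reads)
        self.ctrl_bounds = ctrl_bounds
        self.alpha = float(alpha)
        self.min_delta = float(min_delta)
        self.adjust = adjust

    @classmethod
    def from_file(cls, path, **kwargs) -> "FineMapping":
        from .io import read_amplicon_table

        return cls(read_amplicon_table(path), **kwargs)

    def fit(self) -> "FineMappingResults":
        table = self.amplicons.sort_values("pos", kind="stable").reset_index(drop=True)
        retained = qc_amplicons(
            table, self.min_reads, self.ctrl_bounds[0], self.ctrl_bounds[1]
        )
        tested = test_markers(retained)
        interval, annotated, warnings = call_interval(
            tested, alpha=self.alpha, min_delta=self.min_delta, adjust=self.adjust
        )
        return FineMappingResults(
            model=self,
            marker_table=annotated,
            interval=interval,
            warnings=warnings,
            n_input=len(table),
            n_retained=len(retained),
        )


@dataclass
class FineMappingResults:
    model: FineMapping
    marker_table: pd.DataFrame
    interval: MappedInterval | None
    warnings: list[str]
    n_input: int
    n_retained: int

    def summary(self) -> str:
        m = self.model
        lines = [
            "Amp-seq fine mapping",
            f"  amplicons: {self.n_input} input, {self.n_retained} passed QC "
            f"(>= {m.min_reads} reads/pool, control AF in "
            f"[{m.ctrl_bounds[0]}, {m.ctrl_bounds[1]}])",
            f"  significance: {m.adjust}-adjusted p <= {m.alpha:g} and "
            f"ΔAF >= {m.min_delta:g}",
        ]
        if self.interval is None:
            lines.append("  no significant markers; no interval called")
        else:
            iv = self.interval
            lines.append(
                f"  interval: {iv.chrom}:{iv.start:,}-{iv.end:,} "
                f"({iv.width_bp:,} bp, {iv.width_kb_display}; "
                f"{len(iv.supporting_amplicons)} supporting amplicons)"
            )
        for w in self.warnings:
            lines.append(f"  warning: {w}")
        return "\n".join(lines)

    def to_bed(self, path) -> None:
        from .io import write_interval_bed

        write_interval_bed(self.interval, path)

    def to_json_dict(self) -> dict:
        d = {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "warnings": list(self.warnings),
            "interval": None,
        }
        if self.interval is not None:
            d["interval"] = {
                "chrom": self.interval.chrom,
                "start": self.interval.start,
                "end": self.interval.end,
                "width_bp": self.interval.width_bp,
                "width_kb_display": self.interval.width_kb_display,
                "supporting_amplicons": list(self.interval.supporting_amplicons),
            }
        return d

    def plot(self, ax=None):
        """ΔAF against position; the called interval is shaded."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3))
        t = self.marker_table
        ax.scatter(t["pos"] / 1e6, t["delta_af"],
                   c=np.where(t["significant"], "tab:red", "tab:gray"), s=18)
        if self.interval is not None:
            ax.axvspan(self.interval.start / 1e6, self.interval.end / 1e6,
                       color="tab:red", alpha=0.15)
        ax.axhline(self.model.min_delta, ls="--", lw=0.8, color="k")
        ax.set_xlabel("position (Mb)")
        ax.set_ylabel("ΔAF (selected − control)")
        return ax
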