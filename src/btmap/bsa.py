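"""BSA-seq linkage-group scan.

Pooled allele frequencies of selected vs unselected backcross pools are
summarized per chromosome as Gaussian kernel density estimates over [0, 1];
the resistance-carrying chromosome is called from the shift of the density
peak between pools. Because the informative (F1) parent of the scan cross is
an achiasmatic female, selection moves the whole chromosome's allele
frequencies together: the causal chromosome's peak moves from ~0.25 toward
~0.5 while unlinked chromosomes stay put.

SNPs with extreme frequencies (< 0.05 or > 0.95, strict) are removed before
density estimation; boundary values are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    InsufficientDataError,
    InvalidParameterError,
    UndefinedAlleleFrequencyError,
)


def compute_af(depth_r: int, depth_s: int) -> float:
    """Frequency of the resistant-strain-derived allele from pooled depths."""
    if depth_r < 0 or depth_s < 0:
        raise InvalidParameterError("depths must be non-negative")
    total = depth_r + depth_s
    if total == 0:
        raise UndefinedAlleleFrequencyError("allele frequency undefined at zero depth")
    return depth_r / total


def allele_frequencies(records: pd.DataFrame, on_zero: str = "drop") -> pd.DataFrame:
    """Add an ``af`` column to an allele-depth table.

    Zero-depth rows are dropped (default) or raise (``on_zero='error'``).
    """
    total = records["depth_R"] + records["depth_S"]
    if (total == 0).any():
        if on_zero == "error":
            raise UndefinedAlleleFrequencyError(
                f"{int((total == 0).sum())} rows with zero total depth"
            )
        records = records.loc[total > 0]
        total = total.loc[records.index]
    out = records.copy()
    out["af"] = out["depth_R"] / total
    return out


def filter_af(records: pd.DataFrame, lower: float = 0.05, upper: float = 0.95) -> pd.DataFrame:
    """Remove SNPs with af < lower or af > upper (boundaries retained)."""
    if not (0.0 <= lower < upper <= 1.0):
        raise InvalidParameterError("need 0 <= lower < upper <= 1")
    if "af" not in records.columns:
        records = allele_frequencies(records)
    return records.loc[(records["af"] >= lower) & (records["af"] <= upper)]


@dataclass(frozen=True)
class KdeProfile:
    """Per-chromosome allele-frequency density on a fixed grid over [0, 1]."""

    chrom: str
    grid: np.ndarray
    density: np.ndarray
    peak_af: float
    n_snps: int

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def kde_profile(afs, bandwidth="silverman", grid_step: float = 0.005,
                chrom: str = "", jitter_degenerate: bool = False) -> KdeProfile:
    """Gaussian-kernel density of allele frequencies on a [0, 1] grid.

    The density is renormalized to unit mass over [0, 1]. The peak is the
    grid argmax (ties break to the lowest grid value). Fewer than two finite
    values raise; zero-variance input raises unless ``jitter_degenerate``
    adds a tiny symmetric jitter first.
    """
    x = np.asarray(afs, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise InsufficientDataError("kde_profile needs >= 2 finite allele frequencies")
    if np.ptp(x) == 0.0:
        if not jitter_degenerate:
            raise InsufficientDataError(
                "zero-variance allele frequencies; pass jitter_degenerate=True to proceed"
            )
        x = x + np.linspace(-1e-9, 1e-9, x.size)
    kde = stats.gaussian_kde(x, bw_method=bandwidth)
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    density = kde(grid)
    mass = np.trapezoid(density, grid)
    if mass > 0:
        density = density / mass
    return KdeProfile(
        chrom=chrom,
        grid=grid,
        density=density,
        peak_af=float(grid[int(np.argmax(density))]),
        n_snps=int(x.size),
    )


@dataclass(frozen=True)
class LinkageCall:
    called_chrom: str | None
    peak_shift_by_chrom: dict[str, float]
    threshold: float


def call_linkage_group(selected_profiles: Mapping[str, KdeProfile],
                       control_profiles: Mapping[str, KdeProfile],
                       shift_threshold: float = 0.1) -> LinkageCall:
    """Call the linkage group from per-chromosome peak shifts.

    The shift is |selected peak − control peak|; the call is the argmax
    chromosome when its shift exceeds the threshold, otherwise no call.
    """
    sel_set, ctrl_set = set(selected_profiles), set(control_profiles)
    if sel_set != ctrl_set:
        raise InvalidParameterError(
            f"chromosome sets differ: {sorted(sel_set ^ ctrl_set)}"
        )
    shifts = {
        c: abs(selected_profiles[c].peak_af - control_profiles[c].peak_af)
        for c in sorted(sel_set)
    }
    called = None
    if shifts:
        best = max(shifts, key=lambda c: (shifts[c], c))
        if shifts[best] > shift_threshold:
            called = best
    return LinkageCall(called_chrom=called, peak_shift_by_chrom=shifts,
                       threshold=shift_threshold)


class LinkageScan:
    """BSA-seq linkage-group scan model.

    Parameters
    ----------
    selected, control : DataFrame
        Allele-depth tables (``chrom, pos, depth_R, depth_S``) for the
        toxin-selected and unselected pools of the same backcross.
    af_bounds : (float, float)
        SNP-frequency filter; values outside are removed (strict).
    bandwidth : str or float
        KDE bandwidth rule or value (scipy convention).
    grid_step : float
        Grid resolution of the density profile.
    shift_threshold : float
        Minimum peak shift for a linkage-group call.
    min_snps : int
        Chromosomes with fewer retained SNPs in either pool are dropped from
        the scan (reported in the results).
    """

    def __init__(self, selected: pd.DataFrame, control: pd.DataFrame,
                 af_bounds: tuple[float, float] = (0.05, 0.95),
                 bandwidth="silverman", grid_step: float = 0.005,
                 shift_threshold: float = 0.1, min_snps: int = 5):
        self.selected = selected
        self.control = control
        self.af_bounds = af_bounds
        self.bandwidth = bandwidth
        self.grid_step = float(grid_step)
        self.shift_threshold = float(shift_threshold)
        self.min_snps = int(min_snps)

    @classmethod
    def from_files(cls, selected_path, control_path, **kwargs) -> "LinkageScan":
        from .io import read_allele_depth_table

        return cls(
            read_allele_depth_table(selected_path),
            read_allele_depth_table(control_path),
            **kwargs,
        )

    def _profiles(self, records: pd.DataFrame) -> dict[str, KdeProfile]:
        lo, hi = self.af_bounds
        kept = filter_af(allele_frequencies(records), lo, hi)
        profiles = {}
        for chrom, group in kept.groupby("chrom", sort=False):
            if len(group) >= max(2, self.min_snps):
                profiles[str(chrom)] = kde_profile(
                    group["af"], bandwidth=self.bandwidth,
                    grid_step=self.grid_step, chrom=str(chrom),
                )
        return profiles

    def fit(self) -> "LinkageScanResults":
        sel = self._profiles(self.selected)
        ctrl = self._profiles(self.control)
        common = sorted(set(sel) & set(ctrl))
        dropped = sorted((set(sel) | set(ctrl)) - set(common))
        call = call_linkage_group(
            {c: sel[c] for c in common},
            {c: ctrl[c] for c in common},
            self.shift_threshold,
        )
        table = pd.DataFrame(
            {
                "peak_selected": [sel[c].peak_af for c in common],
                "peak_control": [ctrl[c].peak_af for c in common],
                "shift": [call.peak_shift_by_chrom[c] for c in common],
                "n_snps_selected": [sel[c].n_snps for c in common],
                "n_snps_control": [ctrl[c].n_snps for c in common],
            },
            index=pd.Index(common, name="chrom"),
        )
        return LinkageScanResults(
            model=self, call=call, shifts=table,
            selected_profiles=sel, control_profiles=ctrl, dropped_chroms=dropped,
        )


@dataclass
class LinkageScanResults:
    model: LinkageScan
    call: LinkageCall
    shifts: pd.DataFrame
    selected_profiles: dict[str, KdeProfile]
    control_profiles: dict[str, KdeProfile]
    dropped_chroms: list[str] = field(default_factory=list)

    @property
    def called_chrom(self) -> str | None:
        return self.call.called_chrom

    def ks_distances(self) -> pd.Series:
        """Secondary diagnostic: KS distance between pool AF samples per chromosome."""
        lo, hi = self.model.af_bounds
        sel = filter_af(allele_frequencies(self.model.selected), lo, hi)
        ctrl = filter_af(allele_frequencies(self.model.control), lo, hi)
        out = {}
        for chrom in self.shifts.index:
            a = sel.loc[sel["chrom"] == chrom, "af"]
            b = ctrl.loc[ctrl["chrom"] == chrom, "af"]
            out[chrom] = float(stats.ks_2samp(a, b).statistic)
        return pd.Series(out, name="ks_distance")

    def summary(self) -> str:
        lines = [
            "BSA-seq linkage-group scan",
            f"  AF filter: [{self.model.af_bounds[0]}, {self.model.af_bounds[1]}]   "
            f"shift threshold: {self.call.threshold}",
            f"  chromosomes scanned: {len(self.shifts)}"
            + (f" (dropped: {', '.join(self.dropped_chroms)})" if self.dropped_chroms else ""),
        ]
        if self.called_chrom is None:
            lines.append("  no linkage group called")
        else:
            row = self.shifts.loc[self.called_chrom]
            lines.append(
                f"  called chromosome: {self.called_chrom} "
                f"(peak {row['peak_control']:.3f} -> {row['peak_selected']:.3f}, "
                f"shift {row['shift']:.3f})"
            )
        top = self.shifts.sort_values("shift", ascending=False).head(5)
        lines.append("  top shifts:")
        for chrom, row in top.iterrows():
            lines.append(
                f"    {chrom:>6}: {row['shift']:.3f} "
                f"({row['peak_control']:.3f} -> {row['peak_selected']:.3f}, "
                f"{int(row['n_snps_selected'])}/{int(row['n_snps_control'])} SNPs)"
            )
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "called_chrom": self.called_chrom,
            "threshold": self.call.threshold,
            "shifts": {c: float(s) for c, s in self.call.peak_shift_by_chrom.items()},
            "peaks_selected": {c: p.peak_af for c, p in self.selected_profiles.items()},
            "peaks_control": {c: p.peak_af for c, p in self.control_profiles.items()},
        }

    def plot(self, chroms=None, ncols: int = 4, ax=None):
        """Grid of per-chromosome KDE profiles, selected vs control pools."""
        import matplotlib.pyplot as plt

        chroms = list(chroms) if chroms is not None else list(self.shifts.index)
        nrows = int(np.ceil(len(chroms) / ncols))
        fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.2 * nrows),
                                 sharex=True, squeeze=False)
        for k, chrom in enumerate(chroms):
            a = axes[k // ncols][k % ncols]
            sp, cp = self.selected_profiles[chrom], self.control_profiles[chrom]
            a.plot(cp.grid, cp.density, label="control", lw=1)
            a.plot(sp.grid, sp.density, label="selected", lw=1)
            a.set_title(chrom, fontsize=9)
        for k in range(len(chroms), nrows * ncols):
            axes[k // ncols][k % ncols].axis("off")
        axes[0][0].legend(fontsize=7)
        fig.supxlabel("allele frequency")
        fig.supylabel("density")
        fig.tight_layout()
        return fig
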