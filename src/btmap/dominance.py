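"""Dominance genetics: diagnostic genotyping, segregation tests, and h.

Survivor genotype counts from a toxin-selected backcross (F1 x resistant
strain) estimate the dominance coefficient of resistance,

    h = (w_RS - w_SS) / (w_RR - w_SS),

where w_G is the survival of genotype G; h = 0 is fully recessive, h = 1
fully dominant. When susceptible homozygotes cannot survive the dose
(w_SS = 0) and the backcross supplies equal numbers of RR and RS before
selection, h simplifies to the survivor count ratio

    h = n(RS survivors) / n(RR survivors).

Segregation ratios are tested against 1:1 with a plain Pearson chi-square
(df = 1, no continuity correction).
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    InvalidParameterError,
    UndefinedDominanceError,
    UnrecognizedAlleleError,
)

#: Diagnostic-PCR fragment sizes (bp) keyed by locus and allele origin
#: (R = resistant-strain-derived, S = susceptible-strain-derived).
ALLELE_FRAGMENT_SIZES = {
    "ABCC2": {"R": 102, "S": 120},
    "APN1": {"R": 327, "S": 234},
}

HOM_R = "RR"
HET = "RS"
HOM_S = "SS"


@dataclass(frozen=True)
class FragmentProfile:
    locus: str
    fragment_lengths: frozenset[int]

    def __post_init__(self):
        object.__setattr__(self, "fragment_lengths", frozenset(self.fragment_lengths))


def genotype_from_fragments(profile: FragmentProfile) -> str:
    """Call a genotype from observed diagnostic-PCR fragment sizes.

    Both sizes -> heterozygote; the resistant (or susceptible) size alone ->
    the corresponding homozygote. Unknown sizes or an empty profile raise.
    """
    try:
        sizes = ALLELE_FRAGMENT_SIZES[profile.locus]
    except KeyError:
        raise InvalidParameterError(f"no fragment map registered for {profile.locus!r}") from None
    observed = set(profile.fragment_lengths)
    if not observed:
        raise UnrecognizedAlleleError(f"{profile.locus}: empty fragment profile")
    unknown = observed - set(sizes.values())
    if unknown:
        raise UnrecognizedAlleleError(
            f"{profile.locus}: unrecognized fragment size(s) {sorted(unknown)}"
        )
    alleles = {a for a, s in sizes.items() if s in observed}
    if alleles == {"R", "S"}:
        return HET
    return HOM_R if alleles == {"R"} else HOM_S


def chi_square_1to1(n1: int, n2: int) -> tuple[float, float]:
    """Pearson chi-square test of a 1:1 segregation ratio (df=1).

    No Yates continuity correction is applied; with correction the test does
    not reproduce standard published backcross P values. Symmetric in its
    arguments.
    """
    if n1 < 0 or n2 < 0:
        raise InvalidParameterError("counts must be non-negative")
    if n1 + n2 == 0:
        raise InvalidParameterError("chi-square of 1:1 undefined for zero total")
    res = stats.chisquare([n1, n2])
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class DominanceResult:
    """Dominance coefficient with provenance.

    ``h`` is clamped to [0, 1] (sampling noise can push the raw ratio above
    1); ``h_raw`` keeps the unclamped value. ``display`` rounds to two
    decimals (round-half-even).
    """

    h: float
    h_raw: float
    method: str  # "count_ratio" or "survival_formula"
    inputs: dict = field(default_factory=dict)

    @property
    def clamped(self) -> bool:
        return self.h != self.h_raw

    @property
    def display(self) -> str:
        return f"{self.h:.2f}"


def _clamp(h_raw: float, method: str, inputs: dict) -> DominanceResult:
    h = min(1.0, max(0.0, h_raw))
    if h != h_raw:
        _warnings.warn(
            f"dominance h = {h_raw:.3f} outside [0, 1]; clamped (sampling noise)",
            stacklevel=3,
        )
    return DominanceResult(h=h, h_raw=h_raw, method=method, inputs=inputs)


def estimate_h_counts(n_het_survivors: int, n_homR_survivors: int) -> DominanceResult:
    """Simplified dominance estimate from survivor counts.

    Valid when susceptible homozygotes cannot survive the dose and the
    backcross contained equal numbers of RR and RS individuals before
    selection; then h = n_het / n_homR.
    """
    if n_het_survivors < 0 or n_homR_survivors < 0:
        raise InvalidParameterError("survivor counts must be non-negative")
    if n_homR_survivors == 0:
        raise UndefinedDominanceError("no homozygous resistant survivors; h undefined")
    h_raw = n_het_survivors / n_homR_survivors
    return _clamp(h_raw, "count_ratio",
                  {"n_het": int(n_het_survivors), "n_homR": int(n_homR_survivors)})


def estimate_h_survival(w_RR: float, w_RS: float, w_SS: float) -> DominanceResult:
    """Dominance from genotype survival proportions: (w_RS - w_SS)/(w_RR - w_SS)."""
    for name, w in (("w_RR", w_RR), ("w_RS", w_RS), ("w_SS", w_SS)):
        if not 0.0 <= w <= 1.0:
            raise InvalidParameterError(f"{name} must be in [0, 1]")
    if w_RR == w_SS:
        raise UndefinedDominanceError("w_RR == w_SS; dominance undefined")
    if w_RR < w_SS:
        raise InvalidParameterError("expected w_RR > w_SS")
    h_raw = (w_RS - w_SS) / (w_RR - w_SS)
    return _clamp(h_raw, "survival_formula",
                  {"w_RR": w_RR, "w_RS": w_RS, "w_SS": w_SS})


class DominanceAnalysis:
    """Segregation tests and dominance estimates over genotype count tables.

    ``counts`` is a DataFrame with one row per family x treatment:
    columns ``family`` (text), ``selection_dose`` (text; empty/None/'0' for
    unselected controls), ``n_hom_R`` and ``n_het``. ``fit()`` tests each row
    against a 1:1 ratio and estimates h on the toxin-selected rows.
    """

    REQUIRED = ["family", "selection_dose", "n_hom_R", "n_het"]

    def __init__(self, counts: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in counts.columns]
        if missing:
            raise InvalidParameterError(f"count table missing columns: {missing}")
        self.counts = counts

    @staticmethod
    def _is_selected(dose) -> bool:
        return not (dose is None or str(dose).strip() in ("", "0", "none", "None"))

    def fit(self) -> "DominanceAnalysisResults":
        rows = []
        for r in self.counts.itertuples(index=False):
            stat, p = chi_square_1to1(int(r.n_hom_R), int(r.n_het))
            h_display, h_value = "-", np.nan
            if self._is_selected(r.selection_dose):
                if r.n_hom_R > 0:
                    res = estimate_h_counts(int(r.n_het), int(r.n_hom_R))
                    h_display, h_value = res.display, res.h
            rows.append(
                {
                    "family": r.family,
                    "selection_dose": r.selection_dose,
                    "n_hom_R": int(r.n_hom_R),
                    "n_het": int(r.n_het),
                    "chi2": stat,
                    "p_value": p,
                    "h": h_value,
                    "h_display": h_display,
                }
            )
        return DominanceAnalysisResults(model=self, table=pd.DataFrame(rows))


@dataclass
class DominanceAnalysisResults:
    model: DominanceAnalysis
    table: pd.DataFrame

    def summary(self) -> str:
        lines = [
            "Dominance analysis (1:1 chi-square, df=1, no continuity correction)",
            f"{'family':<28}{'dose':>12}{'hom_R':>7}{'het':>6}{'P':>8}{'h':>7}",
        ]
        for r in self.table.itertuples(index=False):
            dose = str(r.selection_dose) if self.model._is_selected(r.selection_dose) else "0"
            lines.append(
                f"{str(r.family):<28}{dose:>12}{r.n_hom_R:>7}{r.n_het:>6}"
                f"{r.p_value:>8.2f}{r.h_display:>7}"
            )
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        recs = self.table.copy()
        recs["h"] = recs["h"].where(recs["h"].notna(), None)
        return {"rows": recs.to_dict(orient="records")}
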