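"""Midgut expression screen: RPKM, expressed-gene detection, strain ratios.

The screen mirrors a locus-restricted candidate-gene analysis: normalize
counts to RPKM, call a gene midgut-expressed when its per-strain mean RPKM
reaches an inclusive cutoff (default 0.5) in at least one strain, estimate
the resistant/susceptible expression ratio in percent, test it with a Welch
two-sample t-test on per-replicate RPKM values, and flag candidates whose
expression differs by more than a fold threshold (default 3) at a per-gene
significance level (default 0.01). No multiplicity correction is applied to
the candidate rule itself; a Benjamini-Hochberg column is reported alongside
for reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, InvalidParameterError


@dataclass
class ExpressionTable:
    """Gene x sample counts with gene lengths and per-sample strain labels.

    ``totals`` optionally carries per-sample mapped-read totals (e.g.
    genome-wide totals); when absent, column sums of the count matrix are
    used — appropriate for toy/locus-restricted tables and documented as a
    divergence from genome-wide normalization.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    strains: pd.Series
    totals: pd.Series | None = None

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise InvalidParameterError("counts must be non-negative")
        if not self.gene_lengths.index.equals(self.counts.index):
            self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any() or (self.gene_lengths <= 0).any():
            raise InvalidParameterError("every gene needs a positive length")
        missing = set(self.counts.columns) - set(self.strains.index)
        if missing:
            raise InvalidParameterError(f"samples without strain label: {sorted(missing)}")
        self.strains = self.strains.reindex(self.counts.columns)

    @property
    def effective_totals(self) -> pd.Series:
        if self.totals is not None:
            return self.totals.reindex(self.counts.columns).astype(float)
        return self.counts.sum(axis=0).astype(float)

    @property
    def strain_names(self) -> list[str]:
        seen: list[str] = []
        for s in self.strains:
            if s not in seen:
                seen.append(s)
        return seen

    def samples_of(self, strain: str) -> list[str]:
        return [s for s in self.counts.columns if self.strains[s] == strain]


def rpkm(count: float, gene_length: int, total_mapped: float) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if gene_length <= 0:
        raise InvalidParameterError("gene_length must be positive")
    if total_mapped <= 0:
        raise InvalidParameterError("total_mapped must be positive")
    return 1e9 * count / (gene_length * total_mapped)


def rpkm_table(table: ExpressionTable) -> pd.DataFrame:
    totals = table.effective_totals
    if (totals <= 0).any():
        raise InvalidParameterError("every sample needs positive mapped-read total")
    return (
        1e9
        * table.counts.div(totals, axis=1).div(table.gene_lengths.astype(float), axis=0)
    )


def mean_rpkm_by_strain(table: ExpressionTable) -> pd.DataFrame:
    rp = rpkm_table(table)
    return pd.DataFrame(
        {strain: rp[table.samples_of(strain)].mean(axis=1) for strain in table.strain_names}
    )


def detect_expressed(mean_rpkm: pd.DataFrame, cutoff: float = 0.5) -> pd.Index:
    """Genes whose mean RPKM reaches ``cutoff`` (inclusive) in >= 1 strain."""
    return mean_rpkm.index[(mean_rpkm >= cutoff).any(axis=1)]


@dataclass
class GeneExpressionResult:
    gene: str
    mean_rpkm: dict[str, float]
    ratio_pct: float
    p_value: float
    expressed_flag: bool
    candidate_flag: bool = False


def strain_ratio_test(table: ExpressionTable, gene: str,
                      strain1: str | None = None, strain2: str | None = None,
                      cutoff: float = 0.5) -> GeneExpressionResult:
    """Ratio (strain2/strain1, percent) and Welch t-test for one gene.

    The t-test compares per-replicate RPKM values between strains. A zero
    strain-1 mean leaves the ratio undefined and raises.
    """
    names = table.strain_names
    strain1 = strain1 or names[0]
    strain2 = strain2 or names[1]
    rp = rpkm_table(table)
    x1 = rp.loc[gene, table.samples_of(strain1)].to_numpy(dtype=float)
    x2 = rp.loc[gene, table.samples_of(strain2)].to_numpy(dtype=float)
    if len(x1) < 2 or len(x2) < 2:
        raise InsufficientDataError("need >= 2 replicates per strain")
    m1, m2 = float(x1.mean()), float(x2.mean())
    if m1 == 0.0:
        raise InvalidParameterError(f"{gene}: reference strain mean RPKM is zero")
    if x1.std() == 0.0 and x2.std() == 0.0:
        p = 1.0 if m1 == m2 else 0.0
    else:
        p = float(stats.ttest_ind(x2, x1, equal_var=False).pvalue)
    return GeneExpressionResult(
        gene=gene,
        mean_rpkm={strain1: m1, strain2: m2},
        ratio_pct=100.0 * m2 / m1,
        p_value=p,
        expressed_flag=bool(max(m1, m2) >= cutoff),
    )


def flag_candidates(results: pd.DataFrame, fold: float = 3.0, alpha: float = 0.01) -> pd.Index:
    """Genes changed more than ``fold``-fold with p <= alpha, expressed in >= 1 strain.

    ``results`` needs columns ``ratio_pct``, ``p_value`` and ``expressed``.
    """
    if fold <= 1:
        raise InvalidParameterError("fold must exceed 1")
    r = results["ratio_pct"]
    big = (r <= 100.0 / fold) | (r >= 100.0 * fold)
    return results.index[big & (results["p_value"] <= alpha) & results["expressed"]]


class ExpressionScreen:
    """Two-strain expression screen over a set of locus genes.

    Parameters
    ----------
    table : ExpressionTable
        Counts, gene lengths, strain labels and optional mapped totals.
    cutoff, fold, alpha : float
        Expressed-gene RPKM cutoff (inclusive), candidate fold threshold, and
        per-gene significance level.
    strain1, strain2 : str, optional
        Reference and comparison strains; default to the first two labels in
        sample order (ratio = strain2 / strain1).
    """

    def __init__(self, table: ExpressionTable, cutoff: float = 0.5, fold: float = 3.0,
                 alpha: float = 0.01, strain1: str | None = None, strain2: str | None = None):
        if len(table.strain_names) != 2 and (strain1 is None or strain2 is None):
            raise InvalidParameterError("screen needs exactly two strains (or explicit labels)")
        self.table = table
        self.cutoff = float(cutoff)
        self.fold = float(fold)
        self.alpha = float(alpha)
        self.strain1 = strain1 or table.strain_names[0]
        self.strain2 = strain2 or table.strain_names[1]

    def fit(self) -> "ExpressionScreenResults":
        from statsmodels.stats.multitest import multipletests

        means = mean_rpkm_by_strain(self.table)[[self.strain1, self.strain2]]
        expressed = (means >= self.cutoff).any(axis=1)
        rows = []
        for gene in self.table.counts.index:
            m1 = float(means.loc[gene, self.strain1])
            m2 = float(means.loc[gene, self.strain2])
            if m1 > 0:
                res = strain_ratio_test(
                    self.table, gene, self.strain1, self.strain2, cutoff=self.cutoff
                )
                ratio, p = res.ratio_pct, res.p_value
            else:
                ratio, p = np.nan, np.nan
            rows.append((gene, m1, m2, ratio, p))
        df = pd.DataFrame(
            rows,
            columns=["gene", f"mean_rpkm_{self.strain1}", f"mean_rpkm_{self.strain2}",
                     "ratio_pct", "p_value"],
        ).set_index("gene")
        df["expressed"] = expressed
        finite = df["p_value"].notna()
        df["p_bh"] = np.nan
        if finite.any():
            df.loc[finite, "p_bh"] = multipletests(
                df.loc[finite, "p_value"], method="fdr_bh"
            )[1]
        testable = df.dropna(subset=["ratio_pct", "p_value"])
        candidates = flag_candidates(testable, fold=self.fold, alpha=self.alpha)
        df["candidate"] = df.index.isin(candidates)
        return ExpressionScreenResults(model=self, per_gene=df)


@dataclass
class ExpressionScreenResults:
    model: ExpressionScreen
    per_gene: pd.DataFrame

    @property
    def expressed_genes(self) -> pd.Index:
        return self.per_gene.index[self.per_gene["expressed"]]

    @property
    def candidates(self) -> pd.Index:
        return self.per_gene.index[self.per_gene["candidate"]]

    def summary(self) -> str:
        m = self.model
        lines = [
            "Expression screen",
            f"  genes: {len(self.per_gene)}   "
            f"expressed (mean RPKM >= {m.cutoff} in >=1 strain): {len(self.expressed_genes)}",
            f"  candidate rule: >{m.fold:g}-fold and p <= {m.alpha:g} "
            f"({m.strain2} vs {m.strain1})",
            f"  candidates: {list(self.candidates) or 'none'}",
        ]
        for gene in self.candidates:
            row = self.per_gene.loc[gene]
            lines.append(
                f"    {gene}: ratio {row['ratio_pct']:.1f}% of {m.strain1}, "
                f"p = {row['p_value']:.2e}"
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return self.per_gene.copy()
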