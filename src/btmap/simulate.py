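"""Backcross, selection, and sequencing simulators.

This module emulates the biphasic linkage-mapping design used to map an
incompletely dominant Bt-resistance locus in a lepidopteran:

* **Female-informative backcross (BC1)** — the heterozygous F1 parent is
  female. Lepidopteran females are achiasmatic (no meiotic crossing over),
  so every maternal chromosome is transmitted intact and a selected pool
  shifts allele frequencies chromosome-wide: a linkage-group scan.
* **Male-informative backcross (BC2)** — the F1 parent is male; crossovers
  occur, so allele-frequency decay around the causal site permits fine
  mapping within the chromosome.
* **Dominance backcross** — F1 x resistant strain, used to count surviving
  homozygotes and heterozygotes at a diagnostic locus under toxin selection.

Two resistance loci are tracked: ``R1`` (an ABC-transporter knockout,
recessive; carried as a per-individual genotype label because it segregates
on a different chromosome) and ``R2`` (the mapped locus; read from the two
haplotypes at a designated causal marker).

Haplotypes are dense per-marker arrays with 1 = allele derived from the
resistant strain and 0 = allele from the susceptible/knockout strain.

Sequencing emulators produce the tabular inputs of the downstream analysis
stages: pooled whole-genome allele depths, per-amplicon read counts with
occasional nonspecific amplification, and negative-binomial expression
counts. No read-level (FASTQ) simulation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import derive_rng
from .exceptions import (
    EmptyPopulationError,
    GenomeMapError,
    InvalidParameterError,
    SelectionModelError,
)
from .genome import GenomeMap, default_r2_locus
from .expression import ExpressionTable

FEMALE = "female"
MALE = "male"

# R1 (ABC-transporter) genotypes. In the mapping crosses every individual is
# R1R1 (both copies knocked out / resistant-derived); in dominance crosses the
# heterozygote R1S1 also occurs.
R1_HOM = "R1R1"
R1_HET = "R1S1"

# R2 genotypes at the causal marker.
R2_HOM_R = "R2R2"
R2_HET = "R2S2"
R2_HOM_S = "S2S2"

_R2_FROM_DOSAGE = {2: R2_HOM_R, 1: R2_HET, 0: R2_HOM_S}
_R2_ALIASES = {"S2R2": R2_HET, "R2S2": R2_HET, "R2R2": R2_HOM_R, "S2S2": R2_HOM_S}

BC1 = "BC1_female_informative"
BC2 = "BC2_male_informative"
DOMINANCE = "dominance_backcross"
DESIGN_NAMES = (BC1, BC2, DOMINANCE)

#: Diagnostic-PCR fragment sizes (bp) per locus and allele origin.
FRAGMENT_SIZES = {
    "ABCC2": {"R": 102, "S": 120},
    "APN1": {"R": 327, "S": 234},
}


def normalize_r2(label: str) -> str:
    try:
        return _R2_ALIASES[label]
    except KeyError:
        raise InvalidParameterError(f"unknown R2 genotype label: {label!r}") from None


Haplotype = dict  # chromosome label -> uint8 array (1=R-derived, 0=S-derived)


@dataclass
class Individual:
    """A diploid individual: two phased haplotypes plus locus genotypes."""

    maternal: Haplotype
    paternal: Haplotype
    sex: str
    r2_locus: tuple[str, int]
    r1_genotype: str = R1_HOM

    def r2_dosage(self, gmap: GenomeMap) -> int:
        chrom, pos = self.r2_locus
        i = gmap[chrom].marker_index(pos)
        return int(self.maternal[chrom][i]) + int(self.paternal[chrom][i])

    def r2_genotype(self, gmap: GenomeMap) -> str:
        return _R2_FROM_DOSAGE[self.r2_dosage(gmap)]


@dataclass(frozen=True)
class CrossDesign:
    """One of the three backcross designs.

    ``informative_parent_sex`` is the sex of the heterozygous F1 parent:
    female for the chromosome-level cross (achiasmatic), male for the
    fine-mapping cross.
    """

    name: str
    n_offspring: int | None = None
    resistant_parent: str = "TnCry1Ac-R"
    susceptible_parent: str = "ABCC2-knockout"

    def __post_init__(self):
        if self.name not in DESIGN_NAMES:
            raise InvalidParameterError(
                f"unknown design {self.name!r}; expected one of {DESIGN_NAMES}"
            )

    @property
    def informative_parent_sex(self) -> str:
        return MALE if self.name == BC2 else FEMALE

    @property
    def recurrent_parent_is_resistant(self) -> bool:
        return self.name == DOMINANCE


@dataclass
class Population:
    individuals: list[Individual]
    design: CrossDesign
    gmap: GenomeMap
    selected_flag: bool = False

    def __len__(self) -> int:
        return len(self.individuals)

    def r2_genotype_counts(self) -> dict[str, int]:
        counts = {R2_HOM_R: 0, R2_HET: 0, R2_HOM_S: 0}
        for ind in self.individuals:
            counts[ind.r2_genotype(self.gmap)] += 1
        return counts

    def r1_genotype_counts(self) -> dict[str, int]:
        counts = {R1_HOM: 0, R1_HET: 0}
        for ind in self.individuals:
            counts[ind.r1_genotype] += 1
        return counts


@dataclass(frozen=True)
class SelectionModel:
    """Genotype-dependent survival under a toxin dose.

    ``survival`` maps (R1 genotype, R2 genotype) to a survival probability in
    [0, 1]. Dose and genetic-background labels are carried for provenance
    only; the background dependence of dominance is expressed by supplying
    different heterozygote survival values, not inferred.
    """

    survival: dict[tuple[str, str], float]
    dose_label: str = ""
    background_label: str = ""

    def __post_init__(self):
        norm = {}
        for (r1, r2), w in self.survival.items():
            if not 0.0 <= w <= 1.0:
                raise InvalidParameterError(f"survival must be in [0,1], got {w}")
            norm[(r1, normalize_r2(r2))] = float(w)
        object.__setattr__(self, "survival", norm)

    def prob(self, r1_genotype: str, r2_genotype: str) -> float:
        key = (r1_genotype, normalize_r2(r2_genotype))
        try:
            return self.survival[key]
        except KeyError:
            raise SelectionModelError(
                f"selection model does not cover genotype {key}"
            ) from None

    @classmethod
    def against_s2s2(cls, w_het: float = 1.0, dose_label: str = "2 ug/cm2",
                     background_label: str = "") -> "SelectionModel":
        """Mapping-cross selection: susceptible homozygotes die, het survive.

        Covers the R1R1 background only (all mapping-cross individuals carry
        the knockout on both copies).
        """
        return cls(
            survival={
                (R1_HOM, R2_HOM_S): 0.0,
                (R1_HOM, R2_HET): w_het,
                (R1_HOM, R2_HOM_R): 1.0,
            },
            dose_label=dose_label,
            background_label=background_label,
        )

    @classmethod
    def dominance_dose(cls, w_het: float, w_hom: float = 1.0,
                       dose_label: str = "7 ug/cm2",
                       background_label: str = "") -> "SelectionModel":
        """High-dose selection on a dominance backcross (F1 x resistant).

        Survival is keyed on the R2 genotype; heterozygous-R1 individuals die
        (the R1 trait is recessive and its resistance alone does not rescue
        survival at the high dose).
        """
        surv = {}
        for r2, w in ((R2_HOM_R, w_hom), (R2_HET, w_het)):
            surv[(R1_HOM, r2)] = w
            surv[(R1_HET, r2)] = 0.0
        return cls(survival=surv, dose_label=dose_label, background_label=background_label)

    @classmethod
    def neutral(cls) -> "SelectionModel":
        surv = {}
        for r1 in (R1_HOM, R1_HET):
            for r2 in (R2_HOM_R, R2_HET, R2_HOM_S):
                surv[(r1, r2)] = 1.0
        return cls(survival=surv, dose_label="none")


# ---------------------------------------------------------------------------
# founders and gametes
# ---------------------------------------------------------------------------

def _uniform_haplotype(gmap: GenomeMap, allele: int) -> Haplotype:
    return {c.label: np.full(c.n_markers, allele, dtype=np.uint8) for c in gmap}


def founder_individual(gmap: GenomeMap, allele: str, sex: str,
                       r2_locus: tuple[str, int], r1_genotype: str = R1_HOM) -> Individual:
    """Fully homozygous founder; ``allele`` is 'R' or 'S'."""
    a = 1 if allele == "R" else 0
    return Individual(
        maternal=_uniform_haplotype(gmap, a),
        paternal=_uniform_haplotype(gmap, a),
        sex=sex,
        r2_locus=r2_locus,
        r1_genotype=r1_genotype,
    )


def f1_individual(gmap: GenomeMap, sex: str, r2_locus: tuple[str, int],
                  r1_genotype: str = R1_HOM) -> Individual:
    """F1 hybrid: one resistant-derived and one susceptible-derived haplotype."""
    return Individual(
        maternal=_uniform_haplotype(gmap, 0),
        paternal=_uniform_haplotype(gmap, 1),
        sex=sex,
        r2_locus=r2_locus,
        r1_genotype=r1_genotype,
    )


def simulate_gamete(parent: Individual, gmap: GenomeMap,
                    rng: np.random.Generator) -> Haplotype:
    """Draw one gamete haplotype from ``parent``.

    Female meiosis is achiasmatic: each chromosome of the gamete is an intact
    copy of one of the two parental homologs, chosen independently per
    chromosome. Male meiosis places crossovers per chromosome with a Poisson
    count of mean ``genetic_length / 100`` Morgans and positions uniform in
    genetic coordinates (no interference; Haldane model). With a uniform
    cM/bp map this is uniform in physical coordinates.
    """
    gamete: Haplotype = {}
    for chrom in gmap:
        mat = parent.maternal[chrom.label]
        pat = parent.paternal[chrom.label]
        if parent.sex == FEMALE:
            gamete[chrom.label] = (mat if rng.integers(2) == 0 else pat).copy()
            continue
        n_x = rng.poisson(chrom.genetic_length / 100.0)
        start = int(rng.integers(2))
        if n_x == 0:
            gamete[chrom.label] = (mat if start == 0 else pat).copy()
            continue
        breaks = np.sort(rng.uniform(0, chrom.physical_length, size=n_x))
        segment = np.searchsorted(breaks, chrom.markers)
        use_pat = (start + segment) % 2 == 1
        gamete[chrom.label] = np.where(use_pat, pat, mat).astype(np.uint8)
    return gamete


# ---------------------------------------------------------------------------
# crosses and selection
# ---------------------------------------------------------------------------

def make_backcross(design: CrossDesign | str, gmap: GenomeMap, n: int, seed: int = 0,
                   r2_locus: tuple[str, int] | None = None) -> Population:
    """Simulate ``n`` backcross offspring under one of the three designs.

    For the mapping designs the recurrent parent is the susceptible knockout
    strain, so offspring are S2S2 : R2S2 at the causal marker in expected
    ratio 1:1 and uniformly R1R1. For the dominance design the recurrent
    parent is the resistant strain: offspring are R2R2 : R2S2 1:1 at the
    causal marker, and independently R1R1 : R1S1 1:1 (the R1 locus segregates
    on another chromosome and is carried as a label).
    """
    if isinstance(design, str):
        design = CrossDesign(name=design)
    if n < 0:
        raise InvalidParameterError("n must be >= 0")
    if r2_locus is None:
        r2_locus = default_r2_locus(gmap)
    chrom_label, pos = r2_locus
    gmap[chrom_label].marker_index(pos)  # validates the causal marker exists

    rng = derive_rng(seed, "make_backcross", design.name)

    f1_sex = design.informative_parent_sex
    f1_r1 = R1_HOM if design.name != DOMINANCE else R1_HET
    f1 = f1_individual(gmap, sex=f1_sex, r2_locus=r2_locus, r1_genotype=f1_r1)
    recurrent_allele = "R" if design.recurrent_parent_is_resistant else "S"
    recurrent = founder_individual(
        gmap, recurrent_allele, sex=MALE if f1_sex == FEMALE else FEMALE,
        r2_locus=r2_locus,
    )
    mother, father = (f1, recurrent) if f1_sex == FEMALE else (recurrent, f1)

    individuals = []
    for _ in range(n):
        egg = simulate_gamete(mother, gmap, rng)
        sperm = simulate_gamete(father, gmap, rng)
        if design.name == DOMINANCE:
            # ABC-transporter locus: F1 is R1S1, recurrent parent R1R1.
            r1 = R1_HOM if rng.integers(2) == 0 else R1_HET
        else:
            r1 = R1_HOM
        individuals.append(
            Individual(
                maternal=egg,
                paternal=sperm,
                sex=FEMALE if rng.integers(2) == 0 else MALE,
                r2_locus=r2_locus,
                r1_genotype=r1,
            )
        )
    return Population(individuals=individuals, design=design, gmap=gmap)


def apply_selection(pop: Population, model: SelectionModel, seed: int = 0) -> Population:
    """Retain each individual independently with its genotype's survival."""
    rng = derive_rng(seed, "apply_selection", model.dose_label)
    survivors = []
    for ind in pop.individuals:
        w = model.prob(ind.r1_genotype, ind.r2_genotype(pop.gmap))
        if w >= 1.0 or rng.random() < w:
            survivors.append(ind)
    return Population(
        individuals=survivors, design=pop.design, gmap=pop.gmap, selected_flag=True
    )


def subsample_population(pop: Population, k: int, seed: int = 0) -> Population:
    """Random subsample of ``k`` individuals without replacement.

    Used to form control pools of the study's sizes; if ``k`` exceeds the
    population size, the whole population is returned.
    """
    if k >= len(pop):
        return replace(pop)
    rng = derive_rng(seed, "subsample_population", k)
    idx = rng.choice(len(pop), size=k, replace=False)
    return Population(
        individuals=[pop.individuals[i] for i in sorted(idx)],
        design=pop.design,
        gmap=pop.gmap,
        selected_flag=pop.selected_flag,
    )


# ---------------------------------------------------------------------------
# sequencing emulators
# ---------------------------------------------------------------------------

def _pool_frequencies(pop: Population) -> dict[str, np.ndarray]:
    """True pool frequency of the resistant-derived allele at every marker."""
    if not pop.individuals:
        raise EmptyPopulationError("cannot pool an empty population")
    n2 = 2.0 * len(pop)
    freqs = {}
    for chrom in pop.gmap:
        dosage = np.zeros(chrom.n_markers, dtype=np.int64)
        for ind in pop.individuals:
            dosage += ind.maternal[chrom.label]
            dosage += ind.paternal[chrom.label]
        freqs[chrom.label] = dosage / n2
    return freqs


def simulate_pool_counts(pop: Population, mean_depth: float = 1000.0,
                         error_rate: float = 0.001, seed: int = 0) -> pd.DataFrame:
    """Pooled whole-genome allele depths at every marker.

    Per marker, site depth is Poisson(``mean_depth``) and the resistant-allele
    depth is Binomial(depth, f') where ``f' = f(1-e) + (1-f)e`` applies a
    symmetric per-read allele-flip error ``e`` to the true pool frequency
    ``f``. Returns a DataFrame with columns ``chrom, pos, depth_R, depth_S``.
    """
    if mean_depth <= 0:
        raise InvalidParameterError("mean_depth must be positive")
    if not 0.0 <= error_rate < 0.5:
        raise InvalidParameterError("error_rate must be in [0, 0.5)")
    freqs = _pool_frequencies(pop)
    rng = derive_rng(seed, "simulate_pool_counts")
    frames = []
    for chrom in pop.gmap:
        f = freqs[chrom.label]
        p = f * (1.0 - error_rate) + (1.0 - f) * error_rate
        depth = rng.poisson(mean_depth, size=f.size)
        depth_r = rng.binomial(depth, p)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom.label,
                    "pos": chrom.markers,
                    "depth_R": depth_r,
                    "depth_S": depth - depth_r,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_amplicon_counts(pop: Population, amplicon_markers,
                             mean_reads: float = 38_000.0,
                             nonspecific_prob: float = 0.05,
                             read_sigma: float = 0.35,
                             offtarget_allele: str = "S",
                             seed: int = 0) -> pd.DataFrame:
    """Per-amplicon read counts for one pool at the given marker SNPs.

    Reads per amplicon are lognormal with mean ``mean_reads`` (shape
    ``read_sigma``). With probability ``nonspecific_prob`` an amplicon is
    contaminated by nonspecific PCR amplification: a fraction drawn
    Uniform(0.3, 0.9) of its reads derives from an off-target locus fixed for
    ``offtarget_allele``, distorting the apparent allele frequency. Such
    amplicons are what the control-pool AF filter of the fine-mapping stage
    is designed to remove.

    ``amplicon_markers`` is a sequence of (chrom, pos) marker pairs or a
    DataFrame with ``chrom``/``pos`` columns. Returns a DataFrame with
    columns ``amplicon_id, chrom, pos, depth_R, depth_S``.
    """
    if isinstance(amplicon_markers, pd.DataFrame):
        pairs = list(zip(amplicon_markers["chrom"], amplicon_markers["pos"]))
    else:
        pairs = [(str(c), int(p)) for c, p in amplicon_markers]
    if offtarget_allele not in ("R", "S"):
        raise InvalidParameterError("offtarget_allele must be 'R' or 'S'")
    freqs = _pool_frequencies(pop)
    f = np.array(
        [freqs[c][pop.gmap[c].marker_index(p)] for c, p in pairs], dtype=float
    )
    k = len(pairs)
    rng = derive_rng(seed, "simulate_amplicon_counts")
    mu = np.log(mean_reads) - read_sigma**2 / 2.0
    reads = np.maximum(1, rng.lognormal(mu, read_sigma, size=k).astype(np.int64))
    contaminated = rng.random(k) < nonspecific_prob
    frac = np.where(contaminated, rng.uniform(0.3, 0.9, size=k), 0.0)
    n_off = np.round(frac * reads).astype(np.int64)
    depth_r = rng.binomial(reads - n_off, f)
    if offtarget_allele == "R":
        depth_r = depth_r + n_off
    return pd.DataFrame(
        {
            "amplicon_id": np.arange(1, k + 1),
            "chrom": [c for c, _ in pairs],
            "pos": [p for _, p in pairs],
            "depth_R": depth_r,
            "depth_S": reads - depth_r,
        }
    )


def paired_amplicon_table(selected: pd.DataFrame, control: pd.DataFrame) -> pd.DataFrame:
    """Merge selected- and control-pool amplicon counts into the fine-mapping input."""
    sel = selected.rename(columns={"depth_R": "sel_depth_R", "depth_S": "sel_depth_S"})
    ctrl = control.rename(columns={"depth_R": "ctrl_depth_R", "depth_S": "ctrl_depth_S"})
    return sel.merge(ctrl, on=["amplicon_id", "chrom", "pos"], validate="one_to_one")


def simulate_expression_counts(n_genes: int, base_means, fold_changes,
                               dispersion: float, n_reps_per_strain: int,
                               gene_lengths, seed: int = 0,
                               strains: tuple[str, str] = ("susceptible", "resistant"),
                               total_mapped: float | None = None) -> ExpressionTable:
    """Negative-binomial expression counts for two strains.

    Strain-1 means are ``base_means``; strain-2 means are
    ``base_means * fold_changes``. Counts are NB with variance
    ``m + dispersion * m**2``. When ``total_mapped`` is given it is used as
    every sample's mapped-read total (as with genome-wide totals); otherwise
    totals default to column sums downstream.
    """
    base = np.broadcast_to(np.asarray(base_means, dtype=float), (n_genes,))
    fc = np.broadcast_to(np.asarray(fold_changes, dtype=float), (n_genes,))
    lengths = np.broadcast_to(np.asarray(gene_lengths, dtype=np.int64), (n_genes,))
    if np.any(base <= 0):
        raise InvalidParameterError("base means must be positive")
    if np.any(fc < 0):
        raise InvalidParameterError("fold changes must be >= 0")
    if dispersion <= 0:
        raise InvalidParameterError("dispersion must be positive")
    if n_reps_per_strain < 2:
        raise InvalidParameterError("need at least 2 replicates per strain")
    if np.any(lengths <= 0):
        raise InvalidParameterError("gene lengths must be positive")

    rng = derive_rng(seed, "simulate_expression_counts")
    size = 1.0 / dispersion  # NB shape parameter

    def _draw(means):
        out = np.zeros((n_genes, n_reps_per_strain), dtype=np.int64)
        pos = means > 0
        if np.any(pos):
            p = size / (size + means[pos])
            out[pos] = rng.negative_binomial(
                size, p[:, None], size=(int(pos.sum()), n_reps_per_strain)
            )
        return out

    counts = np.hstack([_draw(base), _draw(base * fc)])
    genes = [f"g{i + 1:03d}" for i in range(n_genes)]
    samples = [f"{s}_{r + 1}" for s in strains for r in range(n_reps_per_strain)]
    strain_of = [s for s in strains for _ in range(n_reps_per_strain)]
    totals = None
    if total_mapped is not None:
        totals = pd.Series(float(total_mapped), index=samples)
    return ExpressionTable(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        gene_lengths=pd.Series(lengths, index=genes),
        strains=pd.Series(strain_of, index=samples),
        totals=totals,
    )


def simulate_dominance_survivor_counts(n_offspring: int, w_het: float,
                                       w_hom: float = 1.0, seed: int = 0) -> tuple[int, int]:
    """Count-level dominance-backcross shortcut: (het survivors, hom-R survivors).

    Offspring genotypes are Binomial(n, 1/2) heterozygote vs resistant
    homozygote; survival is Bernoulli per genotype. Distributionally
    identical to the full cross + selection path at the causal marker, and
    fast enough for large estimator-consistency sweeps.
    """
    rng = derive_rng(seed, "simulate_dominance_survivor_counts")
    n_het = int(rng.binomial(n_offspring, 0.5))
    n_hom = n_offspring - n_het
    return int(rng.binomial(n_het, w_het)), int(rng.binomial(n_hom, w_hom))


def fragment_profile(ind: Individual, locus: str, gmap: GenomeMap) -> set[int]:
    """Diagnostic-PCR fragment sizes an individual would show at a locus.

    ABCC2 fragments follow the R1 genotype label; APN1 fragments follow the
    R2 genotype at the causal marker.
    """
    try:
        sizes = FRAGMENT_SIZES[locus]
    except KeyError:
        raise InvalidParameterError(f"unknown locus {locus!r}") from None
    if locus == "ABCC2":
        alleles = {"R"} if ind.r1_genotype == R1_HOM else {"R", "S"}
    else:
        geno = ind.r2_genotype(gmap)
        alleles = {R2_HOM_R: {"R"}, R2_HET: {"R", "S"}, R2_HOM_S: {"S"}}[geno]
    return {sizes[a] for a in alleles}
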