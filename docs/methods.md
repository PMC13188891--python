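# Methods

## Scope and model

`btmap` implements the analysis chain of a biphasic backcross mapping study of
an incompletely dominant Bt-toxin-resistance locus (called R2 throughout) in a
lepidopteran that also carries a recessive, major resistance locus (R1, an ABC
transporter knockout) on a different chromosome. The pipeline starts from
tabular sequencing summaries — pooled allele depths per SNP, per-amplicon read
counts, gene-level expression counts — not from reads; read processing,
alignment and variant calling are out of scope.

The simulator is a first-class component: its defaults define the study
conditions under which the analysis stages are validated.

## Cross and meiosis model

* Individuals carry two phased haplotypes over a marker map, one allele per
  marker, coded by strain of origin (resistant-derived vs
  susceptible/knockout-derived). The R2 genotype is read from the haplotypes at
  a designated causal marker. The R1 genotype is carried as a per-individual
  label (its chromosome is not simulated at marker resolution) and segregates
  independently, which is correct because the two loci are on different
  chromosomes.
* **Female meiosis is achiasmatic**: each gamete chromosome is an intact copy
  of one parental homolog, chosen independently per chromosome with
  probability 1/2.
* **Male meiosis** places a Poisson(genetic_length/100 Morgans) number of
  crossovers per chromosome, positions uniform in genetic coordinates, no
  interference (Haldane model). cM/bp is uniform within a chromosome.
* The default genome has 31 chromosomes plus an unanchored group `chr0`
  (32 labels), 12.5 Mb and 50 cM each. No public genetic map exists for this
  species; 50 cM (one expected crossover per bivalent per male meiosis) is a
  standard default and is configurable per chromosome. Because of this
  placeholder map, simulated fine-mapping intervals are *qualitatively* right
  (ΔAF decays with distance from the causal site; the interval contains it)
  but their widths are not calibrated to the real recombination landscape —
  at 4 cM/Mb the whole amplicon panel stays partially linked to the causal
  site, so simulated intervals are much wider than a real ~675 kb call.
* Three designs: female-informative backcross (F1 female × knockout male;
  linkage-group scan), male-informative backcross (F1 male × knockout female;
  fine mapping), and a dominance backcross (F1 × resistant strain). Default
  pool sizes mirror the study conditions: 160 selected / 86 control larvae for
  the scan cross, 253 / 257 for the fine-mapping cross.

## Selection

Survival is Bernoulli per individual with probability w(R1 genotype,
R2 genotype) ∈ [0, 1]. Two factory models cover the standard settings:
mapping-dose selection (susceptible R2 homozygotes die, heterozygotes survive)
and high-dose dominance selection (R1 heterozygotes die regardless of R2; R2
heterozygote survival `w_het` is the *generator's* dominance parameter). The
background dependence of dominance is an input of the simulator, never
something the package infers.

## Sequencing emulators

* **Pooled WGS**: per marker, depth ~ Poisson(mean_depth, default 1000);
  resistant-allele depth ~ Binomial(depth, f(1−e) + (1−f)e) with true pool
  frequency f and symmetric per-read allele-flip error e (default 0.001, the
  scale of Illumina substitution error; bias on AF is second order).
* **Amplicons**: reads per amplicon lognormal with mean 38,000 (the scale of
  real deep amplicon pools), shape 0.35. With probability `nonspecific_prob`
  (default 0.05) an amplicon is contaminated: a Uniform(0.3, 0.9) fraction of
  its reads comes from an off-target locus fixed for one allele. This is the
  failure mode the control-AF QC band is designed to catch.
* **Expression**: negative-binomial counts with variance m + αm² (dispersion
  α default 0.05, a typical within-strain biological CV² for inbred larval
  tissue), 6 replicates per strain, with strain-2 means = base × fold-change.

Not emulated: read-level errors tied to sequence context, mapping artifacts,
index hopping, batch effects, or library-size variation beyond the Poisson /
lognormal draws. Passing tests therefore demonstrate correctness of the
*analysis logic* under idealized sampling, not robustness to every real-data
pathology.

## Random numbers

One top-level integer seed; every stochastic operation draws from an
independent stream derived from (seed, operation label[, replicate]) via
CRC-32-hashed `SeedSequence` words. Reports exclude timestamps, so a given
(seed, config) reproduces byte-identical JSON.

## Linkage-group scan

AF = depth_R / (depth_R + depth_S); sites with zero depth are dropped. The SNP
filter removes AF < 0.05 or > 0.95 — strict inequalities, so boundary values
are retained. Densities use a Gaussian kernel with Silverman bandwidth
(overridable) on a fixed grid over [0, 1] with step 0.005, renormalized to
unit mass on [0, 1]; the peak is the grid argmax with ties broken to the
lower value. Zero-variance input raises by default (a tiny-jitter fallback is
available behind a flag). The call statistic is the absolute difference of
peak locations between pools — deliberately the simple peak-shift argument,
not a distribution distance; a Kolmogorov–Smirnov distance per chromosome is
available as a secondary diagnostic. Default call threshold 0.1, roughly
half the expected causal shift (0.25 → 0.5) and several times the
segregation-noise scale of peaks at the default pool sizes. Chromosomes with
fewer than 5 retained SNPs in either pool are dropped from the scan and
reported.

## Fine mapping

QC keeps amplicons with ≥ 500 total reads in both pools and a control-pool AF
inside [0.125, 0.5] (inclusive); the band is centred on the 0.25 expectation
for an unselected backcross pool and a control AF outside it indicates
nonspecific amplification. The paired test is a one-sided two-proportion
z-test (selected > control) on allele counts — at pooled depths in the
thousands the normal approximation is accurate to a few percent of the
p-value, verified against a Monte-Carlo two-binomial oracle. P-values are
Benjamini–Hochberg adjusted across retained amplicons; significance further
requires ΔAF ≥ 0.1 so that sheer depth cannot make a negligible shift
"significant". The interval spans the outermost significant SNP positions
(1-based inclusive; width displayed as round(bp/1000) kb). No gap-bridging:
all significant markers define one spanning interval, and significant markers
isolated between non-significant neighbours are listed as warnings rather
than trimmed. BED export converts to 0-based half-open coordinates.

## Dominance

Diagnostic-PCR fragment sizes map to genotypes per locus (ABC transporter:
susceptible 120 bp / resistant 102 bp; aminopeptidase N: resistant 327 bp /
susceptible 234 bp); both sizes together call a heterozygote. Segregation is
tested with a plain Pearson chi-square against 1:1 (df = 1). **No Yates
continuity correction**: the uncorrected statistic reproduces the standard
published two-decimal P values for backcross tables of this size, and the
corrected one does not; the correction is deliberately omitted. The
count-ratio estimator h = n_het/n_homR is applied only to toxin-selected rows
(it presumes w_SS = 0 and equal pre-selection genotype numbers, which the
unselected control rows verify via the 1:1 test). h is clamped to [0, 1] with
a warning — sampling noise can push the raw ratio above 1 — and the raw value
is retained. Display rounding is two decimals, round-half-even.

## Expression screen

RPKM = 1e9 × count / (gene length × mapped total). For toy or locus-restricted
tables the mapped total defaults to the column sum of the matrix — a
documented divergence from genome-wide totals, overridable via the table's
`totals` field (the simulator sets an explicit 10M-read total so RPKM is
meaningful even for single-gene tables). The expressed cutoff (mean RPKM ≥ 0.5
in at least one strain) is inclusive. The ratio test is a Welch
(unequal-variance) t-test on per-replicate RPKM values, untransformed: with
n = 6 per strain Welch is the safer default where the variance structure is
unknown; Student's/log-scale variants were considered and rejected as
defaults to keep one canonical path. The candidate rule (≥ 3-fold change and
p ≤ 0.01, per gene) is applied without multiplicity correction, mirroring a
per-gene screening rule over a few dozen locus genes; a BH-adjusted column is
emitted alongside for reference.

## Problem sizes in the test suite

The suite validates the pipeline at desk scale, chosen to keep every check
sharp at minimal cost: full-genome scans use 32 chromosomes × 200 markers with
320 offspring; allele-frequency expectations use 200+ markers at depth 1,000;
estimator-consistency sweeps use 500 replicates of n = 2,000 backcrosses via a
count-level shortcut that is distributionally identical to the full
individual-based path at the causal marker; fine-mapping recovery uses 100
seeded runs at the 48-amplicon panel geometry. Genome-scale SNP counts
(~10⁶ SNPs) and the study's observed data-specific values (e.g. an observed
selected-pool peak of 0.43, or specific expression percentages) are not
reproduction targets — the structural analogues above are.

## Known limitations

* The genetic map is a placeholder; interval *widths* from the simulator are
  not comparable to real fine-mapping resolution (see above).
* One diagnostic SNP per amplicon; no within-amplicon haplotype phasing.
* The AF orientation (which allele is resistant-derived) must be supplied for
  real VCF data via an orientation table; the simulator knows it by
  construction.
* No LC50 / probit bioassay fitting; dose–response enters only through the
  genotype-survival table.
* The peak-shift call has no formal significance test attached; the threshold
  plays that role, and the KS diagnostic is descriptive.
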