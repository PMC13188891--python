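"""End-to-end biphasic workflow on simulated data.

Chains the two mapping phases and the two companion analyses:

1. female-informative backcross + toxin selection + pooled sequencing →
   BSA-seq KDE scan → linkage-group call;
2. male-informative backcross on the amplicon panel → Amp-seq fine mapping →
   candidate interval;
3. dominance backcrosses under two genetic backgrounds → survivor genotype
   counts → chi-square and dominance h;
4. negative-binomial midgut expression counts for the locus genes →
   expression screen → candidate genes.

Everything is driven by one seed; reports are canonical JSON, byte-stable
for a given (seed, config).
"""

from __future__ import annotations

import numpy as np

from . import simulate as sim
from ._rng import spawn_seed
from .bsa import LinkageScan
from .config import RunConfig
from .dominance import DominanceAnalysis
from .expression import ExpressionScreen
from .finemap import FineMapping
from .genome import default_genome, default_r2_locus
from .panels import finemap_genome

#: Generator fold changes for the two differentially expressed locus genes
#: (strongly down-regulated aminopeptidase N 1, up-regulated aminopeptidase
#: N 6 in the resistant strain).
APN1_FOLD = 0.016
APN6_FOLD = 13.249


def run_bc1_scan(config: RunConfig, seed: int):
    """Phase 1: simulate BC1, select, pool, sequence, scan. Returns (results, truth)."""
    gmap = default_genome(
        markers_per_chromosome=config.markers_per_chromosome,
        genetic_length=config.genetic_length_cm,
    )
    r2_locus = default_r2_locus(gmap)
    pop = sim.make_backcross(sim.BC1, gmap, config.bc1_n_offspring,
                             seed=spawn_seed(seed, "bc1"), r2_locus=r2_locus)
    survivors = sim.apply_selection(pop, sim.SelectionModel.against_s2s2(),
                                    seed=spawn_seed(seed, "bc1-select"))
    sel_pool = sim.subsample_population(survivors, config.bc1_pool_selected,
                                        seed=spawn_seed(seed, "bc1-selpool"))
    ctrl_pool = sim.subsample_population(pop, config.bc1_pool_control,
                                         seed=spawn_seed(seed, "bc1-ctrlpool"))
    sel = sim.simulate_pool_counts(sel_pool, config.mean_depth, config.error_rate,
                                   seed=spawn_seed(seed, "bc1-selseq"))
    ctrl = sim.simulate_pool_counts(ctrl_pool, config.mean_depth, config.error_rate,
                                    seed=spawn_seed(seed, "bc1-ctrlseq"))
    scan = LinkageScan(
        sel, ctrl,
        af_bounds=(config.af_lower, config.af_upper),
        bandwidth=config.kde_bandwidth,
        grid_step=config.kde_grid_step,
        shift_threshold=config.shift_threshold,
    ).fit()
    return scan, {"true_chrom": r2_locus[0], "true_pos": r2_locus[1]}


def run_bc2_finemap(config: RunConfig, seed: int, causal_pos: int = 2_100_000):
    """Phase 2: simulate BC2 on the amplicon panel and fine-map. Returns (results, truth)."""
    gmap, r2_locus, amplicons = finemap_genome(
        causal_pos=causal_pos, genetic_length=config.genetic_length_cm
    )
    pop = sim.make_backcross(sim.BC2, gmap, config.bc2_n_offspring,
                             seed=spawn_seed(seed, "bc2"), r2_locus=r2_locus)
    survivors = sim.apply_selection(pop, sim.SelectionModel.against_s2s2(),
                                    seed=spawn_seed(seed, "bc2-select"))
    sel_pool = sim.subsample_population(survivors, config.bc2_pool_selected,
                                        seed=spawn_seed(seed, "bc2-selpool"))
    ctrl_pool = sim.subsample_population(pop, config.bc2_pool_control,
                                         seed=spawn_seed(seed, "bc2-ctrlpool"))
    sel = sim.simulate_amplicon_counts(
        sel_pool, amplicons, mean_reads=config.amplicon_mean_reads,
        nonspecific_prob=config.amplicon_nonspecific_prob,
        seed=spawn_seed(seed, "bc2-selamp"),
    )
    ctrl = sim.simulate_amplicon_counts(
        ctrl_pool, amplicons, mean_reads=config.amplicon_mean_reads,
        nonspecific_prob=config.amplicon_nonspecific_prob,
        seed=spawn_seed(seed, "bc2-ctrlamp"),
    )
    table = sim.paired_amplicon_table(sel, ctrl)
    results = FineMapping(
        table,
        min_reads=config.min_amplicon_reads,
        ctrl_bounds=(config.ctrl_af_lower, config.ctrl_af_upper),
        alpha=config.finemap_alpha,
        min_delta=config.min_delta_af,
    ).fit()
    return results, {"true_chrom": r2_locus[0], "true_pos": r2_locus[1]}


def run_dominance(config: RunConfig, seed: int,
                  backgrounds: dict[str, float] | None = None):
    """Phase 3: dominance backcrosses per genetic background.

    ``backgrounds`` maps a background label to the heterozygote survival used
    by the generator (default: an incompletely recessive and an incompletely
    dominant background).
    """
    import pandas as pd

    if backgrounds is None:
        backgrounds = {"background-A": 0.23, "background-B": 0.92}
    gmap = default_genome(markers_per_chromosome=4, n_anchored=9,
                          include_unanchored=False)
    r2_locus = default_r2_locus(gmap)
    rows = []
    for label, w_het in backgrounds.items():
        pop = sim.make_backcross(sim.DOMINANCE, gmap, config.dominance_n_offspring,
                                 seed=spawn_seed(seed, "dom", label), r2_locus=r2_locus)
        model = sim.SelectionModel.dominance_dose(w_het=w_het, background_label=label)
        survivors = sim.apply_selection(pop, model, seed=spawn_seed(seed, "dom-sel", label))
        for dose, group in (("0", pop), ("250 ug/mL", survivors)):
            counts = {"RR": 0, "RS": 0, "SS": 0}
            for ind in group.individuals:
                geno = sim.fragment_profile(ind, "APN1", gmap)
                from .dominance import FragmentProfile, genotype_from_fragments

                counts[genotype_from_fragments(FragmentProfile("APN1", geno))] += 1
            rows.append(
                {"family": label, "selection_dose": dose,
                 "n_hom_R": counts["RR"], "n_het": counts["RS"]}
            )
    return DominanceAnalysis(pd.DataFrame(rows)).fit(), backgrounds


def locus_expression_table(config: RunConfig, seed: int,
                           n_genes: int = 37, n_expressed: int = 25):
    """Simulated expression counts for the locus genes.

    ``n_expressed`` genes get base means spanning RPKM ~0.75-1,360 at a
    10M-read library and 2-kb transcripts; the rest sit below the detection
    cutoff. Two genes are differentially expressed: a strongly down-regulated
    one (APN1-like fold) and an up-regulated one (APN6-like fold).
    """
    total = 1e7
    length = 2000
    # RPKM = count/ (length/1e3 * total/1e6) = count / 20 at these settings
    expressed_means = np.geomspace(15, 27_200, n_expressed)
    silent_means = np.full(n_genes - n_expressed, 2.0)
    base = np.concatenate([expressed_means, silent_means])
    fold = np.ones(n_genes)
    down_idx = int(np.argmin(np.abs(expressed_means - 5000)))
    up_idx = int(np.argmin(np.abs(expressed_means - 50)))
    fold[down_idx] = APN1_FOLD
    fold[up_idx] = APN6_FOLD
    table = sim.simulate_expression_counts(
        n_genes=n_genes, base_means=base, fold_changes=fold,
        dispersion=config.expression_dispersion,
        n_reps_per_strain=config.expression_reps,
        gene_lengths=length, seed=spawn_seed(seed, "expression"),
        total_mapped=total,
    )
    genes = table.counts.index
    return table, {"down": genes[down_idx], "up": genes[up_idx]}


def run_demo(seed: int = 0, config: RunConfig | None = None) -> dict:
    """Full biphasic workflow on simulated data; returns the JSON report body."""
    config = config or RunConfig(seed=seed)
    scan, truth1 = run_bc1_scan(config, seed)
    finemap, truth2 = run_bc2_finemap(config, seed)
    dom, backgrounds = run_dominance(config, seed)
    table, perturbed = locus_expression_table(config, seed)
    screen = ExpressionScreen(
        table, cutoff=config.rpkm_cutoff, fold=config.candidate_fold,
        alpha=config.expression_alpha,
    ).fit()
    return {
        "seed": seed,
        "config": config.asdict(),
        "linkage_scan": {
            **scan.to_json_dict(),
            "true_chrom": truth1["true_chrom"],
        },
        "fine_mapping": {
            **finemap.to_json_dict(),
            "true_pos": truth2["true_pos"],
        },
        "dominance": {
            **dom.to_json_dict(),
            "generator_w_het": backgrounds,
        },
        "expression": {
            "n_genes": len(screen.per_gene),
            "n_expressed": int(len(screen.expressed_genes)),
            "candidates": list(screen.candidates),
            "perturbed_genes": {k: str(v) for k, v in perturbed.items()},
        },
    }
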