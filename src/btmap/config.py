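"""Run configuration: defaults for the whole two-phase workflow.

Defaults mirror the study conditions: BC1 pools of 160 selected / 86 control
larvae, BC2 pools of 253 / 257, ~38,000 reads per amplicon, the 0.05/0.95
SNP-frequency filter, the 500-read and 0.125/0.5 amplicon QC thresholds, the
RPKM 0.5 expression cutoff and the 3-fold / P 0.01 candidate rule.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .exceptions import InvalidParameterError


@dataclass
class RunConfig:
    seed: int = 0

    # cross / pool sizes
    bc1_n_offspring: int = 320
    bc1_pool_selected: int = 160
    bc1_pool_control: int = 86
    bc2_n_offspring: int = 510
    bc2_pool_selected: int = 253
    bc2_pool_control: int = 257
    dominance_n_offspring: int = 500

    # genome
    markers_per_chromosome: int = 200
    genetic_length_cm: float = 50.0

    # sequencing
    mean_depth: float = 1000.0
    error_rate: float = 0.001
    amplicon_mean_reads: float = 38_000.0
    amplicon_nonspecific_prob: float = 0.05

    # BSA-seq scan
    af_lower: float = 0.05
    af_upper: float = 0.95
    kde_bandwidth: str | float = "silverman"
    kde_grid_step: float = 0.005
    shift_threshold: float = 0.1

    # fine mapping
    min_amplicon_reads: int = 500
    ctrl_af_lower: float = 0.125
    ctrl_af_upper: float = 0.5
    finemap_alpha: float = 0.01
    min_delta_af: float = 0.1

    # expression screen
    rpkm_cutoff: float = 0.5
    candidate_fold: float = 3.0
    expression_alpha: float = 0.01
    expression_dispersion: float = 0.05
    expression_reps: int = 6

    def __post_init__(self):
        for lo, hi, name in (
            (self.af_lower, self.af_upper, "af filter"),
            (self.ctrl_af_lower, self.ctrl_af_upper, "control AF band"),
        ):
            if not 0.0 <= lo < hi <= 1.0:
                raise InvalidParameterError(f"{name}: need 0 <= lower < upper <= 1")
        if not 0.0 <= self.error_rate < 0.5:
            raise InvalidParameterError("error_rate must be in [0, 0.5)")
        for name in ("finemap_alpha", "expression_alpha"):
            a = getattr(self, name)
            if not 0.0 < a <= 1.0:
                raise InvalidParameterError(f"{name} must be in (0, 1]")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def asdict(self) -> dict:
        return asdict(self)
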