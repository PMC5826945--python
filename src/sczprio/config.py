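"""Pipeline configuration: thresholds, permutation counts, seed, and the
early/late developmental windows.

Ages are post-conception days throughout.  The default early window ends at
4 months after birth (~386 days post conception) and the late window starts
at 8 years (~3,186 days); samples between the windows do not enter the
early-vs-late comparison.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass(frozen=True)
class PipelineConfig:
    #: eQTL p-value below which a SNP counts as an eSNP of a gene
    esnp_p_threshold: float = 1e-5
    #: prior variance W of the standardized effect under association
    lbf_prior_variance_w: float = 0.15
    #: cis-eQTL p-value required of an SMR instrument
    smr_instrument_p_threshold: float = 5e-8
    #: |Pearson r| above which a gene pair is connected in co-expression
    coexpr_r_threshold: float = 0.8
    #: matched-random-set permutations for the network/pattern tests
    n_permutations: int = 1000
    #: Monte-Carlo null draws for the gene-level LBF p-value
    n_null_draws_lbf: int = 10000
    rng_seed: int = 0
    #: end of the embryonic/fetal window, post-conception days
    early_stage_max: float = 386.0
    #: start of the childhood/adult window, post-conception days
    late_stage_min: float = 3186.0
    #: family-wise error rate for Bonferroni-corrected calls
    alpha: float = 0.05
    #: classical pooled-variance Student t (True) vs Welch (False)
    de_equal_var: bool = True

    def __post_init__(self):
        for name in ("esnp_p_threshold", "smr_instrument_p_threshold", "alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must be in (0, 1), got {v!r}")
        if not (0.0 < self.coexpr_r_threshold < 1.0):
            raise ValidationError("coexpr_r_threshold must be in (0, 1)")
        if self.lbf_prior_variance_w <= 0:
            raise ValidationError("lbf_prior_variance_w must be positive")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.n_null_draws_lbf < 100:
            raise ValidationError("n_null_draws_lbf must be >= 100")
        if not self.early_stage_max < self.late_stage_min:
            raise ValidationError("early_stage_max must be < late_stage_min")

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} is not a key/value mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
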