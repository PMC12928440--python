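"""Pipeline configuration with the workflow's canonical thresholds."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class PipelineConfig:
    """All stage parameters in one declarative object.

    Defaults are the workflow's canonical thresholds: similarity hits kept
    at e-value < 1e-5, identity >= 70%, alignment length >= 60 bp, <= 25%
    repeat content; Ks window [0.01, 3); blocks of >= 5 pairs with gaps
    <= 100 genes (<= 20 for painting); 1000 bootstrap replicates with
    0.5 support / 0.05 margin; clock rate 6.5e-9 subs/site/year.
    """

    seed: int = 0
    # homology filters
    max_evalue: float = 1e-5
    min_identity: float = 70.0
    min_length: int = 60
    max_repeat_fraction: float = 0.25
    # Ks
    ks_min: float = 0.01
    ks_max: float = 3.0
    mixture_k_range: list = field(default_factory=lambda: [1, 2, 3, 4, 5])
    convergence_tol: float = 0.001
    n_bootstrap: int = 1000
    # synteny
    min_pairs: int = 5
    max_gap: int = 100
    painting_max_gap: int = 20
    # karyotype
    support_min: float = 0.5
    margin_min: float = 0.05
    min_segment: int = 5
    ambiguity_threshold: float = 0.5
    ambiguity_window: int = 10
    # clock
    mu: float = 6.5e-9

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(source)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def override(self, **kwargs) -> "PipelineConfig":
        data = asdict(self)
        for key, value in kwargs.items():
            if value is None:
                continue
            if key not in data:
                raise KeyError(f"unknown config key {key!r}")
            data[key] = value
        return PipelineConfig(**data)
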