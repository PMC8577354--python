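"""Pipeline run configuration with lossless YAML round-trip."""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclasses.dataclass
class RunConfig:
    """Every knob of the pipeline, with a default for each field.

    CLI flags mirror these fields 1:1; a config round-trips to YAML
    losslessly.
    """

    # inputs
    expression: str | None = None
    clinical: str | None = None
    panel: str | None = None
    signatures: str | None = None  # TSV/GMT path; None = built-in registry
    # preprocessing
    already_log2: bool = False
    normalize: bool = True
    pseudocount: float = 1.0
    duplicate_genes: str = "mean"
    # scoring
    min_coverage: float = 1.0
    ratio_numerator: str = "ECM_STROMAL"
    ratio_denominator: str = "IA"
    ratio_mode: str = "rank_ratio"
    # correlation
    alpha: float = 0.05
    adjust: str | None = None
    # survival
    minprop: float = 0.1
    pmethod: str = "lausen_approx"
    cut_stat: str = "scores"
    n_perm: int = 1000
    # secretome
    fold_threshold: float = 5.0
    interaction_tolerance: float = 0.25
    vehicle_floor: float | None = None
    top_k: int = 10
    rank_by: str = "combo"
    # run
    seed: int = 0
    outdir: str = "results"

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValidationError("config YAML must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        """Stable digest of the analysis-relevant fields.

        The output directory is excluded: two runs of the same analysis
        into different directories share a hash (and a bundle).
        """
        fields = dataclasses.asdict(self)
        fields.pop("outdir")
        return hashlib.sha256(yaml.safe_dump(fields, sort_keys=True).encode()).hexdigest()[:16]
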