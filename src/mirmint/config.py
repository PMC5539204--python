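"""Pipeline configuration: input paths, thresholds and the YAML round-trip."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs.

    Paths
    -----
    gene_expression, mirna_ct, sample_map, predictions, gene_sets : required
    inputs; ppi is an optional gene-gene interaction table (gene_1, gene_2).

    Thresholds
    ----------
    fc_cut, p_cut, use_adjusted : DE filter for genes and miRNAs (linear fold
    change >= 1, p in (0, 1]).
    min_algorithms, accept_validated : consensus-target retention rule.
    n_permutations : randomization-test resamples for the miRNA stage.
    enrichment_p_cutoff, kappa_threshold, min_overlap : enrichment stage.
    n_references : how many geNorm-top reference small RNAs normalize the
    miRNA Ct data.
    """

    gene_expression: str
    mirna_ct: str
    sample_map: str
    predictions: str
    gene_sets: str
    output_dir: str
    ppi: str | None = None
    reference_mirnas: tuple[str, ...] = ()
    control_group: str = "control"
    case_group: str = "case"
    fc_cut: float = 1.5
    p_cut: float = 0.05
    use_adjusted: bool = False
    quantile_normalization: bool = True
    min_algorithms: int = 4
    accept_validated: bool = True
    n_permutations: int = 10_000
    n_references: int = 4
    enrichment_p_cutoff: float = 0.001
    kappa_threshold: float = 0.3
    min_overlap: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.fc_cut < 1:
            raise ConfigurationError(f"fc_cut must be >= 1, got {self.fc_cut}")
        if not (0 < self.p_cut <= 1):
            raise ConfigurationError(f"p_cut must be in (0, 1], got {self.p_cut}")
        if not (0 < self.enrichment_p_cutoff <= 1):
            raise ConfigurationError(f"enrichment_p_cutoff must be in (0, 1], got {self.enrichment_p_cutoff}")
        if not (-1 <= self.kappa_threshold <= 1):
            raise ConfigurationError(f"kappa_threshold must be in [-1, 1], got {self.kappa_threshold}")
        if self.min_algorithms < 1:
            raise ConfigurationError(f"min_algorithms must be >= 1, got {self.min_algorithms}")
        if self.n_permutations < 1:
            raise ConfigurationError(f"n_permutations must be >= 1, got {self.n_permutations}")
        if self.n_references < 1:
            raise ConfigurationError(f"n_references must be >= 1, got {self.n_references}")
        if self.min_overlap < 0:
            raise ConfigurationError(f"min_overlap must be >= 0, got {self.min_overlap}")
        self.reference_mirnas = tuple(self.reference_mirnas)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["reference_mirnas"] = list(self.reference_mirnas)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} does not hold a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config field(s) {sorted(unknown)}")
        return cls(**raw)

    def required_inputs(self) -> dict[str, Path]:
        req = {
            "gene_expression": Path(self.gene_expression),
            "mirna_ct": Path(self.mirna_ct),
            "sample_map": Path(self.sample_map),
            "predictions": Path(self.predictions),
            "gene_sets": Path(self.gene_sets),
        }
        if self.ppi:
            req["ppi"] = Path(self.ppi)
        return req
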