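"""Synthetic datasets with planted ground truth for every pipeline input.

The generator emulates a two-group (control vs cachectic) muscle-wasting
expression study: a gene matrix and a miRNA matrix on the log2 scale with a
fraction of features carrying a planted group effect, a set of true
miRNA -> gene regulatory edges joining differentially expressed miRNAs to
oppositely-directed differentially expressed genes, noisy multi-algorithm
target-prediction tables over those edges, curated validated-target rows
(noiseless subsets of the true edges), gene-set collections with planted
enriched sets, qPCR amplification curves with known efficiency, and a
candidate reference-gene panel with planted stable members.

All randomness flows from a single seed, split into fixed per-generator
substreams (expression = 0, predictions = 1, gene sets = 2, curves = 3,
reference panel = 4) so each generator is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .qpcr import AmplificationCurve

__all__ = [
    "SyntheticConfig",
    "PlantedTruth",
    "generate_expression_dataset",
    "generate_amplification_curves",
    "generate_prediction_tables",
    "generate_gene_sets",
    "generate_reference_panel",
    "expression_to_ct",
    "write_dataset",
]

_STREAMS = {"expression": 0, "predictions": 1, "gene_sets": 2, "curves": 3, "reference_panel": 4}

# Ct offset used to carry log2 abundance onto the Ct scale (Ct = offset - log2 signal)
CT_OFFSET = 30.0


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the synthetic two-group experiment.

    Defaults emulate the monocrotaline rat cachexia design at desk scale:
    two groups of 6 animals, a gene panel scaled down from a ~17k-transcript
    array and a miRNA panel scaled down from a 373-miRNA card, ~7.5% of
    genes and ~5% of miRNAs differentially expressed, |log2FC| = 1.5,
    residual SD 0.5 on the log2 scale, and 7 evidence sources (5 prediction
    algorithms + 2 curated validated-target databases).
    """

    n_genes: int = 2000
    n_mirnas: int = 120
    n_samples_per_group: int = 6
    frac_de_genes: float = 0.075
    frac_de_mirnas: float = 0.05
    effect_log2fc: float = 1.5
    noise_sd: float = 0.5
    n_algorithms: int = 7
    targets_per_mirna: int = 12
    prediction_sensitivity: float = 0.9
    prediction_fpr: float = 0.005
    n_gene_sets: int = 50
    genes_per_set: int = 20
    n_enriched_sets: int = 5
    enriched_member_fraction: float = 0.8
    n_reference_small_rnas: int = 4
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_genes": self.n_genes,
            "n_mirnas": self.n_mirnas,
            "n_samples_per_group": self.n_samples_per_group,
            "n_algorithms": self.n_algorithms,
            "targets_per_mirna": self.targets_per_mirna,
            "n_gene_sets": self.n_gene_sets,
            "genes_per_set": self.genes_per_set,
        }
        for name, v in counts.items():
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigurationError(f"{name} must be an integer >= 1, got {v!r}")
        if self.n_algorithms < 3:
            raise ConfigurationError("n_algorithms must be >= 3 (>= 1 prediction + 2 validated sources)")
        props = {
            "frac_de_genes": self.frac_de_genes,
            "frac_de_mirnas": self.frac_de_mirnas,
            "prediction_sensitivity": self.prediction_sensitivity,
            "prediction_fpr": self.prediction_fpr,
            "enriched_member_fraction": self.enriched_member_fraction,
        }
        for name, v in props.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v!r}")
        if self.effect_log2fc <= 0:
            raise ConfigurationError(f"effect_log2fc must be > 0, got {self.effect_log2fc!r}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd!r}")
        if self.n_enriched_sets < 0 or self.n_enriched_sets > self.n_gene_sets:
            raise ConfigurationError("n_enriched_sets must be in [0, n_gene_sets]")
        if self.genes_per_set > self.n_genes:
            raise ConfigurationError(
                f"genes_per_set ({self.genes_per_set}) exceeds n_genes ({self.n_genes})"
            )
        if self.n_reference_small_rnas < 1:
            raise ConfigurationError("n_reference_small_rnas must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth planted by the generator.

    Directions are +1 (up in the case group) or -1 (down); every true edge
    joins a DE miRNA to a DE gene of the opposite direction.
    """

    gene_directions: dict[str, int]
    mirna_directions: dict[str, int]
    true_edges: frozenset[tuple[str, str]]
    enriched_set_ids: tuple[str, ...] = field(default_factory=tuple)
    reference_mirnas: tuple[str, ...] = field(default_factory=tuple)

    @property
    def de_gene_ids(self) -> set[str]:
        return set(self.gene_directions)

    @property
    def de_mirna_ids(self) -> set[str]:
        return set(self.mirna_directions)

    def genes_up(self) -> list[str]:
        return sorted(g for g, d in self.gene_directions.items() if d > 0)

    def genes_down(self) -> list[str]:
        return sorted(g for g, d in self.gene_directions.items() if d < 0)

    def mirnas_up(self) -> list[str]:
        return sorted(m for m, d in self.mirna_directions.items() if d > 0)

    def mirnas_down(self) -> list[str]:
        return sorted(m for m, d in self.mirna_directions.items() if d < 0)

    def to_dict(self) -> dict:
        return {
            "gene_directions": self.gene_directions,
            "mirna_directions": self.mirna_directions,
            "true_edges": sorted(list(e) for e in self.true_edges),
            "enriched_set_ids": list(self.enriched_set_ids),
            "reference_mirnas": list(self.reference_mirnas),
        }


def _feature_ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _pick_de(rng: np.random.Generator, ids: list[str], frac: float) -> dict[str, int]:
    n_de = int(round(frac * len(ids)))
    if n_de == 0:
        return {}
    chosen = rng.choice(len(ids), size=n_de, replace=False)
    chosen.sort()
    directions = {}
    for j, idx in enumerate(chosen):
        # alternate directions deterministically after a random shuffle so
        # both directions are populated whenever n_de >= 2
        directions[ids[idx]] = 1 if j % 2 == 0 else -1
    # shuffle which half is up vs down
    if rng.random() < 0.5:
        directions = {k: -v for k, v in directions.items()}
    return directions


def generate_expression_dataset(config: SyntheticConfig):
    """Generate (gene matrix, miRNA matrix, truth) on the log2 scale.

    Values are baseline + group * direction * effect_log2fc + N(0, noise_sd);
    the case-group columns carry the planted effect.  The miRNA matrix
    additionally contains ``n_reference_small_rnas`` stable normalizer
    features (ids prefixed ``ref_``) with no group effect.
    """
    rng = _rng(config.seed, "expression")
    n = config.n_samples_per_group
    samples = [f"ct_{i}" for i in range(1, n + 1)] + [f"cc_{i}" for i in range(1, n + 1)]
    group = np.array([0] * n + [1] * n)

    gene_ids = _feature_ids("gene_", config.n_genes)
    mirna_ids = _feature_ids("mir_", config.n_mirnas)
    ref_ids = [f"ref_smallrna_{i}" for i in range(1, config.n_reference_small_rnas + 1)]

    gene_dir = _pick_de(rng, gene_ids, config.frac_de_genes)
    mirna_dir = _pick_de(rng, mirna_ids, config.frac_de_mirnas)

    def _matrix(ids, directions, base_lo, base_hi):
        baseline = rng.uniform(base_lo, base_hi, size=len(ids))
        effect = np.array([directions.get(f, 0) for f in ids], dtype=float) * config.effect_log2fc
        noise = rng.normal(0.0, config.noise_sd, size=(len(ids), 2 * n)) if config.noise_sd > 0 else 0.0
        values = baseline[:, None] + effect[:, None] * group[None, :] + noise
        return pd.DataFrame(values, index=ids, columns=samples)

    genes = _matrix(gene_ids, gene_dir, 6.0, 12.0)
    mirnas = _matrix(mirna_ids, mirna_dir, 4.0, 10.0)
    refs = _matrix(ref_ids, {}, 8.0, 10.0)
    mirnas = pd.concat([mirnas, refs])

    # true edges: each DE miRNA regulates targets of the opposite direction
    up_genes, down_genes = [], []
    for g, d in gene_dir.items():
        (up_genes if d > 0 else down_genes).append(g)
    up_genes.sort()
    down_genes.sort()
    edges = set()
    for m in sorted(mirna_dir):
        pool = down_genes if mirna_dir[m] > 0 else up_genes
        if not pool:
            raise ConfigurationError(
                "frac_de_genes too small: no DE gene available with direction opposite "
                f"to miRNA {m!r}"
            )
        k = min(config.targets_per_mirna, len(pool))
        chosen = rng.choice(len(pool), size=k, replace=False)
        for idx in sorted(chosen):
            edges.add((m, pool[idx]))

    truth = PlantedTruth(
        gene_directions=gene_dir,
        mirna_directions=mirna_dir,
        true_edges=frozenset(edges),
        reference_mirnas=tuple(ref_ids),
    )
    return genes, mirnas, truth


def generate_amplification_curves(
    efficiency: float,
    f0: float = 1e-3,
    n_cycles: int = 40,
    noise_sd: float = 0.0,
    plateau_cycle: int = 30,
    seed: int = 0,
    well: str = "well_1",
) -> AmplificationCurve:
    """Simulate one amplification curve with known efficiency.

    fluorescence(c) = f0 * efficiency**c for c < plateau_cycle, constant at
    the plateau level afterwards, with multiplicative log-normal noise of
    log-scale SD ``noise_sd``.
    """
    if not (1.0 < efficiency <= 2.0):
        raise InputError(f"efficiency must be in (1, 2], got {efficiency}")
    if f0 <= 0:
        raise InputError("f0 must be > 0")
    if noise_sd < 0:
        raise InputError("noise_sd must be >= 0")
    cycles = np.arange(1, n_cycles + 1)
    exponent = np.minimum(cycles, plateau_cycle).astype(float)
    fluo = f0 * efficiency**exponent
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fluo = fluo * np.exp(rng.normal(0.0, noise_sd, size=fluo.shape))
    return AmplificationCurve(well=well, cycles=cycles, fluorescence=fluo)


def algorithm_names(config: SyntheticConfig) -> tuple[list[str], list[str]]:
    """Evidence-source names: (prediction algorithms, validated databases)."""
    n_pred = config.n_algorithms - 2
    return [f"pred_algo_{i}" for i in range(1, n_pred + 1)], ["validated_db_1", "validated_db_2"]


def generate_prediction_tables(truth: PlantedTruth, config: SyntheticConfig) -> pd.DataFrame:
    """Emulate multi-algorithm target-prediction output over the truth.

    Each prediction algorithm reports every true edge with probability
    ``prediction_sensitivity`` and every false (miRNA, gene) pair with
    probability ``prediction_fpr``.  The two validated databases emit
    noiseless subsets of the true edges (each edge with probability
    ``prediction_sensitivity``), flagged validated.
    """
    rng = _rng(config.seed, "predictions")
    pred_names, val_names = algorithm_names(config)

    mirna_ids = _feature_ids("mir_", config.n_mirnas)
    gene_ids = _feature_ids("gene_", config.n_genes)
    true_edges = sorted(truth.true_edges)
    true_idx = {
        (m, g) for m, g in true_edges
    }

    rows: list[tuple[str, str, str, int]] = []
    n_pairs = len(mirna_ids) * len(gene_ids)
    for algo in pred_names:
        if config.prediction_sensitivity > 0:
            hits = rng.random(len(true_edges)) < config.prediction_sensitivity
            for (m, g), h in zip(true_edges, hits):
                if h:
                    rows.append((m, g, algo, 0))
        if config.prediction_fpr > 0:
            n_false = rng.binomial(n_pairs, config.prediction_fpr)
            seen = set()
            while len(seen) < n_false:
                draw = rng.integers(0, n_pairs, size=n_false - len(seen))
                for flat in draw:
                    pair = (mirna_ids[flat // len(gene_ids)], gene_ids[flat % len(gene_ids)])
                    if pair not in true_idx:
                        seen.add(pair)
                    if len(seen) == n_false:
                        break
            for m, g in sorted(seen):
                rows.append((m, g, algo, 0))
    for db in val_names:
        hits = rng.random(len(true_edges)) < config.prediction_sensitivity
        for (m, g), h in zip(true_edges, hits):
            if h:
                rows.append((m, g, db, 1))

    return pd.DataFrame(rows, columns=["mirna", "gene", "algorithm", "validated"])


def generate_gene_sets(truth: PlantedTruth, config: SyntheticConfig):
    """Gene-set collection with planted enriched sets.

    The first ``n_enriched_sets`` sets draw ``enriched_member_fraction`` of
    their members from planted DE genes (the rest uniformly from non-DE
    genes); remaining sets are uniform draws from all genes.
    """
    from .enrich import GeneSetCollection

    rng = _rng(config.seed, "gene_sets")
    gene_ids = _feature_ids("gene_", config.n_genes)
    de = sorted(truth.de_gene_ids)
    non_de = sorted(set(gene_ids) - set(de))

    sets: dict[str, tuple[str, list[str]]] = {}
    enriched_ids = []
    for i in range(1, config.n_enriched_sets + 1):
        n_from_de = int(round(config.enriched_member_fraction * config.genes_per_set))
        n_from_de = min(n_from_de, len(de))
        n_rest = config.genes_per_set - n_from_de
        members = []
        if n_from_de:
            members += [de[j] for j in rng.choice(len(de), size=n_from_de, replace=False)]
        if n_rest:
            members += [non_de[j] for j in rng.choice(len(non_de), size=min(n_rest, len(non_de)), replace=False)]
        term = f"set_enriched_{i:03d}"
        sets[term] = ("planted enriched set", sorted(set(members)))
        enriched_ids.append(term)
    for i in range(1, config.n_gene_sets - config.n_enriched_sets + 1):
        members = [gene_ids[j] for j in rng.choice(len(gene_ids), size=config.genes_per_set, replace=False)]
        sets[f"set_background_{i:03d}"] = ("background set", sorted(set(members)))

    collection = GeneSetCollection(sets)
    truth_with_sets = PlantedTruth(
        gene_directions=truth.gene_directions,
        mirna_directions=truth.mirna_directions,
        true_edges=truth.true_edges,
        enriched_set_ids=tuple(enriched_ids),
        reference_mirnas=truth.reference_mirnas,
    )
    return collection, truth_with_sets


def generate_reference_panel(
    n_candidates: int = 16,
    n_stable: int = 3,
    n_samples: int = 12,
    stable_sd: float = 0.2,
    unstable_sd: float = 1.0,
    sample_shift_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Candidate reference-gene Ct panel with planted stable members.

    Every candidate shares a per-sample shift (loading/input variation,
    which geNorm ratios cancel); stable candidates add N(0, stable_sd) Ct
    noise, unstable ones N(0, unstable_sd).  Returns a tidy Ct table and the
    planted stable candidate ids.
    """
    if n_stable > n_candidates:
        raise ConfigurationError("n_stable cannot exceed n_candidates")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS["reference_panel"],)))
    ids = [f"cand_{i:02d}" for i in range(1, n_candidates + 1)]
    stable = sorted(rng.choice(ids, size=n_stable, replace=False))
    samples = [f"s_{i:02d}" for i in range(1, n_samples + 1)]
    shift = rng.normal(0.0, sample_shift_sd, size=n_samples)
    base = rng.uniform(18.0, 26.0, size=n_candidates)
    rows = []
    for i, cand in enumerate(ids):
        sd = stable_sd if cand in stable else unstable_sd
        ct = base[i] + shift + rng.normal(0.0, sd, size=n_samples)
        rows += [(samples[j], cand, float(ct[j])) for j in range(n_samples)]
    return pd.DataFrame(rows, columns=["sample", "target", "ct"]), list(stable)


def expression_to_ct(matrix: pd.DataFrame, offset: float = CT_OFFSET) -> pd.DataFrame:
    """Carry a log2 abundance matrix onto the Ct scale (tidy table).

    Ct = offset - log2 signal: one amplification cycle per doubling of
    template, lower Ct = more template (assumes E = 2).
    """
    tidy = matrix.reset_index(names="target").melt(id_vars="target", var_name="sample", value_name="ct")
    tidy["ct"] = offset - tidy["ct"]
    return tidy[["sample", "target", "ct"]]


def write_dataset(config: SyntheticConfig, out_dir) -> dict[str, str]:
    """Generate and write the full synthetic input bundle to ``out_dir``.

    Writes gene/miRNA expression TSVs, the miRNA Ct table, the sample map,
    the prediction table, the GMT collection and the truth JSON; returns the
    mapping of logical names to file paths.
    """
    from pathlib import Path

    from . import io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes, mirnas, truth = generate_expression_dataset(config)
    predictions = generate_prediction_tables(truth, config)
    collection, truth = generate_gene_sets(truth, config)

    n = config.n_samples_per_group
    groups = pd.Series(
        ["control"] * n + ["case"] * n,
        index=list(genes.columns),
        name="group",
    )

    paths = {
        "gene_expression": out / "gene_expression.tsv",
        "mirna_expression": out / "mirna_expression.tsv",
        "mirna_ct": out / "mirna_ct.tsv",
        "sample_map": out / "sample_map.tsv",
        "predictions": out / "predictions.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "truth": out / "truth.json",
    }
    io.write_expression(genes, paths["gene_expression"])
    io.write_expression(mirnas, paths["mirna_expression"])
    io.write_ct(expression_to_ct(mirnas), paths["mirna_ct"])
    io.write_sample_map(groups, paths["sample_map"])
    io.write_predictions(predictions, paths["predictions"])
    collection.to_gmt(paths["gene_sets"])
    io.write_json(truth.to_dict(), paths["truth"])
    return {k: str(v) for k, v in paths.items()}
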