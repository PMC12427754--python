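"""Synthetic platelet-RNA cohort generation with planted ground truth.

The generator emulates the structure of a curated platelet RNA-seq cancer
screening cohort: a library-size-normalized expression matrix on a log-like
scale (samples x genes), an imbalanced cancer/control label, 18 cancer-type
strata with stage labels, a 4-way institution covariate, age and sex, and a
"flagged" subset of symptomatic controls that downstream curation removes.
A configurable set of informative genes carries a class-conditional mean
shift (Cohen's d in standardized units); genes are organized into correlated
blocks driven by shared latent factors.

Ground truth (the planted gene set and the generating parameters) travels
with the cohort so that feature selection, model training and attribution
can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

STAGES = ("I", "II", "III", "IV", "unknown")

METADATA_COLUMNS = [
    "sample_id",
    "label",
    "cancer_type",
    "stage",
    "age",
    "sex",
    "institution",
    "flagged",
]


class CohortConfigError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the curated screening cohort the pipeline targets:
    1628 cancer samples over 18 tumor types, 390 asymptomatic controls plus
    333 flagged symptomatic controls, four contributing institutions.
    """

    n_cancer: int = 1628
    n_control: int = 390
    n_flagged_controls: int = 333
    n_genes: int = 2000
    n_informative: int = 20
    effect_size: float = 1.5
    block_size: int = 10
    block_rho: float = 0.3
    n_types: int = 18
    stage_probs: tuple[float, ...] = (0.10, 0.25, 0.30, 0.25, 0.10)
    n_institutions: int = 4
    age_mean: float = 58.0
    age_sd: float = 12.0
    sex_prob: float = 0.5
    # standardized perturbation applied to flagged controls on a random gene
    # subset, mimicking confounding molecular activity; default 0.5 * d
    flagged_shift: float | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cancer", "n_control", "n_flagged_controls", "n_genes",
                     "n_informative", "block_size", "n_types", "n_institutions"):
            value = getattr(self, name)
            if int(value) != value or value < 0:
                raise CohortConfigError(f"{name} must be a non-negative integer, got {value!r}")
        if self.n_informative > self.n_genes:
            raise CohortConfigError("n_informative exceeds n_genes")
        if not (0.0 <= self.block_rho < 1.0):
            raise CohortConfigError(f"block_rho must lie in [0, 1), got {self.block_rho}")
        if self.block_size < 1:
            raise CohortConfigError("block_size must be >= 1")
        if len(self.stage_probs) != len(STAGES):
            raise CohortConfigError(f"stage_probs must have {len(STAGES)} entries (I-IV, unknown)")
        if any(p < 0 for p in self.stage_probs):
            raise CohortConfigError("stage_probs must be non-negative")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9:
            raise CohortConfigError("stage_probs must sum to 1 within 1e-9")
        if not (0.0 <= self.sex_prob <= 1.0):
            raise CohortConfigError("sex_prob must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.n_cancer + self.n_control + self.n_flagged_controls


@dataclass
class SyntheticCohort:
    """Expression matrix + metadata + planted ground truth."""

    expression: pd.DataFrame  # samples x genes, index = sample_id
    metadata: pd.DataFrame  # METADATA_COLUMNS
    informative_genes: frozenset[str]
    # generating parameters reused by generate_external_cohort so that the
    # class-conditional structure of shared genes is preserved
    gen_params: dict = field(default_factory=dict, repr=False)

    def validate(self) -> None:
        if self.expression.shape[0] != self.metadata.shape[0]:
            raise ValueError("expression and metadata row counts differ")
        if self.metadata["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        missing = set(self.informative_genes) - set(self.expression.columns)
        if missing:
            raise ValueError(f"informative genes absent from expression: {sorted(missing)[:5]}")

    def write(self, out_dir: str | Path, sep: str = ",") -> None:
        """Write expression (samples x genes, first column sample_id) and metadata CSVs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        expr = self.expression.copy()
        expr.insert(0, "sample_id", self.metadata["sample_id"].to_numpy())
        expr.to_csv(out / "expression.csv", sep=sep, index=False)
        self.metadata.to_csv(out / "metadata.csv", sep=sep, index=False)
        pd.Series(sorted(self.informative_genes)).to_csv(
            out / "informative_genes.csv", index=False, header=["gene"]
        )


def _sample_gene_params(cfg: CohortConfig, rng: np.random.Generator) -> dict:
    """Draw the gene-level generating parameters (fixed across samples)."""
    genes = np.array([f"G{i:05d}" for i in range(cfg.n_genes)])
    block_of = np.arange(cfg.n_genes) // cfg.block_size
    base_mean = rng.normal(5.0, 1.5, size=cfg.n_genes)  # log-like abundance scale
    informative_idx = rng.choice(cfg.n_genes, size=cfg.n_informative, replace=False)
    signs = rng.choice([-1.0, 1.0], size=cfg.n_informative)
    flagged_shift = 0.5 * cfg.effect_size if cfg.flagged_shift is None else cfg.flagged_shift
    n_perturbed = max(1, cfg.n_genes // 10) if cfg.n_flagged_controls else 0
    perturbed_idx = rng.choice(cfg.n_genes, size=n_perturbed, replace=False) if n_perturbed else np.array([], int)
    return {
        "genes": genes,
        "block_of": block_of,
        "base_mean": base_mean,
        "informative_idx": informative_idx,
        "signs": signs,
        "flagged_shift": flagged_shift,
        "perturbed_idx": perturbed_idx,
    }


def _simulate_expression(
    cfg: CohortConfig,
    params: dict,
    y: np.ndarray,
    flagged: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Latent-factor block model: unit-variance genes, pairwise within-block
    correlation block_rho, class-conditional mean shift of effect_size
    (standardized units) on informative genes."""
    n = y.size
    n_blocks = int(params["block_of"].max()) + 1 if cfg.n_genes else 0
    factors = rng.standard_normal((n, n_blocks))
    noise = rng.standard_normal((n, cfg.n_genes))
    sqrt_rho = np.sqrt(cfg.block_rho)
    sqrt_res = np.sqrt(1.0 - cfg.block_rho)
    x = sqrt_rho * factors[:, params["block_of"]] + sqrt_res * noise
    x += params["base_mean"][None, :]
    shift = np.zeros(cfg.n_genes)
    shift[params["informative_idx"]] = cfg.effect_size * params["signs"]
    x += np.outer(y.astype(float), shift)
    if flagged.any() and params["perturbed_idx"].size:
        pert = np.zeros(cfg.n_genes)
        pert[params["perturbed_idx"]] = params["flagged_shift"]
        x += np.outer(flagged.astype(float), pert)
    return x


def _simulate_metadata(
    cfg: CohortConfig, y: np.ndarray, flagged: np.ndarray, rng: np.random.Generator, prefix: str
) -> pd.DataFrame:
    n = y.size
    cancer_types = np.array([f"type_{t + 1:02d}" for t in range(max(cfg.n_types, 1))])
    ctype = np.where(y == 1, cancer_types[rng.integers(0, max(cfg.n_types, 1), size=n)], "control")
    stage = np.full(n, "none", dtype=object)
    n_cancer = int(y.sum())
    stage[y == 1] = rng.choice(STAGES, size=n_cancer, p=np.asarray(cfg.stage_probs))
    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, size=n), 18, 95).round(1)
    sex = np.where(rng.random(n) < cfg.sex_prob, "F", "M")
    institution = np.array([f"inst_{k + 1}" for k in rng.integers(0, cfg.n_institutions, size=n)])
    return pd.DataFrame(
        {
            "sample_id": [f"{prefix}{i:05d}" for i in range(n)],
            "label": np.where(y == 1, "cancer", "control"),
            "cancer_type": ctype,
            "stage": stage,
            "age": age,
            "sex": sex,
            "institution": institution,
            "flagged": flagged.astype(int),
        }
    )


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a synthetic cohort; bit-identical under a fixed config/seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    params = _sample_gene_params(config, rng)

    y = np.concatenate(
        [
            np.ones(config.n_cancer, dtype=int),
            np.zeros(config.n_control + config.n_flagged_controls, dtype=int),
        ]
    )
    flagged = np.zeros(config.n_samples, dtype=bool)
    flagged[config.n_cancer + config.n_control:] = True

    metadata = _simulate_metadata(config, y, flagged, rng, prefix="S")
    x = _simulate_expression(config, params, y, flagged, rng)
    expression = pd.DataFrame(x, index=metadata["sample_id"].to_numpy(), columns=params["genes"])
    cohort = SyntheticCohort(
        expression=expression,
        metadata=metadata,
        informative_genes=frozenset(params["genes"][params["informative_idx"]]),
        gen_params={"config": config, **params},
    )
    cohort.validate()
    return cohort


def generate_external_cohort(
    base: SyntheticCohort,
    n_samples: int = 285,
    n_overlap: int = 30,
    gene_subset_fraction: float = 1.0,
    cancer_fraction: float = 0.7,
    seed: int = 1,
) -> SyntheticCohort:
    """Independent validation cohort sharing the generating process of ``base``.

    Exactly ``n_overlap`` samples (ids and rows) are copied from the base
    cohort; the remainder are fresh draws from the same gene-level model, so
    the class-conditional structure of shared informative genes is preserved.
    The gene set is a random subset of the base genes of the stated fraction.
    """
    if n_overlap > n_samples:
        raise ValueError(f"n_overlap ({n_overlap}) exceeds n_samples ({n_samples})")
    if n_overlap > base.expression.shape[0]:
        raise ValueError("n_overlap exceeds base cohort size")
    if not (0.0 < gene_subset_fraction <= 1.0):
        raise ValueError("gene_subset_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    cfg: CohortConfig = base.gen_params["config"]
    params = base.gen_params

    n_new = n_samples - n_overlap
    y_new = (rng.random(n_new) < cancer_fraction).astype(int)
    flagged_new = np.zeros(n_new, dtype=bool)
    meta_new = _simulate_metadata(cfg, y_new, flagged_new, rng, prefix="E")
    x_new = _simulate_expression(cfg, params, y_new, flagged_new, rng)
    expr_new = pd.DataFrame(x_new, index=meta_new["sample_id"].to_numpy(), columns=params["genes"])

    overlap_pos = rng.choice(base.expression.shape[0], size=n_overlap, replace=False)
    expr_overlap = base.expression.iloc[overlap_pos]
    meta_overlap = base.metadata.iloc[overlap_pos].reset_index(drop=True)

    expression = pd.concat([expr_overlap, expr_new], axis=0)
    metadata = pd.concat([meta_overlap, meta_new], axis=0, ignore_index=True)

    n_keep = int(round(gene_subset_fraction * cfg.n_genes))
    if n_keep < cfg.n_genes:
        keep_idx = np.sort(rng.choice(cfg.n_genes, size=n_keep, replace=False))
        expression = expression.iloc[:, keep_idx]
    informative = frozenset(g for g in base.informative_genes if g in expression.columns)

    cohort = SyntheticCohort(
        expression=expression,
        metadata=metadata,
        informative_genes=informative,
        gen_params=dict(base.gen_params),
    )
    cohort.validate()
    return cohort


def read_cohort(in_dir: str | Path, sep: str = ",") -> SyntheticCohort:
    """Read a cohort written by :meth:`SyntheticCohort.write`."""
    in_dir = Path(in_dir)
    expr = pd.read_csv(in_dir / "expression.csv", sep=sep)
    metadata = pd.read_csv(in_dir / "metadata.csv", sep=sep)
    expr = expr.set_index("sample_id")
    expr.index.name = None
    genes_file = in_dir / "informative_genes.csv"
    informative: frozenset[str] = frozenset()
    if genes_file.exists():
        informative = frozenset(pd.read_csv(genes_file)["gene"].astype(str))
    return SyntheticCohort(expression=expr, metadata=metadata, informative_genes=informative)
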