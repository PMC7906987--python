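"""Synthetic multi-cohort, two-compartment expression data with known truth.

The generator emulates the kind of inputs the pipeline consumes from public
repositories: several case/control log2 expression cohorts per compartment
(with study-specific batch shifts), plus paired cohorts in which tubule and
glomerulus were profiled in the same patients.  Planted differential genes
and planted cross-compartment correlated pairs provide ground truth for
recovery and null-calibration tests.

Model (all on the log2 scale):
  value = baseline_mean(gene) + batch(dataset) + noise,  noise ~ N(0, noise_sd)
  planted DEG: case samples shifted by +/- effect_size_true * noise_sd, so the
  true Hedges' g is ~effect_size_true regardless of noise_sd.
  planted pair: a patient-level latent factor z ~ N(0,1) drives both sides,
  x_tub = sqrt(|rho|) z + sqrt(1-|rho|) e1,
  x_glom = sign(rho) sqrt(|rho|) z + sqrt(1-|rho|) e2   (e1, e2 ~ N(0,1)),
  giving population cross-correlation exactly rho.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .datatypes import ExpressionDataset, StudyCollection
from .exceptions import ConfigError

BASELINE_MEAN = 8.0     # typical log2 microarray intensity
BASELINE_SD = 2.0


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic collection (defaults = the scale
    of one desk-size emulation: 4 cohorts of 15v15 per compartment, 4 paired
    cohorts of 40 patients)."""

    n_genes: int = 1000
    n_datasets: int = 4            # case/control cohorts per compartment
    n_case: int = 15
    n_control: int = 15
    n_planted_degs: int = 50       # per compartment; half up-, half down-regulated
    effect_size_true: float = 1.0  # Hedges-scale g of planted DEGs
    n_paired_cohorts: int = 4
    n_patients: int = 40           # per paired cohort
    n_planted_pairs: int = 20
    rho_true: float = 0.85         # latent-factor cross-compartment correlation
    batch_shift_sd: float = 0.5    # per-dataset location shift, log2 units
    noise_sd: float = 1.0          # per-sample noise, log2 units
    seed: int = 0

    def validate(self) -> "GeneratorConfig":
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        if self.n_planted_degs > self.n_genes:
            raise ConfigError("n_planted_degs cannot exceed n_genes")
        if 2 * self.n_planted_pairs > self.n_genes:
            raise ConfigError("planted pairs need 2*n_planted_pairs <= n_genes")
        if not (abs(self.rho_true) < 1):
            raise ConfigError("|rho_true| must be < 1")
        for name in ("noise_sd", "batch_shift_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        return self

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ConfigError(f"unknown generator config keys: {unknown}")
        return cls(**d).validate()


@dataclass
class SyntheticTruth:
    """Ground truth: planted DEGs (signed effect sizes) and planted pairs."""

    degs: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["compartment", "gene", "true_g"]))
    pairs: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["tubule_gene", "glom_gene", "rho_true", "sign"]))

    def deg_genes(self, compartment: str) -> set[str]:
        sel = self.degs["compartment"] == compartment
        return set(self.degs.loc[sel, "gene"])

    def pair_keys(self) -> set[tuple[str, str]]:
        return set(zip(self.pairs["tubule_gene"], self.pairs["glom_gene"]))


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _baseline_means(config: GeneratorConfig) -> np.ndarray:
    rng = stage_rng(config.seed, "simulate_baseline")
    return BASELINE_MEAN + BASELINE_SD * rng.standard_normal(config.n_genes)


def generate_meta_cohorts(
    config: GeneratorConfig,
    compartment: str = "tubule",
    baseline: np.ndarray | None = None,
) -> tuple[list[ExpressionDataset], SyntheticTruth]:
    """Case/control cohorts for one compartment with planted DEGs.

    Half the planted genes are negated (down-regulated in cases).  Every
    draw derives from ``config.seed``; the same config reproduces identical
    matrices.
    """
    config.validate()
    genes = _gene_names(config.n_genes)
    if baseline is None:
        baseline = _baseline_means(config)
    rng = stage_rng(config.seed, "simulate_meta", compartment)

    deg_idx = rng.choice(config.n_genes, size=config.n_planted_degs, replace=False)
    signs = np.ones(config.n_planted_degs)
    signs[: config.n_planted_degs // 2] = -1.0
    delta = np.zeros(config.n_genes)
    delta[deg_idx] = signs * config.effect_size_true * config.noise_sd

    datasets = []
    n_samples = config.n_case + config.n_control
    group = np.array(["case"] * config.n_case + ["control"] * config.n_control)
    for d in range(config.n_datasets):
        batch = rng.normal(0.0, config.batch_shift_sd)
        vals = (baseline[:, None] + batch
                + config.noise_sd * rng.standard_normal((config.n_genes, n_samples)))
        vals[:, : config.n_case] += delta[:, None]
        prefix = "tub" if compartment == "tubule" else "glm"
        ds_id = f"{prefix}_meta{d + 1}"
        samples = [f"{ds_id}_s{j + 1:02d}" for j in range(n_samples)]
        datasets.append(ExpressionDataset(
            dataset_id=ds_id,
            values=pd.DataFrame(vals, index=genes, columns=samples),
            compartment=compartment,
            group=pd.Series(group, index=samples),
        ).validate())

    truth = SyntheticTruth(degs=pd.DataFrame({
        "compartment": compartment,
        "gene": [genes[i] for i in deg_idx],
        "true_g": signs * config.effect_size_true,
    }).sort_values("gene", kind="stable").reset_index(drop=True))
    return datasets, truth


def generate_paired_compartments(
    config: GeneratorConfig,
    pair_genes: list[tuple[str, str]] | None = None,
    baseline: np.ndarray | None = None,
) -> tuple[list[tuple[ExpressionDataset, ExpressionDataset]], SyntheticTruth]:
    """Paired tubule/glomerulus cohorts sharing patients, with planted pairs.

    ``pair_genes`` optionally fixes which (tubule gene, glomerulus gene)
    pairs carry the latent factor (used to draw pairs from planted DEG
    sets); by default disjoint genes are sampled.  Non-planted genes are
    independent noise.  All cohorts are disease patients (single group):
    they feed the correlation stage, not the case/control meta-analysis.
    """
    config.validate()
    genes = _gene_names(config.n_genes)
    if baseline is None:
        baseline = _baseline_means(config)
    rng = stage_rng(config.seed, "simulate_paired")

    if pair_genes is None:
        idx = rng.choice(config.n_genes, size=2 * config.n_planted_pairs, replace=False)
        pair_genes = [(genes[idx[2 * i]], genes[idx[2 * i + 1]])
                      for i in range(config.n_planted_pairs)]
    gene_pos = {g: i for i, g in enumerate(genes)}
    rho = config.rho_true
    a = np.sqrt(abs(rho))
    b = np.sqrt(1.0 - abs(rho))

    cohorts = []
    for c in range(config.n_paired_cohorts):
        npat = config.n_patients
        patients = [f"c{c + 1}_p{j + 1:03d}" for j in range(npat)]
        batch_t = rng.normal(0.0, config.batch_shift_sd)
        batch_g = rng.normal(0.0, config.batch_shift_sd)
        zt = rng.standard_normal((config.n_genes, npat))
        zg = rng.standard_normal((config.n_genes, npat))
        for tg, gg in pair_genes:
            z = rng.standard_normal(npat)
            zt[gene_pos[tg]] = a * z + b * rng.standard_normal(npat)
            zg[gene_pos[gg]] = np.sign(rho) * a * z + b * rng.standard_normal(npat)
        vt = baseline[:, None] + batch_t + config.noise_sd * zt
        vg = baseline[:, None] + batch_g + config.noise_sd * zg

        tub_id, glom_id = f"paired{c + 1}_tub", f"paired{c + 1}_glm"
        tub_samples = [f"{tub_id}_{p}" for p in patients]
        glom_samples = [f"{glom_id}_{p}" for p in patients]
        tub = ExpressionDataset(
            dataset_id=tub_id,
            values=pd.DataFrame(vt, index=genes, columns=tub_samples),
            compartment="tubule",
            group=pd.Series("case", index=tub_samples),
            patient_id=pd.Series(patients, index=tub_samples),
        ).validate()
        glom = ExpressionDataset(
            dataset_id=glom_id,
            values=pd.DataFrame(vg, index=genes, columns=glom_samples),
            compartment="glomerulus",
            group=pd.Series("case", index=glom_samples),
            patient_id=pd.Series(patients, index=glom_samples),
        ).validate()
        cohorts.append((tub, glom))

    truth = SyntheticTruth(pairs=pd.DataFrame({
        "tubule_gene": [t for t, _ in pair_genes],
        "glom_gene": [g for _, g in pair_genes],
        "rho_true": rho,
        "sign": "pos" if rho >= 0 else "neg",
    }))
    return cohorts, truth


def generate_study(config: GeneratorConfig) -> tuple[StudyCollection, SyntheticTruth]:
    """Full synthetic study: meta cohorts for both compartments plus paired
    cohorts, with planted pairs drawn from the planted DEG sets so the
    DEG-restricted correlation universe contains the truth.
    """
    config.validate()
    baseline = _baseline_means(config)
    tub_ds, tub_truth = generate_meta_cohorts(config, "tubule", baseline)
    glom_ds, glom_truth = generate_meta_cohorts(config, "glomerulus", baseline)

    rng = stage_rng(config.seed, "simulate_paired", "pair_choice")
    tub_degs = sorted(tub_truth.deg_genes("tubule"))
    glom_degs = sorted(glom_truth.deg_genes("glomerulus"))
    n_pairs = min(config.n_planted_pairs, len(tub_degs), len(glom_degs))
    tub_pick = rng.choice(len(tub_degs), size=n_pairs, replace=False)
    glom_pick = rng.choice(len(glom_degs), size=n_pairs, replace=False)
    pair_genes = [(tub_degs[i], glom_degs[j]) for i, j in zip(tub_pick, glom_pick)]

    paired, pair_truth = generate_paired_compartments(config, pair_genes, baseline)
    datasets = tub_ds + glom_ds + [d for pair in paired for d in pair]
    collection = StudyCollection(
        datasets=datasets,
        paired_cohorts=[(t.dataset_id, g.dataset_id) for t, g in paired],
    ).validate()
    truth = SyntheticTruth(
        degs=pd.concat([tub_truth.degs, glom_truth.degs], ignore_index=True),
        pairs=pair_truth.pairs,
    )
    return collection, truth


# ---------------------------------------------------------------------------
# truth round trip
# ---------------------------------------------------------------------------

def write_truth(truth: SyntheticTruth, out_dir) -> dict[str, str]:
    """Write the truth tables as TSV; header-only files are valid for empty truth."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "degs": os.path.join(out_dir, "truth_degs.tsv"),
        "pairs": os.path.join(out_dir, "truth_pairs.tsv"),
    }
    truth.degs.to_csv(paths["degs"], sep="\t", index=False, float_format="%.10g")
    truth.pairs.to_csv(paths["pairs"], sep="\t", index=False, float_format="%.10g")
    return paths


def read_truth(out_dir) -> SyntheticTruth:
    import os

    degs = pd.read_csv(os.path.join(out_dir, "truth_degs.tsv"), sep="\t",
                       dtype={"compartment": str, "gene": str})
    pairs = pd.read_csv(os.path.join(out_dir, "truth_pairs.tsv"), sep="\t",
                        dtype={"tubule_gene": str, "glom_gene": str, "sign": str})
    return SyntheticTruth(degs=degs, pairs=pairs)
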