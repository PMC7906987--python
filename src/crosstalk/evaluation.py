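"""Calibration and recovery experiments on synthetic data.

These functions regenerate data from scratch, run the pipeline's own
estimators, and measure operating characteristics: null DEG-call rate,
planted-DEG sensitivity and false-discovery proportion, SAM null q-value
behavior, planted-pair recovery, and end-to-end determinism.  They back
both the test suite and the reproduction script.
"""

from __future__ import annotations

import hashlib
import os
import tempfile
from dataclasses import dataclass, replace

import numpy as np

from ._rng import stage_rng
from .datatypes import AnalysisConfig
from .meta import meta_analyze, sam_qvalues
from .pairs import find_pairs_one_cohort, intersect_pairs
from .pipeline import run_pipeline
from .simulate import (GeneratorConfig, generate_meta_cohorts,
                       generate_paired_compartments, generate_study)


@dataclass
class NullDegResult:
    fractions: list[float]
    mean_fraction: float
    se: float


def null_deg_call_rate(
    n_replicates: int = 20,
    seed: int = 0,
    gen: GeneratorConfig | None = None,
    analysis: AnalysisConfig | None = None,
) -> NullDegResult:
    """Fraction of genes called final DEGs on data with no planted effects.

    Defaults: 4 datasets x 1000 genes x 15v15 per replicate.  With a valid
    procedure the mean fraction stays at or below fdr_max.
    """
    gen = gen or GeneratorConfig()
    gen = replace(gen, n_planted_degs=0)
    fractions = []
    for rep in range(n_replicates):
        g = replace(gen, seed=int(stage_rng(seed, "evaluation", "null_deg", rep)
                                  .integers(2**31)))
        datasets, _truth = generate_meta_cohorts(g, "tubule")
        cfg = (analysis or AnalysisConfig()).with_updates(seed=g.seed)
        res = meta_analyze(datasets, cfg)
        fractions.append(len(res.deg_genes()) / len(res.meta))
    arr = np.asarray(fractions)
    se = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return NullDegResult(fractions, float(arr.mean()), se)


@dataclass
class RecoveryResult:
    sensitivities: list[float]
    fdps: list[float]
    mean_sensitivity: float
    mean_fdp: float


def deg_recovery(
    n_seeds: int = 5,
    seed: int = 0,
    gen: GeneratorConfig | None = None,
    analysis: AnalysisConfig | None = None,
) -> RecoveryResult:
    """Sensitivity and false-discovery proportion of final DEG calls on data
    with planted effects (defaults: 50 planted DEGs at g=1.0, 4 x 15v15)."""
    gen = gen or GeneratorConfig()
    sens, fdps = [], []
    for rep in range(n_seeds):
        g = replace(gen, seed=int(stage_rng(seed, "evaluation", "recovery", rep)
                                  .integers(2**31)))
        datasets, truth = generate_meta_cohorts(g, "tubule")
        cfg = (analysis or AnalysisConfig()).with_updates(seed=g.seed)
        res = meta_analyze(datasets, cfg)
        called = res.deg_genes()
        true = truth.deg_genes("tubule")
        tp = len(called & true)
        sens.append(tp / len(true))
        fdps.append((len(called) - tp) / max(1, len(called)))
    return RecoveryResult(sens, fdps, float(np.mean(sens)), float(np.mean(fdps)))


def sam_null_q_fraction(
    n_replicates: int = 20,
    n_genes: int = 500,
    n_per_group: int = 10,
    n_permutations: int = 1000,
    seed: int = 0,
    q_cut: float = 0.10,
) -> float:
    """Mean fraction of genes with SAM q < q_cut on fully null matrices."""
    labels = np.array(["case"] * n_per_group + ["control"] * n_per_group)
    fractions = []
    for rep in range(n_replicates):
        rng = stage_rng(seed, "evaluation", "sam_null", rep)
        x = rng.standard_normal((n_genes, 2 * n_per_group))
        res = sam_qvalues(x, labels, n_permutations=n_permutations, rng=rng)
        fractions.append(float((res.q < q_cut).mean()))
    return float(np.mean(fractions))


@dataclass
class PairRecoveryResult:
    recoveries: list[float]
    false_pair_counts: list[int]
    mean_recovery: float
    mean_false_pairs: float


def pair_recovery(
    n_seeds: int = 5,
    seed: int = 0,
    gen: GeneratorConfig | None = None,
    analysis: AnalysisConfig | None = None,
) -> PairRecoveryResult:
    """Planted-pair recovery across all paired cohorts (defaults: 20 pairs at
    rho=0.85, 4 cohorts x 40 patients, 300 x 300 DEG universe)."""
    gen = gen or GeneratorConfig(n_genes=300)
    recs, fps = [], []
    for rep in range(n_seeds):
        g = replace(gen, seed=int(stage_rng(seed, "evaluation", "pairs", rep)
                                  .integers(2**31)))
        cohorts, truth = generate_paired_compartments(g)
        cfg = (analysis or AnalysisConfig()).with_updates(seed=g.seed)
        genes = cohorts[0][0].genes
        per_cohort = {f"c{i}": find_pairs_one_cohort(tub, glom, genes, genes, cfg)
                      for i, (tub, glom) in enumerate(cohorts)}
        found = {p.key for p in intersect_pairs(per_cohort)}
        true = truth.pair_keys()
        recs.append(len(found & true) / len(true))
        fps.append(len(found - true))
    return PairRecoveryResult(recs, fps, float(np.mean(recs)), float(np.mean(fps)))


def _hash_dir(path: str) -> dict[str, str]:
    out = {}
    for name in sorted(os.listdir(path)):
        full = os.path.join(path, name)
        if os.path.isfile(full):
            out[name] = hashlib.sha256(open(full, "rb").read()).hexdigest()
    return out


def pipeline_determinism(seed: int = 0, gen: GeneratorConfig | None = None,
                         analysis: AnalysisConfig | None = None) -> bool:
    """Run the full pipeline twice on identical synthetic inputs with the
    same seed; True iff every output file is byte-identical."""
    gen = gen or GeneratorConfig(n_genes=300, n_datasets=2, n_case=10, n_control=10,
                                 n_planted_degs=30, n_paired_cohorts=2, n_patients=25,
                                 n_planted_pairs=8, seed=seed)
    collection, _truth = generate_study(gen)
    cfg = (analysis or AnalysisConfig(n_permutations=300)).with_updates(seed=seed)
    hashes = []
    with tempfile.TemporaryDirectory() as tmp:
        sec_path = os.path.join(tmp, "secretome.txt")
        rng = stage_rng(seed, "evaluation", "determinism")
        genes = collection.datasets[0].genes
        secreted = sorted(rng.choice(genes, size=max(2, len(genes) // 10), replace=False))
        with open(sec_path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(map(str, secreted)) + "\n")
        for run in ("a", "b"):
            out = os.path.join(tmp, run)
            run_pipeline(collection, cfg, sec_path, out)
            hashes.append(_hash_dir(out))
    return hashes[0] == hashes[1]
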