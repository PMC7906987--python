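"""Core containers: per-study expression datasets, study collections, and
the analysis configuration holding every threshold of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataValidationError

COMPARTMENTS = ("tubule", "glomerulus")
GROUPS = ("case", "control")

CONSENSUS_RULES = ("all_three", "any_one", "pearson_only")
SAM_COMBINE_METHODS = ("fisher", "binomial")


@dataclass
class ExpressionDataset:
    """One study's log2 expression matrix plus sample annotations.

    ``values`` is a genes x samples DataFrame (rows = gene ids, columns =
    sample ids).  ``group`` maps each sample to ``case`` or ``control``;
    ``patient_id`` is present for paired tubule/glomerulus cohorts.
    """

    dataset_id: str
    values: pd.DataFrame
    compartment: str
    group: pd.Series
    patient_id: Optional[pd.Series] = None

    # -- derived views ----------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_case(self) -> int:
        return int((self.group == "case").sum())

    @property
    def n_control(self) -> int:
        return int((self.group == "control").sum())

    def case_matrix(self) -> pd.DataFrame:
        return self.values.loc[:, self.group[self.group == "case"].index]

    def control_matrix(self) -> pd.DataFrame:
        return self.values.loc[:, self.group[self.group == "control"].index]

    @property
    def meta_ready(self) -> bool:
        """Usable for case/control meta-analysis (>=2 samples per group)."""
        return self.n_case >= 2 and self.n_control >= 2

    # -- contract ---------------------------------------------------------
    def validate(self) -> "ExpressionDataset":
        if self.compartment not in COMPARTMENTS:
            raise DataValidationError(
                f"{self.dataset_id}: compartment {self.compartment!r} not in {COMPARTMENTS}"
            )
        if self.values.index.duplicated().any():
            dups = sorted(self.values.index[self.values.index.duplicated()].unique())
            raise DataValidationError(
                f"{self.dataset_id}: duplicate gene identifiers: {dups[:10]}"
            )
        if set(self.group.index) != set(self.values.columns):
            missing = sorted(set(self.values.columns) - set(self.group.index))
            extra = sorted(set(self.group.index) - set(self.values.columns))
            raise DataValidationError(
                f"{self.dataset_id}: group annotation mismatch "
                f"(samples without group: {missing}; annotated non-samples: {extra})"
            )
        bad = sorted(set(self.group.unique()) - set(GROUPS))
        if bad:
            raise DataValidationError(
                f"{self.dataset_id}: group labels must be in {GROUPS}, got {bad}"
            )
        vals = self.values.to_numpy()
        if vals.size and not np.isfinite(vals.astype(float)).all():
            n_bad = int((~np.isfinite(vals.astype(float))).sum())
            raise DataValidationError(
                f"{self.dataset_id}: {n_bad} non-finite values after preprocessing"
            )
        if self.patient_id is not None and set(self.patient_id.index) != set(self.values.columns):
            raise DataValidationError(f"{self.dataset_id}: patient_id index mismatch")
        return self


@dataclass
class StudyCollection:
    """All datasets of one analysis plus the tubule/glomerulus pairing."""

    datasets: list[ExpressionDataset]
    paired_cohorts: list[tuple[str, str]] = field(default_factory=list)

    def get(self, dataset_id: str) -> ExpressionDataset:
        for ds in self.datasets:
            if ds.dataset_id == dataset_id:
                return ds
        raise KeyError(f"no dataset with id {dataset_id!r}")

    def by_compartment(self, compartment: str) -> list[ExpressionDataset]:
        return [d for d in self.datasets if d.compartment == compartment]

    def shared_patients(self, cohort: tuple[str, str]) -> list[str]:
        tub, glom = self.get(cohort[0]), self.get(cohort[1])
        if tub.patient_id is None or glom.patient_id is None:
            return []
        return sorted(set(tub.patient_id) & set(glom.patient_id))

    def validate(self) -> "StudyCollection":
        ids = [d.dataset_id for d in self.datasets]
        if len(set(ids)) != len(ids):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise DataValidationError(f"duplicate dataset ids: {dups}")
        for ds in self.datasets:
            ds.validate()
        for tub_id, glom_id in self.paired_cohorts:
            tub, glom = self.get(tub_id), self.get(glom_id)
            if tub.compartment != "tubule" or glom.compartment != "glomerulus":
                raise DataValidationError(
                    f"paired cohort ({tub_id}, {glom_id}) must be (tubule, glomerulus)"
                )
            n_shared = len(self.shared_patients((tub_id, glom_id)))
            if n_shared < 3:
                raise DataValidationError(
                    f"paired cohort ({tub_id}, {glom_id}) shares only "
                    f"{n_shared} patients (need >=3)"
                )
        return self


@dataclass
class AnalysisConfig:
    """Every tunable threshold of the pipeline, with the published defaults.

    fdr_max          BH-adjusted FDR cutoff on the pooled effect size (0.05).
    sam_q_max        per-dataset SAM q-value cutoff (0.10).
    repl_p_max       cutoff on the cross-dataset combination p-value (0.05).
    r_min            correlation-magnitude cutoff for pair screening (0.7),
                     applied to Pearson r; see match_rank_thresholds.
    corr_p_max       correlation p-value cutoff (0.001).
    fold_change_min  linear fold-change cutoff for enrichment export (1.5).
    corr_consensus   which correlation methods must pass: all_three (default),
                     any_one, or pearson_only.
    sam_combine      how per-dataset SAM evidence is combined across cohorts:
                     'fisher' (default; Fisher's chi-square combination of
                     per-dataset permutation p-values) or 'binomial' (exact
                     binomial tail on the count of per-dataset q < sam_q_max
                     calls at null rate sam_q_max).
    match_rank_thresholds
                     when True (default), the magnitude cutoff for Spearman
                     and Kendall is mapped to the rank scale of equivalent
                     stringency under a bivariate-normal model
                     (rho_s = 6/pi*asin(r/2), tau = 2/pi*asin(r)); when
                     False, r_min is applied verbatim to all three.
    """

    fdr_max: float = 0.05
    sam_q_max: float = 0.10
    repl_p_max: float = 0.05
    r_min: float = 0.7
    corr_p_max: float = 0.001
    fold_change_min: float = 1.5
    n_permutations: int = 1000
    seed: int = 0
    corr_consensus: str = "all_three"
    min_datasets_present: int = 2
    sam_combine: str = "fisher"
    match_rank_thresholds: bool = True

    def validate(self) -> "AnalysisConfig":
        for name in ("fdr_max", "sam_q_max", "repl_p_max", "corr_p_max"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        if not (0.0 < self.r_min <= 1.0):
            raise ConfigError(f"r_min must be in (0, 1], got {self.r_min}")
        if self.fold_change_min < 1.0:
            raise ConfigError(f"fold_change_min must be >=1, got {self.fold_change_min}")
        if self.n_permutations < 100:
            raise ConfigError(f"n_permutations must be >=100, got {self.n_permutations}")
        if self.corr_consensus not in CONSENSUS_RULES:
            raise ConfigError(
                f"corr_consensus must be one of {CONSENSUS_RULES}, got {self.corr_consensus!r}"
            )
        if self.sam_combine not in SAM_COMBINE_METHODS:
            raise ConfigError(
                f"sam_combine must be one of {SAM_COMBINE_METHODS}, got {self.sam_combine!r}"
            )
        if self.min_datasets_present < 1:
            raise ConfigError("min_datasets_present must be >=1")
        return self

    def with_updates(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw).validate()

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ConfigError(f"unknown analysis config keys: {unknown}")
        return cls(**d).validate()
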