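"""Readers and writers for every on-disk format of the pipeline.

File dialect: tab-separated UTF-8, genes as rows and samples as columns,
decimal point, no thousands separators.  Floats are written with 10
significant digits so every writer round-trips losslessly through its
paired reader.  Gene identifiers are opaque strings.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .datatypes import AnalysisConfig, ExpressionDataset, StudyCollection
from .exceptions import ConfigError, DataValidationError
from .pairs import CorrelatedPair
from .preprocess import ProbeGeneMap, collapse_probes

FLOAT_FMT = "%.10g"

DEG_TABLE_COLUMNS = ["gene", "f_meta", "se", "z", "p", "q_fdr", "mean_log2fc",
                     "sam_k_significant", "repl_p", "final_call"]


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(
    path,
    metadata_path,
    probe_map: ProbeGeneMap | None = None,
    collapse_rule: str = "max_mean_probe",
    dataset_id: str | None = None,
) -> ExpressionDataset:
    """Read a genes x samples TSV plus its sample metadata table.

    The matrix has a header row of sample ids and a first column of
    gene/probe ids.  The metadata TSV must carry ``sample_id``, ``group``
    and ``compartment`` columns (``patient_id`` optional) covering every
    sample column.  Duplicate row ids are a hard error unless ``probe_map``
    is given, in which case rows are probes and are collapsed to genes.
    Row/column order is preserved from the file.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        col = non_numeric[0]
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad_rows = df.index[coerced.isna() & df[col].notna()]
        row = bad_rows[0] if len(bad_rows) else df.index[0]
        raise DataValidationError(
            f"{path}: non-numeric value {df.at[row, col]!r} at row {row!r}, column {col!r}"
        )

    if df.index.duplicated().any() and probe_map is None:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise DataValidationError(
            f"{path}: duplicated gene row ids {dups[:10]} and no probe map supplied"
        )

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"sample_id", "group", "compartment"}
    missing_cols = sorted(required - set(meta.columns))
    if missing_cols:
        raise DataValidationError(f"{metadata_path}: missing columns {missing_cols}")
    meta = meta.set_index("sample_id")
    missing = [s for s in df.columns if s not in meta.index]
    if missing:
        raise DataValidationError(
            f"{metadata_path}: no metadata for sample(s) {missing} of {path}"
        )
    meta = meta.loc[list(df.columns)]

    compartments = meta["compartment"].unique()
    if len(compartments) != 1:
        raise DataValidationError(
            f"{path}: samples span multiple compartments {sorted(compartments)}"
        )

    if probe_map is not None:
        df, _prov, _unmapped = collapse_probes(df, probe_map, collapse_rule)

    patient = None
    if "patient_id" in meta.columns and meta["patient_id"].notna().all():
        patient = meta["patient_id"]

    return ExpressionDataset(
        dataset_id=dataset_id or os.path.splitext(os.path.basename(str(path)))[0],
        values=df.astype(float),
        compartment=str(compartments[0]),
        group=meta["group"],
        patient_id=patient,
    ).validate()


def write_expression_matrix(dataset: ExpressionDataset, matrix_path, metadata_path) -> None:
    dataset.values.to_csv(matrix_path, sep="\t", float_format=FLOAT_FMT,
                          index_label="gene")
    meta = pd.DataFrame({
        "sample_id": dataset.samples,
        "group": dataset.group.loc[dataset.samples].to_numpy(),
        "compartment": dataset.compartment,
    })
    if dataset.patient_id is not None:
        meta["patient_id"] = dataset.patient_id.loc[dataset.samples].to_numpy()
    meta.to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# DEG tables
# ---------------------------------------------------------------------------

def build_deg_table(meta: pd.DataFrame, replication: pd.DataFrame,
                    calls: pd.DataFrame) -> pd.DataFrame:
    """Merge the meta-analysis tables into the serializable DEG table."""
    t = meta[["f_meta", "se", "z", "p", "q_fdr", "mean_log2fc"]].copy()
    t["sam_k_significant"] = replication["k_significant"].reindex(t.index)
    t["repl_p"] = replication["p_repl"].reindex(t.index)
    t["final_call"] = calls["final"].reindex(t.index).fillna(False)
    t = t.reset_index()
    t = t.rename(columns={t.columns[0]: "gene"})
    return t[DEG_TABLE_COLUMNS]


def write_deg_table(table: pd.DataFrame, path) -> None:
    """Write the DEG table (sorted by q_fdr ascending). Empty input is an error."""
    if table is None or len(table) == 0:
        raise DataValidationError("refusing to write an empty DEG table")
    missing = [c for c in DEG_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise DataValidationError(f"DEG table missing columns {missing}")
    out = table[DEG_TABLE_COLUMNS].sort_values(
        ["q_fdr", "gene"], kind="stable").reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_deg_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    df["final_call"] = df["final_call"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# gene lists and SIF networks
# ---------------------------------------------------------------------------

def write_genelist(genes, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_genelist(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def write_sif_network(pairs: list[CorrelatedPair], path, node_attr_path=None) -> None:
    """Write consensus pairs as a SIF edge list for network viewers.

    One line per pair: ``<tubule_gene>\\t<pos|neg>\\t<glom_gene>``.  The
    optional node-attribute side file labels each gene tubule, glomerulus,
    or both.
    """
    if not pairs:
        raise DataValidationError("refusing to write an empty SIF network")
    with open(path, "w", encoding="utf-8") as fh:
        for p in sorted(pairs, key=lambda q: q.key):
            fh.write(f"{p.tubule_gene}\t{p.consensus_sign}\t{p.glom_gene}\n")
    if node_attr_path is not None:
        tub = {p.tubule_gene for p in pairs}
        glom = {p.glom_gene for p in pairs}
        with open(node_attr_path, "w", encoding="utf-8") as fh:
            fh.write("gene\tside\n")
            for gene in sorted(tub | glom):
                side = ("both" if gene in tub and gene in glom
                        else "tubule" if gene in tub else "glomerulus")
                fh.write(f"{gene}\t{side}\n")


def write_pairs_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class DatasetSpec:
    dataset_id: str
    matrix: str
    metadata: str
    probe_map: str | None = None
    already_log2: bool = True


@dataclass
class RunSpec:
    """Parsed run configuration: dataset file layout + analysis thresholds."""

    datasets: list[DatasetSpec]
    paired_cohorts: list[tuple[str, str]] = field(default_factory=list)
    secretome: str | None = None
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)


def load_run_spec(path) -> RunSpec:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: run config must be a mapping")
    unknown = sorted(set(raw) - {"datasets", "paired_cohorts", "secretome", "analysis"})
    if unknown:
        raise ConfigError(f"{path}: unknown run config keys {unknown}")
    specs = []
    for entry in raw.get("datasets", []):
        bad = sorted(set(entry) - {"dataset_id", "matrix", "metadata", "probe_map",
                                   "already_log2"})
        if bad:
            raise ConfigError(f"{path}: unknown dataset keys {bad}")
        specs.append(DatasetSpec(**entry))
    if not specs:
        raise ConfigError(f"{path}: no datasets listed")
    cohorts = [tuple(c) for c in raw.get("paired_cohorts", [])]
    analysis = AnalysisConfig.from_dict(raw.get("analysis", {}))
    return RunSpec(datasets=specs, paired_cohorts=cohorts,
                   secretome=raw.get("secretome"), analysis=analysis)


def load_collection(spec: RunSpec, base_dir=".") -> StudyCollection:
    """Materialize a validated StudyCollection from a RunSpec's file layout."""
    datasets = []
    for ds in spec.datasets:
        pm = None
        if ds.probe_map:
            pm = ProbeGeneMap.from_tsv(os.path.join(base_dir, ds.probe_map))
        datasets.append(read_expression_matrix(
            os.path.join(base_dir, ds.matrix),
            os.path.join(base_dir, ds.metadata),
            probe_map=pm, dataset_id=ds.dataset_id,
        ))
    return StudyCollection(datasets=datasets,
                           paired_cohorts=spec.paired_cohorts).validate()
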