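"""Raw-matrix preprocessing: log2 transform, quantile normalization, and
probe-to-gene collapsing.

Normalization is performed within each dataset; the meta-analysis stage then
pools evidence across datasets, which absorbs between-study location/scale
differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataValidationError

COLLAPSE_RULES = ("max_mean_probe", "median_of_probes")


@dataclass
class ProbeGeneMap:
    """Many-to-one probe -> gene mapping (both sides opaque strings)."""

    mapping: dict[str, str]

    @classmethod
    def from_tsv(cls, path) -> "ProbeGeneMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["probe_id", "gene_id"],
                         dtype=str, comment="#")
        if df["probe_id"].duplicated().any():
            dups = sorted(df.loc[df["probe_id"].duplicated(), "probe_id"].unique())
            raise DataValidationError(
                f"probe map assigns multiple genes to probes: {dups[:10]}"
            )
        return cls(dict(zip(df["probe_id"], df["gene_id"])))

    def __len__(self) -> int:
        return len(self.mapping)


def log2_transform(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """out[i, j] = log2(in[i, j] + pseudocount).

    Inputs must be non-negative; a positive pseudocount is required whenever
    zeros are present.  Not idempotent: the caller flags whether a matrix is
    already on the log scale.
    """
    vals = matrix.to_numpy(dtype=float)
    if (vals < 0).any():
        i, j = np.argwhere(vals < 0)[0]
        raise DataValidationError(
            f"negative expression value {vals[i, j]} at gene "
            f"{matrix.index[i]!r}, sample {matrix.columns[j]!r}; "
            "log2 transform requires non-negative input"
        )
    if pseudocount < 0:
        raise DataValidationError("pseudocount must be non-negative")
    if pseudocount == 0 and (vals == 0).any():
        raise DataValidationError("pseudocount must be > 0 when zeros are present")
    return pd.DataFrame(np.log2(vals + pseudocount), index=matrix.index,
                        columns=matrix.columns)


def _qn_reference(vals: np.ndarray) -> np.ndarray:
    return np.sort(vals, axis=0).mean(axis=1)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common empirical distribution.

    The reference distribution is the vector of row means of the column-wise
    sorted matrix.  Within each column ranks are preserved; tied values
    receive the mean of the reference values their positions span.
    """
    vals = matrix.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise DataValidationError("quantile normalization requires complete data")
    if vals.shape[1] < 2:
        warnings.warn("quantile_normalize: single-column matrix returned unchanged")
        return matrix.copy()
    ref = _qn_reference(vals)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        # ties: average the reference values spanned by each tie block
        s = pd.Series(assigned)
        out[:, j] = s.groupby(col).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def collapse_probes(
    matrix: pd.DataFrame,
    probe_map: ProbeGeneMap,
    rule: str = "max_mean_probe",
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Collapse a probe-level matrix to one row per gene.

    Returns ``(gene_matrix, provenance, unmapped_probes)``.  Provenance has
    one row per output gene: the chosen probe (max_mean_probe) or the probe
    count (median_of_probes), so the collapse is auditable.  Probes absent
    from the map are excluded and reported, never silently dropped.
    """
    if rule not in COLLAPSE_RULES:
        raise DataValidationError(f"collapse rule must be in {COLLAPSE_RULES}, got {rule!r}")
    mapped_mask = matrix.index.to_series().isin(probe_map.mapping).to_numpy()
    unmapped = sorted(matrix.index[~mapped_mask])
    sub = matrix.loc[mapped_mask]
    genes = sub.index.to_series().map(probe_map.mapping)

    rows: dict[str, np.ndarray] = {}
    prov: list[dict] = []
    for gene, block in sub.groupby(genes.to_numpy(), sort=True):
        if rule == "max_mean_probe":
            means = block.mean(axis=1)
            best = means.idxmax()
            rows[gene] = block.loc[best].to_numpy()
            prov.append({"gene": gene, "chosen_probe": best, "n_probes": len(block)})
        else:
            rows[gene] = block.median(axis=0).to_numpy()
            prov.append({"gene": gene, "chosen_probe": "", "n_probes": len(block)})
    gene_matrix = pd.DataFrame.from_dict(rows, orient="index", columns=matrix.columns)
    gene_matrix.index.name = matrix.index.name
    provenance = pd.DataFrame(prov, columns=["gene", "chosen_probe", "n_probes"])
    return gene_matrix, provenance, unmapped


def drop_incomplete_genes(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop genes with any missing value (no imputation); report them."""
    incomplete = matrix.index[matrix.isna().any(axis=1)]
    return matrix.drop(index=incomplete), sorted(incomplete)
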