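"""Secreted-protein annotation of consensus gene pairs.

A user-supplied secretome list (e.g. the Human Protein Atlas predicted
secretome, one gene id per line) flags which side of each cross-compartment
pair encodes a secreted protein — the ligand-like candidates for
tubule-to-glomerulus (or reverse) signaling.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import pandas as pd

from .exceptions import DataValidationError
from .pairs import CorrelatedPair

logger = logging.getLogger(__name__)


@dataclass
class SecretomeList:
    genes: set[str]
    source: str = ""
    sha256: str = ""

    @property
    def size(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return str(gene).strip().upper() in self.genes


def load_secretome(path) -> SecretomeList:
    """Load a one-gene-per-line list; ids are uppercased and trimmed.

    Comment lines (#) are allowed; duplicates and blanks are counted and
    logged.  An effectively empty file is an error.
    """
    raw = open(path, "rb").read()
    genes: list[str] = []
    n_blank = n_comment = 0
    for line in raw.decode("utf-8").splitlines():
        stripped = line.strip()
        if not stripped:
            n_blank += 1
        elif stripped.startswith("#"):
            n_comment += 1
        else:
            genes.append(stripped.upper())
    unique = set(genes)
    if not unique:
        raise DataValidationError(
            f"secretome file {path} contains no gene ids "
            f"({n_comment} comment, {n_blank} blank lines)"
        )
    n_dup = len(genes) - len(unique)
    if n_dup or n_blank:
        logger.info("secretome %s: %d duplicate and %d blank lines collapsed",
                    path, n_dup, n_blank)
    return SecretomeList(genes=unique, source=str(path),
                         sha256=hashlib.sha256(raw).hexdigest())


def annotate_pairs(
    pairs: list[CorrelatedPair], secretome: SecretomeList
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Flag each pair's tubule/glomerulus gene as secreted or not.

    Returns ``(table, counts)``.  Counts are of *distinct* secreted genes per
    compartment side (a secreted gene appearing in three pairs counts once).
    Pairs whose tubule-side gene is secreted rank first: a secreted tubular
    product is the natural candidate ligand acting on the glomerulus.
    Annotation never adds or removes pairs.
    """
    rows = []
    for p in pairs:
        rows.append({
            "tubule_gene": p.tubule_gene,
            "glom_gene": p.glom_gene,
            "consensus_sign": p.consensus_sign,
            "median_r": p.median_r,
            "tubule_secreted": p.tubule_gene in secretome,
            "glom_secreted": p.glom_gene in secretome,
        })
    table = pd.DataFrame(rows, columns=["tubule_gene", "glom_gene", "consensus_sign",
                                        "median_r", "tubule_secreted", "glom_secreted"])
    if len(table):
        table = table.sort_values(
            by=["tubule_secreted", "glom_secreted", "tubule_gene", "glom_gene"],
            ascending=[False, False, True, True], kind="stable",
        ).reset_index(drop=True)
    counts = {
        "tubule": len({p.tubule_gene.strip().upper() for p in pairs} & secretome.genes),
        "glomerulus": len({p.glom_gene.strip().upper() for p in pairs} & secretome.genes),
    }
    return table, counts
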