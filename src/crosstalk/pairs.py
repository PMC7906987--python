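"""Cross-compartment correlation screening.

For each paired cohort (tubule and glomerulus profiled in the same
patients), every tubular-DEG x glomerular-DEG pair is correlated across
patients with Pearson, Spearman, and Kendall coefficients.  A pair survives
a cohort when the configured consensus rule passes, and becomes a consensus
pair when it survives every cohort with a consistent sign.

The magnitude cutoff ``r_min`` is stated on the Pearson scale.  Rank
coefficients are systematically attenuated relative to Pearson's r: under a
bivariate normal with correlation r, the population values are
rho_s = (6/pi) asin(r/2) and tau = (2/pi) asin(r) (Greiner's relation), so
tau never exceeds ~0.64 even at r = 0.85.  By default the cutoff applied to
Spearman and Kendall is therefore mapped through these relations so all
three tests are of equivalent stringency; set
``AnalysisConfig.match_rank_thresholds = False`` to apply r_min verbatim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AnalysisConfig, ExpressionDataset
from .exceptions import DataValidationError

logger = logging.getLogger(__name__)

METHODS = ("pearson", "spearman", "kendall")


@dataclass
class CorrelationTriple:
    """All three correlation coefficients of one gene pair in one cohort."""

    r_pearson: float
    p_pearson: float
    rho_spearman: float
    p_spearman: float
    tau_kendall: float
    p_kendall: float
    n_patients: int

    def sign(self) -> int:
        return int(np.sign(self.r_pearson))


@dataclass
class CorrelatedPair:
    """A (tubule gene, glomerulus gene) pair surviving every paired cohort."""

    tubule_gene: str
    glom_gene: str
    per_cohort: dict[str, CorrelationTriple] = field(default_factory=dict)
    consensus_sign: str = "pos"   # 'pos' | 'neg'

    @property
    def median_r(self) -> float:
        return float(median(t.r_pearson for t in self.per_cohort.values()))

    @property
    def key(self) -> tuple[str, str]:
        return (self.tubule_gene, self.glom_gene)


# ---------------------------------------------------------------------------
# coefficients
# ---------------------------------------------------------------------------

def _t_pvalue(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """One coefficient and two-sided p-value.

    Pearson: product-moment r with t-distribution p (df = n-2).
    Spearman: Pearson on average ranks, same t approximation.
    Kendall: tau-b (tie-corrected) with the asymptotic normal p.
    Constant input returns (nan, nan): undefined, never coerced to 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataValidationError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise DataValidationError("need >=3 paired observations")
    if method not in METHODS:
        raise DataValidationError(f"method must be one of {METHODS}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    if method == "kendall":
        res = stats.kendalltau(x, y, variant="b", method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.clip((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)), -1.0, 1.0))
    return r, _t_pvalue(r, n)


def correlation_triple(x, y) -> CorrelationTriple:
    rp, pp = correlate(x, y, "pearson")
    rs, ps = correlate(x, y, "spearman")
    rk, pk = correlate(x, y, "kendall")
    return CorrelationTriple(rp, pp, rs, ps, rk, pk, n_patients=len(x))


def _pearson_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-by-row cross-correlation matrix, NaN for constant rows."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    xn = np.sqrt((xc**2).sum(axis=1))
    yn = np.sqrt((yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc.T) / np.outer(xn, yn)
    r[xn == 0, :] = np.nan
    r[:, yn == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def _t_pvalue_matrix(r: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def equivalent_rank_thresholds(r_min: float) -> tuple[float, float]:
    """Map a Pearson-scale cutoff to equally stringent Spearman/Kendall cutoffs
    via the bivariate-normal relations rho_s = 6/pi*asin(r/2), tau = 2/pi*asin(r).
    """
    return (float(6.0 / np.pi * np.arcsin(r_min / 2.0)),
            float(2.0 / np.pi * np.arcsin(r_min)))


# ---------------------------------------------------------------------------
# pair screening
# ---------------------------------------------------------------------------

def _aligned_matrices(
    tub: ExpressionDataset, glom: ExpressionDataset, tub_degs, glom_degs
) -> tuple[np.ndarray, np.ndarray, list[str], list[str], int]:
    if tub.patient_id is None or glom.patient_id is None:
        raise DataValidationError("paired correlation requires patient ids on both datasets")
    shared = sorted(set(tub.patient_id) & set(glom.patient_id))
    if len(shared) < 3:
        raise DataValidationError(
            f"cohort ({tub.dataset_id}, {glom.dataset_id}) shares "
            f"{len(shared)} patients; need >=3"
        )
    # one sample per patient per compartment (first occurrence wins, stable)
    tub_samples = {p: s for s, p in reversed(list(tub.patient_id.items()))}
    glom_samples = {p: s for s, p in reversed(list(glom.patient_id.items()))}
    tub_cols = [tub_samples[p] for p in shared]
    glom_cols = [glom_samples[p] for p in shared]

    tub_genes = [g for g in sorted(set(tub_degs)) if g in tub.values.index]
    glom_genes = [g for g in sorted(set(glom_degs)) if g in glom.values.index]
    missing_t = sorted(set(tub_degs) - set(tub_genes))
    missing_g = sorted(set(glom_degs) - set(glom_genes))
    if missing_t or missing_g:
        logger.warning(
            "cohort (%s, %s): %d tubular and %d glomerular DEGs absent from the "
            "matrices were skipped", tub.dataset_id, glom.dataset_id,
            len(missing_t), len(missing_g),
        )
    if not tub_genes or not glom_genes:
        raise DataValidationError("no DEG present in the paired matrices")
    x = tub.values.loc[tub_genes, tub_cols].to_numpy(dtype=float)
    y = glom.values.loc[glom_genes, glom_cols].to_numpy(dtype=float)
    return x, y, tub_genes, glom_genes, len(shared)


def find_pairs_one_cohort(
    tub: ExpressionDataset,
    glom: ExpressionDataset,
    tub_degs,
    glom_degs,
    config: AnalysisConfig,
) -> dict[tuple[str, str], CorrelationTriple]:
    """Screen the tubular-DEG x glomerular-DEG universe in one paired cohort.

    Samples are aligned by patient before correlating.  Pearson and Spearman
    are evaluated as full vectorized matrices; Kendall (the costly
    coefficient) is evaluated only on pairs whose fate still depends on it.
    Returns the surviving pairs with their full correlation triple.
    """
    config.validate()
    x, y, tub_genes, glom_genes, n = _aligned_matrices(tub, glom, tub_degs, glom_degs)

    if config.match_rank_thresholds:
        s_min, k_min = equivalent_rank_thresholds(config.r_min)
    else:
        s_min = k_min = config.r_min

    rp = _pearson_matrix(x, y)
    pp = _t_pvalue_matrix(rp, n)
    xr = np.apply_along_axis(stats.rankdata, 1, x)
    yr = np.apply_along_axis(stats.rankdata, 1, y)
    rs = _pearson_matrix(xr, yr)
    ps = _t_pvalue_matrix(rs, n)

    pass_p = (np.abs(rp) > config.r_min) & (pp < config.corr_p_max)
    pass_s = (np.abs(rs) > s_min) & (ps < config.corr_p_max)
    same_sign = np.sign(rp) == np.sign(rs)

    if config.corr_consensus == "pearson_only":
        candidates = np.argwhere(pass_p)
    elif config.corr_consensus == "all_three":
        candidates = np.argwhere(pass_p & pass_s & same_sign)
    else:  # any_one: kendall can rescue any pair, so all defined pairs stay in
        candidates = np.argwhere(~np.isnan(rp))

    out: dict[tuple[str, str], CorrelationTriple] = {}
    for i, j in candidates:
        res = stats.kendalltau(x[i], y[j], variant="b", method="asymptotic")
        rk, pk = float(res.statistic), float(res.pvalue)
        pass_k = (abs(rk) > k_min) and (pk < config.corr_p_max)
        if config.corr_consensus == "all_three":
            keep = pass_p[i, j] and pass_s[i, j] and pass_k and (
                np.sign(rk) == np.sign(rp[i, j]))
        elif config.corr_consensus == "pearson_only":
            keep = bool(pass_p[i, j])
        else:
            keep = bool(pass_p[i, j] or pass_s[i, j] or pass_k)
        if keep:
            out[(tub_genes[i], glom_genes[j])] = CorrelationTriple(
                r_pearson=float(rp[i, j]), p_pearson=float(pp[i, j]),
                rho_spearman=float(rs[i, j]), p_spearman=float(ps[i, j]),
                tau_kendall=rk, p_kendall=pk, n_patients=n,
            )
    return out


def intersect_pairs(
    per_cohort: dict[str, dict[tuple[str, str], CorrelationTriple]],
    require_sign_consistency: bool = True,
) -> list[CorrelatedPair]:
    """Pairs present in ALL cohorts, merged into CorrelatedPair records.

    With sign consistency (default) a pair whose Pearson sign flips between
    cohorts is rejected.  Output order is deterministic (sorted by gene pair).
    """
    if not per_cohort:
        raise DataValidationError("need at least one cohort")
    cohort_ids = list(per_cohort)
    common = set(per_cohort[cohort_ids[0]])
    for cid in cohort_ids[1:]:
        common &= set(per_cohort[cid])
    pairs: list[CorrelatedPair] = []
    for key in sorted(common):
        triples = {cid: per_cohort[cid][key] for cid in cohort_ids}
        signs = {t.sign() for t in triples.values()}
        if require_sign_consistency and len(signs) > 1:
            continue
        sign = next(iter(signs)) if len(signs) == 1 else int(
            np.sign(sum(t.sign() for t in triples.values())) or 1)
        pairs.append(CorrelatedPair(
            tubule_gene=key[0], glom_gene=key[1], per_cohort=triples,
            consensus_sign="pos" if sign >= 0 else "neg",
        ))
    return pairs


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def build_network(pairs: list[CorrelatedPair]):
    """Bipartite signed network of consensus pairs (networkx Graph).

    Nodes carry ``side`` in {tubule, glomerulus, both}; edges carry the
    consensus sign and the median Pearson coefficient across cohorts.
    """
    import networkx as nx

    if not pairs:
        raise DataValidationError("cannot build a network from zero pairs")
    g = nx.Graph()
    tub_side = {p.tubule_gene for p in pairs}
    glom_side = {p.glom_gene for p in pairs}
    for gene in sorted(tub_side | glom_side):
        side = ("both" if gene in tub_side and gene in glom_side
                else "tubule" if gene in tub_side else "glomerulus")
        g.add_node(gene, side=side)
    for p in pairs:
        g.add_edge(p.tubule_gene, p.glom_gene, sign=p.consensus_sign,
                   median_r=p.median_r)
    return g


def pairs_table(pairs: list[CorrelatedPair]) -> pd.DataFrame:
    """Flat per-pair table (one row per pair, per-cohort triples unpacked)."""
    rows = []
    for p in pairs:
        row = {"tubule_gene": p.tubule_gene, "glom_gene": p.glom_gene,
               "consensus_sign": p.consensus_sign, "median_r": p.median_r}
        for cid, t in sorted(p.per_cohort.items()):
            row.update({
                f"{cid}.r_pearson": t.r_pearson, f"{cid}.p_pearson": t.p_pearson,
                f"{cid}.rho_spearman": t.rho_spearman, f"{cid}.p_spearman": t.p_spearman,
                f"{cid}.tau_kendall": t.tau_kendall, f"{cid}.p_kendall": t.p_kendall,
                f"{cid}.n_patients": t.n_patients,
            })
        rows.append(row)
    return pd.DataFrame(rows)


def expected_false_pairs(n_tests: int, config: AnalysisConfig, n_cohorts: int) -> float:
    """Implied expected count of null pairs passing all cohorts at corr_p_max.

    Raw p-values are not multiple-testing corrected (the screen applies a raw
    p cutoff); this bound (n_tests * (corr_p_max/2)^n_cohorts, the factor 2
    from the sign-consistency requirement) is logged for transparency.
    """
    per_cohort = config.corr_p_max / 2.0
    return float(n_tests * per_cohort**n_cohorts)
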