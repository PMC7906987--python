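"""Dual-method differential-expression meta-analysis.

Two independent lines of evidence are combined per compartment:

1. *Effect sizes*: per-dataset Hedges' g (bias-corrected standardized mean
   difference, case minus control) pooled with a fixed-effect
   inverse-variance model; two-sided normal p on the pooled z; BH FDR.
2. *SAM with cross-dataset replication*: per-dataset SAM statistic
   d = (mean_case - mean_control)/(s + s0) with permutation q-values, then a
   cross-dataset combination: Fisher's chi-square combination of per-dataset
   permutation p-values (default), or an exact binomial tail on the number
   of datasets calling the gene at q < sam_q_max.

A gene is a final DEG only when it passes both methods.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import stage_rng
from .datatypes import AnalysisConfig, ExpressionDataset
from .exceptions import DataValidationError, DegenerateDataError

__all__ = [
    "hedges_g",
    "combine_effect_sizes",
    "bh_fdr",
    "sam_statistic",
    "choose_s0",
    "sam_qvalues",
    "replication_test",
    "fisher_combine",
    "meta_analyze",
    "call_degs",
    "export_enrichment_genelist",
    "MetaAnalysisResult",
]


# ---------------------------------------------------------------------------
# effect sizes
# ---------------------------------------------------------------------------

def _hedges_g_arrays(case: np.ndarray, control: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Hedges' g per row. Returns (g, var_g); NaN where degenerate."""
    n1, n2 = case.shape[1], control.shape[1]
    if n1 < 2 or n2 < 2:
        raise DataValidationError("Hedges' g needs >=2 samples per group")
    m1 = case.mean(axis=1)
    m2 = control.mean(axis=1)
    ss1 = ((case - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((control - m2[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    s2p = (ss1 + ss2) / df
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = j * (m1 - m2) / np.sqrt(s2p)
    g = np.where(s2p > 0, g, np.nan)
    var_g = (n1 + n2) / (n1 * n2) + g**2 / (2.0 * (n1 + n2))
    return g, var_g


def hedges_g(case_values, control_values) -> tuple[float, float]:
    """Bias-corrected standardized mean difference and its sampling variance.

    g = J * (mean_case - mean_control) / s_pooled with pooled-SD degrees of
    freedom n1+n2-2 and small-sample correction J = 1 - 3/(4(n1+n2-2) - 1);
    var_g = (n1+n2)/(n1*n2) + g^2/(2(n1+n2)).
    """
    case = np.asarray(case_values, dtype=float)[None, :]
    control = np.asarray(control_values, dtype=float)[None, :]
    g, var_g = _hedges_g_arrays(case, control)
    if np.isnan(g[0]):
        raise DegenerateDataError("zero pooled standard deviation; effect size undefined")
    return float(g[0]), float(var_g[0])


def combine_effect_sizes(gs, var_gs) -> tuple[float, float, float, float]:
    """Fixed-effect inverse-variance pooling of per-dataset effect sizes.

    Returns (f_meta, se, z, p): f_meta = sum(w_i g_i)/sum(w_i) with
    w_i = 1/var_i, se = sqrt(1/sum(w_i)), z = f_meta/se, p two-sided normal.
    """
    gs = np.asarray(gs, dtype=float)
    var_gs = np.asarray(var_gs, dtype=float)
    if gs.size == 0:
        raise DataValidationError("no usable effect-size records")
    if (var_gs <= 0).any():
        raise DataValidationError("effect-size variances must be positive")
    w = 1.0 / var_gs
    f_meta = float((w * gs).sum() / w.sum())
    se = float(np.sqrt(1.0 / w.sum()))
    z = f_meta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return f_meta, se, z, p


def heterogeneity(gs, var_gs) -> tuple[float, float]:
    """Cochran's Q and I^2 (logged for transparency; never gates calls)."""
    gs = np.asarray(gs, dtype=float)
    w = 1.0 / np.asarray(var_gs, dtype=float)
    f = (w * gs).sum() / w.sum()
    q = float((w * (gs - f) ** 2).sum())
    k = gs.size
    i2 = float(max(0.0, (q - (k - 1)) / q)) if q > 0 and k > 1 else 0.0
    return q, i2


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise DataValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def _sam_terms(values: np.ndarray, case_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene numerator (mean diff) and gene-wise scatter s_i of the SAM d."""
    n1 = int(case_mask.sum())
    n2 = case_mask.size - n1
    if n1 < 2 or n2 < 2:
        raise DataValidationError("SAM needs >=2 samples per group")
    case = values[:, case_mask]
    control = values[:, ~case_mask]
    m1 = case.mean(axis=1)
    m2 = control.mean(axis=1)
    ss = ((case - m1[:, None]) ** 2).sum(axis=1) + ((control - m2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2) * ss)
    return m1 - m2, s


def sam_statistic(values, group_labels, s0: float = 0.0) -> np.ndarray:
    """SAM relative difference d_i = (mean_case_i - mean_control_i)/(s_i + s0).

    s_i = sqrt((1/n1 + 1/n2)/(n1+n2-2) * (sum case devs^2 + sum control devs^2)).
    Genes with s_i + s0 == 0 get NaN (flagged undefined).
    """
    if s0 < 0:
        raise DataValidationError("s0 must be non-negative")
    vals = np.asarray(values, dtype=float)
    case_mask = _case_mask(group_labels, vals.shape[1])
    num, s = _sam_terms(vals, case_mask)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = num / (s + s0)
    return np.where(s + s0 > 0, d, np.nan)


def _case_mask(group_labels, n_samples: int) -> np.ndarray:
    labels = np.asarray(group_labels)
    if labels.size != n_samples:
        raise DataValidationError("group labels do not match sample count")
    if labels.dtype == bool:
        return labels
    mask = labels == "case"
    if not set(np.unique(labels)) <= {"case", "control"}:
        raise DataValidationError("group labels must be 'case'/'control' or boolean")
    return mask


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def choose_s0(per_gene_s, per_gene_numerators) -> float:
    """Select the SAM fudge factor s0 (Tusher-style).

    Candidates are the percentiles {0, 5, ..., 100} of the gene-wise scatter
    s.  The chosen s0 minimizes the coefficient of variation of the median
    absolute deviation of d = num/(s + s0) across 100 s-quantile windows,
    which decouples the spread of d from the expression-dependent scatter.
    Ties take the smallest candidate.  Below 100 genes the criterion is too
    noisy and the 5th percentile of s is used.
    """
    s = np.asarray(per_gene_s, dtype=float)
    num = np.asarray(per_gene_numerators, dtype=float)
    if s.size != num.size or s.size == 0:
        raise DataValidationError("s and numerators must be equal-length and non-empty")
    if s.size < 100:
        return float(np.percentile(s, 5))
    candidates = np.percentile(s, np.arange(0, 101, 5))
    n_bins = 100
    edges = np.quantile(s, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_bins - 1)
    groups = pd.Series(np.arange(s.size)).groupby(bins).groups
    best_cv, best_cand = np.inf, None
    for cand in candidates:
        denom = s + cand
        if (denom <= 0).any():
            continue
        d = num / denom
        mads = np.array([_mad(d[idx]) for idx in groups.values()])
        mean_mad = mads.mean()
        cv = 0.0 if mads.std() == 0 else (np.inf if mean_mad == 0 else mads.std() / mean_mad)
        if cv < best_cv:  # strict: ties keep the smaller (earlier) candidate
            best_cv, best_cand = cv, float(cand)
    if best_cand is None:
        raise DegenerateDataError("no valid s0 candidate (all-zero scatter)")
    return best_cand


@dataclass
class SamResult:
    """Per-gene SAM output for one dataset."""

    d: np.ndarray           # observed statistic
    q: np.ndarray           # permutation q-value (fraction, monotone in |d| rank)
    p_perm: np.ndarray      # pooled permutation p-value of |d| (for combination)
    s0: float
    n_permutations: int     # distinct label assignments actually used
    exact: bool             # True when all assignments were enumerated


def _permutation_masks(n: int, n1: int, n_permutations: int, rng) -> tuple[np.ndarray, bool]:
    total = comb(n, n1)
    if total < 10:
        raise DataValidationError(
            f"only {total} distinct label assignments exist (need >=10); "
            "exact enumeration was attempted but is too small to estimate q-values"
        )
    if total <= n_permutations:
        masks = np.zeros((total, n), dtype=bool)
        for b, idx in enumerate(itertools.combinations(range(n), n1)):
            masks[b, list(idx)] = True
        return masks, True
    # sample assignments: first n1 positions of a random permutation
    keys = rng.random((n_permutations, n))
    order = np.argsort(keys, axis=1)
    masks = np.zeros((n_permutations, n), dtype=bool)
    rows = np.repeat(np.arange(n_permutations), n1)
    masks[rows, order[:, :n1].ravel()] = True
    return masks, False


def sam_qvalues(
    values,
    group_labels,
    n_permutations: int = 1000,
    seed: int = 0,
    s0: float | None = None,
    rng=None,
) -> SamResult:
    """Permutation-based SAM q-values for one dataset.

    For each gene ranked by |d|, the estimated FDR at threshold |d|_(i) is
    the mean (over label permutations) count of null |d*| at or above the
    threshold, pooled across genes, divided by the observed count i, capped
    at 1.  q_i is the minimum estimated FDR over all thresholds at least as
    lenient as the gene's own, so q is monotone in the |d| ranking.  When
    fewer than ``n_permutations`` distinct label assignments exist they are
    enumerated exactly.

    ``p_perm`` is the pooled permutation p-value of each |d| with add-one
    smoothing, used by the Fisher cross-dataset combination.
    """
    vals = np.asarray(values, dtype=float)
    n_genes, n = vals.shape
    case_mask = _case_mask(group_labels, n)
    n1 = int(case_mask.sum())
    if rng is None:
        rng = np.random.default_rng(seed)

    num, s = _sam_terms(vals, case_mask)
    if s0 is None:
        s0 = choose_s0(s, num)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(s + s0 > 0, num / (s + s0), np.nan)
    absd = np.abs(d)

    masks, exact = _permutation_masks(n, n1, n_permutations, rng)
    b_used = masks.shape[0]
    n2 = n - n1
    tot_sum = vals.sum(axis=1)
    tot_sq = (vals**2).sum(axis=1)
    s1 = vals @ masks.T.astype(float)            # genes x B case sums
    q1 = (vals**2) @ masks.T.astype(float)
    m1 = s1 / n1
    m2 = (tot_sum[:, None] - s1) / n2
    ss = (q1 - n1 * m1**2) + ((tot_sq[:, None] - q1) - n2 * m2**2)
    ss = np.maximum(ss, 0.0)                     # guard tiny negative round-off
    s_star = np.sqrt((1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2) * ss)
    with np.errstate(divide="ignore", invalid="ignore"):
        d_star = np.where(s_star + s0 > 0, (m1 - m2) / (s_star + s0), np.nan)
    null_abs = np.sort(np.abs(d_star[np.isfinite(d_star)]).ravel())
    n_null = null_abs.size

    defined = np.isfinite(absd)
    q = np.full(n_genes, np.nan)
    p_perm = np.full(n_genes, np.nan)
    if defined.any():
        vals_def = absd[defined]
        uniq = np.unique(vals_def)[::-1]          # descending thresholds
        obs_sorted = np.sort(vals_def)
        n_def = vals_def.size
        # counts at each unique threshold; the null |d*| are compared with a
        # relative epsilon so permutations reproducing the observed labeling
        # are counted despite round-off in the vectorized sums-of-squares
        thr = uniq - 1e-9 * np.abs(uniq)
        i_u = n_def - np.searchsorted(obs_sorted, uniq, side="left")
        null_ge = n_null - np.searchsorted(null_abs, thr, side="left")
        fdr_u = np.minimum((null_ge / b_used) / i_u, 1.0)
        q_u = np.minimum.accumulate(fdr_u[::-1])[::-1]
        idx = np.searchsorted(-uniq, -vals_def)   # position of each gene's threshold
        q[defined] = q_u[idx]
        thr_g = vals_def - 1e-9 * np.abs(vals_def)
        p_perm[defined] = (1.0 + (n_null - np.searchsorted(null_abs, thr_g, side="left"))) / (
            1.0 + n_null
        )
    return SamResult(d=d, q=q, p_perm=p_perm, s0=float(s0),
                     n_permutations=b_used, exact=exact)


# ---------------------------------------------------------------------------
# cross-dataset combination of SAM evidence
# ---------------------------------------------------------------------------

def replication_test(k_significant: int, m_datasets: int, rate: float) -> float:
    """One-sided exact binomial tail P(K >= k | m, rate).

    The probability of a gene being called significant in >= k of m datasets
    if per-dataset calls were null at the per-dataset q cutoff rate.
    """
    if not (0 <= k_significant <= m_datasets):
        raise DataValidationError("need 0 <= k <= m")
    if not (0.0 < rate < 1.0):
        raise DataValidationError("rate must be in (0, 1)")
    return float(stats.binom.sf(k_significant - 1, m_datasets, rate))


def fisher_combine(p_values) -> float:
    """Fisher's method: -2 * sum(ln p) against chi-square with 2m df."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0 or ((p <= 0) | (p > 1)).any():
        raise DataValidationError("p-values must lie in (0, 1]")
    x = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x, 2 * p.size))


# ---------------------------------------------------------------------------
# per-compartment orchestration
# ---------------------------------------------------------------------------

@dataclass
class MetaAnalysisResult:
    """All per-gene tables of one compartment's meta-analysis."""

    effects: pd.DataFrame       # gene x dataset Hedges' g records
    meta: pd.DataFrame          # pooled effect sizes (index: gene)
    sam: pd.DataFrame           # per-dataset SAM d/q/p_perm records
    replication: pd.DataFrame   # cross-dataset combination (index: gene)
    calls: pd.DataFrame         # final DEG calls (index: gene)
    s0_by_dataset: dict = field(default_factory=dict)
    excluded: dict = field(default_factory=dict)   # gene -> reason

    def deg_genes(self) -> set[str]:
        return set(self.calls.index[self.calls["final"]])


def meta_analyze(datasets: list[ExpressionDataset], config: AnalysisConfig) -> MetaAnalysisResult:
    """Run the dual-method DEG meta-analysis over one compartment's datasets."""
    config.validate()
    usable = [ds for ds in datasets if ds.meta_ready]
    if not usable:
        raise DataValidationError("no dataset with >=2 case and >=2 control samples")

    # --- method 1: pooled effect sizes -------------------------------------
    effect_rows = []
    for ds in usable:
        case = ds.case_matrix().to_numpy(dtype=float)
        control = ds.control_matrix().to_numpy(dtype=float)
        g, var_g = _hedges_g_arrays(case, control)
        log2fc = case.mean(axis=1) - control.mean(axis=1)
        effect_rows.append(pd.DataFrame({
            "gene": ds.genes,
            "dataset_id": ds.dataset_id,
            "g": g,
            "var_g": var_g,
            "n_case": ds.n_case,
            "n_control": ds.n_control,
            "log2fc": log2fc,
        }))
    effects = pd.concat(effect_rows, ignore_index=True)
    usable_effects = effects.dropna(subset=["g"])

    meta_rows = []
    for gene, grp in usable_effects.groupby("gene", sort=True):
        if len(grp) < config.min_datasets_present:
            continue
        f_meta, se, z, p = combine_effect_sizes(grp["g"].to_numpy(), grp["var_g"].to_numpy())
        q_het, i2 = heterogeneity(grp["g"].to_numpy(), grp["var_g"].to_numpy())
        meta_rows.append({
            "gene": gene, "f_meta": f_meta, "se": se, "z": z, "p": p,
            "mean_log2fc": float(grp["log2fc"].mean()),
            "n_datasets_used": len(grp), "het_q": q_het, "het_i2": i2,
        })
    if not meta_rows:
        raise DataValidationError(
            f"no gene present in >= {config.min_datasets_present} datasets"
        )
    meta = pd.DataFrame(meta_rows).set_index("gene")
    meta["q_fdr"] = bh_fdr(meta["p"].to_numpy())

    # --- method 2: SAM + cross-dataset combination -------------------------
    sam_rows = []
    s0_by_dataset = {}
    for ds in usable:
        rng = stage_rng(config.seed, "sam_permutations", ds.dataset_id)
        res = sam_qvalues(ds.values.to_numpy(dtype=float), ds.group.loc[ds.samples].to_numpy(),
                          n_permutations=config.n_permutations, rng=rng)
        s0_by_dataset[ds.dataset_id] = res.s0
        sam_rows.append(pd.DataFrame({
            "gene": ds.genes, "dataset_id": ds.dataset_id,
            "d": res.d, "q": res.q, "p_perm": res.p_perm,
        }))
    sam = pd.concat(sam_rows, ignore_index=True)
    sam_defined = sam.dropna(subset=["q"])

    repl_rows = []
    for gene, grp in sam_defined.groupby("gene", sort=True):
        m = len(grp)
        if m < config.min_datasets_present:
            continue
        k = int((grp["q"] < config.sam_q_max).sum())
        if config.sam_combine == "binomial":
            p_repl = replication_test(k, m, config.sam_q_max)
        else:
            p_repl = fisher_combine(grp["p_perm"].to_numpy())
        repl_rows.append({"gene": gene, "k_significant": k, "m_datasets": m,
                          "p_repl": p_repl})
    replication = pd.DataFrame(repl_rows, columns=["gene", "k_significant", "m_datasets", "p_repl"])
    replication = replication.set_index("gene")

    calls, excluded = call_degs(meta, replication, config)
    return MetaAnalysisResult(effects=effects, meta=meta, sam=sam,
                              replication=replication, calls=calls,
                              s0_by_dataset=s0_by_dataset, excluded=excluded)


def call_degs(
    meta: pd.DataFrame, replication: pd.DataFrame, config: AnalysisConfig
) -> tuple[pd.DataFrame, dict]:
    """Final DEG call = (effect-size q_fdr <= fdr_max) AND (p_repl <= repl_p_max).

    Genes missing from either method are never final DEGs; they are reported
    in the returned ``excluded`` mapping with the reason.
    """
    genes = sorted(set(meta.index) | set(replication.index))
    excluded: dict[str, str] = {}
    rows = []
    for gene in genes:
        in_meta = gene in meta.index
        in_sam = gene in replication.index
        if not in_meta:
            excluded[gene] = "missing_effect"
        elif not in_sam:
            excluded[gene] = "missing_sam"
        q_fdr = float(meta.at[gene, "q_fdr"]) if in_meta else np.nan
        p_repl = float(replication.at[gene, "p_repl"]) if in_sam else np.nan
        passes_effect = bool(in_meta and q_fdr <= config.fdr_max)
        passes_sam = bool(in_sam and p_repl <= config.repl_p_max)
        direction = int(np.sign(meta.at[gene, "f_meta"])) if in_meta else 0
        rows.append({
            "gene": gene, "passes_effect": passes_effect, "passes_sam": passes_sam,
            "final": passes_effect and passes_sam, "direction": direction,
            "reason": excluded.get(gene, ""),
        })
    calls = pd.DataFrame(rows).set_index("gene")
    return calls, excluded


def export_enrichment_genelist(
    calls: pd.DataFrame, meta: pd.DataFrame, config: AnalysisConfig
) -> dict[str, list[str]]:
    """Final DEGs passing |mean_log2fc| >= log2(fold_change_min), split by direction.

    These lists are the hand-off to external GO/pathway enrichment tools.
    """
    cut = np.log2(config.fold_change_min)
    final = calls.index[calls["final"]]
    up, down = [], []
    for gene in final:
        fc = float(meta.at[gene, "mean_log2fc"])
        if abs(fc) >= cut:
            (up if fc > 0 else down).append(gene)
    return {"up": sorted(up), "down": sorted(down)}
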