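"""Pathological-signature importance and molecular association analysis.

Signature importance is permutation importance on the final ensemble output:
how much the WSI-level AUC drops when one of the 200 slide features
(histogram bin or TF-IDF word weight) is shuffled across slides.  The
molecular side computes the standard genomic quantities (tumor mutation
burden, INDEL load, gene-set deficiency calls) from a MAF-like mutation
table — synonymous variants are excluded throughout — and the transcriptomic
immune scores (cytolytic activity, CD8 T-effector mean), with Wilcoxon
rank-sum and Spearman machinery for group contrasts and correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .aggregation import EplaModel
from .evaluation import roc_auc

#: MAF Variant_Classification -> controlled vocabulary
MAF_CLASS_MAP = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Nonstop_Mutation": "nonsense",
    "Frame_Shift_Ins": "INS",
    "Frame_Shift_Del": "DEL",
    "In_Frame_Ins": "INS",
    "In_Frame_Del": "DEL",
    "Splice_Site": "frameshift",
    "Translation_Start_Site": "missense",
    "Silent": "synonymous",
}

SYNONYMOUS = "synonymous"
DEFAULT_EXOME_MB = 38.0

MMR_GENE_SET = frozenset({"MLH1", "MSH2", "MSH6", "PMS2"})
CD8_TEFF_SET = ("CD8A", "IFNG", "GZMA", "PRF1", "CXCL9", "CXCL10", "TBX21", "GZMB")


def load_maf(path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a MAF-like TSV into (sample_id, gene, variant_class) rows."""
    df = pd.read_csv(path, sep={"tsv": "\t", "csv": ","}[dialect])
    cols = {c.lower(): c for c in df.columns}
    sid = cols.get("sample_id") or cols.get("tumor_sample_barcode")
    gene = cols.get("gene") or cols.get("hugo_symbol")
    vc = cols.get("variant_class") or cols.get("variant_classification")
    out = df[[sid, gene, vc]].copy()
    out.columns = ["sample_id", "gene", "variant_class"]
    out["variant_class"] = out["variant_class"].map(
        lambda v: MAF_CLASS_MAP.get(v, v)
    )
    return out


def _sample_rows(profile: pd.DataFrame, sample_id: str) -> pd.DataFrame:
    if sample_id not in set(profile["sample_id"]):
        raise KeyError(f"unknown sample {sample_id!r}")
    return profile[profile["sample_id"] == sample_id]


def _nonsynonymous(rows: pd.DataFrame) -> pd.DataFrame:
    return rows[rows["variant_class"] != SYNONYMOUS]


def tmb(profile: pd.DataFrame, sample_id: str,
        exome_size_mb: float = DEFAULT_EXOME_MB) -> float:
    """Tumor mutation burden: nonsynonymous mutations per Mb of exome."""
    rows = _sample_rows(profile, sample_id)
    return len(_nonsynonymous(rows)) / exome_size_mb


def indel_load(profile: pd.DataFrame, sample_id: str) -> int:
    """Count of insertion/deletion variant rows for the sample."""
    rows = _sample_rows(profile, sample_id)
    return int(rows["variant_class"].isin(("INS", "DEL")).sum())


def pathway_deficiency(profile: pd.DataFrame, sample_id: str, gene_set) -> str:
    """'deficient' iff the sample has any nonsynonymous hit in the gene set."""
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    rows = _nonsynonymous(_sample_rows(profile, sample_id))
    return "deficient" if rows["gene"].isin(gene_set).any() else "proficient"


def minmax_normalize(values) -> np.ndarray:
    """Scale to [0,1]; an all-equal input maps to 0.5 everywhere (with warning)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one value")
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn("constant input to minmax_normalize; returning 0.5", stacklevel=2)
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def _expr_value(expr: pd.DataFrame, gene: str, sample_id: str) -> float:
    if gene not in expr.index:
        raise KeyError(f"gene {gene!r} absent from expression matrix")
    if sample_id not in expr.columns:
        raise KeyError(f"sample {sample_id!r} absent from expression matrix")
    return float(expr.loc[gene, sample_id])


def cyt_score(expr: pd.DataFrame, sample_id: str) -> float:
    """Cytolytic activity: geometric mean of GZMA and PRF1 with pseudocount 1."""
    g = _expr_value(expr, "GZMA", sample_id)
    p = _expr_value(expr, "PRF1", sample_id)
    return float(np.sqrt((g + 1) * (p + 1)) - 1)


def gene_set_score(expr: pd.DataFrame, sample_id: str,
                   genes=CD8_TEFF_SET) -> float:
    """Mean log2(x+1) expression over the present genes of a set.

    Missing genes are skipped with a warning; all genes missing is an error.
    """
    present = [g for g in genes if g in expr.index]
    if not present:
        raise KeyError("none of the requested genes present in expression matrix")
    missing = len(list(genes)) - len(present)
    if missing:
        warnings.warn(f"{missing} gene(s) of the set missing", stacklevel=2)
    vals = [np.log2(_expr_value(expr, g, sample_id) + 1) for g in present]
    return float(np.mean(vals))


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns the rank-sum statistic W of the first sample (midrank ties) and a
    two-sided p: exact by enumeration for small tie-free samples
    (n_x + n_y <= 12), else normal approximation with tie and continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    w = float(ranks[: x.size].sum())
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (x.size + y.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return w, float(res.pvalue)


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation (Pearson on midranks) with two-sided t-approx p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length inputs with at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        warnings.warn("constant input to spearman_corr; rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class ImportanceRanking:
    """Per-feature importances sorted by rank (1 = most important)."""

    table: pd.DataFrame  # columns: feature_name, importance, rank

    def top(self, k: int) -> list[str]:
        return self.table.head(k)["feature_name"].tolist()


def permutation_importance(
    signature_matrix: pd.DataFrame,
    labels,
    model: EplaModel,
    n_repeats: int = 5,
    seed: int = 0,
) -> ImportanceRanking:
    """Mean drop in ensemble AUC when one signature column is shuffled.

    Importance of a feature is the baseline WSI-level ensemble AUC minus the
    mean AUC over ``n_repeats`` independent shuffles of that column, clipped
    at zero.  Deterministic per seed.  Ties in importance rank by feature
    order.
    """
    from .aggregation import feature_names

    if list(signature_matrix.columns) != feature_names():
        raise ValueError("signature matrix columns do not match the fitted layout")
    x = signature_matrix.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    base = roc_auc(model.score_signature_matrix(x), y)
    importances = np.zeros(x.shape[1])
    for k in range(x.shape[1]):
        col = x[:, k]
        if np.unique(col).size == 1:
            continue  # shuffling a constant changes nothing
        drops = []
        for _ in range(n_repeats):
            xs = x.copy()
            xs[:, k] = rng.permutation(col)
            drops.append(base - roc_auc(model.score_signature_matrix(xs), y))
        importances[k] = max(float(np.mean(drops)), 0.0)
    order = np.argsort(-importances, kind="stable")
    table = pd.DataFrame(
        {
            "feature_name": signature_matrix.columns[order],
            "importance": importances[order],
            "rank": np.arange(1, len(order) + 1),
        }
    )
    return ImportanceRanking(table)


def association_table(names, statistics, pvalues) -> pd.DataFrame:
    """Assemble (name, statistic, p, adjusted_p) with Benjamini-Hochberg adjustment."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    prev = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        val = min(p[i] * n / (rank_idx + 1), prev)
        adj[i] = val
        prev = val
    return pd.DataFrame(
        {"name": names, "statistic": statistics, "p": p, "adjusted_p": adj}
    )
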