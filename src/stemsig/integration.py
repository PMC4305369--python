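"""Cross-dataset "virtual array" integration and clustering.

Datasets from different platforms are joined on their common gene symbols,
quantile-normalized to one reference distribution, and centered per gene
within each dataset (median), which removes additive platform/batch shifts
while preserving the between-group structure inside each dataset.  Downstream
come one-way ANOVA gene ranking, PCA with replicate barycenters, and
average-linkage correlation clustering with newick export.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_formats import AnnotationTable, DesignTable, ExpressionMatrix
from .preprocessing import quantile_between_arrays


def collapse_probes_to_genes(m: ExpressionMatrix,
                             ann: AnnotationTable) -> ExpressionMatrix:
    """Average each symbol's probes into one gene-level row.

    Unannotated probes are dropped (their IDs live on in probe-level outputs);
    symbols are upper-cased.  Row order follows first appearance.
    """
    symbols = pd.Series([ann.symbol_of(p) for p in m.values.index],
                        index=m.values.index)
    keep = symbols.notna()
    if not keep.any():
        raise ValueError("no probe of the matrix is covered by the annotation")
    sub = m.values[keep.to_numpy()]
    by_symbol = sub.groupby(symbols[keep].to_numpy(), sort=False).mean()
    by_symbol.index = [s.upper() for s in by_symbol.index]
    return ExpressionMatrix(by_symbol, m.design, level="gene")


@dataclass
class IntegratedMatrix:
    """Genes x samples matrix joined across datasets, with sample metadata."""

    values: pd.DataFrame      # common genes x all samples
    sample_meta: pd.DataFrame  # index sample_id; columns dataset, group

    @property
    def design(self) -> DesignTable:
        return DesignTable(self.sample_meta["group"])

    def samples_of_dataset(self, dataset: str) -> list[str]:
        return list(self.sample_meta.index[self.sample_meta["dataset"] == dataset])


def build_virtual_array(
    datasets: Sequence[ExpressionMatrix],
    dataset_labels: Optional[Sequence[str]] = None,
) -> IntegratedMatrix:
    """Join gene-level datasets on common symbols and remove batch shifts.

    Steps: restrict every dataset to the symbol intersection; quantile-
    normalize all samples jointly to one reference distribution; center each
    gene within each dataset by its per-dataset median.  Sample ids are
    prefixed with the dataset label when they would otherwise collide.
    """
    if len(datasets) < 2:
        raise ValueError("virtual array needs at least 2 datasets")
    if dataset_labels is None:
        dataset_labels = [f"ds{i + 1}" for i in range(len(datasets))]
    if len(dataset_labels) != len(datasets):
        raise ValueError("dataset_labels length mismatch")
    for d in datasets:
        if d.level != "gene":
            raise ValueError("virtual array integration requires gene-level matrices")

    common: Optional[set] = None
    for d in datasets:
        syms = set(d.values.index)
        common = syms if common is None else (common & syms)
    if not common:
        raise ValueError("empty common symbol set across datasets")
    genes = sorted(common)

    pieces = []
    meta_rows = []
    seen_samples: set[str] = set()
    for label, d in zip(dataset_labels, datasets):
        block = d.values.loc[genes].copy()
        rename = {}
        for s in block.columns:
            new = s if s not in seen_samples else f"{label}:{s}"
            rename[s] = new
            seen_samples.add(new)
        block = block.rename(columns=rename)
        pieces.append(block)
        for old, new in rename.items():
            meta_rows.append({"sample_id": new, "dataset": label,
                              "group": d.design.assignments[old]})
    joined = pd.concat(pieces, axis=1)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")

    design = DesignTable(meta["group"])
    qn = quantile_between_arrays(ExpressionMatrix(joined, design, level="gene"))
    values = qn.values
    for label in dataset_labels:
        cols = meta.index[meta["dataset"] == label]
        med = values[cols].median(axis=1)
        values[cols] = values[cols].sub(med, axis=0)
    return IntegratedMatrix(values=values, sample_meta=meta)


def anova_rank(values: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """One-way ANOVA of each gene across biological groups, ranked.

    Returns a frame (index gene) with columns F, p, sorted by ascending p,
    ties by descending F, then symbol order — a deterministic ranking.  Genes
    with zero between- and within-group variation get F = 0, p = 1.
    """
    seen: dict[str, None] = {}
    for g in groups:
        seen.setdefault(g, None)
    group_labels = list(seen)
    if len(group_labels) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    X = values.to_numpy(dtype=float)
    n_total = X.shape[1]
    grand = X.mean(axis=1)
    ss_between = np.zeros(X.shape[0])
    ss_within = np.zeros(X.shape[0])
    col_pos = {s: i for i, s in enumerate(values.columns)}
    for g in group_labels:
        cols = [col_pos[s] for s in groups.index[groups == g]]
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        sub = X[:, cols]
        mu = sub.mean(axis=1)
        ss_between += len(cols) * (mu - grand) ** 2
        ss_within += ((sub - mu[:, None]) ** 2).sum(axis=1)
    df_between = len(group_labels) - 1
    df_within = n_total - len(group_labels)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_between) / (ss_within / df_within)
    p = np.empty_like(F)
    finite = np.isfinite(F)
    p[finite] = stats.f.sf(F[finite], df_between, df_within)
    # within = 0: either no signal at all (F := 0, p = 1) or infinite F (p = 0)
    zero_within = ss_within == 0
    no_signal = zero_within & (ss_between <= 1e-300)
    F[no_signal] = 0.0
    p[no_signal] = 1.0
    inf_F = zero_within & ~no_signal
    F[inf_F] = np.inf
    p[inf_F] = 0.0
    out = pd.DataFrame({"F": F, "p": p}, index=values.index)
    out["_sym"] = out.index
    out = out.sort_values(by=["p", "F", "_sym"], ascending=[True, False, True])
    return out.drop(columns="_sym")


def top_n(ranked: pd.DataFrame, k: int = 1000) -> list[str]:
    """The first k genes of an :func:`anova_rank` result."""
    return list(ranked.index[:k])


@dataclass
class PcaResult:
    scores: pd.DataFrame            # samples x components
    barycenters: pd.DataFrame       # groups x components (replicate means)
    variance_fractions: np.ndarray


def pca_scores(values: pd.DataFrame, design: DesignTable) -> PcaResult:
    """Row-centered PCA over samples, with per-group replicate barycenters.

    Genes are features (rows); each is centered across samples before the
    SVD.  A constant matrix yields all-zero scores.
    """
    if values.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_comp = min(Xc.shape)
    scores = (Vt[:n_comp].T * s[:n_comp])
    total = float(np.sum(s**2))
    fractions = (s[:n_comp] ** 2 / total) if total > 0 else np.zeros(n_comp)
    if total == 0:
        scores = np.zeros_like(scores)
    cols = [f"PC{i + 1}" for i in range(n_comp)]
    score_df = pd.DataFrame(scores, index=values.columns, columns=cols)
    bary = score_df.groupby(design.assignments.loc[score_df.index], sort=False).mean()
    return PcaResult(scores=score_df, barycenters=bary, variance_fractions=fractions)


@dataclass
class ClusterTree:
    """Agglomerative sample tree: scipy linkage matrix plus leaf labels."""

    linkage: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        if self.linkage.shape[0] != len(self.labels) - 1:
            raise ValueError("a tree over n samples must have n - 1 merges")

    def to_newick(self) -> str:
        """Newick text with branch lengths from merge heights."""
        root = hierarchy.to_tree(self.linkage)

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        left = render(root.left, root.dist)
        right = render(root.right, root.dist)
        return f"({left},{right});"

    def cophenetic(self) -> pd.DataFrame:
        """Pairwise cophenetic (merge-height) distances between samples."""
        d = hierarchy.cophenet(self.linkage)
        mat = squareform(d)
        return pd.DataFrame(mat, index=self.labels, columns=self.labels)

    def root_split(self) -> tuple[set[str], set[str]]:
        """Leaf label sets of the root's two subtrees."""
        root = hierarchy.to_tree(self.linkage)
        left = {self.labels[i] for i in root.left.pre_order()}
        right = {self.labels[i] for i in root.right.pre_order()}
        return left, right


def hierarchical_tree(values: pd.DataFrame, distance: str = "correlation",
                      linkage: str = "average") -> ClusterTree:
    """Agglomerative clustering of samples (columns).

    Default distance is 1 - Pearson correlation across genes; linkage is
    average (UPGMA).  Columns are ordered by sample id before clustering so
    ties break deterministically.
    """
    if values.shape[1] < 2:
        raise ValueError("clustering needs at least 2 samples")
    ordered = values[sorted(values.columns)]
    X = ordered.to_numpy(dtype=float).T  # samples x genes
    if distance == "correlation":
        sds = X.std(axis=1)
        flat = np.where(sds == 0)[0]
        if len(flat):
            raise ValueError(
                f"zero-variance sample under correlation distance: "
                f"{ordered.columns[flat[0]]}"
            )
        corr = np.corrcoef(X)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        condensed = squareform(dist, checks=False)
    elif distance == "euclidean":
        condensed = squareform(
            np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)),
            checks=False,
        )
    else:
        raise ValueError(f"unknown distance {distance!r}")
    Z = hierarchy.linkage(condensed, method=linkage)
    return ClusterTree(linkage=Z, labels=list(ordered.columns))
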