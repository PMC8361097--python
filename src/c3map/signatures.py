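"""Differential expression, subtype signatures and gene-set scoring.

The 1-vs-all differential-expression "score" is a tie-corrected two-sided
Wilcoxon rank-sum z statistic computed on library-size-normalized,
log-transformed counts, with the log2 fold change taken on expm1-ed group
means (pseudocount 1e-9) and Benjamini-Hochberg adjustment within each
group's gene list.  Subtype signatures are the top 200 up-regulated genes
per subtype; a gene making several subtypes' top lists is assigned only to
the subtype where its score is higher, so signatures within a compartment
are disjoint.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import norm, rankdata
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .containers import GeneSignature

TARGET_LIBRARY_SIZE = 10_000.0  # CP10K convention
LFC_PSEUDOCOUNT = 1e-9


def normalize_log(adata: ad.AnnData, target_sum: float = TARGET_LIBRARY_SIZE) -> ad.AnnData:
    """Library-size normalize to a common total and log(1 + x) transform.

    Raw counts are preserved in ``layers["counts"]``; the
    ``uns["lognorm"]`` flag prevents accidental double normalization.
    """
    if adata.uns.get("lognorm", False):
        raise ValueError("matrix is already log-normalized")
    out = adata.copy()
    X = out.X.astype(np.float64)
    out.layers["counts"] = out.X.copy()
    totals = np.asarray(X.sum(axis=1)).ravel()
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals), where=totals > 0)
    if sp.issparse(X):
        X = sp.diags(scale) @ X.tocsr()
        X.data = np.log1p(X.data)
    else:
        X = np.log1p(X * scale[:, None])
    out.X = X
    out.uns["lognorm"] = True
    return out


def _tie_correction_term(col: np.ndarray) -> float:
    """sum(t^3 - t) over groups of tied values in one gene's column."""
    _, counts = np.unique(col, return_counts=True)
    t = counts[counts > 1].astype(np.float64)
    return float((t**3 - t).sum())


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def de_rank_genes(
    adata: ad.AnnData,
    groupby: str,
    scope_mask: np.ndarray | None = None,
    values: np.ndarray | None = None,
    feature_names: list[str] | None = None,
    min_group_size: int = 3,
    log_data: bool = True,
) -> pd.DataFrame:
    """1-vs-all tie-corrected rank-sum differential expression.

    Parameters
    ----------
    adata
        Log-normalized matrix (``uns["lognorm"]`` True) unless ``values``
        is supplied.
    groupby
        ``obs`` column holding the group labels.
    scope_mask
        Optional boolean cell mask restricting the background (e.g. all
        cells of one broad compartment); each group is tested against the
        rest of the scope only.
    values
        Optional dense cells x features matrix tested instead of ``.X``
        (used for receptor-activity enrichment); ``log_data=False`` then
        computes the fold change as log2 of the ratio of raw means.

    Returns
    -------
    Tidy table with one row per (group, gene): ``score`` (z statistic),
    ``log2fc``, ``pval``, ``padj`` (BH within the group) and ``frac``
    (fraction of group cells with nonzero value).  Groups smaller than
    ``min_group_size`` are excluded with a warning.
    """
    if values is None:
        if not adata.uns.get("lognorm", False):
            raise ValueError("de_rank_genes expects log-normalized input")
        X = _dense(adata.X)
        features = np.asarray(adata.var_names)
    else:
        X = np.asarray(values, dtype=np.float64)
        if feature_names is not None:
            features = np.asarray(feature_names)
        elif X.shape[1] == adata.n_vars:
            features = np.asarray(adata.var_names)
        else:
            features = np.asarray([f"f{j}" for j in range(X.shape[1])])
    labels = adata.obs[groupby].to_numpy()
    if scope_mask is not None:
        X = X[scope_mask]
        labels = labels[scope_mask]
    N = X.shape[0]
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups within scope")

    ranks = rankdata(X, axis=0)
    ties = np.array([_tie_correction_term(X[:, j]) for j in range(X.shape[1])])

    frames = []
    for g in groups:
        mask = labels == g
        n1 = int(mask.sum())
        n2 = N - n1
        if n1 < min_group_size:
            warnings.warn(f"group {g!r} has fewer than {min_group_size} cells; excluded")
            continue
        R1 = ranks[mask].sum(axis=0)
        expected = n1 * (N + 1) / 2.0
        var = n1 * n2 / 12.0 * ((N + 1) - ties / (N * (N - 1)))
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(var > 0, (R1 - expected) / np.sqrt(var), 0.0)
        pval = 2.0 * norm.sf(np.abs(z))

        mean_in = X[mask].mean(axis=0)
        mean_out = X[~mask].mean(axis=0)
        if log_data:
            lfc = np.log2(
                (np.expm1(mean_in) + LFC_PSEUDOCOUNT)
                / (np.expm1(mean_out) + LFC_PSEUDOCOUNT)
            )
        else:
            lfc = np.log2(
                (mean_in + LFC_PSEUDOCOUNT) / (mean_out + LFC_PSEUDOCOUNT)
            )
        padj = multipletests(pval, method="fdr_bh")[1]
        frames.append(
            pd.DataFrame(
                {
                    "group": g,
                    "gene": features,
                    "score": z,
                    "log2fc": lfc,
                    "pval": pval,
                    "padj": padj,
                    "frac": (X[mask] > 0).mean(axis=0),
                }
            )
        )
    if not frames:
        raise ValueError("no group large enough to test")
    return pd.concat(frames, ignore_index=True)


def derive_subtype_signatures(de: pd.DataFrame, top_n: int = 200) -> list[GeneSignature]:
    """Top ``top_n`` up-regulated genes per group, disjoint across groups.

    A gene in several groups' top lists is assigned to the group with the
    higher score; only genes with positive score qualify, so signatures
    may be shorter than ``top_n``.
    """
    tops: dict[str, pd.DataFrame] = {}
    for g, sub in de.groupby("group", sort=False):
        up = sub[sub["score"] > 0].sort_values(
            ["score", "gene"], ascending=[False, True]
        )
        tops[g] = up.head(top_n)
    # resolve multi-assignment: keep the occurrence with the highest score
    pooled = pd.concat(tops.values(), ignore_index=True)
    best = pooled.loc[pooled.groupby("gene")["score"].idxmax()]
    winner = dict(zip(best["gene"], best["group"]))
    sigs = []
    for g, sub in tops.items():
        keep = sub[sub["gene"].map(winner) == g]
        sigs.append(
            GeneSignature(name=str(g), genes=list(keep["gene"]), scores=list(keep["score"]))
        )
    return sigs


def coexpression_modules(
    adata: ad.AnnData,
    de: pd.DataFrame,
    fdr: float = 0.05,
    min_abs_lfc: float = 0.3,
    min_degree: int = 5,
    min_abs_corr: float = 0.4,
    n_modules: int | None = None,
    apply_lfc_filter: bool = True,
) -> tuple[list[dict], pd.DataFrame]:
    """Partition DE-filtered, well-connected genes into co-expression modules.

    Genes pass if differentially expressed in any group (BH FDR <= ``fdr``
    and, optionally, |log2 FC| >= ``min_abs_lfc``) and have at least
    ``min_degree`` partners with |Pearson r| >= ``min_abs_corr``.
    Survivors are clustered hierarchically (complete linkage, Euclidean
    distance on correlation profiles); the cut either yields ``n_modules``
    or maximizes the mean silhouette over 2..10 modules.

    Returns (modules, correlation matrix over surviving genes); each
    module is a dict with ``module_id``, ``genes`` and
    ``mean_intra_correlation``.
    """
    passing = de[(de["padj"] <= fdr)]
    if apply_lfc_filter:
        passing = passing[passing["log2fc"].abs() >= min_abs_lfc]
    genes = pd.unique(passing["gene"])
    genes = [g for g in genes if g in set(adata.var_names)]
    if len(genes) == 0:
        warnings.warn("no gene passed the differential-expression filter")
        return [], pd.DataFrame()

    X = _dense(adata[:, genes].X)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    adj = (np.abs(corr) >= min_abs_corr) & ~np.eye(len(genes), dtype=bool)
    degree = adj.sum(axis=1)
    keep = degree >= min_degree
    if keep.sum() == 0:
        warnings.warn("no gene passed the degree filter")
        return [], pd.DataFrame()
    genes = [g for g, k in zip(genes, keep) if k]
    corr = corr[np.ix_(keep, keep)]

    if len(genes) == 1:
        labels = np.array([1])
    else:
        Z = linkage(pdist(corr, metric="euclidean"), method="complete")
        if n_modules is not None:
            labels = fcluster(Z, t=min(n_modules, len(genes)), criterion="maxclust")
        else:
            best, labels = -np.inf, np.ones(len(genes), dtype=int)
            for k in range(2, min(10, len(genes) - 1) + 1):
                cand = fcluster(Z, t=k, criterion="maxclust")
                if len(np.unique(cand)) < 2:
                    continue
                s = silhouette_score(corr, cand, metric="euclidean")
                if s > best:
                    best, labels = s, cand

    modules = []
    for mid in np.unique(labels):
        members = [g for g, l in zip(genes, labels) if l == mid]
        idx = np.where(labels == mid)[0]
        if len(idx) > 1:
            sub = corr[np.ix_(idx, idx)]
            intra = float(sub[~np.eye(len(idx), dtype=bool)].mean())
        else:
            intra = 1.0
        modules.append(
            {"module_id": int(mid), "genes": members, "mean_intra_correlation": intra}
        )
    corr_df = pd.DataFrame(corr, index=genes, columns=genes)
    return modules, corr_df


def score_cells_binned(
    adata: ad.AnnData,
    signature: GeneSignature,
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Binned-background per-cell signature score (Tirosh-style).

    Mean expression of the signature genes minus the mean of control genes
    sampled from the same average-expression bins; delegates to scanpy's
    ``score_genes``.
    """
    import scanpy as sc

    if len(signature.genes) == 0:
        raise ValueError("empty signature")
    tmp = adata.copy()
    sc.tl.score_genes(
        tmp,
        gene_list=[g for g in signature.genes if g in adata.var_names],
        ctrl_size=n_ctrl,
        n_bins=n_bins,
        score_name="_score",
        random_state=seed,
    )
    return tmp.obs["_score"].to_numpy()


def score_samples_ssgsea(
    expr: pd.DataFrame,
    signatures: list[GeneSignature],
    weight: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """Single-sample gene-set enrichment scores (rank-weighted running sum).

    Parameters
    ----------
    expr
        Samples x genes expression table (any monotone scale; only the
        within-sample gene ranks matter).
    weight
        Exponent on the rank weights (ssGSEA convention, 0.25).
    normalize
        Divide all enrichment scores by the global score range, as in the
        reference implementation.

    Returns a samples x signatures score table.
    """
    if expr.shape[1] < 2:
        raise ValueError("expression table needs at least two genes")
    gene_names = np.asarray(expr.columns)
    scores = np.zeros((expr.shape[0], len(signatures)))
    for si, sig in enumerate(signatures):
        in_set = np.isin(gene_names, list(sig.genes))
        m = int(in_set.sum())
        if m == 0:
            raise ValueError(f"signature {sig.name!r} shares no genes with the table")
        if m == expr.shape[1]:
            raise ValueError(f"signature {sig.name!r} covers every gene")
        for ci in range(expr.shape[0]):
            row = expr.iloc[ci].to_numpy(dtype=float)
            ranks = rankdata(row)  # 1..N ascending in expression
            order = np.argsort(-row, kind="stable")
            set_sorted = in_set[order]
            w = np.abs(ranks[order]) ** weight
            w_in = np.where(set_sorted, w, 0.0)
            denom = w_in.sum()
            p_hit = np.cumsum(w_in) / denom
            p_miss = np.cumsum(~set_sorted) / (len(row) - m)
            scores[ci, si] = float((p_hit - p_miss).sum())
    if normalize:
        rng_ = scores.max() - scores.min()
        if rng_ > 0:
            scores = scores / rng_
    return pd.DataFrame(scores, index=expr.index, columns=[s.name for s in signatures])


def quartile_stratify(scores: pd.Series) -> pd.Series:
    """Assign Q1..Q4 labels by empirical score quartiles.

    Ties at quartile edges are broken by stable sample order; constant
    scores collapse to Q1 with a warning.
    """
    scores = pd.Series(scores)
    if scores.nunique() == 1:
        warnings.warn("constant scores: all samples assigned to Q1")
        return pd.Series("Q1", index=scores.index)
    ranks = scores.rank(method="first")
    q = np.ceil(ranks * 4 / len(scores)).astype(int).clip(1, 4)
    return pd.Series([f"Q{i}" for i in q], index=scores.index)
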