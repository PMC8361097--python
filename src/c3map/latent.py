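"""Latent-time transfer from normal epithelium to tumor cells.

Tumor cells inherit the latent (pseudo)time of their transcriptionally
nearest normal cell, where nearness is the L1 norm over a panel of
latent-time-correlated genes selected per normal sample (top 500 by
correlation with latent time, minimum 0.3) and unioned across samples.
Interval signatures then come from a 1-vs-all differential-expression
test over 5 evenly spaced time bins.
"""

from __future__ import annotations

import logging
import warnings

import anndata as ad
import numpy as np
import pandas as pd

from .containers import GeneSignature
from .signatures import _dense, de_rank_genes, derive_subtype_signatures

logger = logging.getLogger(__name__)


def select_latent_genes(
    normals: list[ad.AnnData] | ad.AnnData,
    top_n: int = 500,
    min_corr: float = 0.3,
    use_abs: bool = False,
) -> list[str]:
    """Genes correlated with latent time, unioned across normal samples.

    Per sample, genes are ranked by Pearson correlation between their
    log-normalized expression and ``obs["latent_time"]``; the top
    ``top_n`` with correlation >= ``min_corr`` are kept (``use_abs``
    switches the criterion to |r|).  The union is deduplicated, preserving
    first-seen order.
    """
    if isinstance(normals, ad.AnnData):
        normals = [normals]
    selected: list[str] = []
    seen: set[str] = set()
    for adata in normals:
        if not adata.uns.get("lognorm", False):
            raise ValueError("normal cohorts must be log-normalized")
        t = adata.obs["latent_time"].to_numpy(dtype=float)
        X = _dense(adata.X)
        tc = t - t.mean()
        Xc = X - X.mean(axis=0)
        denom = np.sqrt((Xc**2).sum(axis=0) * (tc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, Xc.T @ tc / denom, 0.0)
        crit = np.abs(r) if use_abs else r
        order = np.argsort(-crit, kind="stable")[:top_n]
        for j in order:
            if crit[j] >= min_corr:
                g = adata.var_names[j]
                if g not in seen:
                    seen.add(g)
                    selected.append(g)
    if not selected:
        warnings.warn("no gene met the latent-time correlation threshold")
    return selected


def transfer_latent_time(
    tumor: ad.AnnData,
    normal: ad.AnnData,
    genes: list[str],
    chunk_size: int = 512,
) -> pd.DataFrame:
    """Inherit each tumor cell's latent time from its L1-nearest normal cell.

    The distance is the L1 norm of the difference of log-normalized
    expression over the shared subset of ``genes``; genes missing from
    either matrix are dropped with a logged count.  Ties resolve to the
    lowest normal-cell index, so the transfer is deterministic, and
    inherited times never extrapolate beyond the normal cohort's range.
    """
    if not genes:
        raise ValueError("gene list is empty")
    for m, nm in ((tumor, "tumor"), (normal, "normal")):
        if not m.uns.get("lognorm", False):
            raise ValueError(f"{nm} matrix must be log-normalized")
    shared = [g for g in genes if g in set(tumor.var_names) and g in set(normal.var_names)]
    dropped = len(genes) - len(shared)
    if dropped:
        logger.info("dropped %d latent genes missing from a matrix", dropped)
    if not shared:
        raise ValueError("gene list disjoint from one of the matrices")

    T = _dense(tumor[:, shared].X)
    Nm = _dense(normal[:, shared].X)
    t_norm = normal.obs["latent_time"].to_numpy(dtype=float)

    nn_idx = np.empty(T.shape[0], dtype=int)
    nn_dist = np.empty(T.shape[0])
    for start in range(0, T.shape[0], chunk_size):
        block = T[start : start + chunk_size]
        d = np.abs(block[:, None, :] - Nm[None, :, :]).sum(axis=2)
        nn_idx[start : start + len(block)] = d.argmin(axis=1)  # lowest index on ties
        nn_dist[start : start + len(block)] = d.min(axis=1)
    return pd.DataFrame(
        {
            "cell_id": tumor.obs_names,
            "latent_time": t_norm[nn_idx],
            "source": "inherited",
            "nearest_normal": normal.obs_names[nn_idx],
            "l1_distance": nn_dist,
        }
    ).set_index("cell_id")


def interval_signatures(
    tumor: ad.AnnData,
    latent_time: pd.Series | None = None,
    n_intervals: int = 5,
    top_n: int = 200,
) -> list[GeneSignature]:
    """Signatures of evenly spaced latent-time intervals.

    Cells are binned into ``n_intervals`` equal-width bins over the
    observed time range (last bin right-closed), a 1-vs-all rank-sum test
    is run per bin, and the top ``top_n`` up-regulated genes are taken; a
    gene topping several bins goes to the bin with the higher score.
    Empty bins are skipped with a warning.
    """
    t = (
        latent_time.to_numpy(dtype=float)
        if latent_time is not None
        else tumor.obs["latent_time"].to_numpy(dtype=float)
    )
    lo, hi = float(t.min()), float(t.max())
    if lo == hi:
        warnings.warn("all cells share one latent time; single occupied interval")
        bins = np.zeros(len(t), dtype=int)
    else:
        edges = np.linspace(lo, hi, n_intervals + 1)
        bins = np.clip(np.digitize(t, edges[1:-1], right=False), 0, n_intervals - 1)
    occupied = np.unique(bins)
    if len(occupied) < n_intervals:
        warnings.warn(
            f"{n_intervals - len(occupied)} latent-time interval(s) empty"
        )
    work = tumor.copy()
    work.obs["_interval"] = [f"interval{b + 1}" for b in bins]
    if len(occupied) < 2:
        return [GeneSignature(name=f"interval{occupied[0] + 1}", genes=[])]
    de = de_rank_genes(work, "_interval")
    return derive_subtype_signatures(de, top_n=top_n)
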