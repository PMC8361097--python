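"""Quality-control filters and hashtag-demultiplexing recovery.

Nuclei with more than 10% mitochondrial UMIs are removed first, then the
top and bottom 5% of nuclei by unique-gene count and by total UMI.  Spots
need at least 1,250 total UMIs and under 10% mitochondrial content, after
which genes detected in fewer than 4 surviving spots are dropped.  The
demultiplexing step recovers nuclei called negative by the initial
mixture-model caller when their counts pass the per-hashtag minimum for
one and only one hashtag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd


@dataclass
class QCThresholds:
    """Cutoffs for nucleus- and spot-level quality control."""

    max_mito_fraction: float = 0.10
    extreme_percentile: float = 0.05
    min_spot_umi: int = 1250
    min_spots_per_gene: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.max_mito_fraction < 1:
            raise ValueError("max_mito_fraction must be in (0, 1)")
        if not 0 < self.extreme_percentile < 0.5:
            raise ValueError("extreme_percentile must be in (0, 0.5)")
        if self.min_spot_umi < 0 or self.min_spots_per_gene < 0:
            raise ValueError("count thresholds must be non-negative")


def demux_recover(hto: pd.DataFrame, thresholds: dict[str, int]) -> pd.DataFrame:
    """Final hashtag call per nucleus after the negative-recovery step.

    Parameters
    ----------
    hto
        Table with one count column per hashtag (the keys of
        ``thresholds``) and an ``initial_call`` column holding
        ``"singlet:<hashtag>"``, ``"doublet"`` or ``"negative"``.
    thresholds
        Positive per-hashtag minimum count.

    Returns
    -------
    DataFrame with ``final_call`` (``singlet:<hashtag>`` or ``removed``)
    and ``recovered`` flag.  Initially negative nuclei whose counts exceed
    the minimum for exactly one hashtag are reassigned to it; doublets and
    remaining negatives are removed; singlets pass through unchanged.
    """
    reserved = {"initial_call", "true_class", "true_hashtag"}
    hashtags = [c for c in hto.columns if c not in reserved]
    missing = [h for h in hashtags if h not in thresholds]
    if missing:
        raise ValueError(f"missing threshold for hashtags: {missing}")
    if any(t <= 0 for t in thresholds.values()):
        raise ValueError("all hashtag thresholds must be positive")
    if "initial_call" not in hto.columns:
        raise ValueError("hto table must carry an initial_call column")

    counts = hto[hashtags].to_numpy()
    thr = np.array([thresholds[h] for h in hashtags])
    passing = counts >= thr  # passes the minimum count
    n_pass = passing.sum(axis=1)

    final = np.empty(len(hto), dtype=object)
    recovered = np.zeros(len(hto), dtype=bool)
    initial = hto["initial_call"].to_numpy()
    for i, call in enumerate(initial):
        if call.startswith("singlet"):
            final[i] = call
        elif call == "doublet":
            final[i] = "removed"
        elif call == "negative":
            if n_pass[i] == 1:
                h = hashtags[int(np.argmax(passing[i]))]
                final[i] = f"singlet:{h}"
                recovered[i] = True
            else:
                final[i] = "removed"
        else:
            raise ValueError(f"unrecognized initial call: {call!r}")
    return pd.DataFrame(
        {"final_call": final, "recovered": recovered}, index=hto.index
    )


def _mito_fraction(adata: ad.AnnData, mito_genes: list[str]) -> np.ndarray:
    missing = set(mito_genes) - set(adata.var_names)
    if missing:
        raise ValueError(f"mito genes absent from gene universe: {sorted(missing)[:3]}")
    X = adata.layers.get("counts", adata.X)
    total = np.asarray(X.sum(axis=1)).ravel()
    mito = np.asarray(adata[:, mito_genes].X.sum(axis=1)).ravel()
    if "counts" in adata.layers:
        mito = np.asarray(adata[:, mito_genes].layers["counts"].sum(axis=1)).ravel()
    return np.divide(mito, total, out=np.zeros_like(mito, dtype=float), where=total > 0)


def qc_filter_nuclei(
    adata: ad.AnnData,
    mito_genes: list[str],
    thresholds: QCThresholds | None = None,
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Remove high-mito nuclei, then the percentile tails of genes and UMIs.

    The mitochondrial rule removes nuclei with mito fraction strictly above
    ``max_mito_fraction`` (a nucleus at exactly 10% is retained).  Both
    percentile filters are then applied jointly to the surviving set; cells
    exactly at a percentile boundary are retained (minimal-removal tie
    policy).  Mito fractions use raw counts.

    Returns the filtered matrix and a removal log naming the rule that
    fired for each removed cell.
    """
    if adata.n_obs == 0:
        raise ValueError("empty matrix")
    if adata.uns.get("qc_nuclei", False):
        # already filtered: re-applying is a no-op (idempotence contract)
        return adata.copy(), pd.DataFrame(
            columns=["cell_id", "rule", "mito_fraction", "total_umi", "n_genes"]
        )
    t = thresholds or QCThresholds()

    frac = _mito_fraction(adata, mito_genes)
    mito_fail = frac > t.max_mito_fraction

    X = adata.layers.get("counts", adata.X)
    total_umi = np.asarray(X.sum(axis=1)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()

    keep_mask = ~mito_fail
    rules = np.full(adata.n_obs, "", dtype=object)
    rules[mito_fail] = "mito_fraction"
    if keep_mask.any():
        for name, values in (("n_genes", n_genes), ("total_umi", total_umi)):
            surv = values[keep_mask]
            lo = np.quantile(surv, t.extreme_percentile)
            hi = np.quantile(surv, 1 - t.extreme_percentile)
            extreme = keep_mask & ((values < lo) | (values > hi))
            rules[extreme & (rules == "")] = f"{name}_percentile"
    percentile_fail = np.char.endswith(rules.astype(str), "_percentile")
    keep_mask &= ~percentile_fail

    log = pd.DataFrame(
        {
            "cell_id": adata.obs_names[~keep_mask],
            "rule": rules[~keep_mask],
            "mito_fraction": frac[~keep_mask],
            "total_umi": total_umi[~keep_mask],
            "n_genes": n_genes[~keep_mask],
        }
    ).reset_index(drop=True)
    out = adata[keep_mask].copy()
    out.uns["qc_nuclei"] = True
    return out, log


def qc_filter_spots(
    spots: ad.AnnData,
    mito_genes: list[str],
    thresholds: QCThresholds | None = None,
) -> ad.AnnData:
    """Keep spots with >= 1,250 UMIs and < 10% mito, then prevalent genes.

    A spot at exactly the UMI minimum is kept ("at least"); a spot at
    exactly the mito maximum is removed ("less than").  After spot
    filtering, genes detected (UMI > 0) in fewer than
    ``min_spots_per_gene`` surviving spots are dropped.
    """
    if spots.n_obs == 0:
        raise ValueError("empty grid")
    if spots.uns.get("qc_spots", False):
        return spots.copy()  # idempotence contract
    t = thresholds or QCThresholds()
    X = spots.layers.get("counts", spots.X)
    total = np.asarray(X.sum(axis=1)).ravel()
    frac = _mito_fraction(spots, [g for g in mito_genes if g in spots.var_names])
    keep_spots = (total >= t.min_spot_umi) & (frac < t.max_mito_fraction)
    out = spots[keep_spots].copy()
    if out.n_obs == 0:
        warnings.warn("no spot passed the UMI/mito filters")
        return out
    Xs = out.layers.get("counts", out.X)
    prevalence = np.asarray((Xs > 0).sum(axis=0)).ravel()
    out = out[:, prevalence >= t.min_spots_per_gene].copy()
    out.uns["qc_spots"] = True
    return out
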