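"""Ligand-receptor interaction scoring with a spatial co-expression filter.

Receptor activity for a cell is the average absolute deviation of the
receptor's downstream signature genes from the mean expression of those
genes in a background of the same broad cell type.  Ligands "available"
in a sender subtype and receptors "active" in a receiver subtype are
called by 1-vs-all enrichment within the broad type (log2 FC >= 0.5 /
0.25 respectively, BH-adjusted p <= 0.05, expressed in >= 10% of the
sender/receiver cells).  Candidate pairs must additionally be spatially
co-expressed: in at least one spot sample, >= 25% of ligand-positive
spots (UMI > 0) must also be receptor-positive.  The interaction
potential is the product of the sender's mean ligand expression and the
receiver's mean receptor activity; ribbon transparency for display is
min(0.9, 1 - (potential / potential_max)^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .containers import InteractionRecord
from .signatures import _dense, de_rank_genes

MIN_SIGNATURE_GENES = 5


@dataclass
class ReceptorSignature:
    receptor: str
    genes: list[str]
    source: str = "prior"


def build_receptor_signatures(
    prior: pd.DataFrame, min_genes: int = MIN_SIGNATURE_GENES
) -> tuple[dict[str, ReceptorSignature], list[str]]:
    """Receptor signatures from the prior table; short ones are excluded.

    Returns (retained signatures keyed by receptor, excluded receptor
    list).  Receptors must accumulate at least ``min_genes`` signature
    genes to be analyzed.
    """
    if len(prior) == 0:
        raise ValueError("empty ligand-receptor prior table")
    sigs: dict[str, ReceptorSignature] = {}
    excluded: list[str] = []
    for receptor, sub in prior.groupby("receptor", sort=False):
        genes = sorted(
            {g for row in sub["signature_genes"] for g in str(row).split(";") if g}
        )
        if len(genes) >= min_genes:
            sigs[receptor] = ReceptorSignature(receptor=receptor, genes=genes)
        else:
            excluded.append(receptor)
    return sigs, excluded


def receptor_activity(
    adata: ad.AnnData,
    broad_col: str,
    signatures: dict[str, ReceptorSignature],
) -> pd.DataFrame:
    """Per-cell receptor activity: mean |expression - broad-type background|.

    ``activity(c, r) = mean_g |x(c, g) - mu_bg(g)|`` over the receptor's
    signature genes, where ``mu_bg(g)`` is the mean of ``g`` across all
    cells sharing ``c``'s broad type (pooled across samples).
    """
    if not adata.uns.get("lognorm", False):
        raise ValueError("receptor_activity expects log-normalized input")
    broad = adata.obs[broad_col].to_numpy()
    gene_set = set(adata.var_names)
    out = pd.DataFrame(index=adata.obs_names)
    X = _dense(adata.X)
    col = {g: j for j, g in enumerate(adata.var_names)}
    bg_mean = {}
    for bt in pd.unique(broad):
        bg_mean[bt] = X[broad == bt].mean(axis=0)
    for receptor, sig in signatures.items():
        genes = [g for g in sig.genes if g in gene_set]
        if not genes:
            warnings.warn(f"receptor {receptor}: no signature gene in matrix; skipped")
            continue
        cols = [col[g] for g in genes]
        act = np.empty(adata.n_obs)
        for bt in bg_mean:
            rows = broad == bt
            act[rows] = np.abs(X[np.ix_(rows, cols)] - bg_mean[bt][cols]).mean(axis=1)
        out[receptor] = act
    return out


def _enrichment_calls(
    de: pd.DataFrame,
    min_lfc: float,
    max_padj: float,
    min_frac: float,
    candidates: set[str],
    frac_lookup: pd.DataFrame | None = None,
) -> dict[str, set[str]]:
    calls: dict[str, set[str]] = {}
    hit = de[
        (de["log2fc"] >= min_lfc)
        & (de["padj"] <= max_padj)
        & (de["gene"].isin(candidates))
    ]
    for g, sub in hit.groupby("group", sort=False):
        if frac_lookup is None:
            sub = sub[sub["frac"] >= min_frac]
            calls[str(g)] = set(sub["gene"])
        else:
            ok = {
                gene
                for gene in sub["gene"]
                if frac_lookup.loc[str(g), gene] >= min_frac
            }
            calls[str(g)] = ok
    return calls


def call_available_ligands(
    adata: ad.AnnData,
    subtype_col: str,
    broad_col: str,
    ligands: set[str],
    min_lfc: float = 0.5,
    max_padj: float = 0.05,
    min_frac: float = 0.10,
) -> dict[str, set[str]]:
    """Ligands enriched in each subtype vs its broad-type background."""
    calls: dict[str, set[str]] = {}
    for bt in pd.unique(adata.obs[broad_col]):
        scope = (adata.obs[broad_col] == bt).to_numpy()
        if len(pd.unique(adata.obs[subtype_col][scope])) < 2:
            continue
        de = de_rank_genes(adata, subtype_col, scope_mask=scope)
        calls.update(_enrichment_calls(de, min_lfc, max_padj, min_frac, ligands))
    return calls


def call_active_receptors(
    adata: ad.AnnData,
    activity: pd.DataFrame,
    subtype_col: str,
    broad_col: str,
    min_lfc: float = 0.25,
    max_padj: float = 0.05,
    min_frac: float = 0.10,
) -> dict[str, set[str]]:
    """Receptors whose activity is enriched in each receiver subtype.

    Enrichment is a 1-vs-all rank-sum test of the activity scores within
    the broad type (fold change on the raw activity means); the receptor
    gene itself must additionally be expressed (count > 0) in at least
    ``min_frac`` of the receiver subtype's cells.
    """
    receptors = [r for r in activity.columns if r in set(adata.var_names)]
    X = _dense(adata[:, receptors].X) if receptors else np.empty((adata.n_obs, 0))
    expr_frac = pd.DataFrame(index=pd.unique(adata.obs[subtype_col]).astype(str), columns=receptors, dtype=float)
    for st in expr_frac.index:
        rows = (adata.obs[subtype_col].astype(str) == st).to_numpy()
        if rows.any() and receptors:
            expr_frac.loc[st] = (X[rows] > 0).mean(axis=0)

    calls: dict[str, set[str]] = {}
    for bt in pd.unique(adata.obs[broad_col]):
        scope = (adata.obs[broad_col] == bt).to_numpy()
        if len(pd.unique(adata.obs[subtype_col][scope])) < 2:
            continue
        de = de_rank_genes(
            adata,
            subtype_col,
            scope_mask=scope,
            values=activity.to_numpy(),
            feature_names=list(activity.columns),
            log_data=False,
        )
        calls.update(
            _enrichment_calls(
                de, min_lfc, max_padj, min_frac,
                set(receptors), frac_lookup=expr_frac,
            )
        )
    return calls


def spatial_coexpression_filter(
    spotframes: list[ad.AnnData],
    pairs: list[tuple[str, str]],
    min_frac: float = 0.25,
) -> list[tuple[str, str]]:
    """Keep pairs where ligand+ spots are receptor+ often enough, anywhere.

    A pair survives if in at least one sample >= ``min_frac`` (inclusive)
    of the spots with ligand UMI > 0 also have receptor UMI > 0.  Pairs
    whose genes appear in no spot sample are dropped with a warning.
    """
    kept = []
    for ligand, receptor in pairs:
        seen = False
        ok = False
        for sf in spotframes:
            names = set(sf.var_names)
            if ligand not in names or receptor not in names:
                continue
            seen = True
            X = sf.layers.get("counts", sf.X)
            lig = np.asarray(X[:, sf.var_names.get_loc(ligand)].todense()).ravel() \
                if hasattr(X, "todense") else np.asarray(X[:, sf.var_names.get_loc(ligand)]).ravel()
            rec = np.asarray(X[:, sf.var_names.get_loc(receptor)].todense()).ravel() \
                if hasattr(X, "todense") else np.asarray(X[:, sf.var_names.get_loc(receptor)]).ravel()
            lig_pos = lig > 0
            if lig_pos.sum() == 0:
                continue
            if (rec[lig_pos] > 0).mean() >= min_frac:
                ok = True
                break
        if not seen:
            warnings.warn(f"pair {ligand}-{receptor} absent from all spot samples; dropped")
            continue
        if ok:
            kept.append((ligand, receptor))
    return kept


def interaction_potential(
    adata: ad.AnnData,
    activity: pd.DataFrame,
    sender_mask: np.ndarray,
    receiver_mask: np.ndarray,
    ligand: str,
    receptor: str,
) -> float:
    """Mean sender ligand expression times mean receiver receptor activity."""
    lig = _dense(adata[:, [ligand]].X).ravel()
    mean_lig = float(lig[sender_mask].mean())
    mean_act = float(activity.loc[np.asarray(adata.obs_names)[receiver_mask], receptor].mean())
    return mean_lig * mean_act


def ribbon_transparency(potential: float, potential_max: float) -> float:
    """Display transparency: min(0.9, 1 - (potential / potential_max)^2).

    The strongest interaction renders fully opaque (0) and weak ones cap
    at 90% transparency so every ribbon stays visible.
    """
    if potential_max <= 0:
        raise ValueError("potential_max must be positive")
    if not 0 <= potential <= potential_max:
        raise ValueError("potential must lie in [0, potential_max]")
    return min(0.9, 1.0 - (potential / potential_max) ** 2)


def run_interaction_analysis(
    adata: ad.AnnData,
    prior: pd.DataFrame,
    subtype_col: str,
    broad_col: str,
    sender: str,
    spotframes: list[ad.AnnData] | None = None,
    min_signature_genes: int = MIN_SIGNATURE_GENES,
) -> list[InteractionRecord]:
    """End-to-end interaction calling from one sender subtype.

    Builds receptor signatures, scores activities, calls available
    ligands and active receptors, applies the spatial co-expression
    filter when spot samples are given, and emits one record per
    surviving (sender, receiver, ligand, receptor) combination with its
    interaction potential and ribbon transparency.
    """
    sigs, _ = build_receptor_signatures(prior, min_genes=min_signature_genes)
    activity = receptor_activity(adata, broad_col, sigs)
    ligands = set(prior["ligand"])
    avail = call_available_ligands(adata, subtype_col, broad_col, ligands)
    active = call_active_receptors(adata, activity, subtype_col, broad_col)

    pair_of = {
        (row.ligand, row.receptor)
        for row in prior.itertuples()
        if row.receptor in sigs
    }
    if spotframes is not None:
        pair_of = set(spatial_coexpression_filter(spotframes, sorted(pair_of)))

    subtypes = pd.unique(adata.obs[subtype_col]).astype(str)
    sender_mask = (adata.obs[subtype_col].astype(str) == sender).to_numpy()
    records: list[InteractionRecord] = []
    for receiver in subtypes:
        if receiver == sender:
            continue
        receiver_mask = (adata.obs[subtype_col].astype(str) == receiver).to_numpy()
        for ligand, receptor in sorted(pair_of):
            if ligand not in avail.get(sender, set()):
                continue
            if receptor not in active.get(receiver, set()):
                continue
            pot = interaction_potential(
                adata, activity, sender_mask, receiver_mask, ligand, receptor
            )
            records.append(
                InteractionRecord(
                    sender=sender, receiver=receiver, ligand=ligand,
                    receptor=receptor, potential=pot,
                )
            )
    if records:
        pmax = max(r.potential for r in records)
        if pmax > 0:
            for r in records:
                r.transparency = ribbon_transparency(r.potential, pmax)
        else:
            for r in records:
                r.transparency = 0.9
    return records
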