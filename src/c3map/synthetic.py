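"""Synthetic-data generators for every input of the analysis pipeline.

Each generator plants a known structure (subtype markers, a latent
differentiation axis, a spatial module program, cellular niches, hashtag
classes) and returns the ground truth alongside the data, so every
downstream stage of the package can be tested for recovery without any
external download.  Counts are negative-binomial to match the
overdispersion of UMI data; identical seeds give byte-identical output.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import SynthConfig

__all__ = [
    "generate_tumor_cohort",
    "generate_normal_cohort",
    "generate_visium",
    "generate_codex",
    "generate_codex_images",
    "generate_lr_prior",
    "hex_grid_coordinates",
]


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with mean ``mu`` and shape ``dispersion``.

    var = mu + mu^2 / dispersion (gamma-Poisson mixture).
    """
    mu = np.maximum(mu, 1e-12)
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p)


def _gene_universe(config: SynthConfig) -> tuple[list[str], dict[str, list[str]], list[str]]:
    """Build gene names: per-subtype markers, mito genes, background."""
    markers = {
        st: [f"{st}-MK{j}" for j in range(config.markers_per_subtype)]
        for st in config.n_cells_per_subtype
    }
    mito = [f"MT-{j}" for j in range(config.n_mito_genes)]
    n_special = sum(len(v) for v in markers.values()) + len(mito)
    if config.n_genes < n_special:
        raise ValueError("n_genes smaller than number of marker + mito genes")
    background = [f"G{j:04d}" for j in range(config.n_genes - n_special)]
    genes = [g for v in markers.values() for g in v] + mito + background
    return genes, markers, mito


def generate_tumor_cohort(
    config: SynthConfig,
) -> tuple[ad.AnnData, pd.DataFrame, dict[str, int]]:
    """Simulate a hashed tumor cohort.

    Returns
    -------
    adata
        Cells x genes raw counts. ``obs`` carries sample, compartment and
        the planted ``subtype``; ``var["mito"]`` flags mitochondrial genes;
        ``uns["marker_genes"]`` maps subtype -> planted markers and
        ``uns["marker_log2fc"]`` the planted effect size.
    hto
        Hashtag-oligo UMI counts per nucleus with the initial demultiplex
        call and the ground-truth class (singlet / doublet / negative /
        recoverable).
    thresholds
        Per-hashtag minimum count used to simulate the initial calls.
    """
    config.validate()
    rng = np.random.default_rng([1, config.seed])
    genes, markers, mito = _gene_universe(config)
    n_genes = len(genes)
    gene_index = {g: j for j, g in enumerate(genes)}

    subtypes = list(config.n_cells_per_subtype)
    labels = np.repeat(subtypes, [config.n_cells_per_subtype[s] for s in subtypes])
    n_cells = len(labels)

    # baseline per-gene means; markers get a higher base so the planted
    # fold change is measurable above NB noise
    base_mu = rng.lognormal(mean=np.log(config.nb_mean), sigma=0.6, size=n_genes)
    for st in subtypes:
        for g in markers[st]:
            base_mu[gene_index[g]] = 2.0

    mu = np.tile(base_mu, (n_cells, 1))
    fold = 2.0 ** config.marker_log2fc
    for st in subtypes:
        rows = labels == st
        cols = [gene_index[g] for g in markers[st]]
        mu[np.ix_(rows, cols)] *= fold

    # per-cell mitochondrial load drawn from the configured range
    lo, hi = config.mito_fraction_range
    mito_frac = rng.uniform(lo, hi, size=n_cells)
    mito_cols = [gene_index[g] for g in mito]
    non_mito_sum = mu.sum(axis=1) - mu[:, mito_cols].sum(axis=1)
    per_gene = (mito_frac / np.maximum(1 - mito_frac, 1e-9)) * non_mito_sum / len(mito_cols)
    mu[:, mito_cols] = per_gene[:, None]

    # mild per-cell depth variation
    depth = rng.lognormal(0.0, 0.25, size=n_cells)
    counts = _nb_counts(rng, mu * depth[:, None], config.nb_dispersion)

    samples = rng.integers(1, config.n_hashtags + 1, size=n_cells)
    obs = pd.DataFrame(
        {
            "sample": [f"S{h}" for h in samples],
            "compartment": "epithelial",
            "subtype": labels,
        },
        index=[f"cell{i:05d}" for i in range(n_cells)],
    )
    var = pd.DataFrame({"mito": [g.startswith("MT-") for g in genes]}, index=genes)
    adata = ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)
    adata.uns["marker_genes"] = {k: list(v) for k, v in markers.items()}
    adata.uns["marker_log2fc"] = config.marker_log2fc
    adata.uns["lognorm"] = False

    hto, thresholds = _generate_hto(config, rng, samples, obs.index)
    return adata, hto, thresholds


def _generate_hto(config, rng, true_hashtag, index):
    """HTO counts with singlets, doublets, negatives and recoverables."""
    n = len(true_hashtag)
    k = config.n_hashtags
    thresholds = {f"HTO{h}": 50 for h in range(1, k + 1)}
    u = rng.random(n)
    cls = np.full(n, "singlet", dtype=object)
    cls[u < config.doublet_rate] = "doublet"
    cut = config.doublet_rate
    cls[(u >= cut) & (u < cut + config.negative_rate)] = "negative"
    cut += config.negative_rate
    cls[(u >= cut) & (u < cut + config.recoverable_rate)] = "recoverable"

    counts = rng.poisson(5.0, size=(n, k)).astype(np.int64)  # ambient background
    high = rng.poisson(250.0, size=n) + 60
    for i in range(n):
        h = true_hashtag[i] - 1
        if cls[i] == "singlet" or cls[i] == "recoverable":
            counts[i, h] += high[i]
        elif cls[i] == "doublet":
            other = (h + rng.integers(1, k)) % k
            counts[i, h] += high[i]
            counts[i, other] += rng.poisson(250.0) + 60
        # true negatives keep background only

    initial = np.where(
        cls == "singlet",
        [f"singlet:HTO{h}" for h in true_hashtag],
        np.where(cls == "doublet", "doublet", "negative"),
    )
    hto = pd.DataFrame(counts, columns=list(thresholds), index=index)
    hto["initial_call"] = initial
    hto["true_class"] = cls
    hto["true_hashtag"] = [f"HTO{h}" for h in true_hashtag]
    return hto, thresholds


def generate_normal_cohort(config: SynthConfig) -> ad.AnnData:
    """Simulate a normal-epithelium cohort with a latent differentiation axis.

    ``obs["latent_time"]`` is uniform on [0, 1]; the first
    ``config.n_time_genes`` background genes (listed in
    ``uns["time_genes"]``) have negative-binomial means increasing
    log-linearly with latent time, the rest are time-independent.
    """
    config.validate()
    rng = np.random.default_rng([2, config.seed])
    genes = [f"G{j:04d}" for j in range(config.n_genes)]
    n = config.n_normal_cells
    if config.n_time_genes > config.n_genes:
        raise ValueError("n_time_genes exceeds n_genes")

    t = rng.uniform(0.0, 1.0, size=n)
    base_mu = rng.lognormal(np.log(config.nb_mean), 0.6, size=config.n_genes)
    time_genes = genes[: config.n_time_genes]
    base_mu[: config.n_time_genes] = 3.0

    mu = np.tile(base_mu, (n, 1))
    mu[:, : config.n_time_genes] *= 2.0 ** (
        config.time_log2fc * (t[:, None] - 0.5)
    )
    counts = _nb_counts(rng, mu, config.nb_dispersion)

    obs = pd.DataFrame(
        {"sample": "N1", "compartment": "epithelial", "latent_time": t},
        index=[f"ncell{i:05d}" for i in range(n)],
    )
    adata = ad.AnnData(X=sp.csr_matrix(counts), obs=obs,
                       var=pd.DataFrame(index=genes))
    adata.uns["time_genes"] = list(time_genes)
    adata.uns["lognorm"] = False
    return adata


def hex_grid_coordinates(rows: int, cols: int) -> np.ndarray:
    """Visium-style array coordinates: row y, column x with x + y even."""
    coords = [(x, y) for y in range(rows) for x in range(y % 2, 2 * cols, 2)]
    return np.array(coords, dtype=int)


def generate_visium(
    config: SynthConfig,
    exclusive_pairs: list[tuple[str, str]] | None = None,
) -> ad.AnnData:
    """Simulate a hexagonal spot grid with a planted co-localized program.

    A contiguous disk of spots carries elevated "module" genes (MOD*) plus
    co-elevated companion genes (CMP*, emulating exhaustion markers around
    tumor-program-high areas).  Spot UMI totals span the 1,250 QC boundary.

    Parameters
    ----------
    exclusive_pairs
        Optional list of gene-name pairs planted mutually exclusively:
        the first gene is expressed only inside the module region, the
        second only outside, so their spot-level co-expression is zero.
    """
    config.validate()
    rng = np.random.default_rng([3, config.seed])
    coords = hex_grid_coordinates(config.grid_rows, config.grid_cols)
    n_spots = len(coords)

    # physical positions in the ring-formula frame: neighbors are
    # (x±1, y±1) and (x, y±2), i.e. sqrt(3) column pitch, unit row pitch
    px = coords[:, 0] * np.sqrt(3.0)
    py = coords[:, 1].astype(float)
    center = np.array([px.mean(), py.mean()])
    # region covers ~4% of the grid so it nests inside a top-5% stratum
    area = (px.max() - px.min()) * (py.max() - py.min())
    rad = np.sqrt(0.04 * area / np.pi)
    in_region = (px - center[0]) ** 2 + (py - center[1]) ** 2 <= rad**2

    module_genes = [f"MOD{j}" for j in range(config.n_module_genes)]
    companion_genes = [f"CMP{j}" for j in range(config.n_companion_genes)]
    mito = [f"MT-{j}" for j in range(config.n_mito_genes)]
    extra = [g for pair in (exclusive_pairs or []) for g in pair]
    n_special = len(module_genes) + len(companion_genes) + len(mito) + len(extra)
    if config.n_genes < n_special:
        raise ValueError("n_genes too small for the requested special genes")
    background = [f"G{j:04d}" for j in range(config.n_genes - n_special)]
    genes = module_genes + companion_genes + mito + extra + background
    gene_index = {g: j for j, g in enumerate(genes)}

    base_mu = rng.lognormal(np.log(config.nb_mean), 0.6, size=len(genes))
    for g in module_genes + companion_genes:
        base_mu[gene_index[g]] = 2.0
    for g in extra:
        base_mu[gene_index[g]] = 2.0

    mu = np.tile(base_mu, (n_spots, 1))
    fold = 2.0 ** config.module_log2fc
    prog_cols = [gene_index[g] for g in module_genes + companion_genes]
    mu[np.ix_(in_region, prog_cols)] *= fold
    for ga, gb in exclusive_pairs or []:
        mu[~in_region, gene_index[ga]] = 0.0
        mu[in_region, gene_index[gb]] = 0.0

    # mitochondrial load and per-spot depth spanning the 1,250 UMI boundary
    mito_cols = [gene_index[g] for g in mito]
    mito_frac = rng.uniform(*config.mito_fraction_range, size=n_spots)
    non_mito = mu.sum(axis=1) - mu[:, mito_cols].sum(axis=1)
    mu[:, mito_cols] = (
        (mito_frac / np.maximum(1 - mito_frac, 1e-9)) * non_mito / len(mito_cols)
    )[:, None]
    target = np.exp(
        rng.uniform(np.log(config.spot_umi_low), np.log(config.spot_umi_high), n_spots)
    )
    mu *= (target / mu.sum(axis=1))[:, None]
    counts = _nb_counts(rng, mu, config.nb_dispersion)

    obs = pd.DataFrame(
        {
            "array_x": coords[:, 0],
            "array_y": coords[:, 1],
            "in_module_region": in_region,
        },
        index=[f"spot{i:04d}" for i in range(n_spots)],
    )
    adata = ad.AnnData(X=sp.csr_matrix(counts), obs=obs,
                       var=pd.DataFrame(index=genes))
    adata.uns["module_genes"] = module_genes
    adata.uns["companion_genes"] = companion_genes
    adata.uns["lognorm"] = False
    return adata


def generate_codex(config: SynthConfig) -> pd.DataFrame:
    """Simulate segmented multiplexed-imaging cell tables with planted niches.

    Each core is split into quadrant regions; each region is assigned one
    of ``config.niche_compositions`` and its cells draw their broad type
    from that mixture.  One type-defining marker per broad type is
    elevated on that type; in addition the "CD49a" channel is shifted up
    by ``config.marker_shift`` on CD8T cells inside niche 3, giving a
    plantable marker-enrichment effect.

    Returns a table with columns: cell_id, spot_id, x, y, broad_type
    (truth), niche_true, and per-marker intensities.
    """
    config.validate()
    rng = np.random.default_rng([4, config.seed])
    types = list(config.broad_types)
    niche_ids = sorted(config.niche_compositions)
    n = config.n_codex_cells
    size = config.core_size

    core = rng.integers(0, config.n_cores, size=n)
    x = rng.uniform(0, size, size=n)
    y = rng.uniform(0, size, size=n)
    quadrant = (x > size / 2).astype(int) + 2 * (y > size / 2).astype(int)
    niche = np.array([niche_ids[q % len(niche_ids)] for q in quadrant])

    comp = {k: np.asarray(v, float) for k, v in config.niche_compositions.items()}
    type_idx = np.empty(n, dtype=int)
    for nid in niche_ids:
        rows = np.where(niche == nid)[0]
        type_idx[rows] = rng.choice(len(types), size=len(rows), p=comp[nid])
    broad = np.array(types, dtype=object)[type_idx]

    markers = {t: f"{t}-marker" for t in types}
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i:06d}" for i in range(n)],
            "spot_id": [f"core{c}" for c in core],
            "x": x + core * (size * 1.5),  # cores laid out side by side
            "y": y,
            "broad_type": broad,
            "niche_true": niche,
        }
    )
    for t in types:
        base = rng.lognormal(0.0, 0.4, size=n)
        df[markers[t]] = np.where(broad == t, base * 8.0, base)
    # niche-conditional shift channel
    cd49a = rng.lognormal(0.0, 0.4, size=n)
    shift_rows = (broad == "CD8T") & (niche == niche_ids[-1])
    df["CD49a"] = cd49a + np.where(shift_rows, config.marker_shift, 0.0)
    return df


def generate_codex_images(
    seed: int = 0,
    n_cells: int = 25,
    image_size: int = 200,
    nucleus_radius: int = 6,
    ring_width: int = 3,
    positive_fraction: float = 0.5,
    positive_intensity: float = 100.0,
):
    """Synthetic labeled nuclear mask + one-channel intensity image.

    Nuclei are disks on a jittered grid; a known subset of cells is made
    ring-positive by painting the band just outside the nucleus at
    ``positive_intensity``.  Returns (mask, intensity, truth) where truth
    maps label -> planted ring positivity.
    """
    rng = np.random.default_rng([5, seed])
    mask = np.zeros((image_size, image_size), dtype=np.int32)
    intensity = np.zeros((image_size, image_size), dtype=np.float32)
    pitch = max(4 * (nucleus_radius + ring_width), 1)
    centers = []
    for cy in range(pitch, image_size - pitch, pitch):
        for cx in range(pitch, image_size - pitch, pitch):
            centers.append((cy + rng.integers(-2, 3), cx + rng.integers(-2, 3)))
    centers = centers[:n_cells]
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    positive = {}
    for label, (cy, cx) in enumerate(centers, start=1):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        mask[d2 <= nucleus_radius**2] = label
        is_pos = rng.random() < positive_fraction
        positive[label] = bool(is_pos)
        if is_pos:
            ring = (d2 > nucleus_radius**2) & (
                d2 <= (nucleus_radius + ring_width) ** 2
            )
            intensity[ring] = positive_intensity
    truth = pd.Series(positive, name="ring_positive")
    return mask, intensity, truth


def generate_lr_prior(
    config: SynthConfig, gene_universe: list[str] | None = None
) -> pd.DataFrame:
    """Toy ligand-receptor prior with receptor signature gene lists.

    Exactly ``round(lr_pairs * small_signature_fraction)`` receptors carry
    fewer than five signature genes, to exercise the exclusion rule.
    Signature genes are drawn from ``gene_universe`` (default: a G####
    universe of ``config.n_genes`` genes).
    """
    config.validate()
    rng = np.random.default_rng([6, config.seed])
    if gene_universe is None:
        gene_universe = [f"G{j:04d}" for j in range(config.n_genes)]
    universe = np.array(gene_universe, dtype=object)
    need = 2 * config.lr_pairs
    if len(universe) < need + config.signature_genes_per_receptor:
        raise ValueError("gene universe too small for the requested prior")

    picks = rng.choice(len(universe), size=need, replace=False)
    ligands = universe[picks[: config.lr_pairs]]
    receptors = universe[picks[config.lr_pairs:]]
    n_small = int(round(config.lr_pairs * config.small_signature_fraction))
    small = set(rng.choice(config.lr_pairs, size=n_small, replace=False).tolist())

    rows = []
    for i in range(config.lr_pairs):
        n_sig = int(rng.integers(1, 5)) if i in small else config.signature_genes_per_receptor
        sig = rng.choice(len(universe), size=n_sig, replace=False)
        rows.append(
            {
                "ligand": ligands[i],
                "receptor": receptors[i],
                "signature_genes": ";".join(universe[sig]),
            }
        )
    prior = pd.DataFrame(rows)
    validate_lr_prior(prior, gene_universe)
    return prior


def validate_lr_prior(prior: pd.DataFrame, gene_universe=None) -> None:
    """Reject duplicated pairs and signature genes outside the universe."""
    required = {"ligand", "receptor", "signature_genes"}
    if not required.issubset(prior.columns):
        raise ValueError(f"prior table must have columns {sorted(required)}")
    dup = prior.duplicated(subset=["ligand", "receptor"])
    if dup.any():
        raise ValueError("duplicated ligand-receptor pair rows in prior table")
    if gene_universe is not None:
        uni = set(gene_universe)
        for sigs in prior["signature_genes"]:
            missing = [g for g in sigs.split(";") if g and g not in uni]
            if missing:
                raise ValueError(f"signature genes outside universe: {missing[:3]}")
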