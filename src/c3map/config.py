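"""Configuration for the synthetic-data generators.

The defaults below define the study conditions every generator emulates:
negative-binomial UMI counts with planted subtype markers, a normal
epithelium with a latent differentiation axis, hexagonal spot grids with a
co-localized module program, and multiplexed-imaging cores with planted
cellular niches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

#: Broad cell types used by the imaging generator and niche analysis.
DEFAULT_BROAD_TYPES = (
    "Epithelial",
    "EpithelialCDH",
    "Stromal",
    "Endothelial",
    "CD8T",
    "CD4T",
    "Bcell",
    "Macrophage",
)

#: Four planted niche compositions over the broad types above.  They are
#: deliberately distinct mixtures: a tumor-dominant niche, an immune niche,
#: a stromal niche and a mixed tumor/T-cell niche.
DEFAULT_NICHE_COMPOSITIONS = {
    0: (0.75, 0.05, 0.05, 0.02, 0.03, 0.03, 0.02, 0.05),
    1: (0.05, 0.05, 0.05, 0.02, 0.35, 0.20, 0.18, 0.10),
    2: (0.08, 0.02, 0.60, 0.15, 0.03, 0.04, 0.03, 0.05),
    3: (0.10, 0.45, 0.05, 0.02, 0.25, 0.05, 0.03, 0.05),
}


@dataclass
class SynthConfig:
    """Parameters shared by all synthetic generators.

    Parameters
    ----------
    seed
        Base seed; every generator derives its stream from it.
    n_cells_per_subtype
        Mapping subtype name -> cell count for the tumor cohort.
    n_genes
        Size of the gene universe (includes markers and mito genes).
    markers_per_subtype
        Number of planted marker genes per subtype.
    marker_log2fc
        Planted log2 fold change of marker genes in their own subtype.
    nb_mean, nb_dispersion
        Negative-binomial baseline mean per gene and inverse-dispersion
        (shape); counts ~ NB(mean=mu, var=mu + mu^2/dispersion).
    n_mito_genes, mito_fraction_range
        Number of "MT-" flagged genes and the per-cell range of the
        fraction of UMIs they attract.
    grid_rows, grid_cols
        Hexagonal array extent for the spot generator.
    niche_compositions
        Mapping niche id -> probability vector over broad cell types.
    marker_shift
        Intensity elevation of designated markers inside planted niches.
    lr_pairs, small_signature_fraction
        Size of the toy ligand-receptor prior and the fraction of its
        receptors given fewer than five signature genes.
    doublet_rate
        Fraction of hashed nuclei emitted as HTO doublets.
    """

    seed: int = 0
    n_cells_per_subtype: dict[str, int] = field(
        default_factory=lambda: {
            "CDH12": 200, "KRT13": 200, "UPK": 200, "KRT6A": 200, "Cycling": 200,
        }
    )
    n_genes: int = 600
    markers_per_subtype: int = 10
    marker_log2fc: float = 2.0
    nb_mean: float = 1.0
    nb_dispersion: float = 2.0
    n_mito_genes: int = 10
    mito_fraction_range: tuple[float, float] = (0.01, 0.08)
    n_hashtags: int = 4
    doublet_rate: float = 0.05
    negative_rate: float = 0.05
    recoverable_rate: float = 0.05
    # normal cohort / latent time
    n_normal_cells: int = 500
    n_time_genes: int = 50
    time_log2fc: float = 3.0
    # Visium-style grid
    grid_rows: int = 30
    grid_cols: int = 30
    n_module_genes: int = 10
    n_companion_genes: int = 5
    module_log2fc: float = 3.0
    spot_umi_low: float = 800.0
    spot_umi_high: float = 4000.0
    # imaging cores / niches
    broad_types: tuple[str, ...] = DEFAULT_BROAD_TYPES
    niche_compositions: dict[int, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_NICHE_COMPOSITIONS)
    )
    n_codex_cells: int = 5000
    n_cores: int = 4
    core_size: float = 1000.0
    marker_shift: float = 3.0
    # ligand-receptor prior
    lr_pairs: int = 30
    small_signature_fraction: float = 0.1
    signature_genes_per_receptor: int = 8

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if any(n <= 0 for n in self.n_cells_per_subtype.values()):
            raise ValueError("n_cells_per_subtype entries must be positive")
        if not self.n_cells_per_subtype:
            raise ValueError("at least one subtype required")
        for nm in ("n_genes", "markers_per_subtype", "n_mito_genes",
                   "grid_rows", "grid_cols", "n_codex_cells", "lr_pairs"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be positive")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("nb_mean and nb_dispersion must be positive")
        lo, hi = self.mito_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("mito_fraction_range must lie within [0, 1]")
        if not 0 <= self.doublet_rate <= 1:
            raise ValueError("doublet_rate must lie in [0, 1]")
        for nid, vec in self.niche_compositions.items():
            v = np.asarray(vec, dtype=float)
            if len(v) != len(self.broad_types):
                raise ValueError(f"niche {nid}: composition length mismatch")
            if abs(v.sum() - 1.0) > 1e-9 or (v < 0).any():
                raise ValueError(f"niche {nid}: composition must sum to 1")

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "niche_compositions" in raw:
            raw["niche_compositions"] = {
                int(k): tuple(v) for k, v in raw["niche_compositions"].items()
            }
        for key in ("mito_fraction_range", "broad_types"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        data["niche_compositions"] = {
            int(k): list(v) for k, v in self.niche_compositions.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
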