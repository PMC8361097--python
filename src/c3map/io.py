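"""Reading and writing the package's on-disk formats.

Count matrices travel as MatrixMarket triplets with gene/barcode TSV
sidecars; annotations and ground truth as CSV; spot frames as CSV + MTX;
images as multi-page TIFF.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


def write_count_matrix(adata: ad.AnnData, outdir) -> None:
    """Write genes x cells MTX with genes.tsv / barcodes.tsv sidecars.

    Cell annotations in ``obs`` go to ``annotations.csv`` alongside.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.layers.get("counts", adata.X)
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    scipy.io.mmwrite(outdir / "matrix.mtx", X.T.tocoo())
    pd.Series(adata.var_names).to_csv(
        outdir / "genes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    if adata.obs.shape[1]:
        adata.obs.to_csv(outdir / "annotations.csv")


def read_count_matrix(indir) -> ad.AnnData:
    indir = Path(indir)
    X = scipy.io.mmread(indir / "matrix.mtx").T.tocsr()
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    obs = pd.DataFrame(index=barcodes.to_numpy())
    ann = indir / "annotations.csv"
    if ann.exists():
        obs = pd.read_csv(ann, index_col=0)
        obs.index = obs.index.astype(str)
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes.to_numpy()))
    adata.uns["lognorm"] = False
    return adata


def write_spot_frame(spots: ad.AnnData, outdir) -> None:
    """Spot frame: MTX + genes.tsv + spots.csv (spot_id, x, y columns)."""
    write_count_matrix(spots, outdir)
    coords = pd.DataFrame(
        {
            "spot_id": spots.obs_names,
            "x": spots.obs["array_x"].to_numpy(),
            "y": spots.obs["array_y"].to_numpy(),
        }
    )
    coords.to_csv(Path(outdir) / "spots.csv", index=False)


def read_spot_frame(indir) -> ad.AnnData:
    adata = read_count_matrix(indir)
    coords = pd.read_csv(Path(indir) / "spots.csv").set_index("spot_id")
    adata.obs["array_x"] = coords.loc[adata.obs_names, "x"].to_numpy()
    adata.obs["array_y"] = coords.loc[adata.obs_names, "y"].to_numpy()
    return adata


def write_images(path, mask: np.ndarray, channels: dict[str, np.ndarray]) -> None:
    """Write the labeled mask and intensity channels as a multi-page TIFF."""
    import tifffile

    pages = [mask.astype(np.float32)] + [
        channels[c].astype(np.float32) for c in sorted(channels)
    ]
    tifffile.imwrite(path, np.stack(pages), metadata={
        "channels": ["mask"] + sorted(channels)
    })
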