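"""Shared lightweight containers and file-format helpers.

Cell x gene and spot x gene matrices travel as :class:`anndata.AnnData`
throughout the package (counts in ``.X`` or ``layers["counts"]``; the
boolean flag ``.uns["lognorm"]`` records normalization state).  The small
value types defined here cover everything AnnData does not: ranked gene
signatures, ligand-receptor interaction records, and detected cellular
niches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GeneSignature:
    """A named, ordered gene list with per-gene derivation scores.

    Genes are ordered by decreasing score (the rank-sum z statistic of
    the 1-vs-all differential-expression test that produced them, or a
    correlation for latent-time signatures).
    """

    name: str
    genes: list[str]
    scores: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.scores and len(self.scores) != len(self.genes):
            raise ValueError("scores and genes must have equal length")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass
class InteractionRecord:
    """One called ligand-receptor interaction between two subtypes."""

    sender: str
    receiver: str
    ligand: str
    receptor: str
    potential: float
    transparency: float = float("nan")
    spatially_coexpressed: bool = True


@dataclass
class CellularNiche:
    """A cellular niche: cells with similar neighborhood composition."""

    niche_id: int
    centroid: np.ndarray
    label: str
    members: np.ndarray  # integer indices into the profiled cell table
    entropy: float = float("nan")


def write_gmt(signatures: list[GeneSignature], path) -> None:
    """Write signatures in the GMT gene-set format (one set per line)."""
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, "c3map"] + list(sig.genes)) + "\n")


def read_gmt(path) -> list[GeneSignature]:
    sigs = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sigs.append(GeneSignature(name=parts[0], genes=parts[2:]))
    return sigs


def interactions_to_frame(records: list[InteractionRecord]) -> pd.DataFrame:
    """Tabulate interaction records, ready for circos-style rendering."""
    return pd.DataFrame(
        [
            {
                "sender": r.sender,
                "receiver": r.receiver,
                "ligand": r.ligand,
                "receptor": r.receptor,
                "potential": r.potential,
                "transparency": r.transparency,
                "spatially_coexpressed": r.spatially_coexpressed,
            }
            for r in records
        ]
    )
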