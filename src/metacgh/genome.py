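"""Reference genome coordinates: chromosome lengths, centromeres, head-to-tail layout.

Array-CGH clones are addressed by (chromosome, basepair midpoint). Genome-wide
profiles are plotted and computed "head-to-tail": chromosomes concatenated in
karyotype order (1..22, X, Y), each clone also carrying a cumulative global
coordinate. The packaged reference table holds nominal chromosome lengths and
centromere midpoints of a GRCh-era human assembly; both are overridable, and
nothing downstream depends on the exact build beyond arm assignment
(position <= centromere -> p, else q) and chromosome extents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

#: Karyotype order used for all head-to-tail layouts.
CHROMOSOME_ORDER = [str(i) for i in range(1, 23)] + ["X", "Y"]

AUTOSOMES = [str(i) for i in range(1, 23)]


def _order_key(chrom: str) -> tuple[int, str]:
    if chrom in CHROMOSOME_ORDER:
        return (CHROMOSOME_ORDER.index(chrom), "")
    return (len(CHROMOSOME_ORDER), chrom)


@dataclass(frozen=True)
class Genome:
    """Chromosome lengths and centromere positions, in karyotype order.

    Parameters
    ----------
    lengths
        Mapping chromosome label -> length in bp.
    centromeres
        Mapping chromosome label -> centromere midpoint in bp. Must cover
        every chromosome in ``lengths``.
    """

    lengths: dict[str, int]
    centromeres: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.lengths) - set(self.centromeres)
        if missing:
            raise ValueError(f"centromere positions missing for chromosomes: {sorted(missing)}")

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.lengths, key=_order_key)

    def subset(self, chromosomes: list[str]) -> "Genome":
        unknown = [c for c in chromosomes if c not in self.lengths]
        if unknown:
            raise KeyError(f"unknown chromosomes: {unknown}")
        return Genome(
            {c: self.lengths[c] for c in chromosomes},
            {c: self.centromeres[c] for c in chromosomes},
        )

    def offsets(self) -> dict[str, int]:
        """Cumulative bp offset of each chromosome in head-to-tail order."""
        out, acc = {}, 0
        for c in self.chromosomes:
            out[c] = acc
            acc += self.lengths[c]
        return out

    def global_bp(self, chromosome: np.ndarray | pd.Series, position_bp: np.ndarray) -> np.ndarray:
        off = self.offsets()
        return np.asarray([off[c] for c in np.asarray(chromosome)]) + np.asarray(position_bp)

    def arm(self, chromosome: str, position_bp: int) -> str:
        return "p" if position_bp <= self.centromeres[chromosome] else "q"


def load_genome(path=None, chromosomes: list[str] | None = None) -> Genome:
    """Load a genome table (columns chromosome, length_bp, centromere_bp).

    Without ``path`` the packaged nominal reference is used.
    """
    if path is None:
        source = resources.files("metacgh.data").joinpath("genome_reference.tsv")
        with resources.as_file(source) as f:
            df = pd.read_csv(f, sep="\t", dtype={"chromosome": str})
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    genome = Genome(
        dict(zip(df["chromosome"], df["length_bp"].astype(int))),
        dict(zip(df["chromosome"], df["centromere_bp"].astype(int))),
    )
    if chromosomes is not None:
        genome = genome.subset(chromosomes)
    return genome


def make_grid(genome: Genome, spacing_bp: int, chromosomes: list[str] | None = None) -> pd.DataFrame:
    """Regular evaluation grid within each chromosome.

    Grid points sit at ``spacing/2 + k*spacing`` inside every chromosome, so
    no point falls on a chromosome boundary and spacing is constant within
    chromosomes. Returns columns chromosome, bp, global_bp.
    """
    if spacing_bp <= 0:
        raise ValueError("spacing_bp must be positive")
    chroms = chromosomes if chromosomes is not None else genome.chromosomes
    off = genome.offsets()
    parts = []
    for c in chroms:
        bp = np.arange(spacing_bp // 2, genome.lengths[c], spacing_bp, dtype=np.int64)
        parts.append(pd.DataFrame({"chromosome": c, "bp": bp, "global_bp": bp + off[c]}))
    grid = pd.concat(parts, ignore_index=True)
    return grid
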