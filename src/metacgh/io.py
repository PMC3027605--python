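"""Clone maps, log2-ratio matrices, cohort tables, and light preprocessing.

The in-memory containers are thin wrappers over pandas/numpy:

* :class:`CloneMap` — ordered genomic positions of array clones with arm
  assignment and a head-to-tail global coordinate.
* :class:`AcghDataset` — samples x clones matrix of log2 tumor/reference
  ratios with group labels; missing values are NaN.
* Cohort covariate tables are plain DataFrames keyed by sample_id, with
  unknowns coded explicitly (never dropped at load time).

All file formats are tab-separated text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .genome import Genome, load_genome

logger = logging.getLogger(__name__)


def parse_decimal(text: str) -> float:
    """Parse a decimal numeral, accepting a decimal comma ("0,027")."""
    return float(str(text).strip().replace(",", "."))


# ---------------------------------------------------------------------------
# CloneMap


@dataclass
class CloneMap:
    """Ordered array-clone coordinates.

    ``table`` has columns clone_id, chromosome, arm, position_bp, global_bp,
    sorted head-to-tail (karyotype chromosome order, then position). Built via
    :meth:`from_positions`, which validates uniqueness and ordering and
    assigns arms from the genome's centromere table.
    """

    table: pd.DataFrame
    genome: Genome

    @classmethod
    def from_positions(cls, df: pd.DataFrame, genome: Genome) -> "CloneMap":
        df = df.copy()
        df["chromosome"] = df["chromosome"].astype(str)
        dup = df["clone_id"][df["clone_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate clone ids: {sorted(set(dup))[:5]} ...")
        unknown = sorted(set(df["chromosome"]) - set(genome.lengths))
        if unknown:
            raise ValueError(f"unknown chromosome labels: {unknown}")
        bad = df[(df["position_bp"] < 1) | (df["position_bp"] > df["chromosome"].map(genome.lengths))]
        if len(bad):
            raise ValueError(f"clone positions outside chromosome bounds: {list(bad['clone_id'])[:5]}")

        order = genome.chromosomes
        key = df["chromosome"].map({c: i for i, c in enumerate(order)})
        sorted_df = df.iloc[np.lexsort((df["position_bp"].to_numpy(), key.to_numpy()))].reset_index(drop=True)
        if not sorted_df["clone_id"].tolist() == df["clone_id"].tolist():
            logger.info("clone map input was not in head-to-tail order; sorted")
        df = sorted_df

        per_chrom = df.groupby("chromosome", sort=False)["position_bp"]
        if (per_chrom.diff().dropna() <= 0).any():
            raise ValueError("duplicate clone positions within a chromosome")

        cen = df["chromosome"].map(genome.centromeres)
        df["arm"] = np.where(df["position_bp"] <= cen, "p", "q")
        df["global_bp"] = genome.global_bp(df["chromosome"], df["position_bp"])
        cols = ["clone_id", "chromosome", "arm", "position_bp", "global_bp"]
        return cls(df[cols], genome)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def clone_ids(self) -> list[str]:
        return self.table["clone_id"].tolist()

    @property
    def chromosome(self) -> np.ndarray:
        return self.table["chromosome"].to_numpy()

    @property
    def arm(self) -> np.ndarray:
        return self.table["arm"].to_numpy()

    @property
    def position_bp(self) -> np.ndarray:
        return self.table["position_bp"].to_numpy()

    @property
    def global_bp(self) -> np.ndarray:
        return self.table["global_bp"].to_numpy()

    def arm_label(self) -> np.ndarray:
        """Per-clone 'chrom+arm' labels, e.g. '20q'."""
        return (self.table["chromosome"] + self.table["arm"]).to_numpy()

    def region_mask(self, region) -> np.ndarray:
        """Boolean clone mask for a region.

        ``region`` is either an arm string like ``"20q"`` / a whole chromosome
        like ``"20"``, or a tuple ``(chromosome, start_bp, end_bp)`` with a
        half-open bp interval [start, end).
        """
        if isinstance(region, str):
            if region and region[-1] in "pq":
                chrom, arm = region[:-1], region[-1]
                return (self.chromosome == chrom) & (self.arm == arm)
            return self.chromosome == region
        chrom, start, end = region
        return (self.chromosome == str(chrom)) & (self.position_bp >= start) & (self.position_bp < end)

    def subset(self, mask: np.ndarray) -> "CloneMap":
        return CloneMap(self.table[mask].reset_index(drop=True), self.genome)


def load_clone_map(path, genome: Genome | None = None) -> CloneMap:
    """Load a clone map from TSV (clone_id, chromosome, position_bp) or
    4-column BED (chrom, start, end, name; clone position = interval midpoint).
    """
    if genome is None:
        genome = load_genome()
    head = pd.read_csv(path, sep="\t", nrows=1, header=None, dtype=str)
    first = str(head.iloc[0, 0]).lower()
    if first in {"clone_id", "cloneid", "clone"}:
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
        df = df.rename(columns={df.columns[0]: "clone_id"})
    else:  # headerless BED
        df = pd.read_csv(path, sep="\t", header=None, dtype={0: str},
                         names=["chromosome", "start", "end", "clone_id"])
        df["chromosome"] = df["chromosome"].str.removeprefix("chr")
        # BED is 0-based half-open; midpoint reported as a 1-based position
        df["position_bp"] = (df["start"] + df["end"]) // 2 + 1
    return CloneMap.from_positions(df[["clone_id", "chromosome", "position_bp"]], genome)


def write_clone_map(clone_map: CloneMap, path) -> None:
    clone_map.table[["clone_id", "chromosome", "position_bp"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# AcghDataset


@dataclass
class AcghDataset:
    """Samples x clones log2-ratio matrix with group labels.

    ``log2`` columns follow ``clone_map`` order exactly; missing measurements
    are NaN (exposed as :attr:`missing_mask`).
    """

    clone_map: CloneMap
    log2: np.ndarray
    sample_ids: list[str]
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.log2 = np.asarray(self.log2, dtype=float)
        self.groups = np.asarray(self.groups, dtype=object)
        if self.log2.shape != (len(self.sample_ids), len(self.clone_map)):
            raise ValueError(
                f"log2 shape {self.log2.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.clone_map)} clones"
            )
        if len(self.groups) != len(self.sample_ids):
            raise ValueError("one group label per sample required")

    @property
    def n_samples(self) -> int:
        return self.log2.shape[0]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.log2)

    @property
    def group_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def group_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.groups == label)

    def subset_samples(self, idx: np.ndarray) -> "AcghDataset":
        idx = np.asarray(idx)
        return AcghDataset(self.clone_map, self.log2[idx],
                           [self.sample_ids[i] for i in idx], self.groups[idx])

    def subset_clones(self, mask: np.ndarray) -> "AcghDataset":
        return AcghDataset(self.clone_map.subset(mask), self.log2[:, mask],
                           self.sample_ids, self.groups)

    def autosomal(self) -> "AcghDataset":
        """Drop sex-chromosome clones (reference DNA is typically male-pooled,
        so X/Y ratios are confounded)."""
        mask = ~np.isin(self.clone_map.chromosome, ["X", "Y"])
        return self.subset_clones(mask) if not mask.all() else self


def load_log2_matrix(path, clone_map: CloneMap, groups: dict[str, str] | None = None) -> AcghDataset:
    """Load a samples x clones TSV: column ``sample_id``, optional ``group``,
    then one column per clone id. Columns may appear in any order; they are
    reindexed to the clone map. NA/blank cells become missing values.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, float_precision="round_trip")
    sample_ids = df["sample_id"].tolist()
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids in matrix file")
    grp = df.pop("group").to_numpy() if "group" in df.columns else None
    df = df.set_index("sample_id")
    file_clones = list(df.columns)
    unknown = sorted(set(file_clones) - set(clone_map.clone_ids))
    if unknown:
        raise ValueError(f"clones absent from clone map: {unknown[:5]} ...")
    missing = sorted(set(clone_map.clone_ids) - set(file_clones))
    if missing:
        raise ValueError(f"clone map clones absent from matrix: {missing[:5]} ...")
    mat = df[clone_map.clone_ids].to_numpy(dtype=float)
    if grp is None:
        grp = np.array([groups[s] for s in sample_ids]) if groups else np.repeat("all", len(sample_ids))
    return AcghDataset(clone_map, mat, sample_ids, grp)


def write_log2_matrix(dataset: AcghDataset, path) -> None:
    df = pd.DataFrame(dataset.log2, index=pd.Index(dataset.sample_ids, name="sample_id"),
                      columns=dataset.clone_map.clone_ids)
    df.insert(0, "group", dataset.groups)
    # %.17g round-trips float64 exactly
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


def load_cohort_table(path) -> pd.DataFrame:
    """Load per-sample covariates keyed by sample_id. Unknowns stay as the
    literal category 'unknown'; nothing is dropped."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("unknown")
    if "sample_id" not in df.columns:
        raise ValueError("cohort table requires a sample_id column")
    return df.set_index("sample_id")


# ---------------------------------------------------------------------------
# Preprocessing


def average_replicates(spot_table: pd.DataFrame) -> pd.Series:
    """Collapse replicate spot measurements to one value per clone.

    ``spot_table`` is a long table with columns clone_id and log2 (replicate
    rows per clone, e.g. triplicate spotting). The mean is taken over
    non-missing replicates; a clone whose replicates are all missing yields
    NaN.
    """
    if not len(spot_table):
        raise ValueError("empty spot table")
    return spot_table.groupby("clone_id", sort=False)["log2"].mean()


def median_center(dataset: AcghDataset) -> AcghDataset:
    """Center each sample so its non-missing log2 values have median zero.

    Removes per-sample intensity offsets (the clone-level analogue of
    subarray median normalization on the physical array).
    """
    med = np.nanmedian(dataset.log2, axis=1, keepdims=True)
    return AcghDataset(dataset.clone_map, dataset.log2 - med, dataset.sample_ids, dataset.groups)


def region_mean_log2(dataset: AcghDataset, region) -> pd.Series:
    """Per-sample mean log2 over the clones in a region (see
    :meth:`CloneMap.region_mask`). Missing values are excluded per sample."""
    mask = dataset.clone_map.region_mask(region)
    if not mask.any():
        raise ValueError(f"region {region!r} contains no clones")
    with np.errstate(invalid="ignore"):
        vals = np.nanmean(dataset.log2[:, mask], axis=1)
    return pd.Series(vals, index=dataset.sample_ids, name="mean_log2")


def copy_number_estimate(mean_log2, reference_ploidy: float = 2.0):
    """Approximate absolute copy number from an averaged log2 ratio:
    ``reference_ploidy * 2**mean_log2`` (2.0 at log2 = 0)."""
    return reference_ploidy * np.exp2(mean_log2)


# ---------------------------------------------------------------------------
# Packaged fixtures (transcribed published summary tables)


def load_cohort_characteristics() -> dict[str, pd.DataFrame]:
    """Packaged per-characteristic contingency tables of the three patient
    groups (M0 / PM / LM columns, categories as rows), including explicit
    'unknown' rows."""
    source = resources.files("metacgh.data").joinpath("cohort_characteristics_counts.tsv")
    with resources.as_file(source) as f:
        df = pd.read_csv(f, sep="\t")
    out = {}
    for name, sub in df.groupby("characteristic", sort=False):
        out[name] = sub.set_index("category")[["M0", "PM", "LM"]]
    return out


def load_chr20_clone_panel(genome: Genome | None = None) -> tuple[CloneMap, pd.Series]:
    """Packaged chromosome-20 clone panel (65 BAC clones, nominal positions)
    with a per-clone flag marking membership in the liver-metastasis
    classifier. Returns (CloneMap, membership Series indexed by clone_id)."""
    source = resources.files("metacgh.data").joinpath("chr20_clone_panel.tsv")
    with resources.as_file(source) as f:
        df = pd.read_csv(f, sep="\t", dtype={"chromosome": str})
    cmap = CloneMap.from_positions(df[["clone_id", "chromosome", "position_bp"]],
                                   genome or load_genome())
    member = df.set_index("clone_id")["in_lm_classifier"].astype(bool)
    return cmap, member.reindex(cmap.clone_ids)
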