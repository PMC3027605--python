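"""Synthetic aCGH cohort generator.

Emulates the statistical structure the downstream analyses assume: a clone
map at regular (~1 Mb) spacing over the autosomes, and per-sample log2
profiles built additively from

* shared aberration segments (recurrent gains/losses present in all groups),
* group-specific segments (e.g. a liver-metastasis-specific 20q gain),
* a per-sample baseline offset ~ N(0, sample_offset_sd^2),
* independent per-clone Gaussian noise ~ N(0, noise_sd^2) (optionally AR(1)
  correlated along the genome for robustness experiments).

Each sample carries each eligible segment with probability ``penetrance``
(independent Bernoulli draws). The full truth — carried segments and
noise-free mean per clone — is returned alongside the dataset, so recovery
can be scored exactly. All randomness flows from one seed; draw order is
fixed (offsets first, then segment carriage per sample in id order and
segment in list order, then the noise matrix), so truths are reproducible.

Default group sizes are LM=36, PM=37, M0=25 — the cohort composition of the
liver-metastasis / peritoneal-metastasis / metastasis-free study design this
generator emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import AUTOSOMES, Genome, load_genome
from .io import AcghDataset, CloneMap


@dataclass(frozen=True)
class AberrationSegment:
    """A planted copy-number aberration.

    amplitude is the log2 shift (positive gain, negative loss); penetrance is
    the fraction of samples in the target groups carrying the segment;
    ``target_groups=None`` targets every group. The bp interval is half-open
    [start_bp, end_bp).
    """

    chromosome: str
    start_bp: int
    end_bp: int
    amplitude: float
    penetrance: float = 1.0
    target_groups: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise ValueError("segment start_bp must be < end_bp")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must lie in [0, 1]")

    @classmethod
    def arm(cls, genome: Genome, chromosome: str, arm: str, amplitude: float,
            penetrance: float = 1.0, target_groups: tuple[str, ...] | None = None) -> "AberrationSegment":
        """Segment spanning a whole chromosome arm."""
        cen = genome.centromeres[chromosome]
        if arm == "p":
            start, end = 1, cen + 1
        elif arm == "q":
            start, end = cen + 1, genome.lengths[chromosome] + 1
        else:
            raise ValueError("arm must be 'p' or 'q'")
        return cls(chromosome, start, end, amplitude, penetrance, target_groups)

    def targets(self, group: str) -> bool:
        return self.target_groups is None or group in self.target_groups


def default_shared_segments(genome: Genome) -> list[AberrationSegment]:
    """Baseline recurrent colorectal-tumor aberrations shared by all groups:
    gains of 7, 8q, 13q and low-level 20q; losses of 8p, 17p and 18q.
    Amplitudes/penetrances are plausible configuration, not measurements.
    Segments on chromosomes absent from the genome are skipped."""
    seg = AberrationSegment.arm
    candidates = [
        ("7", None, 0.15), ("8", "q", 0.2), ("13", "q", 0.2), ("20", "q", 0.1),
        ("8", "p", -0.2), ("17", "p", -0.2), ("18", "q", -0.25),
    ]
    out = []
    for chrom, arm, amp in candidates:
        if chrom not in genome.lengths:
            continue
        pen = 0.4 if (chrom, arm) == ("20", "q") else 0.5
        if arm is None:
            out.append(AberrationSegment(chrom, 1, genome.lengths[chrom] + 1, amp, pen))
        else:
            out.append(seg(genome, chrom, arm, amp, pen))
    return out


def default_specific_segments(genome: Genome) -> list[AberrationSegment]:
    """The planted group-specific effect: a 20q gain confined to the
    liver-metastasis group (amplitude 0.3 log2, penetrance 0.8)."""
    if "20" not in genome.lengths:
        return []
    return [AberrationSegment.arm(genome, "20", "q", 0.3, 0.8, target_groups=("LM",))]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic cohort. See the module docstring for the
    generative model. ``shared_segments``/``specific_segments`` default to
    the packaged baseline when left as None."""

    group_sizes: dict[str, int] = field(default_factory=lambda: {"LM": 36, "PM": 37, "M0": 25})
    shared_segments: list[AberrationSegment] | None = None
    specific_segments: list[AberrationSegment] | None = None
    noise_sd: float = 0.2
    sample_offset_sd: float = 0.05
    clone_spacing_bp: int = 1_000_000
    chromosomes: tuple[str, ...] = tuple(AUTOSOMES)
    ar1_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        if self.noise_sd < 0 or self.sample_offset_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        if not -1 < self.ar1_rho < 1:
            raise ValueError("ar1_rho must lie in (-1, 1)")

    def resolved_segments(self, genome: Genome) -> tuple[list[AberrationSegment], list[AberrationSegment]]:
        shared = self.shared_segments if self.shared_segments is not None else default_shared_segments(genome)
        specific = self.specific_segments if self.specific_segments is not None else default_specific_segments(genome)
        return list(shared), list(specific)


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort: segments carried per sample, the
    noise-free mean log2 per sample x clone (segments + sample offset), and
    the per-sample offsets."""

    carried: dict[str, list[AberrationSegment]]
    mean_log2: np.ndarray
    sample_offsets: np.ndarray
    specific_segments: list[AberrationSegment]


def generate_clone_map(spec: SyntheticSpec, genome: Genome | None = None) -> CloneMap:
    """Deterministic clone map: one clone per complete spacing bin, at the
    bin midpoint — floor(length/spacing) clones per chromosome."""
    if spec.clone_spacing_bp <= 0:
        raise ValueError("clone_spacing_bp must be positive")
    genome = (genome or load_genome()).subset(list(spec.chromosomes))
    rows = []
    for chrom in genome.chromosomes:
        s = spec.clone_spacing_bp
        positions = np.arange(s // 2, genome.lengths[chrom] - s // 2 + 1, s, dtype=np.int64)
        for pos in positions:
            rows.append((f"SIM-{chrom}-{pos // spec.clone_spacing_bp:04d}", chrom, int(pos)))
    df = pd.DataFrame(rows, columns=["clone_id", "chromosome", "position_bp"])
    return CloneMap.from_positions(df, genome)


def _segment_clone_mask(seg: AberrationSegment, clone_map: CloneMap) -> np.ndarray:
    genome = clone_map.genome
    if seg.chromosome not in genome.lengths:
        raise ValueError(f"segment chromosome {seg.chromosome!r} not in the genome")
    if seg.start_bp > genome.lengths[seg.chromosome]:
        raise ValueError(f"segment {seg} lies outside chromosome {seg.chromosome}")
    return clone_map.region_mask((seg.chromosome, seg.start_bp, seg.end_bp))


def generate_cohort(spec: SyntheticSpec, genome: Genome | None = None) -> tuple[AcghDataset, SyntheticTruth]:
    """Draw one cohort. Fully reproducible from ``spec.seed``."""
    clone_map = generate_clone_map(spec, genome)
    shared, specific = spec.resolved_segments(clone_map.genome)
    segments = shared + specific
    seg_masks = [_segment_clone_mask(s, clone_map) for s in segments]

    sample_ids, groups = [], []
    for grp, n in spec.group_sizes.items():
        for i in range(n):
            sample_ids.append(f"{grp}-{i + 1:02d}")
            groups.append(grp)
    n_samples, n_clones = len(sample_ids), len(clone_map)

    rng = np.random.default_rng(spec.seed)
    offsets = rng.normal(0.0, spec.sample_offset_sd, size=n_samples) if spec.sample_offset_sd > 0 else np.zeros(n_samples)

    mean = np.tile(offsets[:, None], (1, n_clones))
    carried: dict[str, list[AberrationSegment]] = {s: [] for s in sample_ids}
    for i, (sid, grp) in enumerate(zip(sample_ids, groups)):
        for seg, mask in zip(segments, seg_masks):
            if not seg.targets(grp):
                continue
            if rng.random() < seg.penetrance:
                mean[i, mask] += seg.amplitude
                carried[sid].append(seg)

    if spec.noise_sd > 0:
        eps = rng.normal(0.0, spec.noise_sd, size=(n_samples, n_clones))
        if spec.ar1_rho != 0.0:
            eps = _ar1_along_genome(eps, clone_map, spec.ar1_rho)
    else:
        eps = np.zeros((n_samples, n_clones))

    dataset = AcghDataset(clone_map, mean + eps, sample_ids, np.array(groups, dtype=object))
    truth = SyntheticTruth(carried, mean, offsets, specific)
    return dataset, truth


def _ar1_along_genome(eps: np.ndarray, clone_map: CloneMap, rho: float) -> np.ndarray:
    """Impose an AR(1) correlation along clone order within each chromosome,
    keeping the marginal variance (innovations rescaled by sqrt(1-rho^2))."""
    out = np.empty_like(eps)
    scale = np.sqrt(1.0 - rho * rho)
    chrom = clone_map.chromosome
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        block = eps[:, idx]
        acc = np.empty_like(block)
        acc[:, 0] = block[:, 0]
        for j in range(1, block.shape[1]):
            acc[:, j] = rho * acc[:, j - 1] + scale * block[:, j]
        out[:, idx] = acc
    return out


#: Default probability of nodal involvement (N+) per group, mirroring the
#: kind of imbalance seen in metastasis-stratified CRC cohorts.
DEFAULT_NPLUS_PROB = {"LM": 0.6, "PM": 0.5, "M0": 0.25}


def simulate_cohort_covariates(sample_ids: list[str], groups: np.ndarray, seed: int,
                               nplus_prob: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-sample covariate table (nodal status) with group-dependent N+
    rates. Unlisted groups default to 0.4."""
    probs = nplus_prob or DEFAULT_NPLUS_PROB
    rng = np.random.default_rng(np.random.SeedSequence([seed, 911]).generate_state(1)[0])
    nodal = [("N+" if rng.random() < probs.get(g, 0.4) else "N0") for g in groups]
    return pd.DataFrame({"sample_id": sample_ids, "group": list(groups),
                         "nodal_status": nodal}).set_index("sample_id")


def null_cohort(spec: SyntheticSpec, genome: Genome | None = None) -> tuple[AcghDataset, SyntheticTruth]:
    """Same generator with group-specific segments removed: groups are
    exchangeable by construction (the null for permutation calibration)."""
    return generate_cohort(replace(spec, specific_segments=[]), genome)
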