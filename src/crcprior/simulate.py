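"""Seeded generators for every input class the pipeline consumes.

Each generator is a pure function of its spec (including the mandatory
seed): rerunning with the same spec reproduces byte-identical data. Every
generator returns the data together with a *truth record* sufficient to
score recovery of the planted structure without re-reading the spec.

What is emulated
----------------
* ``gen_se_landscape`` - a panel of cell lines sharing one planted driver
  SE cluster (top within-sample ranks, high recurrence) among decoy
  clusters with uniformly lower ranks, plus gene models and per-sample
  TSS peak calls.
* ``gen_cohort`` - a tumor cohort in which the driver gene's expression is
  shifted by arm-level copy-number gain and linked to survival hazard
  (exponential times, proportional hazards per SD of expression,
  independent censoring); all other genes are pure noise.
* ``gen_fourc`` - Bernoulli fragment coverage with planted
  high-coverage interaction windows on a background rate.
* ``gen_checkerboard`` - Hill-curve single agents combined under exact
  Bliss independence plus a planted synergy offset and optional noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CopyNumberSegment,
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    SampleTable,
    SurvivalTable,
    ValidationError,
)
from .fourc import FragmentTrack
from .synergy import Checkerboard

__all__ = [
    "LandscapeSpec",
    "CohortSpec",
    "FourCSpec",
    "CheckerboardSpec",
    "gen_se_landscape",
    "gen_cohort",
    "gen_fourc",
    "gen_checkerboard",
]

CHR17Q_START = 38_100_000
CHR17Q_END = 81_100_000


@dataclass
class LandscapeSpec:
    """A panel of ``n_samples`` cell lines with one driver SE cluster
    (present in ``harboring_samples`` lines at within-sample rank <=
    ``driver_max_rank``) and ``n_decoy_clusters`` decoys with uniform
    ranks. Planted clusters are spaced ``cluster_spacing`` bp apart, far
    beyond ``max_gap``, so the expected cluster count is known."""

    seed: int
    n_samples: int = 26
    n_decoy_clusters: int = 20
    harboring_samples: int = 24
    driver_max_rank: int = 3
    chrom: str = "chr17"
    region_start: int = CHR17Q_START
    cluster_spacing: int = 1_500_000
    cluster_width: int = 20_000
    jitter: int = 200
    max_gap: int = 500
    decoy_min_recurrence: int = 3

    def __post_init__(self) -> None:
        if self.harboring_samples > self.n_samples:
            raise ValidationError("harboring_samples must be <= n_samples")
        if self.jitter * 2 > self.cluster_width:
            raise ValidationError("jitter must be small relative to cluster width")
        if self.cluster_spacing <= self.cluster_width + 2 * self.jitter + self.max_gap:
            raise ValidationError("clusters must be separated by more than max_gap")


def gen_se_landscape(spec: LandscapeSpec):
    """Generate per-sample SE call tables, gene models, TSS peak tables
    and the truth record for one planted landscape."""
    rng = np.random.default_rng(spec.seed)
    n_clusters = spec.n_decoy_clusters + 1
    centers = [
        spec.region_start + spec.cluster_spacing * (k + 1) for k in range(n_clusters)
    ]
    driver_idx = int(rng.integers(n_clusters))

    membership = np.zeros((n_clusters, spec.n_samples), dtype=bool)
    membership[driver_idx, rng.choice(spec.n_samples, spec.harboring_samples, replace=False)] = True
    recurrences = {}
    for k in range(n_clusters):
        if k == driver_idx:
            continue
        r = int(rng.integers(spec.decoy_min_recurrence, spec.n_samples + 1))
        membership[k, rng.choice(spec.n_samples, r, replace=False)] = True
        recurrences[k] = r
    recurrences[driver_idx] = spec.harboring_samples

    sample_ids = [f"CL{i + 1:02d}" for i in range(spec.n_samples)]
    se_tables: dict[str, SampleTable] = {}
    planted_ranks: dict[tuple[int, str], int] = {}
    for s, sid in enumerate(sample_ids):
        present = [k for k in range(n_clusters) if membership[k, s]]
        m = len(present)
        if m == 0:
            se_tables[sid] = SampleTable(sid, [])
            continue
        ranks = _plant_ranks(rng, present, driver_idx, spec.driver_max_rank, m)
        intervals = []
        for k, rank in zip(present, ranks):
            jit = int(rng.integers(-spec.jitter, spec.jitter + 1))
            start = centers[k] - spec.cluster_width // 2 + jit
            # signal decreasing in rank with a jitter smaller than the gap
            # between consecutive rank levels, so ranks are recoverable
            signal = float((m - rank + 1) * 100 + rng.uniform(0, 50))
            intervals.append(
                GenomicInterval(spec.chrom, start, start + spec.cluster_width, signal)
            )
            planted_ranks[(k, sid)] = rank
        se_tables[sid] = SampleTable(sid, intervals)

    genes, tss_peaks = _landscape_genes_and_peaks(spec, centers, sample_ids, driver_idx)
    truth = {
        "driver_cluster": driver_idx,
        "driver_gene_id": f"GENE{driver_idx:03d}",
        "cluster_centers": centers,
        "cluster_spans": [
            GenomicInterval(
                spec.chrom,
                c - spec.cluster_width // 2 - spec.jitter,
                c + spec.cluster_width // 2 + spec.jitter,
            )
            for c in centers
        ],
        "recurrences": recurrences,
        "planted_ranks": planted_ranks,
        "tf_gene_ids": [f"GENE{k:03d}" for k in range(n_clusters)],
    }
    return se_tables, genes, tss_peaks, truth


def _plant_ranks(rng, present, driver_idx, driver_max_rank, m) -> list[int]:
    if driver_idx in present:
        r_d = int(rng.integers(1, min(driver_max_rank, m) + 1))
        others = [r for r in range(1, m + 1) if r != r_d]
        rng.shuffle(others)
        ranks, j = [], 0
        for k in present:
            if k == driver_idx:
                ranks.append(r_d)
            else:
                ranks.append(others[j])
                j += 1
        return ranks
    ranks = list(range(1, m + 1))
    rng.shuffle(ranks)
    return ranks


def _landscape_genes_and_peaks(spec, centers, sample_ids, driver_idx):
    genes: list[GeneModel] = []
    for k, center in enumerate(centers):
        tss = center + 30_000
        genes.append(
            GeneModel(
                gene_id=f"GENE{k:03d}",
                symbol=f"TF{k}",
                chrom=spec.chrom,
                start=tss,
                end=tss + 10_000,
                strand="+",
                is_tf=True,
            )
        )
        # a nearby non-TF gene exercising the TF gate
        genes.append(
            GeneModel(
                gene_id=f"NTF{k:03d}",
                symbol=f"NONTF{k}",
                chrom=spec.chrom,
                start=tss + 50_000,
                end=tss + 60_000,
                strand="-",
                is_tf=False,
            )
        )
    peaks = {
        sid: SampleTable(
            sid,
            [
                GenomicInterval(g.chrom, g.tss - 200, g.tss + 200)
                for g in genes
            ],
        )
        for sid in sample_ids
    }
    return genes, peaks


@dataclass
class CohortSpec:
    """A tumor cohort with expression, survival, copy-number segments and
    stage annotations. ``driver_hr`` is the hazard ratio per standard
    deviation of driver expression; ``gain_expression_shift`` is the
    additive log2-expression shift in arm-gained tumors."""

    seed: int
    n_tumors: int = 200
    driver_hr: float = 2.5
    gain_fraction: float = 0.5
    gain_expression_shift: float = 1.0
    stage_high_fraction: float = 0.5
    baseline_hazard: float = 1.0 / 1500.0  # per day
    censoring_rate: float = 0.3
    noise_sd: float = 1.0
    baseline_expression: float = 8.0
    gained_log2: float = 0.5
    segment_log2_sd: float = 0.05
    chrom: str = "chr17"

    def __post_init__(self) -> None:
        for name in ("gain_fraction", "stage_high_fraction", "censoring_rate"):
            if not 0 <= getattr(self, name) < 1:
                raise ValidationError(f"{name} must be in [0, 1)")
        if self.driver_hr <= 0 or self.baseline_hazard <= 0:
            raise ValidationError("hazard parameters must be positive")


def gen_cohort(spec: CohortSpec, gene_ids: list[str], driver_gene_id: str):
    """Generate (expression, survival, segments, stage_high, truth)."""
    if driver_gene_id not in gene_ids:
        raise ValidationError("driver gene must be among the cohort's genes")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_tumors
    sample_ids = [f"T{i + 1:03d}" for i in range(n)]

    gained = rng.random(n) < spec.gain_fraction
    stage_high = rng.random(n) < spec.stage_high_fraction

    values = pd.DataFrame(
        rng.normal(spec.baseline_expression, spec.noise_sd, (len(gene_ids), n)),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=sample_ids,
    )
    driver = (
        spec.baseline_expression
        + spec.gain_expression_shift * gained
        + rng.normal(0, spec.noise_sd, n)
    )
    values.loc[driver_gene_id] = driver
    expression = ExpressionMatrix(values)

    z = (driver - driver.mean()) / driver.std(ddof=0)
    hazard = spec.baseline_hazard * spec.driver_hr**z
    event_time = rng.exponential(1.0 / hazard)
    if spec.censoring_rate > 0:
        c_rate = spec.baseline_hazard * spec.censoring_rate / (1 - spec.censoring_rate)
        censor_time = rng.exponential(1.0 / c_rate, n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    survival = SurvivalTable(
        pd.DataFrame({"sample_id": sample_ids, "time": time, "event": event})
    )

    segments = {}
    for i, sid in enumerate(sample_ids):
        log2 = (spec.gained_log2 if gained[i] else 0.0) + rng.normal(
            0, spec.segment_log2_sd
        )
        segments[sid] = [
            CopyNumberSegment(spec.chrom, CHR17Q_START, CHR17Q_END, float(log2))
        ]
    stage = dict(zip(sample_ids, (bool(v) for v in stage_high)))
    truth = {
        "gained": dict(zip(sample_ids, (bool(v) for v in gained))),
        "driver_gene_id": driver_gene_id,
        "driver_expression": dict(zip(sample_ids, driver)),
    }
    return expression, survival, segments, stage, truth


@dataclass
class FourCSpec:
    """Bernoulli fragment coverage at rate ``p_bg`` with planted windows
    (fragment start index, width in fragments, coverage probability)."""

    seed: int
    n_fragments: int = 5_000
    p_bg: float = 0.05
    planted_windows: list[tuple[int, int, float]] = field(default_factory=list)
    viewpoint_index: int | None = None
    chrom: str = "chr17"
    start_pos: int = 59_000_000
    min_frag: int = 200
    max_frag: int = 2_000

    def __post_init__(self) -> None:
        if not 0 <= self.p_bg <= 1:
            raise ValidationError("p_bg must be in [0, 1]")
        ends = []
        for start, width, p_hi in self.planted_windows:
            if not self.p_bg < p_hi <= 1:
                raise ValidationError("need p_bg < p_hi <= 1 for planted windows")
            if start < 0 or start + width > self.n_fragments:
                raise ValidationError("planted window outside the track")
            ends.append((start, start + width))
        ends.sort()
        for (s1, e1), (s2, e2) in zip(ends, ends[1:]):
            if s2 < e1:
                raise ValidationError("planted windows must not overlap")


def gen_fourc(spec: FourCSpec):
    """Generate a FragmentTrack plus the truth record of planted windows."""
    rng = np.random.default_rng(spec.seed)
    widths = rng.integers(spec.min_frag, spec.max_frag + 1, spec.n_fragments)
    starts = spec.start_pos + np.concatenate([[0], np.cumsum(widths[:-1])])
    prob = np.full(spec.n_fragments, spec.p_bg)
    for start, width, p_hi in spec.planted_windows:
        prob[start : start + width] = p_hi
    covered = rng.random(spec.n_fragments) < prob
    counts = covered * (1 + rng.poisson(2.0, spec.n_fragments))
    track = FragmentTrack(
        chrom=spec.chrom,
        fragment_starts=starts,
        counts=counts.astype(np.int64),
        viewpoint_index=spec.viewpoint_index,
    )
    truth = {
        "planted_windows": [
            {"start_index": s, "width": w, "p_hi": p}
            for s, w, p in spec.planted_windows
        ],
        "p_bg": spec.p_bg,
    }
    return track, truth


def _hill_viability(dose: np.ndarray, ec50: float, slope: float, emax: float) -> np.ndarray:
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        frac = dose**slope / (dose**slope + ec50**slope)
    frac = np.where(dose == 0, 0.0, frac)
    return 100.0 * (1.0 - emax * frac)


# three-fold dilution series mirroring the checkerboard layout used for
# the BET/CDK7 inhibitor pair (top doses 33.3 uM and 0.333 uM, 9 steps)
def _dilution_series(top_nm: float, n: int = 9, factor: float = 3.0) -> list[float]:
    return [0.0] + [top_nm / factor ** (n - 1 - k) for k in range(n)]


@dataclass
class CheckerboardSpec:
    """Hill single agents combined under Bliss independence plus a planted
    synergy offset on the combination cells."""

    seed: int
    doses_a: list[float] = field(default_factory=lambda: _dilution_series(33_300.0))
    doses_b: list[float] = field(default_factory=lambda: _dilution_series(333.0))
    ec50_a: float = 1_000.0
    slope_a: float = 1.0
    emax_a: float = 0.9
    ec50_b: float = 30.0
    slope_b: float = 1.2
    emax_b: float = 0.85
    synergy_term: float | np.ndarray = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def gen_checkerboard(spec: CheckerboardSpec):
    """Generate a Checkerboard plus the truth record of the planted
    excess-over-Bliss surface."""
    rng = np.random.default_rng(spec.seed)
    doses_a = np.asarray(spec.doses_a, dtype=float)
    doses_b = np.asarray(spec.doses_b, dtype=float)
    i_a = 1.0 - _hill_viability(doses_a, spec.ec50_a, spec.slope_a, spec.emax_a) / 100.0
    i_b = 1.0 - _hill_viability(doses_b, spec.ec50_b, spec.slope_b, spec.emax_b) / 100.0

    synergy = np.zeros((len(doses_a), len(doses_b)))
    syn = np.asarray(spec.synergy_term, dtype=float)
    if syn.ndim == 0:
        synergy[1:, 1:] = float(syn)
    else:
        if syn.shape != synergy[1:, 1:].shape:
            raise ValidationError("synergy_term matrix must cover the combination cells")
        synergy[1:, 1:] = syn

    expected = i_a[:, None] + i_b[None, :] - i_a[:, None] * i_b[None, :]
    inhibition = expected + synergy
    viability = 100.0 * (1.0 - inhibition)
    if (viability < 0).any() or (viability > 100).any():
        raise ValidationError("planted synergy pushes viability outside [0, 100]")
    if spec.noise_sd > 0:
        viability = viability + rng.normal(0, spec.noise_sd * 100.0, viability.shape)
        viability = np.clip(viability, 0.0, None)
        viability[0, 0] = 100.0
    board = Checkerboard(doses_a=doses_a, doses_b=doses_b, viability=viability)
    truth = {"planted_eob": synergy}
    return board, truth
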