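"""Synthetic cfDNA cohort generator.

Generates healthy-donor panels and patient plasma/tumor samples with the
statistical structure the downstream analysis assumes:

* binned sWGS coverage where tumor copy-number alterations are mixed at
  tumor fraction theta into a diploid background, modulated by smooth GC
  bias, per-segment biological variability, and negative-binomial count
  noise;
* fragment-length histograms drawn from a theta-weighted mixture of a
  normal-cfDNA length distribution (mode 166 bp) and a shorter
  tumor-derived one (mode 145 bp);
* somatic mutations whose expected plasma VAF follows the mixture algebra
  theta*CCF*m / (theta*c_s + (1-theta)*2) for local tumor copy number c_s
  and multiplicity m, observed as binomial draws at the assay depth with a
  substitution-error floor.

Healthy donors are theta = 0 with no mutations. All randomness flows from
one master seed; per-sample streams are derived by stable hashing of the
sample id, so any sample can be regenerated independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from cftriage.errors import ConfigurationError, DomainError
from cftriage.genome import GenomeDef

MAX_LEN = 500


@dataclass(frozen=True)
class MutationSpec:
    """Generating truth for one somatic mutation."""

    locus_id: str
    ccf: float
    multiplicity: int = 1
    hotspot: bool = False
    in_panel: bool = True  # ultra-deep (small) panel membership
    in_targeted: bool = True  # targeted (large) panel membership
    segment_id: str | None = None  # None -> diploid locus
    chrom: str = "chr1"
    pos: int = 1_000_000
    ref: str = "C"
    alt: str = "T"

    def __post_init__(self) -> None:
        if not (0 < self.ccf <= 1):
            raise ConfigurationError(f"CCF {self.ccf} outside (0, 1]")
        if self.multiplicity < 1:
            raise ConfigurationError("multiplicity must be >= 1")


@dataclass(frozen=True)
class FragLenParams:
    """Discretized-normal fragment-length law on [1, 500] bp."""

    mode: float
    sd: float

    def pmf(self) -> np.ndarray:
        """Probability of each integer length 1..500 (index = length; slot 0 is 0)."""
        edges = np.arange(0.5, MAX_LEN + 1.5)
        cdf = sps.norm.cdf(edges, loc=self.mode, scale=self.sd)
        p = np.diff(cdf)
        p = np.r_[0.0, p]
        return p / p.sum()


def default_cna_profile(n_segments: int = 20) -> dict[str, float]:
    """Default tumor copy-number profile: 4 single-copy gains, 4 losses, rest diploid.

    Eight of twenty segments altered (~40% of the genome) is typical of
    CNA-bearing metastatic solid tumors.
    """
    profile = {f"seg{i:02d}": 2.0 for i in range(n_segments)}
    for i in (1, 5, 9, 13):
        profile[f"seg{i:02d}"] = 3.0
    for i in (3, 7, 11, 17):
        profile[f"seg{i:02d}"] = 1.0
    return profile


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults reproduce the study's assay scales: ~10M sWGS reads per
    sample, 644x tumor and 631x plasma targeted depth, 12,000x collapsed
    ultra-deep depth, a 10-donor healthy panel and 118 patients.
    """

    seed: int = 0
    n_healthy: int = 10
    n_patients: int = 118
    theta_grid: tuple[float, ...] | None = None  # None -> log-uniform [0.002, 0.6]
    cna_profile: dict[str, float] | None = None  # None -> default_cna_profile()
    n_reads_swgs: int = 10_000_000
    depth_tumor: int = 644
    depth_plasma_targeted: int = 631
    depth_ultradeep: int = 12_000
    error_targeted: float = 2e-4
    error_ultradeep: float = 1e-5
    fraglen_normal_params: FragLenParams = FragLenParams(166.0, 25.0)
    fraglen_tumor_params: FragLenParams = FragLenParams(145.0, 25.0)
    n_fragments: int = 10_000
    mutation_spec: tuple[MutationSpec, ...] | None = None  # None -> drawn per patient
    nb_dispersion: float = 2.0  # variance = dispersion * mean
    gc_bias_slope: float = 0.5  # factor 1 + slope * (gc - 0.40)
    segment_noise_sd: float = 0.008  # per-sample per-segment lognormal sd
    fraglen_mode_jitter_sd: float = 6.0  # per-sample bp jitter of both modes
    theta_range: tuple[float, float] = (0.004, 0.6)
    cn_attenuated_prob: float = 0.15  # P(patient tumor is copy-number-quiet)
    cn_attenuation_range: tuple[float, float] = (0.2, 0.6)  # CNA scale for quiet tumors
    tumor_available_prob: float = 76 / 118
    panel_negative_prob: float = 0.08  # P(all drivers outside both panels)
    mean_mutations: float = 5.0  # per patient, 1 + Poisson(mean - 1)

    def __post_init__(self) -> None:
        if self.n_healthy < 0 or self.n_patients < 0:
            raise ConfigurationError("cohort sizes must be >= 0")
        if self.theta_grid is not None and any(not 0 <= t <= 1 for t in self.theta_grid):
            raise ConfigurationError("theta values must lie in [0, 1]")
        for d in (self.depth_tumor, self.depth_plasma_targeted, self.depth_ultradeep):
            if d <= 0:
                raise ConfigurationError("assay depths must be positive")
        for e in (self.error_targeted, self.error_ultradeep):
            if not 0 <= e <= 0.01:
                raise ConfigurationError("error rates must lie in [0, 0.01]")
        if self.nb_dispersion < 1:
            raise ConfigurationError("nb_dispersion must be >= 1 (variance >= mean)")


@dataclass
class SimulatedSample:
    """One simulated plasma sample (healthy donor or patient) plus its truth."""

    sample_id: str
    role: str  # healthy | patient
    theta: float
    bin_counts: np.ndarray = field(repr=False)
    fragment_length_counts: np.ndarray = field(repr=False)
    mutations: pd.DataFrame | None = field(default=None, repr=False)
    truth: dict = field(default_factory=dict, repr=False)

    @property
    def fragment_lengths(self) -> np.ndarray:
        """Expanded multiset of fragment lengths (bp)."""
        return np.repeat(np.arange(MAX_LEN + 1), self.fragment_length_counts)


def sample_rng(master_seed: int, sample_id: str) -> np.random.Generator:
    """Independent, reproducible stream for one sample id."""
    return np.random.default_rng(
        np.random.SeedSequence([master_seed & 0x7FFFFFFF, zlib.crc32(sample_id.encode())])
    )


def expected_vaf(theta: float, ccf: float, multiplicity: int = 1, copy_number: float = 2.0) -> float:
    """Expected plasma VAF: theta*CCF*m / (theta*c + (1-theta)*2)."""
    denom = theta * copy_number + (1 - theta) * 2.0
    return theta * ccf * multiplicity / denom


def expected_tumor_fragment_weight(theta: float, copy_numbers: np.ndarray) -> float:
    """Genome-averaged weight of the tumor fragment-length component."""
    c = np.asarray(copy_numbers, dtype=float)
    return float(np.mean(theta * c / (theta * c + (1 - theta) * 2.0)))


def expected_short_long_ratio(cfg: SimulationConfig, theta: float, copy_numbers=None) -> float:
    """Expected (1-150 bp)/(151-500 bp) count ratio at tumor fraction theta.

    Computed on the mixture's exact pmf (no sampling, no mode jitter);
    strictly increasing in theta because the tumor component is shorter.
    """
    if copy_numbers is None:
        copy_numbers = np.full(20, 2.0)
    w = expected_tumor_fragment_weight(theta, copy_numbers)
    pmf = (1 - w) * cfg.fraglen_normal_params.pmf() + w * cfg.fraglen_tumor_params.pmf()
    short = pmf[1:151].sum()
    long_ = pmf[151:501].sum()
    return float(short / long_)


def _segment_copy_numbers(genome: GenomeDef, cna_profile: dict[str, float]) -> np.ndarray:
    out = np.array([cna_profile.get(s, 2.0) for s in genome.segment_ids], dtype=float)
    if (out < 0).any():
        raise ConfigurationError("copy numbers must be non-negative")
    return out


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with variance = dispersion * mean."""
    mean = np.maximum(mean, 1e-9)
    if dispersion <= 1.0:
        return rng.poisson(mean)
    r = mean / (dispersion - 1.0)  # var = mean + mean^2/r = dispersion*mean
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _simulate_coverage(
    cfg: SimulationConfig, genome: GenomeDef, theta: float, seg_cn: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    seg_idx = genome.segment_index()
    mix = ((1 - theta) * 2.0 + theta * seg_cn[seg_idx]) / 2.0
    gc_factor = 1.0 + cfg.gc_bias_slope * (genome.gc - 0.40)
    # per-sample biological coverage variability, correlated within segments
    seg_noise = np.exp(rng.normal(0.0, cfg.segment_noise_sd, size=genome.n_segments))
    weights = genome.bin_lengths * gc_factor * mix * seg_noise[seg_idx]
    mean = cfg.n_reads_swgs * weights / weights.sum()
    return _nb_draw(rng, mean, cfg.nb_dispersion)


def _simulate_fragments(
    cfg: SimulationConfig, theta: float, seg_cn: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    w_tumor = expected_tumor_fragment_weight(theta, seg_cn)
    jitter = rng.normal(0.0, cfg.fraglen_mode_jitter_sd)
    normal = replace(cfg.fraglen_normal_params, mode=cfg.fraglen_normal_params.mode + jitter)
    tumor = replace(cfg.fraglen_tumor_params, mode=cfg.fraglen_tumor_params.mode + jitter)
    pmf = (1 - w_tumor) * normal.pmf() + w_tumor * tumor.pmf()
    return rng.multinomial(cfg.n_fragments, pmf / pmf.sum())


def _draw_mutation_spec(
    rng: np.random.Generator, cfg: SimulationConfig, genome: GenomeDef, patient: str
) -> tuple[MutationSpec, ...]:
    n_mut = 1 + rng.poisson(max(cfg.mean_mutations - 1.0, 0.0))
    panel_negative = rng.random() < cfg.panel_negative_prob
    bases = np.array(list("ACGT"))
    specs = []
    bins = genome.bins
    for j in range(n_mut):
        clonal = rng.random() < 0.6
        ccf = rng.uniform(0.75, 1.0) if clonal else rng.uniform(0.2, 0.75)
        row = bins.iloc[int(rng.integers(genome.n_bins))]
        ref, alt = rng.choice(bases, size=2, replace=False)
        specs.append(
            MutationSpec(
                locus_id=f"{patient}_m{j}",
                ccf=float(ccf),
                multiplicity=1,
                hotspot=bool(rng.random() < 0.25),
                in_panel=False if panel_negative else bool(rng.random() < 0.4),
                in_targeted=not panel_negative,
                segment_id=str(row["segment_id"]),
                chrom=str(row["chrom"]),
                pos=int(row["start"] + rng.integers(row["end"] - row["start"])),
                ref=str(ref),
                alt=str(alt),
            )
        )
    return tuple(specs)


def _mutation_table(
    cfg: SimulationConfig,
    genome: GenomeDef,
    theta: float,
    spec: tuple[MutationSpec, ...],
    seg_cn: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    seg_order = {s: i for i, s in enumerate(genome.segment_ids)}
    rows = []
    for m in spec:
        c = seg_cn[seg_order[m.segment_id]] if m.segment_id in seg_order else 2.0
        ev = expected_vaf(theta, m.ccf, m.multiplicity, c)
        tumor_vaf = min(1.0, m.ccf * m.multiplicity / max(c, 1e-9))
        p_targeted = min(1.0, ev + cfg.error_targeted)
        p_ultra = min(1.0, ev + cfg.error_ultradeep)
        alt_t = int(rng.binomial(cfg.depth_plasma_targeted, p_targeted))
        alt_u = int(rng.binomial(cfg.depth_ultradeep, p_ultra))
        alt_tumor = int(rng.binomial(cfg.depth_tumor, min(1.0, tumor_vaf + cfg.error_targeted)))
        rows.append(
            {
                "locus": m.locus_id,
                "chrom": m.chrom,
                "pos": m.pos,
                "ref": m.ref,
                "alt": m.alt,
                "segment_id": m.segment_id,
                "ccf": m.ccf,
                "multiplicity": m.multiplicity,
                "hotspot": m.hotspot,
                "in_panel": m.in_panel,
                "in_targeted": m.in_targeted,
                "copy_number": c,
                "expected_vaf": ev,
                "tumor_vaf_truth": tumor_vaf,
                "alt_targeted": alt_t,
                "depth_targeted": cfg.depth_plasma_targeted,
                "alt_ultradeep": alt_u,
                "depth_ultradeep": cfg.depth_ultradeep,
                "alt_tumor": alt_tumor,
                "depth_tumor": cfg.depth_tumor,
            }
        )
    return pd.DataFrame(rows)


def simulate_healthy_panel(cfg: SimulationConfig, genome: GenomeDef) -> list[SimulatedSample]:
    """Healthy-donor panel: theta = 0, no mutations, normal fragment law.

    Requires >= 4 donors so leave-one-out panel statistics remain defined.
    """
    if cfg.n_healthy < 4:
        raise ConfigurationError("n_healthy must be >= 4 for leave-one-out panel statistics")
    diploid = np.full(genome.n_segments, 2.0)
    samples = []
    for i in range(cfg.n_healthy):
        sid = f"healthy{i:03d}"
        rng = sample_rng(cfg.seed, sid)
        samples.append(
            SimulatedSample(
                sample_id=sid,
                role="healthy",
                theta=0.0,
                bin_counts=_simulate_coverage(cfg, genome, 0.0, diploid, rng),
                fragment_length_counts=_simulate_fragments(cfg, 0.0, diploid, rng),
                mutations=None,
                truth={"theta": 0.0},
            )
        )
    return samples


def simulate_patient(
    cfg: SimulationConfig,
    genome: GenomeDef,
    theta: float,
    sample_id: str = "patient000",
    cna_profile: dict[str, float] | None = None,
    mutation_spec: tuple[MutationSpec, ...] | None = None,
) -> SimulatedSample:
    """One patient plasma sample at tumor fraction theta."""
    if not 0 <= theta <= 1:
        raise DomainError(f"theta {theta} outside [0, 1]")
    profile = cna_profile if cna_profile is not None else (cfg.cna_profile or default_cna_profile(genome.n_segments))
    seg_cn = _segment_copy_numbers(genome, profile)
    rng = sample_rng(cfg.seed, sample_id)
    spec = mutation_spec if mutation_spec is not None else (
        cfg.mutation_spec or _draw_mutation_spec(rng, cfg, genome, sample_id)
    )
    muts = _mutation_table(cfg, genome, theta, spec, seg_cn, rng)
    return SimulatedSample(
        sample_id=sample_id,
        role="patient",
        theta=theta,
        bin_counts=_simulate_coverage(cfg, genome, theta, seg_cn, rng),
        fragment_length_counts=_simulate_fragments(cfg, theta, seg_cn, rng),
        mutations=muts,
        truth={
            "theta": theta,
            "cna_profile": dict(profile),
            "expected_vafs": dict(zip(muts["locus"], muts["expected_vaf"])) if len(muts) else {},
        },
    )


@dataclass
class Cohort:
    """Full synthetic study: healthy panel, patients, and the truth table."""

    healthy: list[SimulatedSample]
    patients: list[SimulatedSample]
    truth: pd.DataFrame = field(repr=False)

    @property
    def all_samples(self) -> list[SimulatedSample]:
        return self.healthy + self.patients


def _draw_thetas(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.theta_grid is not None:
        reps = int(np.ceil(cfg.n_patients / len(cfg.theta_grid)))
        return np.tile(np.asarray(cfg.theta_grid, float), reps)[: cfg.n_patients]
    lo, hi = cfg.theta_range
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_patients))


def simulate_cohort(cfg: SimulationConfig, genome: GenomeDef | None = None) -> Cohort:
    """Simulate the healthy panel plus ``n_patients`` patient samples.

    Patient thetas follow ``theta_grid`` if given, otherwise the default
    log-uniform law on ``theta_range``. A ``cn_attenuated_prob`` fraction of
    patients carry a copy-number-quiet tumor: their CNA deviations from
    diploid are scaled by a uniform factor in [0, 0.4], emulating tumors
    whose fraction cannot be read from coverage alone. Each patient's
    mutation complement is drawn independently; a ``tumor_available_prob``
    fraction have matched tumor sequencing (enabling genotyping mode and
    concordance analysis).
    """
    genome = genome or GenomeDef.toy()
    cohort_rng = sample_rng(cfg.seed, "__cohort__")
    healthy = simulate_healthy_panel(cfg, genome) if cfg.n_healthy else []
    base_profile = cfg.cna_profile or default_cna_profile(genome.n_segments)
    thetas = _draw_thetas(cfg, cohort_rng)
    patients = []
    truth_rows = []
    for i in range(cfg.n_patients):
        sid = f"patient{i:03d}"
        attenuated = cohort_rng.random() < cfg.cn_attenuated_prob
        scale = float(cohort_rng.uniform(*cfg.cn_attenuation_range)) if attenuated else 1.0
        profile = {s: 2.0 + scale * (c - 2.0) for s, c in base_profile.items()}
        tumor_available = cohort_rng.random() < cfg.tumor_available_prob
        s = simulate_patient(cfg, genome, float(thetas[i]), sid, cna_profile=profile)
        s.truth["cn_scale"] = scale
        s.truth["tumor_available"] = tumor_available
        patients.append(s)
        truth_rows.append(
            {
                "sample": sid,
                "theta": float(thetas[i]),
                "cn_scale": scale,
                "tumor_available": tumor_available,
                "n_mutations": 0 if s.mutations is None else len(s.mutations),
            }
        )
    healthy_rows = [
        {"sample": h.sample_id, "theta": 0.0, "cn_scale": 0.0, "tumor_available": False, "n_mutations": 0}
        for h in healthy
    ]
    truth = pd.DataFrame(healthy_rows + truth_rows)
    return Cohort(healthy=healthy, patients=patients, truth=truth)
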