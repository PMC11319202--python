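"""Synthetic cohorts: genotypes, latent factors, waveforms, labels.

The generator produces the statistical structure the encoding-GWAS
pipeline assumes: block-LD genotypes in Hardy–Weinberg proportions,
additively heritable latent factors, spirogram / PPG waveforms that are
smooth monotone functions of those factors, genotype-independent
covariates, and binary disease labels driven by the factors through a
logistic model.  Every draw is a pure function of the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .core import GenotypePanel, WaveformRecord

__all__ = [
    "SimConfig",
    "SpiroParams",
    "PPGParams",
    "SyntheticCohort",
    "simulate_genotypes",
    "simulate_cohort",
    "spirogram_from_params",
    "ppg_from_params",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Cohort-level simulation settings.

    ``heritability_per_factor`` is the fraction of each latent factor's
    variance explained by its causal dosages; ``ld_rho`` is the target
    pairwise *dosage* correlation within an LD block.  ``disease_weights``
    are logistic coefficients on the (standardized) latent factors and
    ``disease_intercept`` sets the baseline prevalence.
    """

    n_individuals: int = 1000
    n_variants: int = 500
    maf_range: tuple = (0.05, 0.45)
    ld_block_size: int = 10
    ld_rho: float = 0.0
    n_latent_factors: int = 2
    causal_per_factor: int = 20
    heritability_per_factor: float = 0.3
    disease_weights: Sequence[float] = field(default_factory=lambda: (1.0, -0.7))
    disease_intercept: float = -2.0
    noise_sd: float = 0.05
    corrupt_fraction: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals <= 0 or self.n_variants <= 0:
            raise ValueError("n_individuals and n_variants must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.ld_block_size <= 0:
            raise ValueError("ld_block_size must be positive")
        if not (0.0 <= self.heritability_per_factor <= 1.0):
            raise ValueError("heritability must lie in [0, 1]")
        if self.causal_per_factor > self.n_variants:
            raise ValueError("causal_per_factor exceeds n_variants")
        if self.n_latent_factors <= 0:
            raise ValueError("need at least one latent factor")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0.0 <= self.corrupt_fraction < 1.0):
            raise ValueError("corrupt_fraction must lie in [0, 1)")
        if len(tuple(self.disease_weights)) != self.n_latent_factors:
            raise ValueError("disease_weights length must equal n_latent_factors")


@dataclass
class SpiroParams:
    """Parameters of one synthetic forced-expiration curve.

    The blow is rendered as a smooth sinusoidal rise to peak flow ``pef``
    at ``rise_time`` followed by a stretched-exponential decay whose
    exponent ``decay_shape`` controls late-curve concavity ("coving").
    The decay timescale is solved so the integrated flow equals ``fvc``.
    """

    fvc: float = 4.0
    pef: float = 8.0
    rise_time: float = 0.12
    decay_shape: float = 1.0
    effort_duration: float = 10.0

    def validate(self) -> None:
        if self.fvc <= 0 or self.pef <= 0:
            raise ValueError("fvc and pef must be positive")
        if self.rise_time <= 0 or self.effort_duration <= 0:
            raise ValueError("rise_time and effort_duration must be positive")
        if self.decay_shape < 0.3:
            raise ValueError("decay_shape too small for a stable render")
        if self.pef * self.rise_time / 2.0 >= self.fvc:
            raise ValueError("rise phase alone exceeds fvc; lower pef or rise_time")


@dataclass
class PPGParams:
    """Parameters of one synthetic 100-point PPG pulse.

    The pulse is a systolic Gaussian bump plus a dicrotic component; when
    ``notch_depth`` > 0 a narrow dip between the two creates the dicrotic
    notch, otherwise the dicrotic component is rescaled into a shoulder so
    the pulse stays unimodal.
    """

    systolic_amp: float = 1.0
    systolic_pos: float = 0.2
    dicrotic_amp: float = 0.45
    dicrotic_pos: float = 0.6
    notch_depth: float = 0.12
    systolic_width: float = 7.0
    dicrotic_width: float = 9.0
    notch_width: float = 3.5
    n_points: int = 100

    def validate(self) -> None:
        if not (0.0 < self.systolic_pos < self.dicrotic_pos < 1.0):
            raise ValueError("need 0 < systolic_pos < dicrotic_pos < 1")
        if self.systolic_amp <= 0:
            raise ValueError("systolic_amp must be positive")
        if self.notch_depth < 0:
            raise ValueError("notch_depth must be nonnegative")
        if min(self.systolic_width, self.dicrotic_width, self.notch_width) <= 0:
            raise ValueError("widths must be positive")


# --------------------------------------------------------------------------
# genotypes: Gaussian copula with calibrated block correlation
# --------------------------------------------------------------------------

def _dosage_thresholds(p: float) -> tuple:
    """Standard-normal cut points: dosage = 1{Z > t0} + 1{Z > t1}."""
    q0 = (1.0 - p) ** 2  # P(X = 0) under HWE
    q1 = q0 + 2.0 * p * (1.0 - p)  # P(X <= 1)
    return special.ndtri(q0), special.ndtri(q1)


def _dosage_from_normal(z: np.ndarray, p: float) -> np.ndarray:
    """Quantile-map standard normals to Binomial(2, p) dosages (exact HWE margins)."""
    t0, t1 = _dosage_thresholds(p)
    return (z > t0).astype(float) + (z > t1).astype(float)


def _copula_dosage_corr(rho: float, p: float) -> float:
    """Pearson correlation of two quantile-mapped dosages at latent corr ``rho``.

    Exact via bivariate-normal quadrant probabilities: since the dosage is
    a sum of two threshold indicators, E[X1 X2] is a sum of four upper
    quadrant probabilities.  Thresholding attenuates the latent
    correlation, so the generator inverts this map to hit a requested
    dosage correlation.
    """
    t0, t1 = _dosage_thresholds(p)
    bvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    e12 = 0.0
    for s in (t0, t1):
        for t in (t0, t1):
            # P(Z1 > s, Z2 > t) by inclusion-exclusion on the lower CDF
            e12 += 1.0 - special.ndtr(s) - special.ndtr(t) + float(bvn.cdf([s, t]))
    mean = 2.0 * p
    var = 2.0 * p * (1.0 - p)
    return (e12 - mean * mean) / var


def _latent_rho_for_target(target: float, p: float) -> float:
    """Latent Gaussian correlation producing dosage correlation ``target``."""
    if target <= 0.0:
        return 0.0
    hi = 0.999
    attainable = _copula_dosage_corr(hi, p)
    if target >= attainable:
        return hi
    return float(
        optimize.brentq(lambda r: _copula_dosage_corr(r, p) - target, 0.0, hi, xtol=1e-4)
    )


def simulate_genotypes(config: SimConfig) -> GenotypePanel:
    """Draw an n x M dosage panel with block-diagonal LD.

    Variants are grouped into blocks of ``ld_block_size``; within a block
    the dosage correlation is calibrated to ``ld_rho`` through an
    equicorrelated Gaussian copula.  Margins are Binomial(2, MAF), i.e.
    exact Hardy–Weinberg proportions.  Blocks are laid on chromosomes
    1..22 with 20-kb spacing between adjacent variants.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_variants
    lo, hi = config.maf_range
    # variants in strong LD carry near-identical allele frequencies, so
    # MAFs are drawn per block with a small within-block jitter
    n_blocks_maf = math.ceil(m / config.ld_block_size)
    block_maf = rng.uniform(lo, hi, size=n_blocks_maf)
    jitter = rng.uniform(-0.02, 0.02, size=m) if hi > lo else np.zeros(m)
    mafs = np.clip(
        np.repeat(block_maf, config.ld_block_size)[:m] + jitter, lo, hi
    )

    dosages = np.empty((n, m), dtype=float)
    n_blocks = math.ceil(m / config.ld_block_size)
    for b in range(n_blocks):
        j0 = b * config.ld_block_size
        j1 = min(m, j0 + config.ld_block_size)
        width = j1 - j0
        if config.ld_rho > 0.0 and width > 1:
            rho_lat = _latent_rho_for_target(config.ld_rho, float(np.mean(mafs[j0:j1])))
            shared = rng.standard_normal((n, 1))
            own = rng.standard_normal((n, width))
            z = math.sqrt(rho_lat) * shared + math.sqrt(1.0 - rho_lat) * own
        else:
            z = rng.standard_normal((n, width))
        for k in range(width):
            dosages[:, j0 + k] = _dosage_from_normal(z[:, k], mafs[j0 + k])

    block_of = np.arange(m) // config.ld_block_size
    n_chrom = min(22, n_blocks)
    chrom_of_block = (block_of[:: config.ld_block_size] * n_chrom // n_blocks) + 1
    chromosome = np.empty(m, dtype=int)
    position = np.empty(m, dtype=int)
    offset = {}
    for j in range(m):
        c = int(chrom_of_block[block_of[j]])
        chromosome[j] = c
        offset[c] = offset.get(c, 0) + 1
        position[j] = 1_000_000 + 20_000 * offset[c]

    variants = pd.DataFrame(
        {
            "chromosome": chromosome,
            "position": position,
            "id": [f"var_{j}" for j in range(m)],
            "ref": "A",
            "alt": "G",
            "frequency": dosages.mean(axis=0) / 2.0,
            "info": 1.0,
            "missing_rate": 0.0,
        }
    )
    ids = [f"ind_{i}" for i in range(n)]
    return GenotypePanel(dosages=dosages, variants=variants, sample_ids=ids)


# --------------------------------------------------------------------------
# waveform rendering
# --------------------------------------------------------------------------

def _spiro_flow_curves(
    fvc: np.ndarray,
    pef: np.ndarray,
    rise_time: np.ndarray,
    decay_shape: np.ndarray,
    effort_duration: np.ndarray,
    n_points: int,
    dt: float,
) -> np.ndarray:
    """Vectorized flow–time rendering; shapes broadcast over individuals."""
    t = np.arange(n_points) * dt
    fvc, pef, tr, s, eff = np.broadcast_arrays(
        np.atleast_1d(fvc)[:, None],
        np.atleast_1d(pef)[:, None],
        np.atleast_1d(rise_time)[:, None],
        np.atleast_1d(decay_shape)[:, None],
        np.atleast_1d(effort_duration)[:, None],
    )
    rise_area = pef * tr / 2.0
    tau = (fvc - rise_area) / (pef * special.gamma(1.0 + 1.0 / s))
    tau = np.maximum(tau, 1e-3)
    rise = pef * np.sin(np.pi * t / (2.0 * tr)) ** 2
    decay = pef * np.exp(-(np.maximum(t - tr, 0.0) / tau) ** s)
    flow = np.where(t < tr, rise, decay)
    flow = np.where(t <= eff, flow, 0.0)
    return flow


def spirogram_from_params(
    p: SpiroParams, n_points: int = 1000, dt: float = 0.01
) -> WaveformRecord:
    """Render a volume–time curve (liters) from blow parameters.

    Volume starts at 0, is nondecreasing and asymptotes to ``fvc``;
    the derived flow peaks near ``pef`` at ``rise_time`` and decays with
    exponent ``decay_shape``.  Deterministic.
    """
    p.validate()
    flow = _spiro_flow_curves(
        np.array([p.fvc]),
        np.array([p.pef]),
        np.array([p.rise_time]),
        np.array([p.decay_shape]),
        np.array([p.effort_duration]),
        n_points,
        dt,
    )[0]
    volume = np.concatenate([[0.0], np.cumsum(flow[:-1]) * dt])
    return WaveformRecord(
        individual_id="", channel="volume_time", values=volume, dt=dt, units="L"
    )


def _ppg_pulse(p: PPGParams) -> np.ndarray:
    n = p.n_points
    x = np.arange(n, dtype=float)
    p1 = p.systolic_pos * (n - 1)
    p2 = p.dicrotic_pos * (n - 1)
    sys = p.systolic_amp * np.exp(-((x - p1) ** 2) / (2.0 * p.systolic_width**2))
    dic = p.dicrotic_amp * np.exp(-((x - p2) ** 2) / (2.0 * p.dicrotic_width**2))
    if p.notch_depth > 0.0:
        pn = 0.5 * (p1 + p2)
        dip = p.notch_depth * np.exp(-((x - pn) ** 2) / (2.0 * p.notch_width**2))
        return sys + dic - dip
    # absent notch: rescale the dicrotic bump so the pulse stays unimodal
    # (nonincreasing after the systolic peak => shoulder, no secondary max)
    d_sys = np.diff(sys)
    d_dic = np.diff(dic)
    after = np.arange(n - 1) >= p1
    rising = after & (d_dic > 1e-12)
    if np.any(rising):
        alpha = float(np.min(-d_sys[rising] / d_dic[rising]))
        alpha = min(1.0, max(0.0, 0.98 * alpha))
    else:
        alpha = 1.0
    return sys + alpha * dic


def ppg_from_params(p: PPGParams) -> WaveformRecord:
    """Render a single 100-point pulse; notch present iff notch_depth > 0."""
    p.validate()
    return WaveformRecord(
        individual_id="", channel="ppg", values=_ppg_pulse(p), dt=None, units="L"
    )


# --------------------------------------------------------------------------
# cohort assembly
# --------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Everything one simulation run produced, aligned on individuals."""

    config: SimConfig
    genotypes: GenotypePanel
    factors: np.ndarray  # n x L, standardized
    causal_indices: List[np.ndarray]
    causal_betas: List[np.ndarray]
    spiro_params: pd.DataFrame
    ppg_params: pd.DataFrame
    spiro_volume: np.ndarray  # n x n_points, liters
    spiro_flow: np.ndarray  # n x n_points, L/s (noisy render)
    ppg_pulses: np.ndarray  # n x 100
    covariates: pd.DataFrame  # id, age, sex
    labels: pd.Series  # binary disease status
    corrupted: np.ndarray = None  # boolean per individual
    acceptability: np.ndarray = None  # boolean per individual
    wiggle: np.ndarray = None  # non-genetic effort-wobble amplitude
    spiro_dt: float = 0.01

    @property
    def sample_ids(self) -> List[str]:
        return list(self.genotypes.sample_ids)

    def volume_record(self, i: int) -> WaveformRecord:
        return WaveformRecord(
            individual_id=self.sample_ids[i],
            channel="volume_time",
            values=self.spiro_volume[i],
            dt=self.spiro_dt,
            acceptability=bool(self.acceptability[i]),
            units="L",
        )

    def flow_record(self, i: int) -> WaveformRecord:
        return WaveformRecord(
            individual_id=self.sample_ids[i],
            channel="flow_time",
            values=self.spiro_flow[i],
            acceptability=bool(self.acceptability[i]),
            dt=self.spiro_dt,
        )

    def ppg_record(self, i: int) -> WaveformRecord:
        return WaveformRecord(
            individual_id=self.sample_ids[i], channel="ppg", values=self.ppg_pulses[i]
        )


def _heritable_factors(
    config: SimConfig, panel: GenotypePanel, rng: np.random.Generator
) -> tuple:
    """Latent factors f = G beta + eps with empirical h2 equal to target."""
    n, m = panel.n, panel.M
    h2 = config.heritability_per_factor
    k = config.causal_per_factor
    all_idx = rng.permutation(m)
    factors = np.empty((n, config.n_latent_factors))
    causal_indices, causal_betas = [], []
    for ell in range(config.n_latent_factors):
        idx = np.sort(all_idx[ell * k : (ell + 1) * k]) if k > 0 else np.array([], int)
        if len(idx) < k:  # not enough disjoint variants left
            raise ValueError(
                f"factor {ell}: requested {k} causal variants but only "
                f"{len(idx)} remain"
            )
        beta = rng.standard_normal(k) if k else np.zeros(0)
        if h2 > 0.0:
            g_score = panel.dosages[:, idx] @ beta if k else np.zeros(n)
            var_g = float(np.var(g_score))
            if var_g <= 0.0:
                raise ValueError(
                    f"factor {ell}: heritability {h2} unreachable with "
                    f"{k} causal variants (zero genetic variance)"
                )
            noise_var = var_g * (1.0 - h2) / h2 if h2 < 1.0 else 0.0
            f = g_score - g_score.mean() + rng.normal(0.0, math.sqrt(noise_var), n)
        else:
            beta = np.zeros(k)
            f = rng.standard_normal(n)
        sd = f.std()
        factors[:, ell] = (f - f.mean()) / (sd if sd > 0 else 1.0)
        causal_indices.append(idx)
        causal_betas.append(beta)
    return factors, causal_indices, causal_betas


def _factor_pair(factors: np.ndarray) -> tuple:
    f1 = factors[:, 0]
    f2 = factors[:, 1] if factors.shape[1] > 1 else np.zeros_like(f1)
    return f1, f2


def _spiro_params_from_factors(f1: np.ndarray, f2: np.ndarray) -> pd.DataFrame:
    # monotone maps keeping every clean draw inside the QC gates; the
    # shape factor warps peak timing and late-curve concavity, so the
    # curve family is a genuinely nonlinear 2-parameter manifold
    return pd.DataFrame(
        {
            "fvc": 3.9 + 0.8 * np.tanh(0.9 * f1),
            "pef": 7.8 + 1.6 * np.tanh(0.9 * f1),
            "rise_time": 0.25 + 0.15 * np.tanh(f2),
            "decay_shape": np.exp(0.5 * np.tanh(f2)),
            "effort_duration": np.full_like(f1, 10.0),
        }
    )


def _ppg_params_from_factors(f1: np.ndarray, f2: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "systolic_amp": 1.0 + 0.15 * np.tanh(f1),
            "systolic_pos": 0.20 + 0.06 * np.tanh(f1),
            "dicrotic_amp": 0.42 + 0.10 * np.tanh(f2),
            "dicrotic_pos": 0.62 + 0.07 * np.tanh(f2),
            "notch_depth": 0.12 + 0.05 * np.tanh(f2),
            "systolic_width": np.full_like(f1, 7.0),
            "dicrotic_width": np.full_like(f1, 9.0),
            "notch_width": np.full_like(f1, 3.5),
        }
    )


def simulate_cohort(config: SimConfig, n_points: int = 1000, dt: float = 0.01) -> SyntheticCohort:
    """Full cohort draw: genotypes -> factors -> waveforms -> labels.

    Measurement noise of sd ``config.noise_sd`` (L/s) is added to the
    rendered flow and integrated into the volume trace, so the volume
    noise is a small random walk rather than white noise (finite
    differencing then recovers a realistically noisy flow).  PPG pulses
    receive white noise of sd ``noise_sd`` / 2 (arbitrary units).
    """
    config.validate()
    if config.causal_per_factor * config.n_latent_factors > config.n_variants:
        raise ValueError("causal sets must be disjoint: too few variants")
    panel = simulate_genotypes(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    factors, causal_indices, causal_betas = _heritable_factors(config, panel, rng)
    f1, f2 = _factor_pair(factors)

    spiro = _spiro_params_from_factors(f1, f2)
    flow = _spiro_flow_curves(
        spiro["fvc"].values,
        spiro["pef"].values,
        spiro["rise_time"].values,
        spiro["decay_shape"].values,
        spiro["effort_duration"].values,
        n_points,
        dt,
    )
    # idiosyncratic effort wobble: a zero-net-volume flow dipole shortly
    # after the peak, i.e. at mid exhaled volume, where the flow-volume
    # curve resolves it.  It leaves FVC (zero integral), PEF (smaller
    # than the peak margin) and FEV1 (both lobes complete before 1 s)
    # essentially untouched, so it is waveform variation the five expert
    # features cannot see — the residual signal a feature-injected
    # encoder is meant to capture.
    t_grid = np.arange(n_points) * dt
    base_volume = np.cumsum(flow, axis=1) * dt
    # anchor the dipole where the blow passes 55% of its final volume, so
    # it stays aligned in flow-volume space across individuals
    frac = base_volume / np.maximum(base_volume[:, -1:], 1e-9)
    t55 = t_grid[np.argmin(np.abs(frac - 0.55), axis=1)]
    # stay clear of the flow peak so PEF is untouched even for late risers
    tc = np.maximum(t55, spiro["rise_time"].values + 0.30)[:, None]
    width = 0.12
    xw = (t_grid[None, :] - tc) / width
    dipole = -xw * np.exp(0.5 - 0.5 * xw**2)
    wiggle = rng.standard_normal(config.n_individuals)
    flow = flow + 0.55 * wiggle[:, None] * dipole

    flow = flow + rng.normal(0.0, config.noise_sd, size=flow.shape)

    # a realistic fraction of blows is corrupted: rescaled effort, early
    # termination or a failed acceptability flag.  These occupy the
    # cohort-percentile tails, which is what the tail QC is for.
    n = config.n_individuals
    corrupted = np.zeros(n, dtype=bool)
    acceptability = np.ones(n, dtype=bool)
    n_corrupt = int(round(config.corrupt_fraction * n))
    if n_corrupt:
        bad = rng.choice(n, size=n_corrupt, replace=False)
        corrupted[bad] = True
        modes = rng.integers(0, 4, size=n_corrupt)
        for i, mode in zip(bad, modes):
            if mode == 0:  # weak effort: whole flow scaled down
                flow[i] *= rng.uniform(0.25, 0.45)
            elif mode == 1:  # overshoot artifact: scaled up
                flow[i] *= rng.uniform(1.3, 1.6)
            elif mode == 2:  # early termination
                cut = int(rng.uniform(0.15, 0.40) * n_points)
                flow[i, cut:] = 0.0
            else:  # device rejects the maneuver
                acceptability[i] = False

    volume = np.concatenate(
        [np.zeros((flow.shape[0], 1)), np.cumsum(flow[:, :-1], axis=1) * dt], axis=1
    )

    ppg = _ppg_params_from_factors(f1, f2)
    pulses = np.stack(
        [
            _ppg_pulse(PPGParams(**{k: float(v) for k, v in row.items()}))
            for _, row in ppg.iterrows()
        ]
    )
    pulses = pulses + rng.normal(0.0, config.noise_sd / 2.0, size=pulses.shape)

    age = rng.uniform(40.0, 70.0, size=config.n_individuals)
    sex = rng.integers(0, 2, size=config.n_individuals)
    covariates = pd.DataFrame(
        {"id": panel.sample_ids, "age": age, "sex": sex}
    ).set_index("id")

    w = np.asarray(tuple(config.disease_weights), dtype=float)
    logit = config.disease_intercept + factors @ w
    prob = special.expit(logit)
    labels = pd.Series(
        (rng.uniform(size=config.n_individuals) < prob).astype(int),
        index=panel.sample_ids,
        name="disease",
    )

    return SyntheticCohort(
        config=config,
        genotypes=panel,
        factors=factors,
        causal_indices=causal_indices,
        causal_betas=causal_betas,
        spiro_params=spiro,
        ppg_params=ppg,
        spiro_volume=volume,
        spiro_flow=flow,
        ppg_pulses=pulses,
        covariates=covariates,
        labels=labels,
        corrupted=corrupted,
        acceptability=acceptability,
        wiggle=wiggle,
        spiro_dt=dt,
    )


# --------------------------------------------------------------------------
# cohort writers (long-format curves + TSV tables)
# --------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write curves.csv (long), genotypes.tsv, labels.tsv, covariates.tsv."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    frames = []
    for name, mat in (
        ("volume_time", cohort.spiro_volume),
        ("flow_time", cohort.spiro_flow),
        ("ppg", cohort.ppg_pulses),
    ):
        n, L = mat.shape
        frames.append(
            pd.DataFrame(
                {
                    "id": np.repeat(cohort.sample_ids, L),
                    "channel": name,
                    "index": np.tile(np.arange(L), n),
                    "value": mat.ravel(),
                }
            )
        )
    curves = pd.concat(frames, ignore_index=True)
    paths["curves"] = os.path.join(outdir, "curves.csv")
    curves.to_csv(paths["curves"], index=False)

    geno = pd.DataFrame(
        cohort.genotypes.dosages,
        index=cohort.sample_ids,
        columns=cohort.genotypes.variants["id"],
    )
    paths["genotypes"] = os.path.join(outdir, "genotypes.tsv")
    geno.to_csv(paths["genotypes"], sep="\t")
    paths["variants"] = os.path.join(outdir, "variants.tsv")
    cohort.genotypes.variants.to_csv(paths["variants"], sep="\t", index=False)

    paths["labels"] = os.path.join(outdir, "labels.tsv")
    cohort.labels.to_frame().to_csv(paths["labels"], sep="\t")
    paths["covariates"] = os.path.join(outdir, "covariates.tsv")
    cohort.covariates.to_csv(paths["covariates"], sep="\t")
    return paths
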