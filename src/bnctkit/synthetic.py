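"""Seeded generators for every input the analysis pipeline consumes.

Each generator emulates the statistical structure of one measured data
stream — boron uptake time courses, per-cell comet %tail-DNA populations,
spheroid mask series with dose-dependent growth inhibition, two-population
flow-cytometry events, and linear ICP-MS calibration runs — anchored to the
published summary values in :mod:`bnctkit.anchors`.  Identical (seed,
parameters) give identical outputs.

Distribution choices (documented, not dictated by the data):

* uptake means follow a gamma-like pulse ``A * (t/tp) * exp(1 - t/tp)``
  peaking at ``tp`` = 4 h, with normal replicate noise scaled so the 4 h SD
  matches the anchor;
* per-cell %tail-DNA is Beta on [0, 100] with the anchor mean and a
  variance of ``n_cells * SE^2`` so the sample SE of the mean matches;
* spheroids are star-convex disks with fixed low-order harmonic boundary
  perturbations (so shape is constant over time and Feret ratios are exact)
  and exponential diameter growth damped by a dose- and boron-dependent
  inhibition factor;
* flow intensities are log-normal mixtures; ICP-MS intensities are linear
  with multiplicative noise under the natural-abundance standard
  convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import anchors
from .comet_stats import CometSample, ExperimentalGroup
from .errors import InputDomainError
from .flow_ki67 import FlowEventTable
from .icpms import CellPellet, IcpmsRun

__all__ = [
    "GeneratorConfig",
    "gen_uptake_timecourse",
    "gen_comet_population",
    "gen_spheroid_experiment",
    "SpheroidSeries",
    "gen_flow_events",
    "gen_icpms_run",
    "SyntheticIcpms",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Seed + profile + effect toggles shared by a simulated experiment."""

    seed: int
    cell_line_profile: str = "FM55p-3D"
    dose_response: bool = True
    freeze_thaw_shift: float = 0.0  # additive %tail-DNA baseline shift
    noise_scale: float = 1.0

    def __post_init__(self):
        if self.cell_line_profile not in anchors.PROFILES:
            raise InputDomainError(
                f"unknown profile {self.cell_line_profile!r}; "
                f"known: {sorted(anchors.PROFILES)}"
            )


# ---------------------------------------------------------------- uptake

def gen_uptake_timecourse(
    profile: str,
    seed: int,
    times_h: tuple = (2, 4, 6, 24),
    n_replicates: int = 3,
    noise_scale: float = 1.0,
    peak_time_h: float = 4.0,
) -> list[tuple[float, np.ndarray]]:
    """Replicate uptake triplets (ug 10B / 1e6 cells) per incubation time.

    The mean curve is a single-peak pulse through the profile's 4 h anchor;
    replicate noise is normal with the anchor's relative SD, clipped at 0.
    ``noise_scale=0`` gives the deterministic mean curve.
    """
    if profile not in anchors.UPTAKE_4H:
        raise InputDomainError(f"unknown profile {profile!r}")
    mean4, sd4 = anchors.UPTAKE_4H[profile]
    rng = np.random.default_rng(seed)
    out = []
    for t in times_h:
        m = mean4 * (t / peak_time_h) * math.exp(1 - t / peak_time_h)
        sd = sd4 * (m / mean4) * noise_scale
        vals = np.clip(rng.normal(m, sd, size=n_replicates), 0, None) if sd > 0 \
            else np.full(n_replicates, m)
        out.append((float(t), vals))
    return out


# ----------------------------------------------------------------- comet

def gen_comet_population(
    mean: float,
    se: float,
    n_cells: int = 150,
    replicates: int = 3,
    seed: int = 0,
    group: ExperimentalGroup = ExperimentalGroup.IR_B,
    time_h: float = 1.0,
    cell_line: str = "",
    dose_group: str = "none",
    baseline_shift: float = 0.0,
) -> list[CometSample]:
    """Per-cell %tail-DNA samples with a target mean and SE of the mean.

    Cells are Beta-distributed on [0, 100] with mean ``mean`` and per-cell
    variance ``n_cells * se**2``, so the SE of a sample mean of ``n_cells``
    cells equals ``se``.  ``baseline_shift`` models freeze-thaw damage as an
    additive offset.  Raises when the (mean, variance) pair is infeasible
    for a Beta distribution.
    """
    m = mean + baseline_shift
    if not 0 < m < 100:
        raise InputDomainError("mean %tail-DNA must be in (0, 100)")
    mu = m / 100.0
    var = n_cells * se**2 / 100.0**2
    if var <= 0:
        rng = np.random.default_rng(seed)
        return [
            CometSample(values=tuple(np.full(n_cells, m)), group=group,
                        time_h=time_h, cell_line=cell_line, dose_group=dose_group)
            for _ in range(replicates)
        ]
    if var >= mu * (1 - mu):
        raise InputDomainError(
            f"variance {var:.4g} infeasible for Beta with mean {mu:.4g}"
        )
    k = mu * (1 - mu) / var - 1
    a, b = mu * k, (1 - mu) * k
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(replicates):
        vals = np.clip(100 * rng.beta(a, b, size=n_cells), 0, 100)
        samples.append(
            CometSample(values=tuple(vals), group=group, time_h=time_h,
                        cell_line=cell_line, dose_group=dose_group)
        )
    return samples


# -------------------------------------------------------------- spheroid

@dataclass
class SpheroidSeries:
    """Mask series for one simulated spheroid with its ground truth."""

    spheroid_id: str
    times_h: tuple
    masks: list  # binary arrays, one per time
    pixel_size: float
    true_feret_um: tuple  # ground-truth max caliper per time
    target_circularity: float
    growth_rate_per_day: float
    meta: dict = field(default_factory=dict)


def _inhibition(dose_gy: float, boron: bool) -> float:
    """Growth-rate inhibition fraction in [0, 1)."""
    if dose_gy <= 0:
        return 0.0
    strength = 0.9 if boron else 0.15
    return strength * (1 - math.exp(-dose_gy / 2.5))


def _radial_profile(rng: np.random.Generator, target_circ: float):
    """Harmonic boundary perturbation hitting an analytic circularity target.

    For r(theta) = R(1 + sum eps_k cos(k theta + phi_k)) the first-order
    circularity deficit is sum eps_k^2 (k^2 - 1) / 2; amplitudes are drawn
    randomly and rescaled to match 1 - target_circ.
    """
    ks = np.array([3, 4, 5, 6, 8])
    w = rng.uniform(0.2, 1.0, size=ks.size)
    deficit = 1.0 - target_circ
    scale2 = deficit / np.sum(w**2 * (ks**2 - 1) / 2)
    eps = w * math.sqrt(scale2)
    phi = rng.uniform(0, 2 * math.pi, size=ks.size)
    return ks, eps, phi


def _rasterize(radius_px: float, ks, eps, phi) -> np.ndarray:
    rmax = radius_px * (1 + float(np.sum(eps)))
    n = 2 * int(math.ceil(rmax)) + 9
    c = n / 2.0 - 0.5
    yy, xx = np.mgrid[0:n, 0:n]
    dy, dx = yy - c, xx - c
    rr = np.hypot(dy, dx)
    th = np.arctan2(dy, dx)
    bound = radius_px * (1 + sum(e * np.cos(k * th + p)
                                 for k, e, p in zip(ks, eps, phi)))
    return rr <= bound


def _true_feret_px(radius_px: float, ks, eps, phi) -> float:
    th = np.linspace(0, math.pi, 4096, endpoint=False)

    def r(t):
        return radius_px * (1 + sum(e * np.cos(k * t + p)
                                    for k, e, p in zip(ks, eps, phi)))

    return float(np.max(r(th) + r(th + math.pi)))


def gen_spheroid_experiment(
    dose_gy: float,
    boron: bool,
    seed: int,
    n_spheroids: int = 3,
    times_h: tuple = (0, 1, 24, 48),
    start_diameter_um: float = 400.0,
    pixel_size: float = 2.0,
    growth_rate_per_day: float = 0.10,
    diameter_cv: float = 0.05,
) -> list[SpheroidSeries]:
    """Mask series for a spheroid group under a given dose / boron status.

    Baseline growth is exponential in time (``growth_rate_per_day`` is the
    fractional diameter increase per 24 h), damped by a dose- and
    boron-dependent inhibition factor.  Irradiated series draw their target
    circularity in the published irradiated band, controls in the control
    band; the boundary harmonics are frozen per spheroid so normalized
    Feret ratios are exact.
    """
    if dose_gy < 0:
        raise InputDomainError("dose cannot be negative")
    rng = np.random.default_rng(seed)
    irradiated = dose_gy > 0
    lo, hi = (anchors.CIRCULARITY_IRRADIATED if irradiated
              else anchors.CIRCULARITY_CONTROL)
    g = growth_rate_per_day * (1 - _inhibition(dose_gy, boron))
    series = []
    for i in range(n_spheroids):
        target_circ = float(rng.uniform(lo, hi))
        ks, eps, phi = _radial_profile(rng, target_circ)
        d0 = start_diameter_um * float(rng.normal(1.0, diameter_cv))
        masks, ferets = [], []
        for t in times_h:
            d = d0 * math.exp(g * t / 24.0)
            r_px = d / 2.0 / pixel_size
            masks.append(_rasterize(r_px, ks, eps, phi))
            ferets.append(_true_feret_px(r_px, ks, eps, phi) * pixel_size)
        series.append(
            SpheroidSeries(
                spheroid_id=f"sph{i}",
                times_h=tuple(float(t) for t in times_h),
                masks=masks,
                pixel_size=pixel_size,
                true_feret_um=tuple(ferets),
                target_circularity=target_circ,
                growth_rate_per_day=g,
                meta={"dose_gy": dose_gy, "boron": boron, "seed": seed},
            )
        )
    return series


# ------------------------------------------------------------------ flow

def gen_flow_events(
    pos_fraction: float,
    separation: float = 2.0,
    n_events: int = 10_000,
    seed: int = 0,
    log_sigma: float = 0.4,
    negative_median: float = 100.0,
    **labels,
) -> FlowEventTable:
    """Two log-normal Ki67 populations mixed at ``pos_fraction``.

    ``separation`` is the distance between the population medians in
    natural-log intensity units; the PI channel is a single log-normal
    population (all events non-debris).
    """
    if not 0 <= pos_fraction <= 1:
        raise InputDomainError("positive fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_pos = int(round(pos_fraction * n_events))
    mu_neg = math.log(negative_median)
    neg = rng.lognormal(mu_neg, log_sigma, size=n_events - n_pos)
    pos = rng.lognormal(mu_neg + separation, log_sigma, size=n_pos)
    c3 = rng.permutation(np.concatenate([neg, pos]))
    c6 = rng.lognormal(math.log(50.0), 0.3, size=n_events)
    return FlowEventTable(c3_ki67=c3, c6_pi=c6, **labels)


# ----------------------------------------------------------------- icpms

@dataclass
class SyntheticIcpms:
    run: IcpmsRun
    pellet: CellPellet
    digest_volume_l: float
    true_ppm: float


def gen_icpms_run(
    true_ppm: float,
    seed: int = 0,
    noise: float = 0.02,
    pellet_mass_g: float = 0.050,
    cell_count: float = 2.0e6,
    digest_volume_l: float = 0.001,
    dilution_factor: float = 10.0,
    f10: float = 0.199,
    sensitivity: float = 120.0,  # counts/s per ug 10B / L
    blank: float = 50.0,  # counts/s
    standard_concs: tuple = (5.0, 10.0, 20.0, 50.0, 100.0),  # ug total B / L
) -> SyntheticIcpms:
    """One synthetic ICP-MS measurement of a monoisotopic 10B sample.

    Calibration standards have natural isotopic abundance, so their 10B
    signal is ``sensitivity * f10 * conc_totalB``; the sample signal is
    ``sensitivity * conc_10B`` plus blank.  Standard-point intensities are
    blank-subtracted (intercept ~ 0), as exported by the instrument
    software.  Multiplicative noise of relative size ``noise`` on every
    intensity; ``noise=0`` makes the round trip exact.
    """
    if true_ppm < 0:
        raise InputDomainError("true concentration cannot be negative")
    rng = np.random.default_rng(seed)

    def jitter(x):
        return x * (1 + noise * rng.standard_normal()) if noise > 0 else x

    points = tuple(
        (c, jitter(sensitivity * f10 * c)) for c in standard_concs
    )
    digest_conc = true_ppm * pellet_mass_g / digest_volume_l  # ug 10B / L
    measured_conc = digest_conc / dilution_factor
    sample_intensity = blank + jitter(sensitivity * measured_conc)
    qc_nominal = 10.0  # mg/L total B
    qc_intensity = jitter(sensitivity * f10 * qc_nominal * 1000.0)
    qc_measured = qc_intensity / (sensitivity * f10) / 1000.0  # back to mg/L
    run = IcpmsRun(
        sample_intensity=float(sample_intensity),
        blank_intensity=blank,
        standard_points=points,
        dilution_factor=dilution_factor,
        qc_nominal=qc_nominal,
        qc_measured=float(qc_measured),
    )
    pellet = CellPellet(mass=pellet_mass_g, cell_count=cell_count)
    return SyntheticIcpms(run=run, pellet=pellet,
                          digest_volume_l=digest_volume_l, true_ppm=true_ppm)
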