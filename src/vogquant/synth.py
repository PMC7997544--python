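"""Synthetic virus-on-glass fields, flow-cytometry events, and luciferase plates.

The generator emulates the statistical structure of a virus-on-glass (VOG)
preparation: mature HIV-1 virions spun onto a coverslip form a thin layer of
diffraction-limited point emitters at sub-confluent density.  Each particle
carries a construct-dependent number of fluorescently labeled integrase (IN)
molecules:

* ``gag_anchored`` — IN fused to a codon-optimized Gag supplied in trans;
  one label per packaged Gag from the labeled construct, so copy numbers
  follow the Gag stoichiometry (mean ~2000, i.e. >1500 copies per virion).
* ``pol_anchored`` — IN labeled within Gag-Pol, packaged at the natural
  Pol:Gag ratio of 1:20, so roughly 5% as many labels per particle.
* ``vpr_anchored`` — Vpr-mediated incorporation, capped at a few hundred
  copies per virion.
* ``none`` — unlabeled in that channel.

In trans configurations a particle carries a construct's label only with
probability ``incorporation_prob``; in cis (packaging-vector) systems every
particle is labeled (``incorporation_prob = 1``).

A mature-capsid immunostain channel (anti-CA antibody, far-red secondary)
marks the ``mature`` subset of particles and serves downstream as the
reference point set for colocalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ImageField
from .optics import _pixel_integrated_gaussian, theoretical_psf

__all__ = [
    "ConstructModel",
    "FieldParams",
    "RLUCondition",
    "assign_labels",
    "simulate_field",
    "simulate_flow_events",
    "simulate_rlu_table",
    "EMISSION_UM",
]

# default emission wavelengths (um) by channel role
EMISSION_UM = {"green": 0.52, "red": 0.60, "farred": 0.67}

_LABEL_MODES = ("gag_anchored", "pol_anchored", "vpr_anchored", "none")


@dataclass(frozen=True)
class ConstructModel:
    """Labeling construct: how many labeled-IN copies a particle carries.

    gag_copy_mean/gag_copy_cv set the log-normal Gag packaging law;
    pol_anchored copies are ``round(gag_copies * pol_to_gag_ratio)``;
    vpr_anchored copies follow their own log-normal with mean
    ``vpr_copy_mean``.  ``photons_per_copy`` is the per-channel gain
    converting labeled copies to expected integrated photons.
    """

    name: str
    channel: str
    in_label_mode: str = "gag_anchored"
    gag_copy_mean: float = 2000.0
    gag_copy_cv: float = 0.25
    pol_to_gag_ratio: float = 1.0 / 20.0
    vpr_copy_mean: float = 700.0
    incorporation_prob: float = 1.0
    photons_per_copy: float = 2.0
    emission_wavelength_um: float | None = None

    def __post_init__(self) -> None:
        if self.in_label_mode not in _LABEL_MODES:
            raise ValueError(f"in_label_mode must be one of {_LABEL_MODES}")
        if self.gag_copy_mean <= 0:
            raise ValueError("gag_copy_mean must be > 0")
        if not 0.0 <= self.incorporation_prob <= 1.0:
            raise ValueError("incorporation_prob must lie in [0, 1]")
        if not 0.0 < self.pol_to_gag_ratio <= 1.0:
            raise ValueError("pol_to_gag_ratio must lie in (0, 1]")

    @property
    def emission_um(self) -> float:
        if self.emission_wavelength_um is not None:
            return self.emission_wavelength_um
        return EMISSION_UM.get(self.channel, 0.58)


@dataclass(frozen=True)
class FieldParams:
    """Imaging geometry, noise, and reference-stain parameters of one field.

    Defaults model a 60x widefield system with 6.5 um camera pixels
    (0.108 um/px), NA 1.4 oil immersion, and a thin particle layer at the
    coverslip.  ``particle_density`` is in particles per square micrometre.
    """

    width_px: int = 512
    height_px: int = 512
    n_z: int = 5
    pixel_size_um: float = 0.108
    z_step_um: float = 0.25
    particle_density: float = 0.02
    background_level: float = 10.0
    read_noise_sd: float = 2.0
    numerical_aperture: float = 1.4
    refractive_index: float = 1.515
    mature_fraction: float = 0.9
    reference_channel: str = "farred"
    reference_photons_mean: float = 3000.0
    reference_photons_cv: float = 0.3
    z_layer_sd_um: float = 0.1
    max_particles: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("voxel pitch must be positive")
        if min(self.width_px, self.height_px, self.n_z) < 1:
            raise ValueError("all dimensions must be >= 1")
        if self.particle_density < 0:
            raise ValueError("particle_density must be >= 0")

    @property
    def area_um2(self) -> float:
        return self.width_px * self.height_px * self.pixel_size_um**2


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    """Log-normal samples with the given arithmetic mean and CV."""
    if cv <= 0:
        return np.full(size, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def assign_labels(
    n_particles: int,
    constructs: list[ConstructModel],
    seed: int | np.random.Generator = 0,
    dual_label_fraction: float | None = None,
) -> pd.DataFrame:
    """Draw per-particle labeled-IN copy counts for each construct's channel.

    Each construct labels a particle independently with its
    ``incorporation_prob`` (trans complementation); passing
    ``dual_label_fraction`` instead makes labeling jointly all-or-none with
    that probability, which models a preparation where the labeled constructs
    co-segregate.

    Returns a DataFrame with ``particle_id`` plus one ``copies_<channel>``
    column per construct.
    """
    if n_particles < 0:
        raise ValueError("n_particles must be >= 0")
    channels = [c.channel for c in constructs]
    if len(set(channels)) != len(channels):
        raise ValueError("constructs must reference distinct channels")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    out = {"particle_id": np.arange(n_particles)}
    joint = None
    if dual_label_fraction is not None:
        joint = rng.random(n_particles) < dual_label_fraction
    for c in constructs:
        if c.in_label_mode == "none":
            copies = np.zeros(n_particles)
        else:
            gag = _lognormal(rng, c.gag_copy_mean, c.gag_copy_cv, n_particles)
            if c.in_label_mode == "gag_anchored":
                copies = np.round(gag)
            elif c.in_label_mode == "pol_anchored":
                copies = np.round(gag * c.pol_to_gag_ratio)
            else:  # vpr_anchored
                copies = np.round(_lognormal(rng, c.vpr_copy_mean, c.gag_copy_cv, n_particles))
        labeled = joint if joint is not None else rng.random(n_particles) < c.incorporation_prob
        out[f"copies_{c.channel}"] = copies * labeled
    return pd.DataFrame(out)


def _render_particles(
    canvas: np.ndarray,
    x_px: np.ndarray,
    y_px: np.ndarray,
    z_pl: np.ndarray,
    photons: np.ndarray,
    sigma_xy_px: float,
    sigma_z_pl: float,
) -> None:
    """Add pixel-integrated 3-D Gaussian spots to a (Z, Y, X) canvas in place."""
    n_z, n_y, n_x = canvas.shape
    r_xy = max(1, int(np.ceil(4 * sigma_xy_px)))
    r_z = max(1, int(np.ceil(4 * sigma_z_pl)))
    for x, y, z, ph in zip(x_px, y_px, z_pl, photons):
        if ph <= 0:
            continue
        cx, cy, cz = int(round(x)), int(round(y)), int(round(z))
        wx = _pixel_integrated_gaussian(sigma_xy_px, r_xy, x - cx)
        wy = _pixel_integrated_gaussian(sigma_xy_px, r_xy, y - cy)
        wz = _pixel_integrated_gaussian(sigma_z_pl, r_z, z - cz)
        x0, x1 = cx - r_xy, cx + r_xy + 1
        y0, y1 = cy - r_xy, cy + r_xy + 1
        z0, z1 = cz - r_z, cz + r_z + 1
        sx = slice(max(x0, 0), min(x1, n_x))
        sy = slice(max(y0, 0), min(y1, n_y))
        sz = slice(max(z0, 0), min(z1, n_z))
        kx = wx[sx.start - x0 : sx.stop - x0]
        ky = wy[sy.start - y0 : sy.stop - y0]
        kz = wz[sz.start - z0 : sz.stop - z0]
        canvas[sz, sy, sx] += ph * kz[:, None, None] * ky[None, :, None] * kx[None, None, :]


def simulate_field(
    params: FieldParams,
    constructs: list[ConstructModel],
    dual_label_fraction: float | None = None,
) -> tuple[ImageField, pd.DataFrame]:
    """Simulate one virus-on-glass field with exact ground truth.

    Particle positions follow a uniform spatial Poisson process over the
    field; each particle gets construct-dependent labeled-IN copies (see
    :func:`assign_labels`), is flagged mature with probability
    ``mature_fraction`` (only mature particles take up the anti-CA
    immunostain), and is rendered as a 3-D Gaussian PSF spot.  Poisson shot
    noise, a constant photon background, and Gaussian read noise are added.

    Returns ``(ImageField, ground_truth)`` where the ground-truth DataFrame
    has one row per rendered particle: positions in um, maturity flag, and
    per-channel copy and expected-photon columns.

    The RNG seed in ``params`` is expanded into independent substreams per
    purpose (geometry, labels, reference stain, shot noise, read noise), so
    adding one noise source never shifts the others.
    """
    channels = [params.reference_channel] + [c.channel for c in constructs]
    if len(set(channels)) != len(channels):
        raise ValueError("constructs must use distinct channels, distinct from the reference")

    expected_n = params.particle_density * params.area_um2
    if expected_n > params.max_particles:
        raise ValueError(
            f"expected particle count {expected_n:.0f} exceeds cap {params.max_particles}; "
            "overlapping-field densities are out of scope"
        )

    streams = np.random.SeedSequence(params.seed).spawn(5)
    rng_geom, rng_lab, rng_ref, rng_shot, rng_read = (np.random.default_rng(s) for s in streams)

    n = int(rng_geom.poisson(expected_n))
    w_um = params.width_px * params.pixel_size_um
    h_um = params.height_px * params.pixel_size_um
    x_um = rng_geom.uniform(0.0, w_um, n)
    y_um = rng_geom.uniform(0.0, h_um, n)
    z_center = (params.n_z - 1) / 2.0 * params.z_step_um
    z_um = np.clip(
        rng_geom.normal(z_center, params.z_layer_sd_um, n),
        0.0,
        (params.n_z - 1) * params.z_step_um,
    )
    mature = rng_geom.random(n) < params.mature_fraction

    truth = assign_labels(n, constructs, seed=rng_lab, dual_label_fraction=dual_label_fraction)
    truth.insert(1, "x_um", x_um)
    truth.insert(2, "y_um", y_um)
    truth.insert(3, "z_um", z_um)
    truth.insert(4, "mature", mature)

    ref_photons = np.where(
        mature,
        _lognormal(rng_ref, params.reference_photons_mean, params.reference_photons_cv, n),
        0.0,
    )
    truth[f"photons_{params.reference_channel}"] = ref_photons
    for c in constructs:
        truth[f"photons_{c.channel}"] = truth[f"copies_{c.channel}"] * c.photons_per_copy

    data = np.zeros((len(channels), params.n_z, params.height_px, params.width_px))
    emis = {params.reference_channel: EMISSION_UM.get(params.reference_channel, 0.67)}
    emis.update({c.channel: c.emission_um for c in constructs})
    for ci, ch in enumerate(channels):
        psf = theoretical_psf(
            params.numerical_aperture,
            emis[ch],
            params.pixel_size_um,
            params.z_step_um,
            params.refractive_index,
        )
        _render_particles(
            data[ci],
            x_um / params.pixel_size_um,
            y_um / params.pixel_size_um,
            z_um / params.z_step_um,
            truth[f"photons_{ch}"].to_numpy(),
            psf.sigma_lateral_px,
            psf.sigma_axial_planes,
        )

    data += params.background_level
    data = rng_shot.poisson(data).astype(np.float64)
    if params.read_noise_sd > 0:
        data += rng_read.normal(0.0, params.read_noise_sd, data.shape)
    np.clip(data, 0.0, None, out=data)

    field = ImageField(
        data=data.astype(np.float32),
        channels=channels,
        pixel_size_um=params.pixel_size_um,
        z_step_um=params.z_step_um,
        meta={"seed": params.seed, "particle_density": params.particle_density},
    )
    return field, truth


def simulate_flow_events(
    n_events: int,
    infected_fraction: float,
    separation: float = 4.0,
    seed: int = 0,
    doublet_fraction: float = 0.05,
    condition: str = "sample",
    gfp_log_mean: float = 1.0,
    gfp_log_sd: float = 0.4,
    infected_log_sd_ratio: float = 0.25,
) -> pd.DataFrame:
    """Simulate a flow-cytometry event table for one condition.

    Scatter heights are log-normal; widths track heights with small relative
    noise for singlets while a ``doublet_fraction`` subpopulation has its
    widths inflated ~2x (doublets present twice the cross-section along the
    flow axis).  GFP fluorescence is a log-normal mixture: the infected
    component is shifted ``separation`` negative-population SDs up in log
    space and is narrower (``infected_log_sd_ratio`` x the negative SD),
    modelling a tight bright reporter-positive population.

    Columns: FSC-H, FSC-W, SSC-H, SSC-W, fluor, condition, true_infected,
    is_doublet (ground truth, synthetic only).
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if not 0.0 <= infected_fraction <= 1.0:
        raise ValueError("infected_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    fsc_h = rng.lognormal(np.log(5e4), 0.15, n_events)
    ssc_h = rng.lognormal(np.log(3e4), 0.20, n_events)
    doublet = rng.random(n_events) < doublet_fraction
    w_ratio_f = rng.normal(1.0, 0.04, n_events)
    w_ratio_s = rng.normal(1.0, 0.04, n_events)
    w_ratio_f[doublet] = rng.normal(2.0, 0.15, int(doublet.sum()))
    w_ratio_s[doublet] = rng.normal(2.0, 0.15, int(doublet.sum()))
    fsc_w = fsc_h * np.clip(w_ratio_f, 0.1, None)
    ssc_w = ssc_h * np.clip(w_ratio_s, 0.1, None)

    infected = rng.random(n_events) < infected_fraction
    log_gfp = rng.normal(gfp_log_mean, gfp_log_sd, n_events)
    n_inf = int(infected.sum())
    if n_inf:
        log_gfp[infected] = rng.normal(
            gfp_log_mean + separation * gfp_log_sd,
            infected_log_sd_ratio * gfp_log_sd,
            n_inf,
        )

    return pd.DataFrame(
        {
            "FSC-H": fsc_h,
            "FSC-W": fsc_w,
            "SSC-H": ssc_h,
            "SSC-W": ssc_w,
            "fluor": 10.0**log_gfp,
            "condition": condition,
            "true_infected": infected,
            "is_doublet": doublet,
        }
    )


@dataclass(frozen=True)
class RLUCondition:
    """One luciferase condition: signal potency per unit p24 and viral input."""

    name: str
    rlu_per_p24: float  # RLU per ng p24; 0 for background-level conditions (RTG, D116N alone)
    p24_ng: float

    def __post_init__(self) -> None:
        if self.p24_ng <= 0:
            raise ValueError("p24_ng must be > 0")
        if self.rlu_per_p24 < 0:
            raise ValueError("rlu_per_p24 must be >= 0")


def simulate_rlu_table(
    conditions: list[RLUCondition],
    seed: int = 0,
    n_replicates: int = 3,
    noise_cv: float = 0.15,
    background_rlu: float = 500.0,
) -> pd.DataFrame:
    """Simulate replicate luciferase readings with multiplicative noise.

    Each replicate is ``background * eps1 + rlu_per_p24 * p24_ng * eps2``
    with log-normal unit-mean noise factors, so integration-blocked
    conditions (raltegravir, D116N without rescue; ``rlu_per_p24 = 0``) sit
    at background and signal scales linearly with p24 input at fixed potency.
    With ``noise_cv = 0`` replicates equal the true mean exactly.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cond in conditions:
        eps_bg = _lognormal(rng, 1.0, noise_cv, n_replicates)
        eps_sig = _lognormal(rng, 1.0, noise_cv, n_replicates)
        rlu = background_rlu * eps_bg + cond.rlu_per_p24 * cond.p24_ng * eps_sig
        for rep, value in enumerate(rlu):
            rows.append(
                {"condition": cond.name, "replicate": rep, "rlu": value, "p24_ng": cond.p24_ng}
            )
    return pd.DataFrame(rows)
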