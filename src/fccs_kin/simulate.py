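"""Brownian-dynamics simulator of two-channel photon-count traces.

Labeled species diffuse through a periodic box containing two overlapping
3D-Gaussian confocal volumes (green and red channel). Per-bin expected
counts are accumulated along each particle trajectory and realised as
Poisson draws, which is the shot-noise model of photon counting. Three
species emulate a reversible nanopore-ligand system: the nanopore NP
(~10 red labels), the ligand L (1 green label) and the bound complex NP.L
carrying both label sets.

Binding/unbinding is much slower (minutes-hours) than a single trace
(seconds-minutes), so species populations are held fixed during a trace:
the free-ligand reservoir approximation. Slow state switching of pores is
available separately through :func:`simulate_state_switching` for building
time courses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import AVOGADRO, ConfocalGeometry

__all__ = [
    "FluorSpecies",
    "BindingSystem",
    "ChannelTrace",
    "IntensityTrace",
    "binding_system",
    "simulate_traces",
    "simulate_state_switching",
    "brownian_trajectories",
]

# Periodic box extents in units of (w_xy, w_xy, w_z). The detection profile
# at the +-3 w boundary is exp(-18) ~ 2e-8 of its peak, so >=99.999% of the
# signal originates far from the boundary while no dark volume is simulated.
BOX_FACTORS = (6.0, 6.0, 6.0)

#: default per-dye molecular brightness, detected counts/s at beam center
DEFAULT_BRIGHTNESS = 3.0e4
#: diffusion coefficient of the 46-nm DNA-origami pore (Stokes-Einstein scale)
D_NANOPORE = 1.1e-11
#: diffusion coefficient of a 20-nt ssDNA ligand
D_LIGAND = 1.0e-10


@dataclass(frozen=True)
class FluorSpecies:
    """One diffusing fluorescent species.

    ``q_green``/``q_red`` are molecular brightnesses per channel: detected
    counts per second per molecule at the beam center. ``D`` may be zero to
    freeze diffusion (used for shot-noise validation).
    """

    name: str
    D: float
    c: float
    q_green: float = 0.0
    q_red: float = 0.0

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError(f"species {self.name!r}: D must be >= 0, got {self.D}")
        if self.c < 0:
            raise ValueError(f"species {self.name!r}: c must be >= 0, got {self.c}")
        if self.q_green < 0 or self.q_red < 0:
            raise ValueError(f"species {self.name!r}: brightness must be >= 0")


@dataclass(frozen=True)
class BindingSystem:
    """Three-species reversible binding system NP + L <-> NP.L."""

    np_species: FluorSpecies
    ligand: FluorSpecies
    complex: FluorSpecies
    geometry: ConfocalGeometry
    k_on: float = 0.0
    k_off: float = 0.0

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off < 0:
            raise ValueError("rate constants must be >= 0")

    @property
    def species(self) -> tuple[FluorSpecies, FluorSpecies, FluorSpecies]:
        return (self.np_species, self.ligand, self.complex)

    @property
    def total_np(self) -> float:
        """Total nanopore concentration (free + complex), a conserved quantity."""
        return self.np_species.c + self.complex.c

    @property
    def total_ligand(self) -> float:
        """Total ligand concentration (free + complex), a conserved quantity."""
        return self.ligand.c + self.complex.c


def binding_system(
    geometry: ConfocalGeometry,
    c_np: float,
    c_ligand: float,
    c_complex: float = 0.0,
    *,
    D_np: float = D_NANOPORE,
    D_ligand: float = D_LIGAND,
    q_dye: float = DEFAULT_BRIGHTNESS,
    n_red_labels: int = 10,
    k_on: float = 0.0,
    k_off: float = 0.0,
) -> BindingSystem:
    """Build the canonical NP / L / NP.L system.

    The nanopore carries ``n_red_labels`` red dyes (10 by default, matching
    the labeling stoichiometry), the ligand one green dye, and the complex
    the additive sum of both (no quenching). Concentrations are free-species
    concentrations in M; the complex diffuses like the pore.
    """
    np_sp = FluorSpecies("NP", D_np, c_np, q_green=0.0, q_red=n_red_labels * q_dye)
    lig = FluorSpecies("L", D_ligand, c_ligand, q_green=q_dye, q_red=0.0)
    cx = FluorSpecies(
        "NP.L", D_np, c_complex, q_green=lig.q_green, q_red=np_sp.q_red
    )
    return BindingSystem(np_sp, lig, cx, geometry, k_on=k_on, k_off=k_off)


@dataclass(frozen=True)
class ChannelTrace:
    """Single-channel view of a binned photon-count trace."""

    counts: np.ndarray
    bin_width: float

    @property
    def duration(self) -> float:
        return self.counts.size * self.bin_width

    @property
    def mean_rate(self) -> float:
        """Mean detected count rate in counts/s."""
        return float(self.counts.mean()) / self.bin_width


@dataclass
class IntensityTrace:
    """Two-channel binned photon-count trace on a shared time base."""

    bin_width: float
    counts_green: np.ndarray
    counts_red: np.ndarray
    seed: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts_green = np.asarray(self.counts_green)
        self.counts_red = np.asarray(self.counts_red)
        if self.counts_green.shape != self.counts_red.shape:
            raise ValueError("both channels must share the time base")
        for name, ch in (("green", self.counts_green), ("red", self.counts_red)):
            if np.any(ch < 0):
                raise ValueError(f"{name} channel has negative counts")

    @property
    def n_bins(self) -> int:
        return self.counts_green.size

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_width

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_width

    @property
    def green(self) -> ChannelTrace:
        return ChannelTrace(self.counts_green, self.bin_width)

    @property
    def red(self) -> ChannelTrace:
        return ChannelTrace(self.counts_red, self.bin_width)


def _wrap(v: np.ndarray, half: float) -> np.ndarray:
    """Periodic wrap of coordinates into [-half, half)."""
    half = v.dtype.type(half)
    length = v.dtype.type(2.0) * half
    # ((v + half) mod length) - half, written via floor
    return v - length * np.floor((v + half) / length)


# block size (in diffusion steps) for the vectorised trajectory kernel;
# bounds peak memory at a few tens of MB per particle block
_BLOCK_STEPS = 1 << 21


def _accumulate_species(
    rng: np.random.Generator,
    n_particles: int,
    init_pos: np.ndarray,  # (k, 3) fixed starting positions; k == 0 -> random
    sigma: float,
    n_bins: int,
    steps_per_bin: int,
    half_x: float,
    half_y: float,
    half_z: float,
    w_xy: float,
    w_z: float,
    x_off_red: float,
    qg_dt: float,
    qr_dt: float,
    mean_g: np.ndarray,
    mean_r: np.ndarray,
) -> None:
    """Add one species' expected per-bin detected intensity to mean_g/mean_r.

    Each particle's trajectory is generated in vectorised blocks: bulk
    normal increments, cumulative sum (unwrapped), periodic wrap for the
    detection-profile evaluation, then per-bin summation of the profile.
    Trajectories and profile values are handled in float32 (sub-percent of
    the position scale; invisible next to shot noise); bin accumulators
    stay float64.
    """
    f32 = np.float32
    a_xy = f32(2.0 / (w_xy * w_xy))
    a_z = f32(2.0 / (w_z * w_z))
    halves = (half_x, half_y, half_z)
    block_bins = max(1, _BLOCK_STEPS // steps_per_bin)
    want_g = qg_dt > 0.0
    want_r = qr_dt > 0.0
    for p in range(n_particles):
        if init_pos.shape[0] > 0:
            pos = init_pos[p].astype(np.float64).copy()
        else:
            pos = np.array([rng.uniform(-h, h) for h in halves])
        for b0 in range(0, n_bins, block_bins):
            nb = min(block_bins, n_bins - b0)
            ns = nb * steps_per_bin
            coords = []
            for ax in range(3):
                if sigma > 0.0:
                    c = rng.standard_normal(ns, dtype=np.float32)
                    c *= f32(sigma)
                    np.cumsum(c, out=c)
                    c += f32(pos[ax])
                    pos[ax] = float(c[-1])
                    coords.append(_wrap(c, halves[ax]))
                else:
                    val = _wrap(np.array([pos[ax]], dtype=np.float32), halves[ax])[0]
                    coords.append(np.full(ns, val, dtype=np.float32))
            xw, yw, zw = coords
            e_common = a_xy * yw * yw
            e_common += a_z * zw * zw
            if want_g:
                w_prof = np.exp(-(a_xy * xw * xw + e_common))
                mean_g[b0 : b0 + nb] += qg_dt * w_prof.reshape(nb, steps_per_bin).sum(
                    axis=1, dtype=np.float64
                )
            if want_r:
                dx = xw - f32(x_off_red)
                w_prof = np.exp(-(a_xy * dx * dx + e_common))
                mean_r[b0 : b0 + nb] += qr_dt * w_prof.reshape(nb, steps_per_bin).sum(
                    axis=1, dtype=np.float64
                )


def _box_half_extents(geometry: ConfocalGeometry) -> tuple[float, float, float]:
    fx, fy, fz = BOX_FACTORS
    return (
        0.5 * fx * geometry.w_xy,
        0.5 * fy * geometry.w_xy,
        0.5 * fz * geometry.w_z,
    )


def box_volume_liters(geometry: ConfocalGeometry) -> float:
    hx, hy, hz = _box_half_extents(geometry)
    return 8.0 * hx * hy * hz * 1e3


def simulate_traces(
    system: BindingSystem,
    duration: float,
    bin_width: float,
    seed: int,
    *,
    background: tuple[float, float] = (0.0, 0.0),
    initial_positions: dict[str, np.ndarray] | None = None,
) -> IntensityTrace:
    """Simulate a two-channel photon-count trace of a binding system.

    Each species receives ``round(c * N_A * V_box)`` particles performing
    Brownian steps with per-axis displacement SD sqrt(2 D dt) in a periodic
    box; expected counts per bin are the path integrals of the channel
    detection profiles times molecular brightness; realised counts are
    Poisson draws. Identical configuration and seed give bit-identical
    traces.

    Parameters
    ----------
    initial_positions : dict, optional
        Map species name -> (n, 3) array of fixed starting positions in
        meters, overriding both random placement and the concentration-based
        particle count. Meant for controlled validation runs (e.g. a single
        particle pinned at the beam center with D = 0).
    """
    if duration <= 0 or bin_width <= 0:
        raise ValueError("duration and bin_width must be positive")
    n_bins = int(round(duration / bin_width))
    if n_bins < 1:
        raise ValueError("zero-duration trace: duration < bin_width")
    if n_bins < 1000:
        warnings.warn(
            f"trace of {n_bins} bins is short; >=1000 bins recommended",
            stacklevel=2,
        )
    geom = system.geometry
    hx, hy, hz = _box_half_extents(geom)
    v_box = box_volume_liters(geom)

    # time step: at most one step per bin, refined so that the RMS step
    # stays below ~w_xy/3 (profile-crossing resolution w_xy^2 / (20 D));
    # only species that put particles in the box count
    active = [
        sp for sp in system.species
        if (sp.c > 0 or (initial_positions and sp.name in initial_positions))
        and (sp.q_green > 0 or sp.q_red > 0)
    ]
    d_max = max((sp.D for sp in active), default=0.0)
    if d_max > 0:
        dt_target = min(bin_width, geom.w_xy**2 / (20.0 * d_max))
    else:
        dt_target = bin_width
    steps_per_bin = max(1, int(math.ceil(bin_width / dt_target)))
    dt = bin_width / steps_per_bin

    mean_g = np.zeros(n_bins)
    mean_r = np.zeros(n_bins)
    empty = np.empty((0, 3))
    any_particles = False
    realized_counts: dict[str, int] = {}
    # independent deterministic sub-stream per species
    seed_seq = np.random.SeedSequence(seed)
    species_seeds = seed_seq.spawn(len(system.species) + 1)
    for i, sp in enumerate(system.species):
        init = empty
        if initial_positions and sp.name in initial_positions:
            init = np.ascontiguousarray(initial_positions[sp.name], dtype=float)
            n_particles = init.shape[0]
        else:
            n_particles = int(round(sp.c * AVOGADRO * v_box))
        realized_counts[sp.name] = n_particles
        if n_particles == 0 or (sp.q_green == 0.0 and sp.q_red == 0.0):
            continue
        any_particles = True
        _accumulate_species(
            np.random.default_rng(species_seeds[i]),
            n_particles,
            init,
            math.sqrt(2.0 * sp.D * dt),
            n_bins,
            steps_per_bin,
            hx,
            hy,
            hz,
            geom.w_xy,
            geom.w_z,
            geom.red_channel_offset,
            sp.q_green * dt,
            sp.q_red * dt,
            mean_g,
            mean_r,
        )
    if not any_particles and background == (0.0, 0.0):
        # all-dark is legal (documented zero trace) unless system is empty
        if all(sp.c == 0 for sp in system.species) and not initial_positions:
            raise ValueError("empty system: no particles in any species")

    rng = np.random.default_rng(species_seeds[-1])  # shot-noise stream
    bg_g, bg_r = background
    counts_g = rng.poisson(mean_g + bg_g * bin_width)
    counts_r = rng.poisson(mean_r + bg_r * bin_width)
    meta = {
        "duration_s": n_bins * bin_width,
        "bin_width_s": bin_width,
        "seed": seed,
        "dt_s": dt,
        "steps_per_bin": steps_per_bin,
        "box_half_extents_m": (hx, hy, hz),
        "box_volume_L": v_box,
        "n_particles": realized_counts,
        "species": [
            {
                "name": sp.name,
                "D_m2_per_s": sp.D,
                "c_M": sp.c,
                "q_green_cps": sp.q_green,
                "q_red_cps": sp.q_red,
            }
            for sp in system.species
        ],
        "geometry": {"w_xy_m": geom.w_xy, "w_z_m": geom.w_z, "f_ov": geom.f_ov},
        "background_cps": list(background),
    }
    return IntensityTrace(bin_width, counts_g, counts_r, seed, meta)


def simulate_state_switching(
    n_np: int,
    k_pseudo: float,
    k_off: float,
    duration: float,
    dt: float,
    seed: int,
    *,
    start_bound: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-state Markov bind/unbind trajectories of ``n_np`` pores.

    Per step, an unbound pore binds with probability ``k_pseudo * dt``
    (pseudo-first-order rate k_on * [L]) and a bound pore unbinds with
    probability ``k_off * dt``. The long-run bound fraction converges to
    k_pseudo / (k_pseudo + k_off).

    Returns
    -------
    times : (n_steps + 1,) array of sample times
    states : (n_steps + 1, n_np) uint8 array, 1 = bound
    """
    if k_pseudo < 0 or k_off < 0:
        raise ValueError("rates must be >= 0")
    k_tot = k_pseudo + k_off
    if k_tot * dt >= 0.1:
        raise ValueError(
            f"dt too coarse: (k_pseudo + k_off) * dt = {k_tot * dt:.3g} "
            "violates the stability bound (k_pseudo + k_off) * dt < 0.1"
        )
    n_steps = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    states = np.empty((n_steps + 1, n_np), dtype=np.uint8)
    states[0] = 1 if start_bound else 0
    p_bind = k_pseudo * dt
    p_unbind = k_off * dt
    cur = states[0].astype(bool)
    for j in range(n_steps):
        u = rng.random(n_np)
        bind = (~cur) & (u < p_bind)
        unbind = cur & (u < p_unbind)
        cur = (cur | bind) & ~unbind
        states[j + 1] = cur
    times = np.arange(n_steps + 1) * dt
    return times, states


def brownian_trajectories(
    n_particles: int, D: float, n_steps: int, dt: float, seed: int
) -> np.ndarray:
    """Unwrapped free Brownian trajectories, shape (n_steps + 1, n, 3).

    Uses the same stepping rule as the photon kernel (per-axis displacement
    SD sqrt(2 D dt)); intended for validating the mean-squared-displacement
    law Var[x(t) - x(0)] = 2 D t per axis.
    """
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, math.sqrt(2.0 * D * dt), size=(n_steps, n_particles, 3))
    out = np.zeros((n_steps + 1, n_particles, 3))
    np.cumsum(steps, axis=0, out=out[1:])
    return out
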