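"""Synthetic subunit-model retina and stimulus generators.

Every analysis stage in this package can be exercised against ground truth
from a generative ganglion-cell model: a grid of small Gaussian subunits
(modeling bipolar-cell inputs, ~40-60 um RF diameter) filters the stimulus
locally; each subunit output passes through a configurable local
nonlinearity (linear, half-wave rectified, partially rectified with
strength lambda, threshold-quadratic, or homogeneity-preferring); the
ganglion cell pools the outputs with Gaussian weights matching a target RF
center and maps the pooled drive through a logistic output nonlinearity to
an expected spike count.  Trial counts are Poisson.

With a linear local nonlinearity the expected response is an exact LN
model, so the LN analysis, the iso-response indices and the grating F2/F1
index all have known target values (RI = CI = 0, straight contours); with
half-wave rectified subunits the model reproduces the classical nonlinear
signatures (RI near 1, elevated F2/F1, SC-boosted responses, depressed LN
performance).

Stimulus generators reproduce the experimental protocols: flashed natural
images (200 ms on / 800 ms gray, 10 trials), spatiotemporal binary white
noise (60 um stixels), contrast-reversing and flashed gratings,
checkerboard-flash contrast pairs, blurred-image series, drifting
gratings for direction/orientation tuning, and saccade-like grating
transitions for image-recurrence sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .blur_scale import blur_image
from .checkerboard import design_contrast_space
from .core_data import TrialResponseTable
from .ln_model import preprocess_image
from .rf_estimation import ParametricRF

__all__ = [
    "SubunitCell",
    "PROTOCOLS",
    "make_phenotype",
    "generate_natural_like_images",
    "simulate_flash_counts",
    "simulate_checkerboard_surface",
    "simulate_grating_responses",
    "simulate_tuning_responses",
    "simulate_saccade_psths",
    "simulate_white_noise_spikes",
    "NaturalImageSet",
]

PIXEL_UM = 7.5

# protocol constants (timing in s, geometry in um)
PROTOCOLS = {
    "white_noise": {"stixel_um": 60.0, "update_hz": 60.0, "contrast": 1.0},
    "image_flash": {"on_s": 0.2, "gray_s": 0.8, "n_trials": 10, "n_images": 300,
                    "count_window_s": 0.25},
    "reversing_grating": {"bar_widths_um": (15, 30, 60, 120, 240, 6000),
                          "phases_per_width": (1, 2, 2, 4, 4, 1),
                          "reversal_s": 1.0, "contrast": 1.0},
    "flashed_grating": {"on_s": 0.2, "gray_s": 0.8},
    "checkerboard_flash": {"tile_um": 120.0, "n_angles": 24, "n_radii": 10,
                           "r_min": 0.03, "r_max": 1.0, "n_trials": 4},
    "local_checkerboard": {"tile_um": 105.0, "patch_tiles": 2,
                           "min_spacing_um": 630.0},
    "blur_series": {"scales_um": (60.0, 120.0, 240.0, 480.0), "n_trials": 10},
    "drifting_sine": {"period_um": 240.0, "temporal_hz": 0.6, "n_directions": 8},
    "drifting_square": {"period_um": 225.0, "temporal_hz": 4.0, "n_directions": 8},
    "saccade_grating": {"period_um": 240.0, "fixation_s": 0.8,
                        "transition_s": 0.1, "n_positions": 4},
}


@dataclass
class NaturalImageSet:
    images: np.ndarray  # (n, size, size) Weber contrast
    pixel_size: float = PIXEL_UM
    source_tags: list = field(default_factory=list)


def _local_nl(name: str, lam: float = 1.0, beta: float = 0.8):
    """Local (subunit-level) nonlinearity by name."""
    if name == "linear":
        return lambda u: u
    if name == "rectified":
        return lambda u: np.clip(u, 0.0, None)
    if name == "partial":
        return lambda u: np.where(u > 0, u, (1.0 - lam) * u)
    if name == "threshold_quadratic":
        return lambda u: 2.0 * np.clip(u, 0.0, None) ** 2
    if name == "homogeneity":
        # mildly compressive in local contrast magnitude: spatial structure
        # reduces the pooled drive relative to a homogeneous stimulus
        return lambda u: u - beta * u**2
    raise ValueError(f"unknown local nonlinearity {name!r}")


@dataclass
class SubunitCell:
    """Generative subunit model of a ganglion cell."""

    rf: ParametricRF
    subunit_centers: np.ndarray  # (n_sub, 2), um
    subunit_sigma: float = 10.0  # um (bipolar-scale RF, ~40 um 4-sigma diameter)
    pooling_weights: np.ndarray = None  # (n_sub,), sums to 1
    nonlinearity: str = "linear"
    lam: float = 1.0  # rectification strength for 'partial'
    sign: float = 1.0  # +1 ON, -1 OFF
    ushape_output: bool = False  # ON-OFF output (U-shaped in the drive)
    off_gain: float = 1.0  # relative OFF-lobe strength for ON-OFF cells
    out_base: float = 0.2
    out_max: float = 16.0
    out_rate: float = 10.0
    out_mid: float = 0.2
    arena_um: float = 1440.0
    pixel_um: float = PIXEL_UM

    def __post_init__(self) -> None:
        self.subunit_centers = np.asarray(self.subunit_centers, dtype=float)
        if self.pooling_weights is None:
            d = self.subunit_centers - self.rf.center_mean
            prec = np.linalg.inv(self.rf.center_cov)
            q = np.einsum("ni,ij,nj->n", d, prec, d)
            w = np.exp(-0.5 * q)
            self.pooling_weights = w / w.sum()
        self._nl = _local_nl(
            "partial" if self.nonlinearity == "partial" else self.nonlinearity,
            self.lam,
        )

    # -- model core ---------------------------------------------------------
    def output(self, z: np.ndarray) -> np.ndarray:
        """Expected spike count from the pooled drive."""
        z = np.asarray(z, dtype=float)
        if self.ushape_output:
            up = 1.0 / (1.0 + np.exp(-self.out_rate * (z - self.out_mid)))
            dn = self.off_gain / (1.0 + np.exp(self.out_rate * (z + self.out_mid)))
            return self.out_base + (self.out_max - self.out_base) * (up + dn)
        s = 1.0 / (1.0 + np.exp(-self.out_rate * (z - self.out_mid)))
        return self.out_base + (self.out_max - self.out_base) * s

    def pooled_drive(self, u: np.ndarray) -> np.ndarray:
        """Pool local drives u (..., n_sub) through the local nonlinearity."""
        return self._nl(self.sign * np.asarray(u)) @ self.pooling_weights

    def expected_counts(self, u: np.ndarray) -> np.ndarray:
        return self.output(self.pooled_drive(u))

    # -- stimulus projection ------------------------------------------------
    def subunit_pixel_index(self) -> tuple[np.ndarray, np.ndarray]:
        n_px = int(round(self.arena_um / self.pixel_um))
        ix = np.clip(
            np.floor(self.subunit_centers[:, 0] / self.pixel_um), 0, n_px - 1
        ).astype(int)
        iy = np.clip(
            np.floor(self.subunit_centers[:, 1] / self.pixel_um), 0, n_px - 1
        ).astype(int)
        return iy, ix

    def drives_from_images(self, images: np.ndarray) -> np.ndarray:
        """Local subunit drives for a stack of contrast images (n, ny, nx)."""
        sig = self.subunit_sigma / self.pixel_um
        iy, ix = self.subunit_pixel_index()
        iy = np.clip(iy, 0, images.shape[1] - 1)
        ix = np.clip(ix, 0, images.shape[2] - 1)
        n = images.shape[0]
        u = np.empty((n, len(ix)))
        for i in range(n):
            sm = gaussian_filter(images[i], sig, mode="reflect")
            u[i] = sm[iy, ix]
        return u


def make_subunit_grid(
    rf: ParametricRF, spacing_um: float = 60.0, extent_sigma: float = 3.0,
    offset_um: float = 30.0,
) -> np.ndarray:
    """Square subunit grid covering the RF center out to ``extent_sigma``.

    The grid is offset from multiples of the spacing so subunit centers do
    not sit on checkerboard-tile borders.
    """
    sigma = np.sqrt(np.linalg.eigvalsh(rf.center_cov).max())
    half = extent_sigma * sigma
    mu = rf.center_mean
    lo = spacing_um * np.floor((mu - half) / spacing_um) + offset_um
    nx = int(np.ceil(2 * half / spacing_um)) + 1
    xs = lo[0] + spacing_um * np.arange(nx)
    ys = lo[1] + spacing_um * np.arange(nx)
    xx, yy = np.meshgrid(xs, ys)
    return np.stack([xx.ravel(), yy.ravel()], axis=-1)


def make_phenotype(
    name: str,
    rf_params: ParametricRF | None = None,
    seed: int = 0,
    lam: float = 1.0,
    spacing_um: float = 60.0,
    subunit_sigma: float = 10.0,
) -> SubunitCell:
    """Construct a named ganglion-cell phenotype.

    Phenotypes: linear_on, linear_off, rectified_on, rectified_off,
    onoff_nonlinear, onoff_linear, homogeneity_detector, ds_cell, os_cell,
    irs_cell.  The tuning/saccade phenotypes carry their planted parameters
    in ``extra`` attributes used by the matching simulators.
    """
    if rf_params is None:
        rf_params = ParametricRF(
            center_mean=np.array([720.0, 720.0]),
            center_cov=np.diag([60.0**2, 60.0**2]),
            surround_strength=0.0,
            surround_scale=2.0,
        )
    grid = make_subunit_grid(rf_params, spacing_um=spacing_um)
    kw = dict(rf=rf_params, subunit_centers=grid, subunit_sigma=subunit_sigma)
    table = {
        "linear_on": dict(nonlinearity="linear", sign=+1),
        "linear_off": dict(nonlinearity="linear", sign=-1),
        "rectified_on": dict(nonlinearity="rectified", sign=+1),
        "rectified_off": dict(nonlinearity="rectified", sign=-1),
        "partial_on": dict(nonlinearity="partial", lam=lam, sign=+1),
        "onoff_nonlinear": dict(nonlinearity="rectified", sign=+1,
                                ushape_output=False),
        "onoff_linear": dict(nonlinearity="linear", sign=+1,
                             ushape_output=True, out_mid=0.2, off_gain=0.6),
        "homogeneity_detector": dict(nonlinearity="homogeneity", sign=+1),
        "ds_cell": dict(nonlinearity="linear", sign=+1),
        "os_cell": dict(nonlinearity="linear", sign=+1),
        "irs_cell": dict(nonlinearity="rectified", sign=+1),
    }
    if name == "onoff_nonlinear":
        # rectified subunits of both signs (OFF pathway slightly weaker, as
        # ON-OFF cells are rarely perfectly balanced): responds to local
        # contrast of either polarity
        cell = SubunitCell(**kw, nonlinearity="rectified", sign=+1)
        cell._nl = lambda u: np.clip(u, 0, None) + 0.6 * np.clip(-u, 0, None)
        return cell
    if name not in table:
        raise ValueError(f"unknown phenotype {name!r}")
    cfg = table[name]
    cell = SubunitCell(**kw, **cfg)
    rng = np.random.default_rng(seed)
    if name == "ds_cell":
        cell.preferred_direction = float(rng.uniform(0, 2 * np.pi))
    if name == "os_cell":
        cell.preferred_orientation = float(rng.uniform(0, np.pi))
    return cell


# ---------------------------------------------------------------------------
# stimulus generators
# ---------------------------------------------------------------------------


def generate_natural_like_images(
    n: int,
    size: int = 192,
    power_exponent: float = 2.0,
    seed: int = 0,
    background: float = 128.0,
    quantize: bool = True,
    envelope_strength: float = 1.5,
    envelope_scale_px: float = 20.0,
) -> NaturalImageSet:
    """Spatially correlated (1/f^exponent power spectrum) random images.

    Natural scenes have two statistical signatures this generator emulates:
    nearby intensities are correlated (a power spectrum falling as
    f^-power_exponent), and local contrast is strongly nonstationary —
    texture-rich and near-homogeneous regions coexist in one scene.  The
    latter is produced by modulating a Gaussian random field with a smooth
    log-normal contrast envelope (``envelope_strength`` = 0 disables it and
    yields a stationary field whose local contrast barely varies between
    images).  Each image then passes through the display normalization
    (mean = background, SD = 40% of mean, clipped at 100% contrast, 8-bit).
    """
    rng = np.random.default_rng(seed)
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.rfftfreq(size)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = np.inf  # zero out DC
    amp = f ** (-power_exponent / 2.0)
    amp[0, 0] = 0.0
    images = np.empty((n, size, size))
    for i in range(n):
        white = rng.standard_normal((size, size))
        spec = np.fft.rfft2(white) * amp
        field_ = np.fft.irfft2(spec, s=(size, size))
        field_ /= field_.std()
        if envelope_strength > 0:
            env = gaussian_filter(
                rng.standard_normal((size, size)), envelope_scale_px, mode="wrap"
            )
            env /= env.std()
            field_ = field_ * np.exp(envelope_strength * env)
        images[i] = preprocess_image(field_ + background, background, quantize)
    return NaturalImageSet(images)


def simulate_flash_counts(
    cell: SubunitCell,
    images: np.ndarray,
    n_trials: int = 10,
    seed: int = 0,
    noiseless: bool = False,
) -> TrialResponseTable:
    """Poisson spike counts to flashed images (250 ms count window)."""
    u = cell.drives_from_images(np.asarray(images, dtype=float))
    mu = cell.expected_counts(u)
    if noiseless:
        counts = np.tile(mu[:, None], (1, n_trials))
    else:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(mu[:, None], size=(mu.size, n_trials)).astype(float)
    return TrialResponseTable(list(range(mu.size)), counts, (0.0, 0.25))


def _checkerboard_masks(cell: SubunitCell, tile_um: float):
    """Smoothed A/B tile indicator drives at the subunit centers."""
    n_px = int(round(cell.arena_um / cell.pixel_um))
    idx = np.arange(n_px)
    tx = np.floor((idx + 0.5) * cell.pixel_um / tile_um).astype(int)
    a_mask = ((tx[None, :] + tx[:, None]) % 2 == 0).astype(float)
    sig = cell.subunit_sigma / cell.pixel_um
    a_sm = gaussian_filter(a_mask, sig, mode="reflect")
    iy, ix = cell.subunit_pixel_index()
    a = a_sm[iy, ix]
    return a, 1.0 - a


def simulate_checkerboard_surface(
    cell: SubunitCell,
    tile_um: float = 120.0,
    design: np.ndarray | None = None,
    n_trials: int = 4,
    seed: int = 0,
    noiseless: bool = False,
):
    """Mean responses over the checkerboard-flash contrast-pair design.

    Returns (points, mean_counts).  The A/B tile drives are linear in
    (s_A, s_B), so per-pair subunit inputs are a two-term combination of
    precomputed smoothed tile indicators.
    """
    if design is None:
        design = design_contrast_space()
    a, b = _checkerboard_masks(cell, tile_um)
    u = design[:, 0:1] * a[None, :] + design[:, 1:2] * b[None, :]
    mu = cell.expected_counts(u)
    if noiseless:
        return design, mu
    rng = np.random.default_rng(seed)
    counts = rng.poisson(mu[:, None], size=(mu.size, n_trials)).astype(float)
    return design, counts.mean(axis=1)


def _grating_profile_drives(
    cell: SubunitCell,
    bar_width_um: float,
    phase_frac: float,
    tilt_deg: float = 22.5,
) -> np.ndarray:
    """Subunit drives for a square-wave grating at 100% contrast.

    The grating is tilted slightly relative to the subunit mosaic's axes
    (a stimulus is never aligned with a biological mosaic), which avoids
    spurious commensurate sampling of fine bars by the regular model grid.
    The Gaussian-smoothed square wave is evaluated analytically from its
    Fourier series (odd harmonics, attenuated by the subunit profile).
    """
    th = np.deg2rad(tilt_deg)
    c = (
        cell.subunit_centers[:, 0] * np.cos(th)
        + cell.subunit_centers[:, 1] * np.sin(th)
    )
    period = 2.0 * bar_width_um
    out = np.zeros(len(c))
    for k in range(1, 11, 2):
        att = np.exp(-0.5 * (2.0 * np.pi * k * cell.subunit_sigma / period) ** 2)
        out += (4.0 / (np.pi * k)) * att * np.sin(
            2.0 * np.pi * k * (c / period + phase_frac)
        )
    return out


def simulate_grating_responses(
    cell: SubunitCell,
    bar_widths=(15, 30, 60, 120, 240, 6000),
    phases_per_width=(1, 2, 2, 4, 4, 1),
    reversal_s: float = 1.0,
    n_cycles: int = 10,
    bin_s: float = 0.010,
    seed: int = 0,
    noiseless: bool = False,
):
    """Reversal-cycle PSTH rates per (bar width, phase index).

    One stimulus cycle spans two contrast reversals (2 x reversal_s).  Each
    reversal evokes a transient whose amplitude is the cell's drive to the
    post-reversal pattern, background-subtracted; rates are averaged over
    ``n_cycles`` noisy cycles (Poisson bin counts) unless ``noiseless``.
    Returns {(width, phase): rate array} with the full-cycle period.
    """
    rng = np.random.default_rng(seed)
    period = 2.0 * reversal_s
    n_bins = int(round(period / bin_s))
    t = (np.arange(n_bins) + 0.5) * bin_s
    # sustained drive model: the square-wave reversal is carried at its
    # temporal fundamental, so each subunit sees d_j * sin(2 pi t / T);
    # frequency doubling then arises only from subunit rectification
    mod = np.sin(2.0 * np.pi * t / period)
    base_hz, gain_hz, slope = 2.0, 60.0, 6.0

    out = {}
    for w, n_ph in zip(bar_widths, phases_per_width):
        for ph in range(n_ph):
            d = _grating_profile_drives(cell, w, ph / (2.0 * n_ph))
            u = mod[:, None] * d[None, :]  # (n_bins, n_sub)
            z = cell.pooled_drive(u)
            # mean-adapted output: periodic stimulation drives the cell
            # around the cycle-mean operating point, so a linear cell's
            # modulation is odd-symmetric and carries no even harmonics
            zc = z - z.mean()
            if cell.ushape_output:
                m = cell.out_mid
                up = 1.0 / (1.0 + np.exp(-slope * (zc - m)))
                dn = cell.off_gain / (1.0 + np.exp(slope * (zc + m)))
                rate = base_hz + gain_hz * (up + dn)
            else:
                rate = base_hz + gain_hz / (1.0 + np.exp(-slope * zc))
            if noiseless:
                out[(float(w), ph)] = rate
            else:
                counts = rng.poisson(rate * bin_s, size=(n_cycles, n_bins))
                out[(float(w), ph)] = counts.mean(axis=0) / bin_s
    return out


def simulate_tuning_responses(
    preferred: float,
    kind: str = "ds",
    n_trials: int = 4,
    base_hz: float = 2.0,
    amp_hz: float = 20.0,
    duration_s: float = 5.0,
    seed: int = 0,
) -> np.ndarray:
    """Per-direction mean rates (8 directions x trials) for a tuned cell.

    kind 'ds': rate ~ base + amp * (1 + cos(theta - preferred))/2;
    kind 'os': rate ~ base + amp * cos^2(theta - preferred);
    kind 'none': untuned (base + amp/2 everywhere).
    """
    rng = np.random.default_rng(seed)
    theta = 2.0 * np.pi * np.arange(8) / 8.0
    if kind == "ds":
        lam = base_hz + amp_hz * 0.5 * (1.0 + np.cos(theta - preferred))
    elif kind == "os":
        lam = base_hz + amp_hz * np.cos(theta - preferred) ** 2
    elif kind == "none":
        lam = np.full(8, base_hz + 0.5 * amp_hz)
    else:
        raise ValueError(f"unknown tuning kind {kind!r}")
    counts = rng.poisson(lam[:, None] * duration_s, size=(8, n_trials))
    return counts / duration_s


def simulate_saccade_psths(
    irs: bool = True,
    n_trials: int = 20,
    fixation_s: float = 0.8,
    bin_s: float = 0.010,
    seed: int = 0,
) -> dict:
    """16 post-transition PSTHs for a grating-saccade protocol.

    For an IRS phenotype, recurrence transitions (target == start) evoke a
    strong transient ~100 ms after fixation onset; contrast-reversal
    transitions (start two positions away) evoke none; the remaining
    transitions an intermediate one.  The phase-insensitive control
    responds equally to all transitions.
    """
    from .core_data import build_psth

    rng = np.random.default_rng(seed)
    n_bins = int(round(fixation_s / bin_s))
    t = (np.arange(n_bins) + 0.5) * bin_s
    tau = 0.03
    dt = t - 0.08
    transient = np.where(dt > 0, (dt / tau) * np.exp(1 - dt / tau), 0.0)
    out = {}
    for i in range(4):  # start
        for j in range(4):  # target
            if not irs:
                amp = 80.0
            elif i == j:
                amp = 100.0
            elif (i - j) % 4 == 2:
                amp = 0.0
            else:
                amp = 30.0
            rate = 2.0 + amp * transient
            # inhomogeneous Poisson spikes across trials
            spikes = []
            for tr in range(n_trials):
                lam = rate * bin_s
                k = rng.poisson(lam)
                for b in np.where(k > 0)[0]:
                    spikes.extend(tr * 10.0 + t[b] + rng.uniform(
                        -bin_s / 2, bin_s / 2, size=k[b]))
            onsets = 10.0 * np.arange(n_trials)
            out[(i, j)] = build_psth(np.sort(spikes), onsets, fixation_s, bin_s)
    return out


def simulate_white_noise_spikes(
    spatial_filter: np.ndarray,
    temporal_filter: np.ndarray,
    n_frames: int,
    frame_rate: float = 60.0,
    gain: float = 8.0,
    base_rate: float = 2.0,
    seed: int = 0,
):
    """Binary white-noise frames and Poisson spikes from a known LN cell.

    The instantaneous rate at frame t is
    base + gain * relu(sum_lag kT[lag] * <kS, frame[t-lag]>); spikes are
    drawn per frame.  Returns (frames, frame_times, spike_times).
    """
    rng = np.random.default_rng(seed)
    ny, nx = spatial_filter.shape
    frames = rng.choice([-1.0, 1.0], size=(n_frames, ny, nx))
    frame_times = np.arange(n_frames) / frame_rate
    proj = frames.reshape(n_frames, -1) @ spatial_filter.ravel()
    drive = np.convolve(proj, temporal_filter, mode="full")[:n_frames]
    rate = base_rate + gain * np.clip(drive, 0.0, None)
    dt = 1.0 / frame_rate
    counts = rng.poisson(rate * dt)
    spikes = []
    for i in np.where(counts > 0)[0]:
        spikes.extend(frame_times[i] + rng.uniform(0, dt, size=counts[i]))
    return frames, frame_times, np.sort(spikes)
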