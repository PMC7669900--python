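"""Synthetic recordings, fluorescence stacks and outcome tables with ground truth.

Every generator is a pure function of its scenario and seed, and returns
the planted ground truth alongside the data, so each downstream analysis
stage can be tested against known answers without any acquired data.

The generators emulate the statistical structure of in vitro insertion
experiments in mouse retina:

* recordings - 20 kHz multi-electrode traces with planted biphasic
  spikes whose electrode-of-occurrence shifts from the lower to the
  upper electrodes as the shank steps deeper; wild-type (WT) mode adds
  stimulus-locked ERG-like field potentials whose polarity reverses past
  a configurable depth, degenerate-retina (rd10) mode adds slow 3-7 Hz
  oscillations with phase-locked spike bursts;
* stacks - two-channel z-stacks with a fluorescent cell layer, an
  elliptical insertion void of known area, and red dead-cell puncta of
  known count inside the trauma region;
* condition samples / outcomes - truncated-normal trauma observations
  and per-shank Bernoulli insertion successes.

Condition presets are reproduced by moment matching: the latent
truncated-normal parameters are solved so that the *observable* mean and
SD (after truncation at zero, and after rounding for counts) equal the
calibration targets.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ephys import DepthStep, ElectrodeInfo, RecordingBlock, StimulusEvent
from .presets import TraumaConditionPreset
from .trauma import FluorescenceStack, ROIPolygon

__all__ = [
    "InsertionProtocol",
    "RecordingScenario",
    "RecordingGroundTruth",
    "StackScenario",
    "StackGroundTruth",
    "OutcomeScenario",
    "gen_recording",
    "gen_stack",
    "gen_preset_stack",
    "gen_condition_samples",
    "gen_count_samples",
    "gen_outcomes",
    "outcomes_from_counts",
    "truncated_normal_latent_params",
    "rounded_truncated_normal_latent_params",
]


# ---------------------------------------------------------------------------
# moment-matched truncated normals


@functools.lru_cache(maxsize=256)
def truncated_normal_latent_params(
    mean: float, sd: float, floor: float = 0.0
) -> tuple[float, float]:
    """Latent (mu, sigma) so a normal truncated at ``floor`` has the given moments.

    Truncation shifts the observable mean above ``mu`` and shrinks the
    SD; solving the two-moment system keeps generated samples matched to
    calibration targets even when the floor carries non-negligible mass.
    """
    if sd <= 0:
        raise ValueError("sd must be > 0")

    def resid(p: np.ndarray) -> list[float]:
        mu, log_sigma = p
        sigma = np.exp(log_sigma)
        a = (floor - mu) / sigma
        d = stats.truncnorm(a, np.inf, loc=mu, scale=sigma)
        return [d.mean() - mean, d.std() - sd]

    sol = optimize.root(resid, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success:
        raise RuntimeError(f"moment matching failed for mean={mean}, sd={sd}")
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _rounded_tn_moments(mu: float, sigma: float, kmax: int = 400) -> tuple[float, float]:
    k = np.arange(kmax)
    z = 1.0 - stats.norm.cdf(-mu / sigma)
    hi = stats.norm.cdf((k + 0.5 - mu) / sigma)
    lo = stats.norm.cdf((np.maximum(k - 0.5, 0.0) - mu) / sigma)
    lo[0] = stats.norm.cdf((0.0 - mu) / sigma)
    p = (hi - lo) / z
    m = float((k * p).sum())
    v = float(((k - m) ** 2 * p).sum())
    return m, np.sqrt(v)


@functools.lru_cache(maxsize=256)
def rounded_truncated_normal_latent_params(mean: float, sd: float) -> tuple[float, float]:
    """Latent (mu, sigma) so ``round(truncnorm(mu, sigma, floor=0))`` matches moments.

    Used for dead-cell counts, whose reported SD differs from the square
    root of the mean (ruling out a Poisson model) and whose mean sits
    close to zero, where truncation and rounding both bias the naive
    parameterisation.
    """
    if sd <= 0:
        raise ValueError("sd must be > 0")

    def resid(p: np.ndarray) -> list[float]:
        mu, log_sigma = p
        m, s = _rounded_tn_moments(mu, np.exp(log_sigma))
        return [m - mean, s - sd]

    sol = optimize.root(resid, x0=[mean - 0.3, np.log(sd)], method="hybr")
    if not sol.success:
        raise RuntimeError(f"count moment matching failed for mean={mean}, sd={sd}")
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _sample_truncnorm(
    rng: np.random.Generator, mu: float, sigma: float, floor: float, n: int
) -> np.ndarray:
    """Inverse-CDF sampling of a lower-truncated normal (reproducible, vectorised)."""
    a = stats.norm.cdf((floor - mu) / sigma)
    u = rng.uniform(a, 1.0, size=n)
    return mu + sigma * stats.norm.ppf(u)


def gen_condition_samples(
    mean: float,
    sd: float,
    n: int,
    floor: float = 0.0,
    seed: int = 0,
    match_moments: bool = True,
) -> np.ndarray:
    """Truncated-normal samples standing in for per-shank trauma observations.

    With ``match_moments`` (default) the latent parameters are solved so
    the truncated distribution itself has the requested mean and SD;
    otherwise ``mean``/``sd`` are used as latent parameters directly.
    ``sd = 0`` degenerates to a constant sample.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return np.full(n, float(mean))
    mu, sigma = (
        truncated_normal_latent_params(mean, sd, floor) if match_moments else (mean, sd)
    )
    return _sample_truncnorm(np.random.default_rng(seed), mu, sigma, floor, n)


def gen_count_samples(mean: float, sd: float, n: int, seed: int = 0) -> np.ndarray:
    """Integer counts drawn as round(truncated-normal) with matched moments."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return np.full(n, int(round(mean)))
    mu, sigma = rounded_truncated_normal_latent_params(mean, sd)
    x = _sample_truncnorm(np.random.default_rng(seed), mu, sigma, 0.0, n)
    return np.rint(x).astype(int)


# ---------------------------------------------------------------------------
# recordings


@dataclass(frozen=True)
class InsertionProtocol:
    """Stepwise insertion schedule.

    ``initial_step_um`` (Z_in, 40-180 um in retina protocols) punctures
    the first layer; ``micro_step_um`` (dZ, 20-40 um) tunes electrode
    depth; ``speed_um_s`` (V_in) is one of the tested insertion speeds.
    ``n_steps`` counts the annotated depth positions Z_0..Z_{n-1}.
    """

    initial_step_um: float = 100.0
    micro_step_um: float = 20.0
    speed_um_s: float = 187.5
    step_lag_s: float = 10.0
    n_steps: int = 6

    def __post_init__(self) -> None:
        if min(self.initial_step_um, self.micro_step_um, self.speed_um_s) <= 0:
            raise ValueError("protocol distances and speed must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass
class RecordingScenario:
    """Configuration of one synthetic insertion recording.

    ``mode`` selects wild-type (light-responsive, ERG-like LFPs) or rd10
    (degenerated, slow oscillations).  Electrode 0 is E-1, the lowest
    (stimulation, 25 um) site; the remaining electrodes are upper
    (recording, 15 um) sites.
    """

    mode: str = "WT"  # "WT" | "rd10"
    n_electrodes: int = 4
    shank: str = "S1"
    oscillation_freqs_hz: tuple[float, ...] = (3.3, 7.0)
    oscillation_amps_uv: tuple[float, ...] = (100.0, 40.0)
    stimuli: list[StimulusEvent] | None = None
    lfp_reversal_depth_index: int = 4
    noise_sd_uv: float = 5.0
    spike_snr: float = 10.0
    spike_rate_hz: float = 20.0
    burst_prob: float = 0.8
    step_duration_s: float = 5.0
    erg_amp_uv: float = 150.0
    planted_spike_times: dict[int, np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("WT", "rd10"):
            raise ValueError("mode must be 'WT' or 'rd10'")
        if self.n_electrodes not in (3, 4):
            raise ValueError(
                "shanks carry 3 or 4 electrodes (one lower + upper recording sites)"
            )
        if self.mode == "rd10" and any(
            not (3.0 <= f <= 7.0) for f in self.oscillation_freqs_hz
        ):
            warnings.warn(
                "rd10 oscillation frequencies outside the typical 3-7 Hz band",
                stacklevel=2,
            )


@dataclass
class RecordingGroundTruth:
    """Planted truth of a synthetic recording."""

    spike_times_s: list[np.ndarray]
    activation_step: np.ndarray  # first step at which each electrode fires
    lfp_polarity: np.ndarray | None  # (n_ch, n_steps), WT only
    success: dict[str, bool]
    oscillation_freqs_hz: tuple[float, ...] | None


FS_HZ = 20000.0


def _spike_template(fs_hz: float) -> np.ndarray:
    """~1 ms biphasic waveform, unit negative peak, zero net area.

    The positive lobe is scaled so the waveform integrates to zero,
    keeping its energy inside the 100 Hz - 3 kHz spike band (no slow
    rebound after band-pass filtering).
    """
    t = np.arange(0.0, 1.2e-3, 1.0 / fs_hz)
    s1, s2 = 0.12e-3, 0.18e-3
    w = -np.exp(-(((t - 0.30e-3) / s1) ** 2)) + (s1 / s2) * np.exp(
        -(((t - 0.65e-3) / s2) ** 2)
    )
    w -= w.mean()
    return w / -w.min()


def _add_spikes(trace: np.ndarray, times: np.ndarray, amp: float, fs: float) -> None:
    tpl = _spike_template(fs) * amp
    for t0 in times:
        i = int(round(t0 * fs))
        j = min(i + tpl.size, trace.size)
        if i < trace.size:
            trace[i:j] += tpl[: j - i]


def gen_recording(
    protocol: InsertionProtocol, scenario: RecordingScenario
) -> tuple[RecordingBlock, RecordingGroundTruth]:
    """Generate one seeded insertion recording with its ground truth.

    Per-electrode traces are Gaussian noise plus planted spikes; the step
    at which each electrode starts firing increases with electrode height
    (activity shifts from E-1 to the upper electrodes as the shank is
    driven deeper).  WT mode adds a stimulus per depth step with a
    difference-of-Gaussians ERG-like response whose sign flips once the
    electrode has passed ``lfp_reversal_depth_index``; rd10 mode adds
    slow sinusoidal LFPs with spike bursts phase-locked near their
    troughs.
    """
    rng = np.random.default_rng(scenario.seed)
    fs = FS_HZ
    n_ch = scenario.n_electrodes
    n_steps = protocol.n_steps
    step_len = scenario.step_duration_s
    n_samp = int(round(n_steps * step_len * fs))
    tt = np.arange(n_samp) / fs

    traces = (
        rng.normal(0.0, scenario.noise_sd_uv, size=(n_ch, n_samp))
        if scenario.noise_sd_uv > 0
        else np.zeros((n_ch, n_samp))
    )
    amp = scenario.spike_snr * (scenario.noise_sd_uv or 5.0)

    steps = [
        DepthStep(index=d, t_start_s=d * step_len, t_stop_s=(d + 1) * step_len)
        for d in range(n_steps)
    ]
    electrodes = [
        ElectrodeInfo(
            shank=scenario.shank,
            index=c,
            role="lower" if c == 0 else "upper",
            diameter_um=25.0 if c == 0 else 15.0,
        )
        for c in range(n_ch)
    ]

    # electrode-of-occurrence shift: electrode c starts firing at this step
    if n_ch > 1 and n_steps > 1:
        activation = np.round(np.arange(n_ch) * (n_steps - 1) / (n_ch - 1)).astype(int)
    else:
        activation = np.zeros(n_ch, dtype=int)

    spike_times: list[np.ndarray] = []
    if scenario.planted_spike_times is not None:
        for c in range(n_ch):
            t = np.sort(np.asarray(scenario.planted_spike_times.get(c, []), dtype=float))
            _add_spikes(traces[c], t, amp, fs)
            spike_times.append(t)
    elif scenario.mode == "WT":
        for c in range(n_ch):
            times = []
            for s in steps:
                if s.index < activation[c]:
                    continue
                n = rng.poisson(scenario.spike_rate_hz * step_len)
                times.append(rng.uniform(s.t_start_s, s.t_stop_s - 2e-3, size=n))
            t = np.sort(np.concatenate(times)) if times else np.empty(0)
            _add_spikes(traces[c], t, amp, fs)
            spike_times.append(t)
    else:  # rd10: bursts phase-locked to the primary oscillation trough
        f0 = scenario.oscillation_freqs_hz[0]
        phase0 = rng.uniform(0, 2 * np.pi)
        trough_times = (np.arange(int(n_steps * step_len * f0)) + 0.5) / f0
        trough_times = trough_times - phase0 / (2 * np.pi * f0)
        trough_times = trough_times[(trough_times > 0.05) & (trough_times < tt[-1] - 0.05)]
        for c in range(n_ch):
            times = []
            for tc in trough_times:
                if rng.uniform() < scenario.burst_prob:
                    nb = rng.poisson(4) + 1
                    times.append(np.sort(tc + rng.uniform(-0.02, 0.02, size=nb)))
            t = np.sort(np.concatenate(times)) if times else np.empty(0)
            _add_spikes(traces[c], t, amp, fs)
            spike_times.append(t)
        # slow oscillatory LFP shared across electrodes
        lfp = np.zeros(n_samp)
        for f, a in zip(scenario.oscillation_freqs_hz, scenario.oscillation_amps_uv):
            ph = phase0 if f == f0 else rng.uniform(0, 2 * np.pi)
            lfp += a * np.sin(2 * np.pi * f * tt + ph)
        traces += lfp[None, :]

    stimuli: list[StimulusEvent] = []
    polarity: np.ndarray | None = None
    if scenario.mode == "WT":
        if scenario.stimuli is not None:
            stimuli = list(scenario.stimuli)
        else:
            stimuli = [
                StimulusEvent(onset_s=s.t_start_s + 1.0, duration_s=0.5) for s in steps
            ]
        # electrode c sits c micro-steps above the tip: its depth at step d
        # is (d - c); polarity reverses once that passes the reversal index
        polarity = np.ones((n_ch, n_steps), dtype=int)
        for c in range(n_ch):
            for d in range(n_steps):
                if (d - c) >= scenario.lfp_reversal_depth_index:
                    polarity[c, d] = -1
        for ev in stimuli:
            d = min(int(ev.onset_s // step_len), n_steps - 1)
            on = np.exp(-(((tt - ev.onset_s - 0.08) / 0.04) ** 2))
            off = np.exp(-(((tt - ev.onset_s - ev.duration_s - 0.08) / 0.06) ** 2))
            resp = scenario.erg_amp_uv * (on - 0.6 * off)
            for c in range(n_ch):
                traces[c] += polarity[c, d] * resp

    block = RecordingBlock(
        traces_uv=traces, fs_hz=fs, electrodes=electrodes, steps=steps, stimuli=stimuli
    )
    last = n_steps - 1
    success = {
        scenario.shank: any(
            np.count_nonzero(spike_times[c] >= last * step_len) >= 3
            for c in range(1, n_ch)
        )
    }
    truth = RecordingGroundTruth(
        spike_times_s=spike_times,
        activation_step=activation,
        lfp_polarity=polarity,
        success=success,
        oscillation_freqs_hz=(
            scenario.oscillation_freqs_hz if scenario.mode == "rd10" else None
        ),
    )
    return block, truth


# ---------------------------------------------------------------------------
# fluorescence stacks


@dataclass
class StackScenario:
    """Configuration of one synthetic two-channel trauma stack.

    The green channel is a jittered field of bright somata over a dim
    diffuse background with an elliptical void of ``hole_area_um2`` at
    the insertion site; the red channel carries ``dead_cell_count``
    puncta planted inside the trauma region plus
    ``n_background_puncta`` well outside it.
    """

    image_shape: tuple[int, int, int] = (256, 256, 3)  # (y, x, z)
    pixel_size_um: float = 0.76
    z_step_um: float = 7.0
    hole_area_um2: float = 800.0
    dead_cell_count: int = 1
    n_background_puncta: int = 3
    cell_radius_px: float = 4.0
    punctum_radius_px: float = 2.5
    soma_spacing_px: float = 11.0
    background_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hole_area_um2 <= 0:
            raise ValueError("hole_area_um2 must be > 0")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel calibration must be > 0")
        if self.dead_cell_count < 0 or self.n_background_puncta < 0:
            raise ValueError("puncta counts must be >= 0")


@dataclass
class StackGroundTruth:
    """Planted truth of a synthetic stack."""

    roi: ROIPolygon
    hole_area_um2: float
    in_roi_count: int
    puncta_xy_in: np.ndarray
    puncta_xy_background: np.ndarray


def _ellipse_polygon(
    center: np.ndarray, a: float, b: float, theta: float, area_px: float, n: int = 180
) -> np.ndarray:
    """(x, y) polygon approximating a rotated ellipse, scaled to exact area."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    ct, st = np.cos(theta), np.sin(theta)
    pts = np.column_stack([center[0] + ct * x - st * y, center[1] + st * x + ct * y])
    shoelace = 0.5 * abs(
        np.dot(pts[:, 0], np.roll(pts[:, 1], -1)) - np.dot(pts[:, 1], np.roll(pts[:, 0], -1))
    )
    scale = np.sqrt(area_px / shoelace)
    return center + (pts - center) * scale


def _place_points(
    rng: np.random.Generator,
    n: int,
    sampler,
    min_sep: float,
    max_tries: int = 2000,
) -> np.ndarray:
    """Rejection-sample n points with pairwise separation, relaxing if cramped."""
    pts: list[np.ndarray] = []
    sep = min_sep
    tries = 0
    while len(pts) < n:
        p = sampler()
        if all(np.hypot(*(p - q)) >= sep for q in pts):
            pts.append(p)
        tries += 1
        if tries > max_tries:
            sep *= 0.5
            tries = 0
            if sep < 1.0:
                raise RuntimeError("could not place puncta with any separation")
    return np.array(pts).reshape(-1, 2)


def gen_stack(scenario: StackScenario) -> tuple[FluorescenceStack, StackGroundTruth]:
    """Generate one seeded trauma stack with its ground truth.

    The ground-truth ROI polygon is the hole ellipse itself, scaled so
    its shoelace area times ``pixel_size_um**2`` equals ``hole_area_um2``
    exactly; in-ROI puncta are planted strictly inside it and background
    puncta strictly outside a guard margin.
    """
    rng = np.random.default_rng(scenario.seed)
    ny, nx, nz = scenario.image_shape
    px = scenario.pixel_size_um
    area_px = scenario.hole_area_um2 / px**2

    aspect = rng.uniform(1.3, 2.0)
    b = np.sqrt(area_px / (np.pi * aspect))
    a = aspect * b
    if 2 * a > 0.8 * min(ny, nx):
        raise ValueError("insertion hole larger than the imaged field")
    theta = rng.uniform(0, np.pi)
    center = np.array([nx / 2.0, ny / 2.0]) + rng.uniform(-5, 5, size=2)

    poly = _ellipse_polygon(center, a, b, theta, area_px)
    roi = ROIPolygon(poly, provenance="ground-truth")

    yy, xx = np.mgrid[0:ny, 0:nx]
    ct, st = np.cos(theta), np.sin(theta)
    xr = (xx - center[0]) * ct + (yy - center[1]) * st
    yr = -(xx - center[0]) * st + (yy - center[1]) * ct
    hole_mask = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0

    green = np.full((nz, ny, nx), 80.0)
    red = np.zeros((nz, ny, nx))
    if scenario.background_noise_sd > 0:
        green += rng.normal(0, scenario.background_noise_sd, size=green.shape)
        red += np.abs(rng.normal(0, scenario.background_noise_sd, size=red.shape))

    # jittered somata field (skipping the hole)
    r_soma = scenario.cell_radius_px
    spacing = scenario.soma_spacing_px
    for gy in np.arange(spacing / 2, ny, spacing):
        for gx in np.arange(spacing / 2, nx, spacing):
            cxy = np.array([gx, gy]) + rng.uniform(-2.5, 2.5, size=2)
            exr = (cxy[0] - center[0]) * ct + (cxy[1] - center[1]) * st
            eyr = -(cxy[0] - center[0]) * st + (cxy[1] - center[1]) * ct
            if (exr / (a + r_soma)) ** 2 + (eyr / (b + r_soma)) ** 2 <= 1.0:
                continue
            z = rng.integers(nz)
            disc = (xx - cxy[0]) ** 2 + (yy - cxy[1]) ** 2 <= r_soma**2
            green[z][disc] = 170.0

    green[:, hole_mask] *= 0.05

    def _blob(channel: np.ndarray, cxy: np.ndarray, z: int, amp: float) -> None:
        sigma = scenario.punctum_radius_px / 1.2
        d2 = (xx - cxy[0]) ** 2 + (yy - cxy[1]) ** 2
        channel[z] += amp * np.exp(-d2 / (2 * sigma**2))

    # in-ROI dead cells, strictly inside a shrunken ellipse
    def _sample_in() -> np.ndarray:
        while True:
            u, v = rng.uniform(-1, 1, size=2)
            if u * u + v * v <= 1.0:
                ex, ey = 0.75 * a * u, 0.75 * b * v
                return center + np.array([ct * ex - st * ey, st * ex + ct * ey])

    sep = 4 * scenario.punctum_radius_px
    puncta_in = (
        _place_points(rng, scenario.dead_cell_count, _sample_in, sep)
        if scenario.dead_cell_count
        else np.empty((0, 2))
    )

    # background dead cells well outside the trauma region
    margin = 2.0

    def _sample_out() -> np.ndarray:
        while True:
            p = rng.uniform([8, 8], [nx - 8, ny - 8])
            exr = (p[0] - center[0]) * ct + (p[1] - center[1]) * st
            eyr = -(p[0] - center[0]) * st + (p[1] - center[1]) * ct
            if (exr / (margin * a)) ** 2 + (eyr / (margin * b)) ** 2 > 1.0:
                return p

    puncta_bg = (
        _place_points(rng, scenario.n_background_puncta, _sample_out, sep)
        if scenario.n_background_puncta
        else np.empty((0, 2))
    )

    for p in np.vstack([puncta_in, puncta_bg]):
        _blob(red, p, int(rng.integers(nz)), 200.0)

    stack = FluorescenceStack(
        green=green, red=red, pixel_size_um=px, z_step_um=scenario.z_step_um
    )
    truth = StackGroundTruth(
        roi=roi,
        hole_area_um2=scenario.hole_area_um2,
        in_roi_count=int(scenario.dead_cell_count),
        puncta_xy_in=puncta_in,
        puncta_xy_background=puncta_bg,
    )
    return stack, truth


#: smallest hole area generated when drawing from a condition preset (um^2);
#: guards against degenerate ellipses in the extreme lower tail
MIN_HOLE_AREA_UM2 = 50.0


def gen_preset_stack(
    preset: TraumaConditionPreset, seed: int = 0, **scenario_overrides
) -> tuple[FluorescenceStack, StackGroundTruth]:
    """Generate one stack whose hole area and dead-cell count follow a condition.

    The hole area is drawn from the moment-matched truncated normal of
    the condition's ITA statistics and the in-ROI count from the matched
    rounded truncated normal of its dead-cell statistics.
    """
    rng = np.random.default_rng(seed)
    ita_mean, ita_sd = preset.hole_area_params
    mu, sigma = truncated_normal_latent_params(ita_mean, ita_sd, 0.0)
    hole = float(max(_sample_truncnorm(rng, mu, sigma, 0.0, 1)[0], MIN_HOLE_AREA_UM2))
    cmu, csigma = rounded_truncated_normal_latent_params(preset.dead_mean, preset.dead_sd)
    count = int(np.rint(_sample_truncnorm(rng, cmu, csigma, 0.0, 1)[0]))
    scenario = StackScenario(
        hole_area_um2=hole,
        dead_cell_count=count,
        seed=int(rng.integers(2**31)),
        **scenario_overrides,
    )
    return gen_stack(scenario)


# ---------------------------------------------------------------------------
# outcomes


@dataclass
class OutcomeScenario:
    """Bernoulli per-shank insertion outcomes grouped by condition.

    Defaults mirror the study design: 6 material-width groups x 16
    insertions x 4 shanks per insertion.
    """

    group_probabilities: dict[str, float] = field(default_factory=dict)
    n_insertions_per_group: int = 16
    shanks_per_insertion: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for g, p in self.group_probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for group {g!r} outside [0, 1]")
        if self.n_insertions_per_group < 1 or self.shanks_per_insertion < 1:
            raise ValueError("design counts must be >= 1")


def gen_outcomes(scenario: OutcomeScenario) -> pd.DataFrame:
    """Per-shank Bernoulli successes: columns group, insertion, shank, success."""
    rng = np.random.default_rng(scenario.seed)
    rows = []
    for group, p in scenario.group_probabilities.items():
        for ins in range(scenario.n_insertions_per_group):
            for sh in range(scenario.shanks_per_insertion):
                rows.append(
                    {
                        "group": group,
                        "insertion": ins,
                        "shank": sh,
                        "success": bool(rng.uniform() < p),
                    }
                )
    return pd.DataFrame(rows)


def outcomes_from_counts(counts: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Deterministic outcome table from exact (successes, total) per group.

    Used for fixtures whose integer counts are known, e.g. the one group
    rate that reconstructs uniquely as 31 successes of 64 shanks.
    """
    rows = []
    for group, (succ, total) in counts.items():
        if not 0 <= succ <= total:
            raise ValueError(f"invalid counts for group {group!r}")
        for i in range(total):
            rows.append(
                {
                    "group": group,
                    "insertion": i // 4,
                    "shank": i % 4,
                    "success": i < succ,
                }
            )
    return pd.DataFrame(rows)
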