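"""Ground-truthed synthetic recordings for every downstream stage.

The generator emulates the study conditions the pipeline assumes: single
units firing ~0.2-3 Hz with class-specific waveforms and burst structure,
SPA events recurring near 1 Hz as a Gamma renewal process with per-event
LFPg/MUA trace windows, 300-s pharmacological epochs with per-unit rate
multipliers, planted mono- (1-3 ms) and polysynaptic (>3 ms) connections,
EM active-zone tables with group-specific length and perforation
statistics, and dark-blob micrographs on a textured bright background.

Every generator is a pure function of (config, seed): a fixed seed gives
byte-identical outputs.  Spike trains are piecewise-homogeneous Poisson
processes (exact sampling via the inverse intensity CDF, no thinning);
burst structure is inserted by grouping part of the spike budget into
short >= 3-spike clusters, so empirical rates converge to the configured
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Epoch, EpochSet, SPAEventSet, Unit, UnitSet

CLASSES = ("RS-PC", "IB-PC", "IN", "UC")


@dataclass
class SimConfig:
    seed: int = 0
    # units
    n_rs: int = 20
    n_ib: int = 10
    n_in: int = 15
    n_uc: int = 15
    waveform_fs: float = 20_000.0
    waveform_samples: int = 64
    # halfmax width bands (ms); margins keep classes unambiguous
    pc_width_band: tuple[float, float] = (0.5, 0.7)
    in_width_band: tuple[float, float] = (0.12, 0.17)
    uc_width_band: tuple[float, float] = (0.25, 0.35)
    # firing
    rate_band_hz: tuple[float, float] = (0.2, 3.0)
    # RS-PC units fire sustainedly by definition; their band stays above
    # the sustained-firing threshold so classes remain margin-separated
    rs_rate_band_hz: tuple[float, float] = (0.8, 3.0)
    burst_fraction: float = 0.6  # of an IB unit's spikes grouped into bursts
    burst_size_band: tuple[int, int] = (3, 5)
    intra_burst_isi_ms: tuple[float, float] = (3.0, 5.0)
    # SPA
    spa_rate_hz: float = 1.0
    spa_gamma_shape: float = 4.0
    lfpg_amplitude_uv: float = 22.0
    mua_amplitude_uv: float = 1.4
    lfpg_noise_uv: float = 3.0
    mua_noise_uv: float = 0.3
    trace_halfwindow_ms: float = 150.0
    bump_sigma_ms: float = 10.0
    spa_mod_window_ms: float = 50.0
    # images
    image_shape: tuple[int, int] = (512, 512)
    cell_radius_px: tuple[float, float] = (7.0, 1.2)  # mean, SD
    min_separation_px: float = 24.0
    background_level: float = 0.85
    cell_level: float = 0.25
    texture_amplitude: float = 0.04
    image_noise_sigma: float = 0.02
    # synapse tables (regimes bracket the printed group statistics)
    synapse_n: dict = field(default_factory=lambda: {
        "non-epileptic": 219, "epileptic": 242})
    patients_per_group: dict = field(default_factory=lambda: {
        "non-epileptic": 6, "epileptic": 7})
    perforation_p: dict = field(default_factory=lambda: {
        "non-epileptic": 0.204, "epileptic": 0.288})
    target_p: dict = field(default_factory=lambda: {
        "non-epileptic": (0.533, 0.388, 0.079),
        "epileptic": (0.665, 0.302, 0.033)})
    # log-normal active-zone lengths: median (μm) by perforation state
    length_median_um: dict = field(default_factory=lambda: {
        False: 0.22, True: 0.16})
    length_log_sigma: float = 0.33
    age_mean_sd: dict = field(default_factory=lambda: {
        "non-epileptic": (61.5, 17.0), "epileptic": (34.6, 13.0)})
    multi_innervation_p: dict = field(default_factory=lambda: {
        "non-epileptic": 0.046, "epileptic": 0.025})


@dataclass
class GroundTruth:
    unit_class: dict  # unit_id -> class label
    base_rate: dict  # unit_id -> {epoch label: Hz}
    burst_params: dict  # unit_id -> dict or None
    spa_multiplier: dict  # unit_id -> rate multiplier inside +-50 ms of events
    connections: list  # (pre_id, post_id, latency_ms, p)
    image_centroids: np.ndarray | None = None

    def __post_init__(self) -> None:
        for m in self.spa_multiplier.values():
            if m <= 0:
                raise ValueError("SPA multiplier must be positive")
        for _, _, lat, p in self.connections:
            if lat <= 0:
                raise ValueError("latency must be positive")
            if not 0 <= p <= 1:
                raise ValueError("transmission probability must be in [0,1]")


# ---------------------------------------------------------------------------
# waveform templates and ground truth


def _template(width_ms: float, fs: float, n: int) -> np.ndarray:
    """Biphasic template whose dominant trough has the given halfmax width."""
    t = (np.arange(n) - n * 0.38) / fs * 1e3  # ms, trough at ~38% of window
    sigma = width_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    trough = -np.exp(-0.5 * (t / sigma) ** 2)
    rebound = 0.18 * np.exp(-0.5 * ((t - 4.5 * sigma) / (2.2 * sigma)) ** 2)
    return 60.0 * (trough + rebound)  # microvolts


def make_units(cfg: SimConfig, rng: np.random.Generator | None = None,
               epoch_labels: tuple[str, ...] = ("control",),
               ) -> tuple[UnitSet, GroundTruth]:
    """Waveform templates plus ground truth (no spikes yet)."""
    rng = rng or np.random.default_rng(cfg.seed)
    plan = [("RS-PC", cfg.n_rs, cfg.pc_width_band),
            ("IB-PC", cfg.n_ib, cfg.pc_width_band),
            ("IN", cfg.n_in, cfg.in_width_band),
            ("UC", cfg.n_uc, cfg.uc_width_band)]
    units, unit_class, base_rate, burst_params, spa_mult = [], {}, {}, {}, {}
    k = 0
    for label, count, band in plan:
        for _ in range(count):
            uid = f"u{k:03d}"
            k += 1
            width = rng.uniform(*band)
            wf = _template(width, cfg.waveform_fs, cfg.waveform_samples)
            units.append(Unit(uid, np.empty(0), channel=int(rng.integers(1, 24)),
                              mean_waveform=wf, waveform_fs=cfg.waveform_fs))
            unit_class[uid] = label
            rate_band = cfg.rs_rate_band_hz if label == "RS-PC" else cfg.rate_band_hz
            r = float(np.exp(rng.uniform(*np.log(rate_band))))
            base_rate[uid] = {lab: r for lab in epoch_labels}
            burst_params[uid] = (
                {"fraction": cfg.burst_fraction,
                 "size_band": cfg.burst_size_band,
                 "intra_isi_ms": cfg.intra_burst_isi_ms}
                if label == "IB-PC" else None)
            spa_mult[uid] = 1.0
    unitset = UnitSet(units, recording_duration=0.0,
                      sampling_rate_waveform=cfg.waveform_fs)
    return unitset, GroundTruth(unit_class, base_rate, burst_params, spa_mult, [])


# ---------------------------------------------------------------------------
# spike trains


def _piecewise_segments(epoch: Epoch, events: np.ndarray | None,
                        mult: float, halfwin_s: float):
    """(starts, ends, rates-multiplier) partition of an epoch around events."""
    if events is None or mult == 1.0 or events.size == 0:
        return (np.array([epoch.start]), np.array([epoch.end]), np.array([1.0]))
    lo = np.clip(events - halfwin_s, epoch.start, epoch.end)
    hi = np.clip(events + halfwin_s, epoch.start, epoch.end)
    bounds = np.unique(np.concatenate([[epoch.start, epoch.end], lo, hi]))
    starts, ends = bounds[:-1], bounds[1:]
    mid = (starts + ends) / 2.0
    inside = np.any((mid[:, None] >= lo[None, :]) & (mid[:, None] < hi[None, :]),
                    axis=1)
    mults = np.where(inside, mult, 1.0)
    keep = ends > starts
    return starts[keep], ends[keep], mults[keep]


def _sample_positions(n: int, starts, ends, weights, rng) -> np.ndarray:
    """n points from the piecewise-constant density via inverse CDF."""
    seg_mass = (ends - starts) * weights
    total = seg_mass.sum()
    if total <= 0 or n == 0:
        return np.empty(0)
    cum = np.concatenate([[0.0], np.cumsum(seg_mass)])
    u = rng.uniform(0.0, total, size=n)
    idx = np.searchsorted(cum, u, side="right") - 1
    idx = np.clip(idx, 0, len(starts) - 1)
    frac = (u - cum[idx]) / np.maximum(seg_mass[idx], 1e-300)
    return starts[idx] + frac * (ends[idx] - starts[idx])


def _burstify(positions: np.ndarray, params: dict, epoch_end: float,
              rng: np.random.Generator) -> np.ndarray:
    """Group a fraction of the spike budget into short bursts.

    Total spike count is preserved (bursts consume budget); burst members
    follow the seed spike at intra-burst ISIs <= 6 ms, clipped to the
    epoch.
    """
    n = positions.size
    f = params["fraction"]
    lo, hi = params["size_band"]
    mean_size = (lo + hi) / 2.0
    n_bursts = int(round(f * n / mean_size))
    if n_bursts == 0 or n < lo:
        return positions
    sizes = rng.integers(lo, hi + 1, size=n_bursts)
    while sizes.sum() > n:  # budget overrun: drop a burst
        sizes = sizes[:-1]
        n_bursts -= 1
    if n_bursts == 0:
        return positions
    budget = int(sizes.sum())
    leftover = n - budget
    if f >= 1.0 and 0 < leftover < lo:
        sizes[-1] += leftover  # fold the remainder into the last burst
        leftover = 0
    order = rng.permutation(n)
    seeds = np.sort(positions[order[:n_bursts]])
    singles = positions[order[n_bursts:n_bursts + leftover]]
    # keep burst onsets apart so one burst's tail cannot strand spikes of
    # the next outside a detection window
    lo_t = positions.min()
    for _ in range(100):
        bad = np.flatnonzero(np.diff(seeds) < 0.030) + 1
        if bad.size == 0:
            break
        seeds[bad] = rng.uniform(lo_t, max(epoch_end - 0.025, lo_t), bad.size)
        seeds = np.sort(seeds)
    isi_lo, isi_hi = params["intra_isi_ms"]
    spikes = [singles]
    for s, size in zip(seeds, sizes):
        isis = rng.uniform(isi_lo, isi_hi, size=size - 1) * 1e-3
        burst = s + np.concatenate([[0.0], np.cumsum(isis)])
        burst = burst[burst < epoch_end]
        if burst.size >= lo:  # a clipped tail is no longer a burst
            spikes.append(burst)
    return np.concatenate(spikes)


def simulate_trains(gt: GroundTruth, epochs: EpochSet, cfg: SimConfig,
                    rng: np.random.Generator | None = None,
                    templates: UnitSet | None = None,
                    spa_events: SPAEventSet | None = None) -> UnitSet:
    """Draw every unit's spike train across the given epochs."""
    if len(epochs) == 0:
        raise ValueError("need at least one epoch")
    rng = rng or np.random.default_rng(cfg.seed + 1)
    halfwin_s = cfg.spa_mod_window_ms * 1e-3
    ev = spa_events.event_times if spa_events is not None else None
    duration = max(e.end for e in epochs)
    units = []
    for uid in gt.unit_class:
        trains = []
        for epoch in epochs:
            rate = gt.base_rate[uid].get(epoch.label, 0.0)
            if rate <= 0:
                continue
            ev_in = ev[(ev >= epoch.start) & (ev < epoch.end)] if ev is not None else None
            starts, ends, mults = _piecewise_segments(
                epoch, ev_in, gt.spa_multiplier[uid], halfwin_s)
            lam = rate * float(((ends - starts) * mults).sum())
            n = int(rng.poisson(lam))
            pos = _sample_positions(n, starts, ends, mults, rng)
            if gt.burst_params.get(uid):
                pos = _burstify(pos, gt.burst_params[uid], epoch.end, rng)
            trains.append(pos)
        t = np.sort(np.concatenate(trains)) if trains else np.empty(0)
        if t.size > 1:  # enforce strictly increasing times at 0.1 ms floor
            keep = np.concatenate([[True], np.diff(t) > 1e-7])
            t = t[keep]
        tmpl = templates[uid] if templates is not None else None
        units.append(Unit(uid, t,
                          channel=tmpl.channel if tmpl else 1,
                          mean_waveform=tmpl.mean_waveform if tmpl else None,
                          waveform_fs=tmpl.waveform_fs if tmpl else None))
    return UnitSet(units, recording_duration=duration,
                   sampling_rate_waveform=cfg.waveform_fs)


def inject_connection(pre_times: np.ndarray, post_times: np.ndarray,
                      latency_ms: float, p: float, jitter_ms: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Add, per presynaptic spike with probability p, one postsynaptic
    spike at pre + latency + Normal(0, jitter); returns the sorted train."""
    if latency_ms <= 0:
        raise ValueError("latency must be positive")
    if not 0 <= p <= 1:
        raise ValueError("transmission probability must be in [0,1]")
    pre = np.asarray(pre_times, dtype=float)
    fired = rng.random(pre.size) < p
    added = pre[fired] + latency_ms * 1e-3
    if jitter_ms > 0:
        added = added + rng.normal(0.0, jitter_ms * 1e-3, size=added.size)
    out = np.sort(np.concatenate([np.asarray(post_times, float), added]))
    if out.size > 1:
        keep = np.concatenate([[True], np.diff(out) > 1e-7])
        out = out[keep]
    return out


# ---------------------------------------------------------------------------
# SPA events and traces


def simulate_spa(cfg: SimConfig, duration: float,
                 rng: np.random.Generator | None = None,
                 start: float = 0.0, with_traces: bool = True) -> SPAEventSet:
    """Gamma-renewal SPA events with per-event LFPg/MUA trace windows."""
    if cfg.spa_rate_hz <= 0:
        raise ValueError("SPA rate must be positive")
    rng = rng or np.random.default_rng(cfg.seed + 2)
    shape = cfg.spa_gamma_shape
    scale = 1.0 / (cfg.spa_rate_hz * shape)  # mean ISI = 1/rate
    # generate ISIs in blocks until the window is covered
    times = []
    t = start
    margin = cfg.trace_halfwindow_ms * 1e-3
    while t < start + duration:
        isis = rng.gamma(shape, scale, size=256)
        for isi in isis:
            t += isi
            if t >= start + duration:
                break
            times.append(t)
    ev = np.asarray(times)
    ev = ev[(ev >= start + margin) & (ev <= start + duration - margin)]

    lfpg = mua = time_ms = None
    if with_traces:
        hw = cfg.trace_halfwindow_ms
        time_ms = np.arange(-hw, hw + 1.0)
        bump = np.exp(-0.5 * (time_ms / cfg.bump_sigma_ms) ** 2)
        n_ev, n_s = ev.size, time_ms.size
        lfpg = cfg.lfpg_amplitude_uv * bump[None, :] \
            + rng.normal(0.0, cfg.lfpg_noise_uv, size=(n_ev, n_s))
        mua = cfg.mua_amplitude_uv * bump[None, :] \
            + np.abs(rng.normal(0.0, cfg.mua_noise_uv, size=(n_ev, n_s)))
    return SPAEventSet(ev, "supragranular", lfpg, mua, time_ms)


# ---------------------------------------------------------------------------
# microscopy images


def render_cells_image(n_cells: int, cfg: SimConfig,
                       rng: np.random.Generator | None = None,
                       noise_sigma: float | None = None,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Dark elliptical somata on a bright textured background.

    Returns (uint8 image, (n, 2) centroid array in row/col order).
    Raises when n_cells cannot be placed at the minimum separation.
    """
    rng = rng or np.random.default_rng(cfg.seed + 3)
    h, w = cfg.image_shape
    if h <= 0 or w <= 0:
        raise ValueError("image dimensions must be positive")
    sigma = cfg.image_noise_sigma if noise_sigma is None else noise_sigma
    r_mean, r_sd = cfg.cell_radius_px
    pad = r_mean + 2 * r_sd + 2

    centroids = np.empty((0, 2))
    tries = 0
    while centroids.shape[0] < n_cells:
        tries += 1
        if tries > 200 * max(n_cells, 1):
            raise ValueError("too many cells for the area at this separation")
        cand = np.array([rng.uniform(pad, h - pad), rng.uniform(pad, w - pad)])
        if centroids.size and np.min(
                np.linalg.norm(centroids - cand, axis=1)) < cfg.min_separation_px:
            continue
        centroids = np.vstack([centroids, cand])

    # background with smooth texture
    from scipy.ndimage import gaussian_filter
    img = np.full((h, w), cfg.background_level)
    img += cfg.texture_amplitude * gaussian_filter(
        rng.standard_normal((h, w)), 16.0) * 16.0
    yy, xx = np.mgrid[0:h, 0:w]
    for cy, cx in centroids:
        a = float(np.clip(rng.normal(r_mean, r_sd), r_mean - 2 * r_sd,
                          r_mean + 2 * r_sd))
        b = float(np.clip(rng.normal(r_mean, r_sd), r_mean - 2 * r_sd,
                          r_mean + 2 * r_sd))
        theta = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        img[inside] = cfg.cell_level
    if sigma > 0:
        img += rng.normal(0.0, sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return (img * 255).astype(np.uint8), centroids


# ---------------------------------------------------------------------------
# EM synapse tables


def simulate_synapse_table(cfg: SimConfig,
                           rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Active-zone record table with group-specific statistics.

    Lengths are log-normal with perforation-specific medians; a
    perforated synapse contributes two active-zone rows sharing its
    synapse id.
    """
    rng = rng or np.random.default_rng(cfg.seed + 4)
    rows = []
    for group, n_syn in cfg.synapse_n.items():
        n_pat = cfg.patients_per_group[group]
        age_m, age_sd = cfg.age_mean_sd[group]
        ages = np.clip(rng.normal(age_m, age_sd, size=n_pat), 18.0, 85.0)
        # configured as the perforated fraction of ACTIVE ZONES (the printed
        # quantity); a perforated synapse contributes two zones, so the
        # per-synapse Bernoulli probability is p/(2-p)
        p_zone = cfg.perforation_p[group]
        p_perf = p_zone / (2.0 - p_zone)
        t_probs = np.asarray(cfg.target_p[group], float)
        t_probs = t_probs / t_probs.sum()
        p_multi = cfg.multi_innervation_p[group]
        patient_of = rng.integers(0, n_pat, size=n_syn)
        for s in range(n_syn):
            pid = f"{group[:3]}-{patient_of[s]:02d}"
            perforated = bool(rng.random() < p_perf)
            target = TARGETS_ORDER[int(rng.choice(3, p=t_probs))]
            region = "SPA" if rng.random() < 0.5 else "NoSPA"
            multi = bool(rng.random() < p_multi)
            n_zones = 2 if perforated else 1
            mu = np.log(cfg.length_median_um[perforated])
            for _ in range(n_zones):
                rows.append({
                    "patient_id": pid, "group": group, "region": region,
                    "synapse_id": f"{group[:3]}-s{s:04d}",
                    "active_zone_length_um": float(rng.lognormal(
                        mu, cfg.length_log_sigma)),
                    "perforated": perforated, "target": target,
                    "multi_innervated": multi,
                    "age": float(ages[patient_of[s]]),
                })
    return pd.DataFrame(rows)


TARGETS_ORDER = ("spine", "dendrite", "unidentified")
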