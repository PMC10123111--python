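"""Ground-truthed synthetic kymograph generation.

The simulator emulates the statistical structure of confocal line-scan data of
fluorescently tagged proteins on a tethered DNA molecule:

* binding events arrive at discrete damage sites as a Poisson process and stay
  bound for exponential-mixture dwell times;
* bound molecules may diffuse in 1D (Brownian, optional anomalous exponent);
* each fluorophore carries a single-exponential photobleaching clock that runs
  only while the laser exposes it (so pulsed excitation stretches the apparent
  bleach lifetime by the inverse duty cycle);
* fluorophores blink: per exposed frame they may switch to a dark state for an
  exponential off time, truncated at a configurable maximum (GFP-derived tags
  blink for periods of up to ~2 s, which is what downstream track curation has
  to repair);
* photons are emitted over a Gaussian point-spread function and counted with
  Poisson statistics on top of a uniform Poisson background.

Time is continuous internally; rendering discretizes to line_time bins, with
an emitting molecule visible in a frame iff it overlaps at least half of the
frame interval.  Every emitted event is recorded in a :class:`GroundTruth`
object so recovery can be scored exactly.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidGeometryError, InvalidParameterError
from .io import Kymograph

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimEvent",
    "simulate_dwell_times",
    "simulate_track",
    "simulate_pair_event",
    "simulate_kymograph",
    "simulate_reference_sequence",
]

#: basepair-to-length conversion for B-form DNA, µm per bp
UM_PER_BP = 0.34e-3

LAMBDA_LENGTH_BP = 48502


@dataclass
class SimulationConfig:
    """Parameters of one synthetic kymograph.

    Defaults mirror the standard imaging geometry for a ~48.5 kb tether:
    100 nm pixels, 0.033 s line time (~30 lines per second), one channel.
    Scalar per-channel parameters broadcast over channels.
    """

    n_channels: int = 1
    pixel_size: float = 100.0          # nm
    line_time: float = 0.033           # s
    n_lines: int = 1000
    dna_length: int = LAMBDA_LENGTH_BP  # bp
    tether_span: float | None = None   # µm; default: contour length of dna_length
    damage_sites: list[int] = field(default_factory=list)       # bp
    arrival_rate: float = 0.01         # events / s / site
    dwell_components: list[tuple[float, float]] = field(
        default_factory=lambda: [(5.0, 1.0)]
    )                                  # (lifetime s, fraction)
    photobleach_lifetime: float | list[float] = np.inf  # s of exposed time, per channel
    blink_off_mean: float = 0.5        # s
    blink_off_max: float = 2.0         # s, truncation of dark periods
    blink_prob: float = 0.0            # per exposed frame
    emission_rate: float = 50.0        # photons / frame at PSF peak
    background_rate: float = 1.0       # photons / pixel / frame
    psf_sigma: float = 1.5             # pixels
    diffusion_D: float = 0.0           # µm²/s
    diffusion_alpha: float = 1.0
    exposure_scheme: list[tuple[float, float]] | None = None  # per channel (exposure, pause)
    seed: int = 0

    def __post_init__(self):
        if self.tether_span is None:
            self.tether_span = self.dna_length * UM_PER_BP
        fractions = sum(f for _, f in self.dwell_components)
        if abs(fractions - 1.0) > 1e-9:
            raise InvalidParameterError(f"dwell fractions sum to {fractions}, not 1")
        if any(tau <= 0 for tau, _ in self.dwell_components):
            raise InvalidParameterError("dwell lifetimes must be positive")
        if self.n_lines < 1:
            raise InvalidParameterError("n_lines must be >= 1")
        if self.arrival_rate < 0 or self.line_time <= 0 or self.pixel_size <= 0:
            raise InvalidParameterError("rates and calibration must be positive")
        for bp in self.damage_sites:
            if not 0 <= bp <= self.dna_length:
                raise InvalidParameterError(f"damage site {bp} outside [0, {self.dna_length}]")

    def bleach_lifetimes(self) -> list[float]:
        tb = self.photobleach_lifetime
        if np.isscalar(tb):
            return [float(tb)] * self.n_channels
        return [float(x) for x in tb]

    def exposure(self) -> list[tuple[float, float]]:
        if self.exposure_scheme is None:
            return [(self.line_time, 0.0)] * self.n_channels
        return [tuple(e) for e in self.exposure_scheme]

    @property
    def n_pixels(self) -> int:
        return max(1, int(round(self.tether_span * 1000.0 / self.pixel_size)))

    def site_position_um(self, bp: float) -> float:
        """Uniform bp-per-pixel mapping of a genomic coordinate onto the tether."""
        return self.tether_span * bp / self.dna_length


@dataclass
class SimEvent:
    """One true binding event as the simulator emitted it."""

    channel: int
    site_bp: float
    start: float               # s, binding
    end: float                 # s, dissociation (start + dwell)
    dwell: float               # s, true dwell
    frames: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    positions_um: np.ndarray = field(default_factory=lambda: np.empty(0))
    visible: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    bleach_time: float = np.inf  # s (wall time at which the fluorophore died)
    class_id: int | None = None

    @property
    def observed_end(self) -> float:
        return min(self.end, self.bleach_time)


@dataclass
class GroundTruth:
    """Every event the simulator emitted, plus the configuration that made it."""

    events: list[SimEvent]
    config: SimulationConfig

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "channel": e.channel,
                "site_bp": e.site_bp,
                "start_s": e.start,
                "end_s": e.end,
                "dwell_s": e.dwell,
                "bleach_time_s": e.bleach_time,
                "class_id": e.class_id,
            }
            for e in self.events
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "channel", "site_bp", "start_s", "end_s",
                "dwell_s", "bleach_time_s", "class_id",
            ],
        )

    def write(self, csv_path: str | Path, json_path: str | Path | None = None) -> None:
        """CSV of events plus a JSON sidecar with the generating parameters."""
        self.to_frame().to_csv(csv_path, index=False, float_format="%.17g")
        if json_path is not None:
            cfg = asdict(self.config)
            cfg["photobleach_lifetime"] = (
                "inf" if np.isscalar(cfg["photobleach_lifetime"])
                and np.isinf(cfg["photobleach_lifetime"])
                else cfg["photobleach_lifetime"]
            )
            Path(json_path).write_text(json.dumps(cfg, indent=2, default=str))


def simulate_dwell_times(
    components: list[tuple[float, float]], n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. dwell times from an exponential mixture.

    ``components`` is a list of ``(lifetime_s, fraction)``; fractions must sum
    to 1.  The mixture mean is ``sum(f_i * tau_i)``.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    taus = np.array([t for t, _ in components], dtype=float)
    fracs = np.array([f for _, f in components], dtype=float)
    if np.any(taus <= 0):
        raise InvalidParameterError("lifetimes must be positive")
    if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-9:
        raise InvalidParameterError("fractions must be non-negative and sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    which = rng.choice(len(taus), size=n, p=fracs)
    return rng.exponential(scale=taus[which])


def simulate_track(
    D: float,
    alpha: float,
    dt: float,
    n_steps: int,
    start: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate a 1D diffusing trajectory sampled every ``dt`` seconds.

    For ``alpha == 1`` this is Brownian motion with independent Gaussian
    increments of variance ``2*D*dt``.  For ``alpha != 1`` positions are drawn
    as a Gaussian process whose marginal variance follows ``2*D*t**alpha``
    (increment scaling approximation, adequate for sanity cases; the analysis
    treats alpha as a fit output, not a simulated input).
    """
    if D < 0:
        raise InvalidParameterError("D must be >= 0")
    if dt <= 0:
        raise InvalidParameterError("dt must be > 0")
    if not 0 < alpha <= 2:
        raise InvalidParameterError("alpha must be in (0, 2]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_steps = int(n_steps)
    if D == 0 or n_steps == 0:
        return np.full(n_steps + 1, float(start))
    t = np.arange(n_steps + 1) * dt
    if alpha == 1.0:
        steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), size=n_steps)
        return start + np.concatenate([[0.0], np.cumsum(steps)])
    # variance budget 2*D*t^alpha distributed over successive increments
    var = 2.0 * D * t**alpha
    inc_var = np.diff(var)
    steps = rng.normal(0.0, np.sqrt(inc_var))
    return start + np.concatenate([[0.0], np.cumsum(steps)])


# ---------------------------------------------------------------------------
# two-color pair events

# class = 3 + 3*row + col with rows/cols ordered (A first, together, B first)
# for arrival (rows) and (A leaves first, together, B leaves first) for
# departure (cols); classes 1 and 2 are the single-color events.
_ORDERINGS = ("A", "together", "B")


def _pair_times(class_id: int, time_window: float, rng: np.random.Generator):
    """Start/end times for the two channels realizing a given class."""
    margin = 1.5 * time_window      # clear separation for ordered pairs
    jitter = 0.4 * time_window      # |delta| < window for "together"
    t0 = 1.0 + rng.uniform(0.0, 2.0)
    overlap = rng.uniform(2.0, 6.0)

    row = (class_id - 3) // 3
    col = (class_id - 3) % 3
    arrival = _ORDERINGS[row]
    departure = _ORDERINGS[col]

    if arrival == "together":
        start_a, start_b = t0, t0 + rng.uniform(-jitter, jitter)
    elif arrival == "A":
        start_a, start_b = t0, t0 + margin + rng.exponential(time_window)
    else:
        start_b, start_a = t0, t0 + margin + rng.exponential(time_window)

    base_end = max(start_a, start_b) + overlap
    if departure == "together":
        end_a, end_b = base_end, base_end + rng.uniform(-jitter, jitter)
    elif departure == "A":
        end_a, end_b = base_end, base_end + margin + rng.exponential(time_window)
    else:
        end_b, end_a = base_end, base_end + margin + rng.exponential(time_window)
    return (start_a, end_a), (start_b, end_b)


def simulate_pair_event(
    class_id: int,
    windows: tuple[float, float] = (200.0, 0.4),
    seed: int | np.random.Generator = 0,
    line_time: float = 0.033,
):
    """Generate a two-channel event pair realizing colocalization class ``class_id``.

    Returns ``(trace_a, trace_b)`` where each trace is an
    :class:`~kymotrace.colocal.EventTrace` (or ``None`` for single-color
    classes).  The generated pair round-trips through
    :func:`kymotrace.colocal.classify_event`.
    """
    from .colocal import EventTrace  # local import to avoid a cycle

    if class_id not in range(1, 12):
        raise InvalidParameterError(f"class_id must be 1..11, got {class_id}")
    dist_window, time_window = windows
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos_a = rng.uniform(2.0, 14.0)  # µm along the tether

    def make(channel, start, end, pos):
        frames = np.arange(int(np.floor(start / line_time)), int(np.ceil(end / line_time)))
        if frames.size == 0:
            frames = np.array([int(start / line_time)])
        times = frames * line_time
        positions = np.full(frames.size, pos)
        return EventTrace(track_id=channel, channel=channel, times=times,
                          positions_um=positions)

    if class_id == 1:
        return make(0, 1.0, 1.0 + rng.uniform(2, 6), pos_a), None
    if class_id == 2:
        return None, make(1, 1.0, 1.0 + rng.uniform(2, 6), pos_a)

    (sa, ea), (sb, eb) = _pair_times(class_id, time_window, rng)
    # within the distance window throughout, with margin for discretization
    pos_b = pos_a + rng.uniform(-0.4, 0.4) * dist_window / 1000.0
    return make(0, sa, ea, pos_a), make(1, sb, eb, pos_b)


# ---------------------------------------------------------------------------
# full kymograph


def _blink_mask(
    n_frames: int, blink_prob: float, off_mean: float, off_max: float,
    line_time: float, rng: np.random.Generator,
) -> np.ndarray:
    """Boolean emitting/dark mask over an event's frames."""
    on = np.ones(n_frames, dtype=bool)
    if blink_prob <= 0:
        return on
    f = 0
    while f < n_frames:
        if rng.random() < blink_prob:
            off = min(rng.exponential(off_mean), off_max)
            n_off = max(1, int(round(off / line_time)))
            on[f : f + n_off] = False
            f += n_off
        f += 1
    return on


def simulate_kymograph(config: SimulationConfig) -> tuple[Kymograph, GroundTruth]:
    """Render a multi-channel kymograph and its exact ground truth.

    Photon counts in each pixel are Poisson with mean = background plus the
    sum of Gaussian point-spread profiles of every molecule emitting in that
    frame.  See the module docstring for the event model.
    """
    n_px = config.n_pixels
    if n_px < 6 * config.psf_sigma:
        raise InvalidGeometryError(
            f"tether span of {n_px} px cannot support a PSF of sigma {config.psf_sigma} px"
        )
    rng = np.random.default_rng(config.seed)
    duration = config.n_lines * config.line_time
    bleach = config.bleach_lifetimes()
    exposure = config.exposure()
    um_per_px = config.pixel_size / 1000.0

    signal = np.zeros((config.n_channels, config.n_lines, n_px))
    events: list[SimEvent] = []

    for ch in range(config.n_channels):
        exp_s, pause_s = exposure[ch]
        duty = exp_s / (exp_s + pause_s) if exp_s + pause_s > 0 else 1.0
        for site in config.damage_sites:
            site_um = config.site_position_um(site)
            # Poisson arrivals over [0, duration)
            t = rng.exponential(1.0 / config.arrival_rate) if config.arrival_rate > 0 else np.inf
            while t < duration:
                dwell = float(simulate_dwell_times(config.dwell_components, 1, rng)[0])
                start, end = t, t + dwell
                # bleach clock runs on exposed time only
                bleach_wall = (
                    start + rng.exponential(bleach[ch]) / duty
                    if np.isfinite(bleach[ch]) else np.inf
                )
                emit_end = min(end, bleach_wall, duration)
                # frames whose interval is covered >= 50% by [start, emit_end)
                f0 = int(np.floor(start / config.line_time))
                f1 = int(np.ceil(emit_end / config.line_time))
                frames = np.arange(max(f0, 0), min(f1, config.n_lines))
                if frames.size:
                    lo = frames * config.line_time
                    hi = lo + config.line_time
                    cover = np.minimum(hi, emit_end) - np.maximum(lo, start)
                    frames = frames[cover >= 0.5 * config.line_time]
                if frames.size:
                    pos = simulate_track(
                        config.diffusion_D, config.diffusion_alpha,
                        config.line_time, frames.size - 1, start=site_um, seed=rng,
                    )
                    on = _blink_mask(
                        frames.size, config.blink_prob, config.blink_off_mean,
                        config.blink_off_max, config.line_time, rng,
                    )
                else:
                    pos = np.empty(0)
                    on = np.empty(0, dtype=bool)
                events.append(SimEvent(
                    channel=ch, site_bp=site, start=start, end=end, dwell=dwell,
                    frames=frames, positions_um=pos, visible=on,
                    bleach_time=bleach_wall,
                ))
                gap = rng.exponential(1.0 / config.arrival_rate)
                t = end + gap  # next arrival after this site frees up

        # render
        px = np.arange(n_px)
        for e in events:
            if e.channel != ch or e.frames.size == 0:
                continue
            centers_px = e.positions_um / um_per_px
            vis = e.visible
            profiles = config.emission_rate * np.exp(
                -0.5 * ((px[None, :] - centers_px[:, None]) / config.psf_sigma) ** 2
            )
            np.add.at(signal[ch], e.frames[vis], profiles[vis])

    counts = rng.poisson(signal + config.background_rate).astype(np.int64)
    kymo = Kymograph(
        counts=counts,
        pixel_size=config.pixel_size,
        line_time=config.line_time,
        channel_names=[f"ch{i}" for i in range(config.n_channels)],
        exposure_scheme=exposure,
        origin=0.0,
    )
    return kymo, GroundTruth(events=events, config=copy.deepcopy(config))


# ---------------------------------------------------------------------------
# synthetic reference sequences

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def simulate_reference_sequence(
    length: int,
    motif: str,
    top_positions: list[int],
    bottom_positions: list[int],
    seed: int = 1416,
) -> str:
    """Build a random nucleotide sequence carrying a motif at chosen positions.

    ``top_positions`` are 0-based start indices where ``motif`` is written on
    the top strand; ``bottom_positions`` are top-strand start indices where its
    reverse complement is written (i.e. the motif occurs on the bottom
    strand).  Every accidental occurrence of the motif elsewhere (either
    strand) is scrubbed, so the final sequence contains the motif exactly
    ``len(top_positions) + len(bottom_positions)`` times across both strands.
    """
    rng = np.random.default_rng(seed)
    seq = rng.choice(list("ACGT"), size=length)
    motif = motif.upper()
    rc = motif.translate(_COMPLEMENT)[::-1]
    planted = set()
    for p in top_positions:
        seq[p : p + len(motif)] = list(motif)
        planted.add(p)
    for p in bottom_positions:
        seq[p : p + len(rc)] = list(rc)
        planted.add(p)
    s = "".join(seq)
    # scrub accidental occurrences (on either strand) not at planted starts;
    # repeat until clean, since a fix for one pattern can create the other
    flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
    for _ in range(100):
        dirty = False
        for pat in (motif, rc):
            i = s.find(pat)
            while i != -1:
                protected = any(abs(i - q) < len(pat) for q in planted)
                if i not in planted and not protected:
                    mid = i + len(pat) // 2
                    s = s[:mid] + flip[s[mid]] + s[mid + 1 :]
                    dirty = True
                    i = s.find(pat)
                    continue
                i = s.find(pat, i + 1)
        if not dirty:
            break
    return s
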