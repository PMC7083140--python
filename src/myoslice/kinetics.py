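"""Twitch kinetics and the force-frequency relationship (FFR) of paced slices.

A slice is field-stimulated through a staircase protocol (default 0.2, 0.5,
1 and 2 Hz, 120 s each) while isometric force is recorded. Each stimulus
elicits one twitch; per twitch we measure peak active force (Fmax), time to
peak (TTP), time from peak to 90 % relaxation (TTR) and the 90 % contraction
duration CD90 = TTP + TTR. Twitches in the last 30 s of each interval are
averaged, and the FFR is summarised by the ratios F(1 Hz)/F(0.5 Hz) and
F(2 Hz)/F(0.5 Hz): above 1 the FFR is positive, below 1 it is negative.
Active wall tension is T = F / A with A the slice cross-section.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import InvalidSpecError

__all__ = [
    "ForceTrace",
    "TwitchWindow",
    "TwitchParams",
    "FrequencyResponse",
    "SliceGeometry",
    "detect_twitches",
    "twitch_params",
    "interval_average",
    "ffr_ratios",
    "wall_tension",
    "aggregate_slices",
]

DEFAULT_PROTOCOL: tuple[tuple[float, float], ...] = (
    (0.2, 120.0),
    (0.5, 120.0),
    (1.0, 120.0),
    (2.0, 120.0),
)

#: Window at the end of each pacing interval over which twitches are averaged.
ANALYSIS_WINDOW_S = 30.0


@dataclass
class ForceTrace:
    """Force recording of one paced slice.

    ``protocol`` is the ordered list of (frequency_hz, duration_s) pacing
    intervals, starting at ``time_s[0]``. ``stimulus_times_s`` is optional;
    when absent, twitch onsets are detected from the trace itself.
    """

    time_s: np.ndarray
    force_mN: np.ndarray
    sampling_hz: float
    protocol: tuple[tuple[float, float], ...] = DEFAULT_PROTOCOL
    stimulus_times_s: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.force_mN = np.asarray(self.force_mN, dtype=float)
        if self.time_s.shape != self.force_mN.shape or self.time_s.ndim != 1:
            raise InvalidSpecError("time_s and force_mN must be matching 1D arrays")
        dt = np.diff(self.time_s)
        if dt.size and (dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise InvalidSpecError("time axis must be strictly increasing and uniform")
        total = sum(d for _, d in self.protocol)
        span = self.time_s[-1] - self.time_s[0] + 1.0 / self.sampling_hz
        if total > span * (1 + 1e-9):
            raise InvalidSpecError("protocol durations exceed the trace span")
        self.protocol = tuple((float(f), float(d)) for f, d in self.protocol)

    def interval_bounds(self) -> list[tuple[float, float, float]]:
        """(frequency_hz, start_s, end_s) for each protocol interval."""
        out, t0 = [], float(self.time_s[0])
        for f, d in self.protocol:
            out.append((f, t0, t0 + d))
            t0 += d
        return out


@dataclass
class TwitchWindow:
    """One stimulus-to-next-stimulus slice of the trace."""

    time_s: np.ndarray
    force_mN: np.ndarray
    stimulus_time_s: float | None
    frequency_hz: float | None = None


@dataclass
class TwitchParams:
    """Kinetic parameters of a single twitch (times in s, force in mN)."""

    f_max_mN: float
    ttp_s: float
    ttr_s: float
    cd90_s: float
    onset_time_s: float
    truncated: bool = False
    fused: bool = False


@dataclass
class FrequencyResponse:
    """Per-frequency averaged twitch kinetics plus FFR summary ratios."""

    frequencies_hz: tuple[float, ...]
    mean_params: dict[float, TwitchParams]
    n_twitches: dict[float, int]
    ffr_1_0p5: float = np.nan
    ffr_2_0p5: float = np.nan
    tension_mN_per_mm2: dict[float, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SliceGeometry:
    """Slice cross-section used for wall tension.

    The top and bottom myocyte layers are damaged during vibratome slicing,
    so the effective thickness is the nominal thickness minus a damaged
    margin; the default geometry is 5 mm x (0.3 - 0.05) mm = 1.25 mm^2.
    """

    width_mm: float = 5.0
    nominal_thickness_mm: float = 0.3
    damaged_margin_mm: float = 0.05

    @property
    def area_mm2(self) -> float:
        a = self.width_mm * (self.nominal_thickness_mm - self.damaged_margin_mm)
        if a <= 0:
            raise InvalidSpecError("slice cross-sectional area must be positive")
        return a


def _interp_crossing(t0, t1, f0, f1, level) -> float:
    if f1 == f0:
        return t0
    return t0 + (level - f0) * (t1 - t0) / (f1 - f0)


def detect_twitches(trace: ForceTrace, onset_fraction: float = 0.05) -> list[TwitchWindow]:
    """Split the trace into one window per stimulus.

    With stimulus times given, each window runs from its stimulus to the
    next (or the end of its pacing interval). Without them, onsets are
    detected as upward crossings of baseline + ``onset_fraction`` of the
    trace amplitude, baseline being the 10th percentile of force.
    """
    t, f = trace.time_s, trace.force_mN
    bounds = trace.interval_bounds()

    if trace.stimulus_times_s is not None:
        stim = np.asarray(trace.stimulus_times_s, dtype=float)
    else:
        baseline = np.percentile(f, 10)
        amp = f.max() - baseline
        if amp <= 0:
            warnings.warn("flat trace: no twitches detected")
            return []
        level = baseline + onset_fraction * amp
        above = f > level
        onsets = np.flatnonzero(~above[:-1] & above[1:]) + 1
        stim = t[onsets]

    if stim.size == 0:
        warnings.warn("no twitches detected")
        return []

    windows: list[TwitchWindow] = []
    for k, s in enumerate(stim):
        end = t[-1] + 1.0 / trace.sampling_hz
        if k + 1 < stim.size:
            end = stim[k + 1]
        freq = None
        for fr, a, b in bounds:
            if a - 1e-9 <= s < b - 1e-9:
                end = min(end, b)
                freq = fr
                break
        sel = (t >= s - 1e-9) & (t < end - 1e-9)
        if not sel.any():
            continue
        windows.append(TwitchWindow(t[sel], f[sel], float(s), freq))
    return windows


def twitch_params(
    window: TwitchWindow,
    baseline: float,
    ttr_recovery: float = 0.9,
    fused_tolerance: float = 0.05,
) -> TwitchParams:
    """Measure Fmax, TTP, TTR and CD90 for one twitch.

    Onset is the stimulus time when the window carries one, otherwise the
    crossing of baseline + 5 % of the twitch amplitude. TTR is the time from
    the peak to recovery of ``ttr_recovery`` (default 90 %) of Fmax, with
    linear interpolation between samples, so CD90 = TTP + TTR. A window that
    never relaxes below baseline + (1 - ttr_recovery) * Fmax is flagged
    truncated; a window whose pre-peak minimum sits well above baseline
    (incomplete relaxation of the previous beat) is flagged fused and
    measured against that intra-beat minimum.
    """
    t, f = window.time_s, window.force_mN
    ipk = int(np.argmax(f))
    peak = f[ipk]
    if peak <= baseline:
        raise InvalidSpecError("window has no maximum above baseline")

    local_baseline = baseline
    fused = False
    if ipk > 0:
        pre_min = float(f[: ipk + 1].min())
        if pre_min > baseline + fused_tolerance * (peak - baseline):
            local_baseline = pre_min
            fused = True
    f_max = peak - local_baseline

    truncated = ipk == 0 or ipk == len(f) - 1

    # onset
    if window.stimulus_time_s is not None:
        onset = window.stimulus_time_s
    else:
        level = local_baseline + 0.05 * f_max
        onset = t[0]
        for i in range(ipk, 0, -1):
            if f[i - 1] <= level < f[i]:
                onset = _interp_crossing(t[i - 1], t[i], f[i - 1], f[i], level)
                break
    ttp = t[ipk] - onset

    # relaxation to (1 - ttr_recovery) of f_max above local baseline
    level = local_baseline + (1.0 - ttr_recovery) * f_max
    ttr = np.nan
    post = f[ipk:]
    below = np.flatnonzero(post <= level)
    if below.size:
        j = ipk + below[0]
        t_cross = t[j] if j == ipk else _interp_crossing(t[j - 1], t[j], f[j - 1], f[j], level)
        ttr = t_cross - t[ipk]
    else:
        truncated = True
    cd90 = ttp + ttr
    return TwitchParams(
        f_max_mN=float(f_max),
        ttp_s=float(ttp),
        ttr_s=float(ttr),
        cd90_s=float(cd90),
        onset_time_s=float(onset),
        truncated=bool(truncated),
        fused=fused,
    )


def interval_average(
    trace: ForceTrace,
    last_window_s: float = ANALYSIS_WINDOW_S,
    ttr_recovery: float = 0.9,
) -> FrequencyResponse:
    """Average twitch parameters over the last ``last_window_s`` of each interval.

    The baseline of each interval is the diastolic force: the median of the
    force sampled just before each stimulus of the interval. Without known
    stimulus times it falls back to the 10th percentile of interval force.
    Truncated twitches are excluded from the averages.
    """
    windows = detect_twitches(trace)
    t, f = trace.time_s, trace.force_mN
    means: dict[float, TwitchParams] = {}
    counts: dict[float, int] = {}
    stim = trace.stimulus_times_s
    for freq, a, b in trace.interval_bounds():
        if b - a < last_window_s:
            warnings.warn(
                f"interval at {freq} Hz shorter than {last_window_s} s; using whole interval"
            )
            w0 = a
        else:
            w0 = b - last_window_s
        sel_iv = (t >= a) & (t < b)
        if not sel_iv.any():
            continue
        baseline = float(np.percentile(f[sel_iv], 10))
        if stim is not None:
            iv_stim = stim[(stim > a) & (stim < b)]
            pre_idx = np.searchsorted(t, iv_stim) - 1
            pre_idx = pre_idx[pre_idx >= 0]
            if pre_idx.size:
                baseline = float(np.median(f[pre_idx]))
        params = []
        for w in windows:
            s = w.stimulus_time_s if w.stimulus_time_s is not None else w.time_s[0]
            if w0 - 1e-9 <= s < b - 1e-9:
                p = twitch_params(w, baseline, ttr_recovery=ttr_recovery)
                if not p.truncated:
                    params.append(p)
        counts[freq] = len(params)
        if params:
            means[freq] = TwitchParams(
                f_max_mN=float(np.mean([p.f_max_mN for p in params])),
                ttp_s=float(np.mean([p.ttp_s for p in params])),
                ttr_s=float(np.mean([p.ttr_s for p in params])),
                cd90_s=float(np.mean([p.cd90_s for p in params])),
                onset_time_s=float(np.mean([p.onset_time_s for p in params])),
                fused=any(p.fused for p in params),
            )
    fr = FrequencyResponse(
        frequencies_hz=tuple(fr for fr, _, _ in trace.interval_bounds()),
        mean_params=means,
        n_twitches=counts,
    )
    return ffr_ratios(fr)


def ffr_ratios(fr: FrequencyResponse) -> FrequencyResponse:
    """Fill in F(1)/F(0.5) and F(2)/F(0.5); missing frequencies yield NaN."""

    def _ratio(num_hz: float, den_hz: float) -> float:
        a = fr.mean_params.get(num_hz)
        b = fr.mean_params.get(den_hz)
        if a is None or b is None or b.f_max_mN <= 0:
            warnings.warn(f"FFR ratio {num_hz}/{den_hz} Hz unavailable")
            return np.nan
        return a.f_max_mN / b.f_max_mN

    fr.ffr_1_0p5 = _ratio(1.0, 0.5)
    fr.ffr_2_0p5 = _ratio(2.0, 0.5)
    return fr


def wall_tension(f_mN: float, geometry: SliceGeometry = SliceGeometry()) -> float:
    """Active wall tension T = F / A in mN/mm^2."""
    return f_mN / geometry.area_mm2


def aggregate_slices(per_slice: list[FrequencyResponse]) -> FrequencyResponse:
    """Component-wise median across 2-8 neighbouring slices of one sample."""
    if not per_slice:
        raise InvalidSpecError("no slices to aggregate")
    freqs = per_slice[0].frequencies_hz
    means: dict[float, TwitchParams] = {}
    counts: dict[float, int] = {}
    for fr_hz in freqs:
        ps = [s.mean_params[fr_hz] for s in per_slice if fr_hz in s.mean_params]
        if not ps:
            continue
        means[fr_hz] = TwitchParams(
            f_max_mN=float(np.median([p.f_max_mN for p in ps])),
            ttp_s=float(np.median([p.ttp_s for p in ps])),
            ttr_s=float(np.median([p.ttr_s for p in ps])),
            cd90_s=float(np.median([p.cd90_s for p in ps])),
            onset_time_s=float(np.median([p.onset_time_s for p in ps])),
        )
        counts[fr_hz] = int(np.median([s.n_twitches.get(fr_hz, 0) for s in per_slice]))
    out = FrequencyResponse(frequencies_hz=freqs, mean_params=means, n_twitches=counts)
    def _median_defined(vals: list[float]) -> float:
        vals = [v for v in vals if np.isfinite(v)]
        return float(np.median(vals)) if vals else np.nan

    out.ffr_1_0p5 = _median_defined([s.ffr_1_0p5 for s in per_slice])
    out.ffr_2_0p5 = _median_defined([s.ffr_2_0p5 for s in per_slice])
    all_t = {f for s in per_slice for f in s.tension_mN_per_mm2}
    for fr_hz in all_t:
        vals = [s.tension_mN_per_mm2[fr_hz] for s in per_slice if fr_hz in s.tension_mN_per_mm2]
        out.tension_mN_per_mm2[fr_hz] = float(np.median(vals))
    return out


def tensions(fr: FrequencyResponse, geometry: SliceGeometry = SliceGeometry()) -> FrequencyResponse:
    """Attach per-frequency wall tension of mean Fmax to a FrequencyResponse."""
    for f_hz, p in fr.mean_params.items():
        fr.tension_mN_per_mm2[f_hz] = wall_tension(p.f_max_mN, geometry)
    return fr
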