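"""Quantification of microtubule plus-end dynamics from kymographs.

The workflow mirrors the manual analysis practised in reconstitution
assays: trace the tip position in every frame of a kymograph, break the
position-time series into constant-velocity phases, classify each phase
by its rate with the standard 0.02 / 0.5 µm min⁻¹ thresholds, and pool
phases into per-condition dynamics statistics (rates, dynamic-state time
fractions, transition frequencies, weighted growth-rate histograms).

Manual line tracing is replaced by penalized least-squares changepoint
segmentation; the segmentation is exact (optimal partition by dynamic
programming), which the test suite verifies against exhaustive search.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .mtsim import (
    FAST_GROWTH,
    GROWTH_STATES,
    PAUSE,
    SHRINKAGE,
    SLOW_GROWTH,
    DEFAULT_VIDEO_LENGTH,
    KymographImage,
    Trajectory,
)

#: Rates slower than this magnitude (µm/min) are pauses.
SLOW_THRESHOLD = 0.02
#: Growth faster than this (µm/min) is fast growth.
FAST_THRESHOLD = 0.5


def classify_phase(
    rate: float,
    slow_threshold: float = SLOW_THRESHOLD,
    fast_threshold: float = FAST_THRESHOLD,
) -> str:
    """Four-way dynamic-state label for a signed rate in µm/min.

    Growth faster than ``fast_threshold`` is fast growth; growth faster
    than ``slow_threshold`` (and at most ``fast_threshold``) is slow
    growth; shrinkage faster than ``slow_threshold`` is shrinkage;
    everything else is a pause. Boundary values go to the slower class.
    """
    if not np.isfinite(rate):
        raise ValueError(f"rate must be finite, got {rate!r}")
    if rate > fast_threshold:
        return FAST_GROWTH
    if rate > slow_threshold:
        return SLOW_GROWTH
    if rate < -slow_threshold:
        return SHRINKAGE
    return PAUSE


@dataclass
class Phase:
    """One constant-velocity episode of a tip trajectory."""

    t_start: float  # s
    t_end: float  # s
    rate: float  # µm/min, signed
    state: str
    is_block: bool = False
    end_polarity: str = "plus"

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


# ---------------------------------------------------------------------------
# Tip tracing
# ---------------------------------------------------------------------------

def trace_kymograph(
    kymo: KymographImage,
    threshold_sd: float = 4.0,
    peak_fraction: float = 0.3,
    despike_window: int = 5,
    despike_px: float = 3.0,
) -> Trajectory:
    """Per-frame sub-pixel tip positions from a kymograph.

    A frame carries signal when its maximum exceeds background
    (median + ``threshold_sd`` robust s.d. of the distal margin). Within a
    signal frame, the tip is the distal-most local maximum above
    ``peak_fraction`` of the frame's peak over background, refined to
    sub-pixel precision by quadratic interpolation. The seed origin is the
    median proximal edge of the signal across rows. Rows without signal
    are imputed by linear interpolation and flagged. A median filter of
    odd ``despike_window`` removes isolated tracing outliers larger than
    ``despike_px`` pixels.
    """
    img = kymo.pixel_values
    if img.shape[0] < 2:
        raise ValueError("kymograph needs at least 2 rows")
    if despike_window % 2 == 0:
        raise ValueError("despike_window must be odd")

    # Background from the distal margin columns: the proximal part of the
    # field carries the lattice signal, so a whole-image median would land
    # on the lattice level whenever the microtubule fills most of the
    # width. The rightmost columns are beyond the tip in every frame.
    n_margin = max(3, img.shape[1] // 32)
    margin = img[:, -n_margin:]
    bg = float(np.median(margin))
    bg_sd = 1.4826 * float(np.median(np.abs(margin - bg)))
    thr = bg + threshold_sd * max(bg_sd, 1e-12)

    n_rows, width = img.shape
    tip_px = np.full(n_rows, np.nan)
    origin_px = np.full(n_rows, np.nan)
    for r in range(n_rows):
        row = img[r]
        peak = float(row.max())
        if peak <= thr:  # no signal in this frame
            continue
        # fraction-of-peak threshold: immune to isolated background
        # noise pixels distal of the tip that clear an absolute cut
        row_thr = max(thr, bg + peak_fraction * (peak - bg))
        above = row > row_thr
        idx = np.flatnonzero(above)
        # seed origin: sub-pixel 50% crossing of the proximal lattice edge
        # (the midpoint of a blurred step sits exactly at the step)
        c0 = int(idx[0])
        plateau = float(np.median(row[idx]))
        half = bg + 0.5 * (plateau - bg)
        o = float(c0)
        for c in range(c0, max(c0 - 6, 0), -1):
            if row[c - 1] < half <= row[c]:
                o = (c - 1) + (half - row[c - 1]) / (row[c] - row[c - 1])
                break
        origin_px[r] = o
        # distal-most local maximum of the above-threshold signal
        cand = idx[(row[idx] >= np.roll(row, 1)[idx]) & (row[idx] >= np.roll(row, -1)[idx])]
        c = int(cand[-1]) if cand.size else int(idx[-1])
        if 0 < c < width - 1:
            denom = row[c - 1] - 2 * row[c] + row[c + 1]
            if denom < 0:
                c = c + 0.5 * (row[c - 1] - row[c + 1]) / denom
        tip_px[r] = c

    if np.all(np.isnan(tip_px)):
        raise ValueError("no tip signal above background in any row")

    flagged = np.isnan(tip_px)
    if flagged.any():
        good = np.flatnonzero(~flagged)
        tip_px = np.interp(np.arange(n_rows), good, tip_px[good])

    # Despike: replace isolated impulse outliers by the running median.
    # A genuine fast excursion (e.g. a one-frame depolymerization to the
    # seed) moves the neighbours apart as well and is left untouched.
    med = ndimage.median_filter(tip_px, size=despike_window, mode="nearest")
    dev = np.abs(tip_px - med) > despike_px
    nb_prev = np.roll(tip_px, 1)
    nb_next = np.roll(tip_px, -1)
    isolated = np.abs(nb_prev - nb_next) <= despike_px
    spikes = dev & isolated
    spikes[0] = spikes[-1] = dev[0] if n_rows else False
    spikes[-1] = dev[-1]
    tip_px = np.where(spikes, med, tip_px)

    origin = float(np.nanmedian(origin_px)) if np.any(~np.isnan(origin_px)) else 0.0
    if np.nanmedian(tip_px) - origin < 5.0:
        # no proximal lattice signal (bare tip marker): report absolute
        # image coordinates instead of seed-relative ones
        origin = 0.0
    positions = np.clip((tip_px - origin) * kymo.pixel_size, 0.0, None)
    times = np.arange(n_rows) * kymo.frame_interval
    return Trajectory(times=times, positions=positions, flagged=flagged | spikes)


# ---------------------------------------------------------------------------
# Changepoint segmentation
# ---------------------------------------------------------------------------

def _linear_sse_table(t: np.ndarray, y: np.ndarray):
    """O(1) residual sum of squares of an OLS line on samples [i, j).

    Returns a function accepting a scalar or array of start indices
    ``i`` and a scalar end ``j``.
    """
    one = np.concatenate([[0.0], np.cumsum(np.ones_like(t))])
    st = np.concatenate([[0.0], np.cumsum(t)])
    stt = np.concatenate([[0.0], np.cumsum(t * t)])
    sy = np.concatenate([[0.0], np.cumsum(y)])
    syy = np.concatenate([[0.0], np.cumsum(y * y)])
    sty = np.concatenate([[0.0], np.cumsum(t * y)])

    def sse(i, j):
        n = one[j] - one[i]
        tm = (st[j] - st[i]) / n
        ym = (sy[j] - sy[i]) / n
        ctt = (stt[j] - stt[i]) - n * tm * tm
        cyy = (syy[j] - syy[i]) - n * ym * ym
        cty = (sty[j] - sty[i]) - n * tm * ym
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(ctt > 0, cyy - cty * cty / np.where(ctt > 0, ctt, 1.0), cyy)
        return np.clip(out, 0.0, None)

    return sse


def optimal_partition(
    t: np.ndarray,
    y: np.ndarray,
    penalty: float,
    min_size: int = 2,
    max_segments: int | None = None,
) -> tuple[list[int], float]:
    """Optimal piecewise-linear partition by dynamic programming.

    Minimizes ``sum_k SSE(segment_k) + penalty * (n_segments - 1)`` over
    partitions of the samples into contiguous runs of at least
    ``min_size`` points. Returns the interior changepoints (start indices
    of every segment after the first) and the optimal penalized cost.
    Ties are broken toward fewer, earlier changepoints.
    """
    n = len(t)
    sse = _linear_sse_table(np.asarray(t, float), np.asarray(y, float))
    if max_segments is None:
        best = np.full(n + 1, np.inf)
        best[0] = -penalty  # first segment carries no penalty
        prev = np.full(n + 1, -1, dtype=int)
        for j in range(min_size, n + 1):
            # valid starts: 0 (no previous segment) or >= min_size
            hi = j - min_size
            if hi >= min_size:
                i_cand = np.concatenate(([0], np.arange(min_size, hi + 1)))
            else:
                i_cand = np.array([0])
            costs = best[i_cand] + penalty + sse(i_cand, j)
            k = int(np.argmin(costs))  # first minimum: earliest changepoint
            best[j] = costs[k]
            prev[j] = i_cand[k]
        cps = []
        j = n
        while prev[j] > 0:
            cps.append(prev[j])
            j = prev[j]
        return sorted(cps), float(best[n])
    # bounded number of segments: DP over (segments used, end index)
    best = np.full((max_segments + 1, n + 1), np.inf)
    prev = np.full((max_segments + 1, n + 1), -1, dtype=int)
    best[0, 0] = 0.0
    for k in range(1, max_segments + 1):
        for j in range(k * min_size, n + 1):
            for i in range((k - 1) * min_size, j - min_size + 1):
                if best[k - 1, i] == np.inf:
                    continue
                c = best[k - 1, i] + sse(i, j)
                if c < best[k, j] - 1e-12:
                    best[k, j] = c
                    prev[k, j] = i
    k_best, cost_best = 1, np.inf
    for k in range(1, max_segments + 1):
        c = best[k, n] + penalty * (k - 1)
        if c < cost_best - 1e-12:
            cost_best, k_best = c, k
    cps = []
    j, k = n, k_best
    while k > 1:
        i = prev[k, j]
        cps.append(i)
        j, k = i, k - 1
    return sorted(cps), float(cost_best)


def default_penalty(t: np.ndarray, y: np.ndarray) -> float:
    """BIC-style penalty: 3 log(n) times a robust noise variance.

    The noise scale is estimated from second differences of the positions
    (slope changes cancel), via the median absolute deviation.
    """
    n = len(y)
    d2 = np.diff(y, 2)
    sigma = 1.4826 * float(np.median(np.abs(d2))) / math.sqrt(6.0) if d2.size else 0.0
    sigma = max(sigma, 1e-6)  # floor keeps noiseless polylines segmentable
    return 3.0 * math.log(max(n, 2)) * sigma * sigma


def _fit_rate(t: np.ndarray, y: np.ndarray, i: int, j: int) -> float:
    """OLS slope over samples [i, j), in µm/min."""
    tt, yy = t[i:j], y[i:j]
    slope = float(np.polyfit(tt, yy, 1)[0])  # µm per s
    return slope * 60.0


def _seg_label(rate_tuple: tuple, rate_se_factor: float) -> str:
    """Class label for a fitted segment.

    A slope statistically indistinguishable from zero is a pause,
    whichever side of the rate threshold its point estimate falls on. The
    threshold uses the Student-t quantile for the segment's degrees of
    freedom (scaled so that ``rate_se_factor`` is the large-sample z
    factor), which keeps very short noisy segments from being scored as
    growth or shrinkage events.
    """
    rate, se, _, n = rate_tuple
    if n > 2:
        tq = stats.t.ppf(0.97725, n - 2)  # Phi(2) at large n
        if abs(rate) < (rate_se_factor / 2.0) * tq * se:
            return PAUSE
    return classify_phase(rate)


def segment_phases(
    traj: Trajectory,
    penalty: float | None = None,
    min_duration: float | None = None,
    rate_se_factor: float = 2.0,
) -> list[Phase]:
    """Break a trajectory into classified constant-velocity phases.

    Changepoints come from exact penalized least-squares minimization
    (:func:`optimal_partition`). Phases shorter than ``min_duration``
    (default ``2 * dt``) are merged into the neighbour with the more
    similar rate, and adjacent same-state phases are merged. A phase
    whose fitted slope is statistically indistinguishable from zero
    (|rate| below ``rate_se_factor`` standard errors) is labelled a pause
    regardless of the 0.02 µm min⁻¹ point threshold — the automated
    counterpart of an analyst calling a visually flat stretch a pause.
    """
    t, y = traj.times, traj.positions
    if t.size < 4:
        raise ValueError("need at least 4 samples to segment")
    dt = traj.dt
    if dt <= 0:
        raise ValueError("degenerate (constant-time) trajectory")
    if min_duration is None:
        min_duration = 2.0 * dt
    if min_duration < 2.0 * dt - 1e-9:
        raise ValueError("min_duration must be at least 2 * dt")
    if penalty is None:
        penalty = default_penalty(t, y)

    cps, _ = optimal_partition(t, y, penalty=penalty, min_size=2)
    bounds = [0, *cps, t.size]

    # A segment owns a time span (tiling the whole record) plus the "core"
    # half-open sample ranges its rate is fitted on. Sub-minimum-duration
    # remnants (e.g. the partial sampling step where a shrinkage excursion
    # meets the seed) donate their span to a neighbour but never their
    # samples, so they cannot drag a genuine phase's rate across a class
    # boundary.
    segs: list[dict] = [
        {"span": (bounds[k], bounds[k + 1]), "cores": [(bounds[k], bounds[k + 1])]}
        for k in range(len(bounds) - 1)
    ]

    def seg_rate(seg: dict) -> tuple[float, float, float]:
        """Slope (µm/min), its standard error, and fit SSE over the cores."""
        tt = np.concatenate([t[i:j] for i, j in seg["cores"]])
        yy = np.concatenate([y[i:j] for i, j in seg["cores"]])
        slope, intercept = np.polyfit(tt, yy, 1)
        resid = yy - (slope * tt + intercept)
        sse_val = float(resid @ resid)
        n = tt.size
        if n > 2:
            ctt = float(np.sum((tt - tt.mean()) ** 2))
            se = math.sqrt(sse_val / (n - 2) / ctt) if ctt > 0 else 0.0
        else:
            se = 0.0
        return float(slope) * 60.0, se * 60.0, sse_val, n


    def seg_duration(seg: dict) -> float:
        # duration of the fitted samples themselves (a 2-point remnant is
        # one interval long no matter how much span it inherits)
        return float(sum(t[min(j, t.size) - 1] - t[i] for i, j in seg["cores"]))

    def fuse(a: dict, b: dict, keep_cores: str) -> dict:
        cores = {
            "left": a["cores"],
            "right": b["cores"],
            "both": a["cores"] + b["cores"],
        }[keep_cores]
        # collapse cores that share their boundary vertex
        merged: list[tuple[int, int]] = []
        for c in sorted(cores):
            if merged and c[0] <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], c[1]))
            else:
                merged.append(c)
        return {"span": (a["span"][0], b["span"][1]), "cores": merged}

    rates = [seg_rate(s) for s in segs]
    changed = True
    while changed and len(segs) > 1:
        changed = False
        for k in range(len(segs)):
            if seg_duration(segs[k]) < min_duration - 1e-9:
                left = abs(rates[k][0] - rates[k - 1][0]) if k > 0 else np.inf
                right = (
                    abs(rates[k][0] - rates[k + 1][0]) if k < len(segs) - 1 else np.inf
                )
                if left <= right:
                    segs[k - 1 : k + 1] = [fuse(segs[k - 1], segs[k], "left")]
                    rates[k - 1 : k + 1] = [seg_rate(segs[k - 1])]
                else:
                    segs[k : k + 2] = [fuse(segs[k], segs[k + 1], "right")]
                    rates[k : k + 2] = [seg_rate(segs[k])]
                changed = True
                break
    # Merge adjacent segments that classify identically, but only when
    # they genuinely lie on one line: the joint refit must stay in the
    # class and its SSE must not exceed the parts' by more than the
    # changepoint penalty. Two growth runs separated by an absorbed
    # seed-reset excursion are contiguous in the list yet not in
    # position, and their sawtooth refit must not be accepted.
    changed = True
    while changed and len(segs) > 1:
        changed = False
        for k in range(len(segs) - 1):
            cls = _seg_label(rates[k], rate_se_factor)
            if cls == _seg_label(rates[k + 1], rate_se_factor):
                fused = fuse(segs[k], segs[k + 1], "both")
                r_new = seg_rate(fused)
                # slack of 10x penalty: pieces of one noisy line merge at
                # ~1-5x penalty, genuine kinks and sawtooths cost 30x and up
                if (
                    _seg_label(r_new, rate_se_factor) == cls
                    and r_new[2] - rates[k][2] - rates[k + 1][2] <= 10.0 * penalty + 1e-12
                ):
                    segs[k : k + 2] = [fused]
                    rates[k : k + 2] = [r_new]
                    changed = True
                    break

    return [
        Phase(
            t_start=float(t[s["span"][0]]),
            t_end=float(t[min(s["span"][1], t.size - 1)]),
            rate=r[0],
            state=_seg_label(r, rate_se_factor),
            end_polarity=traj.end_polarity,
        )
        for s, r in zip(segs, rates)
    ]


def detect_blocks(
    phases: list[Phase],
    video_length: float = DEFAULT_VIDEO_LENGTH,
    tol: float = 1.0,
) -> list[Phase]:
    """Mark terminal pauses as blocks.

    A pause that persists to the end of the observation (within ``tol``
    seconds of ``video_length``) with no subsequent growth is a block;
    transient pauses followed by regrowth are not. Block durations are
    censored at ``video_length``.
    """
    if any(
        phases[k].t_start > phases[k + 1].t_start for k in range(len(phases) - 1)
    ):
        raise ValueError("phases must be time-ordered")
    out = []
    for k, ph in enumerate(phases):
        is_block = (
            ph.state == PAUSE
            and k == len(phases) - 1
            and ph.t_end >= video_length - tol
        )
        out.append(
            Phase(
                t_start=ph.t_start,
                t_end=min(ph.t_end, ph.t_start + video_length),
                rate=ph.rate,
                state=ph.state,
                is_block=is_block,
                end_polarity=ph.end_polarity,
            )
        )
    return out


@dataclass
class DynamicsSummary:
    """Pooled dynamics statistics for a set of trajectories."""

    growth_rates: dict[str, np.ndarray]  # state -> pooled signed rates (µm/min)
    rate_mean: dict[str, float]
    rate_sem: dict[str, float]
    weighted_rate_mean: dict[str, float]  # duration-weighted, per state
    pause_durations: np.ndarray  # s (transient pauses)
    block_durations: np.ndarray  # s (censored at video length)
    percent_time: dict[str, float]  # sums to 100
    transition_frequencies: dict[str, float | None]  # events / min, None if undefined
    n_events: dict[str, int]
    n_trajectories: int
    total_time: float  # s
    per_experiment: dict | None = None

    def to_dict(self) -> dict:
        return {
            "rate_mean": self.rate_mean,
            "rate_sem": self.rate_sem,
            "weighted_rate_mean": self.weighted_rate_mean,
            "percent_time": self.percent_time,
            "transition_frequencies": self.transition_frequencies,
            "n_events": self.n_events,
            "n_trajectories": self.n_trajectories,
            "total_time_s": self.total_time,
            "pause_duration_mean_s": (
                float(np.mean(self.pause_durations)) if self.pause_durations.size else None
            ),
            "block_duration_mean_s": (
                float(np.mean(self.block_durations)) if self.block_durations.size else None
            ),
            "per_experiment": self.per_experiment,
        }


def _summary_core(phase_sets: list[list[Phase]]) -> dict:
    state_time = {s: 0.0 for s in (FAST_GROWTH, SLOW_GROWTH, PAUSE, SHRINKAGE)}
    rates = {s: [] for s in state_time}
    durs = {s: [] for s in state_time}
    pause_durs, block_durs = [], []
    counts = {"catastrophe": 0, "rescue": 0, "pause_entry": 0, "pause_exit": 0}
    for phases in phase_sets:
        for ph in phases:
            state_time[ph.state] += ph.duration
            rates[ph.state].append(ph.rate)
            durs[ph.state].append(ph.duration)
            if ph.state == PAUSE:
                (block_durs if ph.is_block else pause_durs).append(ph.duration)
        for a, b in zip(phases, phases[1:]):
            if a.state in GROWTH_STATES and b.state == SHRINKAGE:
                counts["catastrophe"] += 1
            if a.state == SHRINKAGE and b.state in GROWTH_STATES:
                counts["rescue"] += 1
            if b.state == PAUSE:
                counts["pause_entry"] += 1
            if a.state == PAUSE:
                counts["pause_exit"] += 1
    return {
        "state_time": state_time,
        "rates": rates,
        "durs": durs,
        "pause_durs": pause_durs,
        "block_durs": block_durs,
        "counts": counts,
    }


def _frequencies(core: dict) -> dict[str, float | None]:
    st = core["state_time"]
    growth_t = st[FAST_GROWTH] + st[SLOW_GROWTH]
    shrink_t = st[SHRINKAGE]
    nonpause_t = growth_t + shrink_t
    c = core["counts"]

    def freq(n: int, t_s: float) -> float | None:
        # events per minute over the time the event could have occurred
        return None if t_s <= 0 else n / (t_s / 60.0)

    return {
        "catastrophe": freq(c["catastrophe"], growth_t),
        "rescue": freq(c["rescue"], shrink_t),
        "pause_entry": freq(c["pause_entry"], nonpause_t),
        "pause_exit": freq(c["pause_exit"], st[PAUSE]),
    }


def summarize_dynamics(
    phase_sets: list[list[Phase]],
    video_length: float = DEFAULT_VIDEO_LENGTH,
    experiment_ids: list | None = None,
) -> DynamicsSummary:
    """Pool per-trajectory phase lists into a dynamics summary.

    Percent time per state is total state time over total observed time;
    catastrophe frequency is growth→shrinkage events per total growth
    time, rescue is shrinkage→growth per total shrinkage time, pause
    entry is entries per total non-pause time (all per minute). Undefined
    frequencies (zero-time denominators) are reported as ``None``, never
    0. With ``experiment_ids`` a mean-of-means per-experiment table is
    attached as well.
    """
    if not phase_sets:
        raise ValueError("need at least one trajectory")
    core = _summary_core(phase_sets)
    total = sum(core["state_time"].values())
    percent = {s: 100.0 * v / total for s, v in core["state_time"].items()}
    rate_mean, rate_sem, wmean, n_events = {}, {}, {}, {}
    for s, vals in core["rates"].items():
        arr = np.asarray(vals)
        n_events[s] = arr.size
        if arr.size:
            rate_mean[s] = float(arr.mean())
            rate_sem[s] = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
            w = np.asarray(core["durs"][s])
            wmean[s] = float(np.average(arr, weights=w))

    per_exp = None
    if experiment_ids is not None:
        if len(experiment_ids) != len(phase_sets):
            raise ValueError("experiment_ids length mismatch")
        per_exp = {}
        for eid in sorted(set(experiment_ids), key=str):
            sub = [ps for ps, e in zip(phase_sets, experiment_ids) if e == eid]
            ecore = _summary_core(sub)
            etotal = sum(ecore["state_time"].values())
            per_exp[str(eid)] = {
                "percent_time": {s: 100.0 * v / etotal for s, v in ecore["state_time"].items()},
                "transition_frequencies": _frequencies(ecore),
                "rate_mean": {
                    s: float(np.mean(v)) for s, v in ecore["rates"].items() if v
                },
            }

    return DynamicsSummary(
        growth_rates={s: np.asarray(v) for s, v in core["rates"].items()},
        rate_mean=rate_mean,
        rate_sem=rate_sem,
        weighted_rate_mean=wmean,
        pause_durations=np.asarray(core["pause_durs"]),
        block_durations=np.clip(np.asarray(core["block_durs"]), None, video_length),
        percent_time=percent,
        transition_frequencies=_frequencies(core),
        n_events=n_events,
        n_trajectories=len(phase_sets),
        total_time=total,
        per_experiment=per_exp,
    )


def weighted_rate_histogram(
    phases: list[Phase], bin_edges: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Duration-weighted growth-rate histogram and cumulative curve.

    Each growth phase contributes its duration divided by the total
    growth time, so weights sum to 1. Returns ``(weights_per_bin,
    sorted_rates, cumulative_weights)``.
    """
    growth = [p for p in phases if p.state in GROWTH_STATES]
    if not growth:
        raise ValueError("no growth events")
    rates = np.array([p.rate for p in growth])
    w = np.array([p.duration for p in growth])
    w = w / w.sum()
    hist, _ = np.histogram(rates, bins=bin_edges, weights=w)
    order = np.argsort(rates, kind="stable")
    return hist, rates[order], np.cumsum(w[order])


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def _dunn_z(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], tuple[float, float]]:
    """Dunn's rank-sum z statistics with tie correction, unadjusted p."""
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n_tot = pooled.size
    ranks = stats.rankdata(pooled)
    mean_rank, sizes, start = {}, {}, 0
    for g in labels:
        n = groups[g].size
        mean_rank[g] = float(ranks[start : start + n].mean())
        sizes[g] = n
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term
    out = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            se = math.sqrt(max(var_base, 0.0) * (1.0 / sizes[a] + 1.0 / sizes[b]))
            if se == 0:
                out[(a, b)] = (0.0, 1.0)
                continue
            z = (mean_rank[a] - mean_rank[b]) / se
            out[(a, b)] = (z, 2.0 * stats.norm.sf(abs(z)))
    return out


def compare_groups(
    samples: dict[str, np.ndarray],
    design: str = "auto",
    control: str | None = None,
    adjust: str = "holm",
) -> dict:
    """Rank-based group comparison matching the figure-legend statistics.

    Two groups: two-sided Mann-Whitney U (exact for small samples).
    Three or more: Kruskal-Wallis H, then Dunn pairwise z tests against
    ``control`` (or all pairs), with Holm multiplicity adjustment by
    default. Degenerate all-identical input returns H = 0, p = 1.
    """
    from statsmodels.stats.multitest import multipletests

    groups = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 1 for g in groups.values()):
        raise ValueError("every group needs n >= 1")
    if design == "auto":
        design = "two-group" if len(groups) == 2 else "multi-group"

    if design == "two-group":
        (la, a), (lb, b) = groups.items()
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return {
            "test": "mann-whitney",
            "groups": [la, lb],
            "U": float(res.statistic),
            "p": float(res.pvalue),
        }

    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):
        h_stat, p_global = 0.0, 1.0
    else:
        h_stat, p_global = stats.kruskal(*groups.values())
    pairs_all = _dunn_z(groups)
    if control is not None:
        if control not in groups:
            raise ValueError(f"control group {control!r} not in samples")
        pairs = {
            k: v for k, v in pairs_all.items() if control in k
        }
    else:
        pairs = pairs_all
    keys = list(pairs)
    raw_p = [pairs[k][1] for k in keys]
    adj_p = multipletests(raw_p, method=adjust)[1] if keys else []
    return {
        "test": "kruskal-dunn",
        "H": float(h_stat),
        "p": float(p_global),
        "posthoc": {
            f"{a} vs {b}": {
                "z": pairs[(a, b)][0],
                "p_raw": pairs[(a, b)][1],
                "p_adj": float(adj_p[i]),
            }
            for i, (a, b) in enumerate(keys)
        },
        "adjustment": adjust,
    }
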