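"""Single-molecule intensity analysis and FRAP recovery fitting.

Spot detection and symmetric 2D Gaussian fitting give integrated
intensities; oligomer number is inferred as the ratio of the
kernel-smoothed intensity-histogram mode of a target set to that of a
monomer reference imaged under matched conditions (the same-coverslip
assumption). FRAP traces are normalized to 1 at the last pre-bleach frame
and 0 at the first post-bleach frame, then fitted with a single
exponential to obtain the recovery rate, half-life and mobile fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal, stats
from skimage.feature import peak_local_max


@dataclass
class SpotRecord:
    """A fitted diffraction-limited spot."""

    x: float  # px, sub-pixel
    y: float  # px
    amplitude: float  # a.u. above offset
    sigma: float  # px
    integrated_intensity: float  # a.u., 2*pi*amplitude*sigma^2
    fit_residual: float = 0.0
    truth_n: int | None = None
    converged: bool = True
    crowded: bool = False

    def __post_init__(self) -> None:
        if self.converged and self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass
class FRAPTrace:
    """Bleach-indexed intensity time series with optional fit results."""

    times: np.ndarray  # s
    intensities: np.ndarray  # a.u.
    bleach_index: int  # frame index of the first post-bleach image
    normalized: np.ndarray | None = None
    fit: dict | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must match in length")
        if not 0 <= self.bleach_index < self.times.size:
            raise ValueError("bleach_index out of range")


# ---------------------------------------------------------------------------
# Spot detection and fitting
# ---------------------------------------------------------------------------

def detect_spots(
    image: np.ndarray,
    threshold_sd: float = 5.0,
    psf_sigma: float = 1.5,
) -> list[dict]:
    """Candidate spot positions: local maxima above background.

    Background mean/s.d. are estimated robustly (median / scaled MAD).
    Non-maximum suppression uses a radius of ``2 * psf_sigma``; a
    candidate with a suppressed neighbour above threshold is flagged
    ``crowded``.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    bg = float(np.median(img))
    bg_sd = 1.4826 * float(np.median(np.abs(img - bg)))
    thr = bg + threshold_sd * max(bg_sd, 1e-12)
    radius = max(int(math.ceil(2 * psf_sigma)), 1)
    peaks = peak_local_max(img, min_distance=radius, threshold_abs=thr)
    dense = peak_local_max(img, min_distance=1, threshold_abs=thr)
    out = []
    for r, c in peaks:
        near = np.hypot(dense[:, 0] - r, dense[:, 1] - c)
        crowded = bool(np.sum(near <= radius) > 1)
        out.append({"row": int(r), "col": int(c), "crowded": crowded})
    return out


def _gauss2d(coords, amp, x0, y0, sigma, offset):
    x, y = coords
    return offset + amp * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2 * sigma**2))


def fit_spot(
    image: np.ndarray,
    position: tuple[int, int],
    psf_sigma_guess: float = 1.5,
    window: int | None = None,
) -> SpotRecord:
    """Least-squares fit of a symmetric 2D Gaussian plus constant offset.

    The fit window spans ``4 * sigma`` (rounded up) around ``position``
    and must lie inside the image. Integrated intensity is
    ``2π · amplitude · sigma²``. Non-converged fits are returned flagged
    (``converged=False``) so callers can exclude them from histograms.
    """
    img = np.asarray(image, dtype=float)
    r0, c0 = int(position[0]), int(position[1])
    half = window if window is not None else int(math.ceil(4 * psf_sigma_guess))
    if r0 - half < 0 or c0 - half < 0 or r0 + half >= img.shape[0] or c0 + half >= img.shape[1]:
        raise ValueError("fit window extends outside the image")
    sub = img[r0 - half : r0 + half + 1, c0 - half : c0 + half + 1]
    xg, yg = np.meshgrid(
        np.arange(r0 - half, r0 + half + 1),
        np.arange(c0 - half, c0 + half + 1),
        indexing="ij",
    )
    offset0 = float(sub.min())
    amp0 = float(sub.max() - offset0)
    p0 = [max(amp0, 1e-6), float(r0), float(c0), psf_sigma_guess, offset0]
    try:
        popt, _ = optimize.curve_fit(
            _gauss2d,
            (xg.ravel(), yg.ravel()),
            sub.ravel(),
            p0=p0,
            bounds=(
                [0, r0 - half, c0 - half, 0.2, -np.inf],
                [np.inf, r0 + half, c0 + half, 4 * half, np.inf],
            ),
            maxfev=2000,
        )
    except RuntimeError:
        return SpotRecord(
            x=float(r0), y=float(c0), amplitude=np.nan, sigma=psf_sigma_guess,
            integrated_intensity=np.nan, fit_residual=np.nan, converged=False,
        )
    amp, x0, y0, sigma, offset = popt
    resid = sub - _gauss2d((xg, yg), *popt)
    return SpotRecord(
        x=float(x0), y=float(y0), amplitude=float(amp), sigma=float(sigma),
        integrated_intensity=float(2 * math.pi * amp * sigma**2),
        fit_residual=float(np.sqrt(np.mean(resid**2))),
    )


def fit_spot_field(image, threshold_sd=5.0, psf_sigma=1.5) -> list[SpotRecord]:
    """Detect then fit every spot in an image, skipping edge candidates."""
    records = []
    half = int(math.ceil(4 * psf_sigma))
    for cand in detect_spots(image, threshold_sd=threshold_sd, psf_sigma=psf_sigma):
        r, c = cand["row"], cand["col"]
        if (
            r - half < 0
            or c - half < 0
            or r + half >= image.shape[0]
            or c + half >= image.shape[1]
        ):
            continue
        rec = fit_spot(image, (r, c), psf_sigma_guess=psf_sigma)
        rec.crowded = cand["crowded"]
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Intensity histograms and stoichiometry
# ---------------------------------------------------------------------------

def intensity_histogram(
    records: list[SpotRecord],
    bins: int | np.ndarray = 50,
    mode_rel_height: float = 0.25,
):
    """Histogram of integrated intensities plus kernel-smoothed modes.

    The density is a Gaussian KDE with Silverman bandwidth; reported
    modes are KDE local maxima at least ``mode_rel_height`` of the global
    peak, ordered by intensity. Requires at least 10 converged records.
    """
    vals = np.array(
        [r.integrated_intensity for r in records if r.converged and np.isfinite(r.integrated_intensity)]
    )
    if vals.size < 10:
        raise ValueError("need at least 10 records for an intensity histogram")
    counts, edges = np.histogram(vals, bins=bins)
    if np.ptp(vals) < 1e-12:  # delta-distributed intensities
        return {"counts": counts, "edges": edges, "modes": [float(vals[0])], "mode": float(vals[0])}
    kde = stats.gaussian_kde(vals, bw_method="silverman")
    grid = np.linspace(vals.min(), vals.max(), 1024)
    dens = kde(grid)
    peaks, _ = signal.find_peaks(dens, height=mode_rel_height * dens.max())
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(dens))])
    modes = [float(grid[p]) for p in peaks]
    primary = float(grid[peaks[np.argmax(dens[peaks])]])
    return {"counts": counts, "edges": edges, "modes": modes, "mode": primary}


def _mode(records: list[SpotRecord]) -> float:
    return intensity_histogram(records)["mode"]


def infer_stoichiometry(
    target: list[SpotRecord],
    monomer_reference: list[SpotRecord],
    n_boot: int = 500,
    seed: int = 0,
    ci: float = 0.95,
) -> dict:
    """Oligomer number of a target set against a monomer standard.

    The estimate is the ratio of intensity-histogram modes, rounded to
    the nearest integer; a bootstrap confidence interval is attached and
    the result is flagged ambiguous when the CI spans two integers.
    Scale-invariant: rescaling all intensities leaves the ratio unchanged.
    """
    ratio = _mode(target) / _mode(monomer_reference)
    rng = np.random.default_rng(seed)
    t_vals = np.array([r.integrated_intensity for r in target if r.converged])
    m_vals = np.array([r.integrated_intensity for r in monomer_reference if r.converged])
    boots = np.empty(n_boot)
    for b in range(n_boot):
        ts = rng.choice(t_vals, size=t_vals.size, replace=True)
        ms = rng.choice(m_vals, size=m_vals.size, replace=True)
        boots[b] = _kde_mode(ts) / _kde_mode(ms)
    lo, hi = np.quantile(boots, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    n = int(round(ratio))
    return {
        "ratio": float(ratio),
        "n": n,
        "ci": (float(lo), float(hi)),
        "ambiguous": int(round(lo)) != int(round(hi)),
    }


def _kde_mode(vals: np.ndarray) -> float:
    if np.ptp(vals) < 1e-12:
        return float(vals[0])
    kde = stats.gaussian_kde(vals, bw_method="silverman")
    grid = np.linspace(vals.min(), vals.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def count_molecules_at_end(
    end_intensity: float,
    monomer_reference: list[SpotRecord],
    n_boot: int = 500,
    seed: int = 0,
    ci: float = 0.95,
) -> dict:
    """Molecule count at a blocked end from its integrated intensity.

    The count is the end intensity divided by the monomer-histogram mode,
    with a bootstrap CI over the monomer reference.
    """
    if not end_intensity > 0:
        raise ValueError("end intensity must be positive")
    mode = _mode(monomer_reference)
    est = end_intensity / mode
    rng = np.random.default_rng(seed)
    m_vals = np.array([r.integrated_intensity for r in monomer_reference if r.converged])
    boots = np.array(
        [
            end_intensity / _kde_mode(rng.choice(m_vals, size=m_vals.size, replace=True))
            for _ in range(n_boot)
        ]
    )
    lo, hi = np.quantile(boots, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    return {"count": float(est), "ci": (float(lo), float(hi))}


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------

def normalize_frap(trace: FRAPTrace, pre_average: int = 1) -> FRAPTrace:
    """Anchor a FRAP trace at 1 (pre-bleach) and 0 (post-bleach).

    ``normalized(t) = (I_t - I_post) / (I_pre - I_post)`` where I_pre is
    the mean of the last ``pre_average`` pre-bleach frames (default: the
    single frame immediately before the bleach) and I_post the first
    post-bleach frame. Affine-invariant in the raw intensities.
    """
    if trace.bleach_index < 1:
        raise ValueError("bleach_index must be >= 1 (need a pre-bleach frame)")
    if pre_average < 1 or pre_average > trace.bleach_index:
        raise ValueError("pre_average out of range")
    i_pre = float(
        trace.intensities[trace.bleach_index - pre_average : trace.bleach_index].mean()
    )
    i_post = float(trace.intensities[trace.bleach_index])
    if math.isclose(i_pre, i_post, rel_tol=0.0, abs_tol=1e-12):
        raise ValueError("no bleach depth: pre- and post-bleach intensities equal")
    norm = (trace.intensities - i_post) / (i_pre - i_post)
    return FRAPTrace(
        times=trace.times,
        intensities=trace.intensities,
        bleach_index=trace.bleach_index,
        normalized=norm,
        fit=trace.fit,
    )


def fit_recovery(
    trace: FRAPTrace,
    no_recovery_plateau: float = 0.05,
) -> dict:
    """Single-exponential recovery fit on the post-bleach samples.

    Fits ``plateau * (1 - exp(-k t'))`` with t' counted from the bleach
    frame. Returns rate ``k`` (s⁻¹), ``half_life = ln2 / k`` (s) and the
    ``plateau`` (mobile fraction). A series with plateau below
    ``no_recovery_plateau`` is classified as no exchange and ``k`` is
    reported absent (None), not 0.
    """
    if trace.normalized is None:
        trace = normalize_frap(trace)
    tp = trace.times[trace.bleach_index :] - trace.times[trace.bleach_index]
    y = trace.normalized[trace.bleach_index :]
    if tp.size < 5:
        raise ValueError("need at least 5 post-bleach frames")

    plateau0 = float(np.clip(np.mean(y[-max(3, y.size // 5) :]), 1e-3, 1.5))
    k0 = 1.0 / max(float(tp[-1]) / 5.0, 1e-6)
    try:
        popt, _ = optimize.curve_fit(
            lambda t, plateau, k: plateau * (1.0 - np.exp(-k * t)),
            tp,
            y,
            p0=[plateau0, k0],
            bounds=([0.0, 0.0], [2.0, np.inf]),
            maxfev=5000,
        )
        plateau, k = float(popt[0]), float(popt[1])
        converged = True
    except RuntimeError:
        plateau, k, converged = float(np.mean(y)), np.nan, False

    if converged and plateau < no_recovery_plateau:
        return {
            "k": None,
            "half_life": None,
            "plateau": plateau,
            "recovered": False,
            "converged": True,
        }
    return {
        "k": k if converged else None,
        "half_life": (math.log(2) / k) if converged and k > 0 else None,
        "plateau": plateau,
        "recovered": converged,
        "converged": converged,
    }
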