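"""UHPLC chromatogram integration and crude-purity computation.

Crude purity — the fraction of total integrated 214 nm absorbance that
belongs to the product peak — is the synthesis-quality readout that the
aggregation factor predicts: suppressed on-resin aggregation shows up
directly as a larger product share of the crude chromatogram.

Integration conventions (simplest defensible set):

* a straight baseline anchored on the first and last 5% of the
  retention-time window, each anchor being the *median* of its edge
  region — the raw minimum of a few hundred noisy samples sits ~2.5
  noise-sd below the true floor, and that offset, multiplied by the
  full valley-to-valley widths, would visibly distort every area
  fraction, while the median is unbiased for a peak-free edge;
* peaks detected on a lightly smoothed copy, as local maxima whose
  prominence exceeds ``k`` x robust noise (default k = 5), with the
  noise scale taken from the median absolute successive difference of
  the raw corrected signal (peak-robust even when peaks crowd the
  window);
* valley-to-valley peak boundaries — each boundary sits at the signal
  minimum between adjacent detected apexes (window edges outermost) —
  trimmed to the contiguous stretch above a noise floor around each
  apex; drop-line integration is not implemented;
* trapezoidal areas above the baseline (signed, so zero-mean noise
  cancels instead of rectifying into spurious area); peaks below a
  minimum area fraction (default 0.1%) are dropped as noise spikes and
  the remaining fractions renormalized.

The product peak is identified by retention time, never by mass —
mass annotation is the peptide-mass module's job.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .exceptions import IntegrationError
from .trace_io import Chromatogram

__all__ = [
    "IntegrationParams",
    "PeakTableEntry",
    "PurityResult",
    "integrate_chromatogram",
    "crude_purity",
    "peak_table_frame",
]


@dataclass(frozen=True)
class IntegrationParams:
    """Integration settings; echoed into every PurityResult."""

    t0_min: float | None = None
    t1_min: float | None = None
    prominence_k: float = 5.0
    min_area_fraction: float = 0.001
    #: Savitzky–Golay span (min) for detection/integration; baseline
    #: anchoring uses 5x this span
    smooth_span_min: float = 0.025

    def to_dict(self) -> dict:
        return {
            "t0_min": self.t0_min,
            "t1_min": self.t1_min,
            "prominence_k": self.prominence_k,
            "min_area_fraction": self.min_area_fraction,
            "smooth_span_min": self.smooth_span_min,
        }


@dataclass(frozen=True)
class PeakTableEntry:
    rt_min: float
    height_au: float
    area_au_min: float
    area_fraction: float
    is_product: bool = False


@dataclass(frozen=True)
class PurityResult:
    crude_purity_percent: float
    product_rt_min: float
    n_peaks_integrated: int
    params: IntegrationParams = field(default_factory=IntegrationParams)

    def __post_init__(self) -> None:
        if not 0.0 <= self.crude_purity_percent <= 100.0:
            raise IntegrationError("purity must be within [0, 100]%")

    def to_dict(self) -> dict:
        return {
            "crude_purity_percent": round(self.crude_purity_percent, 2),
            "product_rt_min": self.product_rt_min,
            "n_peaks_integrated": self.n_peaks_integrated,
            "integration_params": self.params.to_dict(),
        }


def _robust_noise(y: np.ndarray) -> float:
    """Noise sigma from the median absolute successive difference."""
    d = np.diff(y)
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def _smooth(y: np.ndarray, dt: float, span: float) -> tuple[np.ndarray, float]:
    """Savitzky–Golay smoothed copy and the white-noise gain of its kernel."""
    from scipy.signal import savgol_coeffs, savgol_filter

    n = max(5, int(round(span / dt)))
    n += 1 - n % 2
    n = min(n, len(y) - (1 - len(y) % 2))
    gain = float(np.sqrt(np.sum(savgol_coeffs(n, 2) ** 2)))
    return savgol_filter(y, n, 2), gain


def integrate_chromatogram(
    chrom: Chromatogram, params: IntegrationParams | None = None
) -> list[PeakTableEntry]:
    """Detect and integrate peaks; return the peak table.

    Raises
    ------
    IntegrationError
        ``"no peaks detected"`` when the window is empty or nothing
        exceeds the prominence threshold.
    """
    if params is None:
        params = IntegrationParams()
    t = chrom.time_min
    y = chrom.absorbance_au
    t0 = params.t0_min if params.t0_min is not None else t[0]
    t1 = params.t1_min if params.t1_min is not None else t[-1]
    sel = (t >= t0) & (t <= t1)
    if sel.sum() < 10:
        raise IntegrationError("no peaks detected: empty integration window")
    t = t[sel]
    y = y[sel]

    dt = float(np.median(np.diff(t)))
    ys, noise_gain = _smooth(y, dt, params.smooth_span_min)

    # straight baseline anchored on the first/last 5% of the window;
    # each anchor is the median of its edge region — the minimum of a
    # few hundred noisy samples sits ~2.5 noise-sd below the floor and
    # would rectify into spurious area across every valley-to-valley
    # slice, whereas the median is unbiased for a peak-free edge
    k = max(2, int(round(0.05 * len(y))))
    ta, ya = float(np.mean(t[:k])), float(np.median(y[:k]))
    tb, yb = float(np.mean(t[-k:])), float(np.median(y[-k:]))
    baseline = ya + (yb - ya) * (t - ta) / (tb - ta)
    yc = ys - baseline

    noise = _robust_noise(y - baseline)
    prominence = max(params.prominence_k * noise, 1e-9 * max(yc.max(), 1e-30))
    apexes, _ = find_peaks(yc, prominence=prominence)
    if len(apexes) == 0:
        raise IntegrationError("no peaks detected")

    # valley-to-valley boundaries ...
    bounds = [0]
    for a, b in zip(apexes, apexes[1:]):
        bounds.append(a + int(np.argmin(yc[a:b])))
    bounds.append(len(yc) - 1)

    # ... trimmed to the contiguous above-floor stretch around each
    # apex, so empty gap stretches do not multiply any residual
    # baseline-anchor error into the areas; the floor is 2x the noise
    # of the smoothed trace actually scanned
    entries = []
    for i, apex in enumerate(apexes):
        lo, hi = bounds[i], bounds[i + 1]
        floor = max(2.0 * noise * noise_gain, 1e-12 * yc[apex])
        i0 = apex
        while i0 > lo and yc[i0 - 1] > floor:
            i0 -= 1
        i1 = apex
        while i1 < hi and yc[i1 + 1] > floor:
            i1 += 1
        area = float(np.trapezoid(yc[i0 : i1 + 1], t[i0 : i1 + 1]))
        if area <= 0:
            continue
        entries.append((float(t[apex]), float(yc[apex]), area))
    if not entries:
        raise IntegrationError("no peaks detected")

    total = sum(a for _, _, a in entries)
    entries = [e for e in entries if e[2] / total >= params.min_area_fraction]
    if not entries:
        raise IntegrationError("no peaks detected")
    total = sum(a for _, _, a in entries)  # renormalize after dropping

    return [
        PeakTableEntry(rt_min=rt, height_au=h, area_au_min=a, area_fraction=a / total)
        for rt, h, a in entries
    ]


def crude_purity(
    table: list[PeakTableEntry],
    product_rt_min: float,
    rt_tol_min: float = 0.1,
    params: IntegrationParams | None = None,
) -> PurityResult:
    """Crude purity = 100 x product peak area / total integrated area.

    Exactly one table entry must fall within ``product_rt_min ±
    rt_tol_min``; zero or several candidates raise an error naming
    them, rather than silently picking one.
    """
    candidates = [e for e in table if abs(e.rt_min - product_rt_min) <= rt_tol_min]
    if len(candidates) != 1:
        rts = ", ".join(f"{e.rt_min:.3f}" for e in candidates) or "none"
        raise IntegrationError(
            f"{len(candidates)} candidate product peaks within "
            f"{product_rt_min} ± {rt_tol_min} min (candidates: {rts})"
        )
    product = candidates[0]
    return PurityResult(
        crude_purity_percent=100.0 * product.area_fraction,
        product_rt_min=product.rt_min,
        n_peaks_integrated=len(table),
        params=params or IntegrationParams(),
    )


def peak_table_frame(table: list[PeakTableEntry], product_rt_min: float | None = None,
                     rt_tol_min: float = 0.1) -> pd.DataFrame:
    """Peak table as a DataFrame, optionally marking the product peak."""
    df = pd.DataFrame(
        {
            "rt_min": [e.rt_min for e in table],
            "height_au": [e.height_au for e in table],
            "area_au_min": [e.area_au_min for e in table],
            "area_fraction": [e.area_fraction for e in table],
        }
    )
    if product_rt_min is not None:
        df["is_product"] = (df["rt_min"] - product_rt_min).abs() <= rt_tol_min
    return df
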