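"""Synthetic flow-SPPS traces and UHPLC chromatograms with known truth.

Real runs live in instrument archives; every downstream stage of this
package is instead exercised on simulated data whose ground truth is
known exactly.  The deprotection-trace generator emulates what in-line
310 nm monitoring shows during a synthesis:

* one transient deprotection peak per residue, centered in its cycle
  window;
* after a programmable aggregation-onset residue, peak width grows
  geometrically (``w_i = w·(1+g)^(i−onset+1)``, the whole time profile
  dilating) while the deprotection yield attenuates the area
  (``area_i = area_{i−1}·yield``) — so peaks broaden *and* flatten,
  the signature the aggregation factor reads;
* an optional single "slow-coupling" residue whose peak is widened
  without starting an onset (emulating a deliberately cold Cys
  coupling), to exercise the exclusion logic;
* Gaussian detector noise and a linear baseline drift.

Peak shapes are either Gaussian or, by default for realism,
exponentially modified Gaussian (EMG) — flow dispersion in the
detector line skews real deprotection peaks toward a tailing edge.
Both are evaluated as unit-area densities and scaled by the target
area, so area bookkeeping is exact by construction.

Ground-truth width/height are measured on a fine noiseless grid
(step ≤ dt/20) with the same half-height-crossing definition the
analysis uses, making the generator a self-contained oracle.

Presets: ``afps`` (fast-flow synthesizer, ~3 min cycles) and
``peptipilot`` (economical larger-scale platform, ~60 min cycles);
the analysis path is identical for both.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.stats import exponnorm, norm

from .exceptions import SimulationError
from .trace_io import (
    Chromatogram,
    CycleSchedule,
    CycleWindow,
    UVTrace,
    write_chromatogram,
    write_cycle_schedule,
    write_uv_trace,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ChromatogramTruth",
    "simulate_deprotection_trace",
    "simulate_chromatogram",
    "make_fixture_sequences",
    "synthesis_labels",
    "write_run",
    "read_ground_truth",
    "GLP1_7_37",
]

#: standard human GLP-1[7–37] sequence (N→C), free-acid C-terminus
GLP1_7_37 = "HAEGTFTSDVSSYLEGQAAKEFIAWLVKGRG"

PRESETS = {
    "afps": {"cycle_duration_s": 180.0},
    "peptipilot": {"cycle_duration_s": 3600.0},
}


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate one synthetic deprotection run.

    Parameters
    ----------
    sequence_labels : tuple of str
        Residue labels in synthesis (C→N coupling) order.
    cycle_duration_s : float
        Seconds per residue cycle (180 for the fast-flow preset,
        3600 for the pilot-scale preset).
    peak_model : {"emg", "gaussian"}
        EMG by default — flow dispersion skews real peaks.
    base_sigma_s, emg_tau_s, base_height_au :
        Unaggregated peak shape: Gaussian width, exponential tail time
        constant (EMG only) and apex height of the first peak.
    onset_index : int or None
        Synthesis-order index at which aggregation begins (widening
        applies from this residue on), or None for a clean run.
    broadening_rate : float
        Per-residue multiplicative width growth g ≥ 0 after onset.
    yield_per_residue : float
        Area retention factor in (0, 1] applied per residue from onset.
    slow_coupling_index : int or None
        Single residue whose peak is widened by
        ``slow_coupling_width_factor`` (area preserved) without any
        onset — the cold-Cys artifact.
    noise_sd_au, baseline_slope_au_per_s, dt_s, seed :
        Detector noise, linear drift, sampling interval and RNG seed
        (mandatory: no silent nondeterminism).
    """

    sequence_labels: tuple[str, ...]
    cycle_duration_s: float = 180.0
    peak_model: str = "emg"
    base_sigma_s: float = 2.0
    emg_tau_s: float = 3.0
    base_height_au: float = 1.0
    onset_index: int | None = None
    broadening_rate: float = 0.15
    yield_per_residue: float = 0.97
    slow_coupling_index: int | None = None
    slow_coupling_width_factor: float = 2.5
    noise_sd_au: float = 0.0
    baseline_slope_au_per_s: float = 0.0
    dt_s: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence_labels) < 1:
            raise SimulationError("sequence_labels must be non-empty")
        if len(set(self.sequence_labels)) != len(self.sequence_labels):
            raise SimulationError("sequence_labels must be unique")
        if self.cycle_duration_s <= 0:
            raise SimulationError("cycle_duration_s must be > 0")
        if self.dt_s <= 0:
            raise SimulationError("dt_s must be > 0")
        if self.dt_s > self.base_sigma_s / 5:
            raise SimulationError(
                "dt_s must be <= base_sigma_s/5 so peaks are resolvable"
            )
        if self.base_height_au <= 0:
            raise SimulationError("base_height_au must be > 0")
        if self.peak_model not in ("gaussian", "emg"):
            raise SimulationError(f"unknown peak_model {self.peak_model!r}")
        if self.peak_model == "emg" and self.emg_tau_s <= 0:
            raise SimulationError("emg_tau_s must be > 0")
        if self.onset_index is not None and not (
            0 <= self.onset_index < len(self.sequence_labels)
        ):
            raise SimulationError("onset_index outside sequence")
        if self.slow_coupling_index is not None and not (
            0 <= self.slow_coupling_index < len(self.sequence_labels)
        ):
            raise SimulationError("slow_coupling_index outside sequence")
        if self.broadening_rate < 0:
            raise SimulationError("broadening_rate must be >= 0")
        if not 0 < self.yield_per_residue <= 1:
            raise SimulationError("yield_per_residue must be in (0, 1]")
        if self.noise_sd_au < 0:
            raise SimulationError("noise_sd_au must be >= 0")
        object.__setattr__(self, "sequence_labels", tuple(self.sequence_labels))

    @classmethod
    def preset(cls, name: str, sequence_labels, **overrides) -> "SimulationConfig":
        """Build a config from an instrument preset (afps | peptipilot)."""
        if name not in PRESETS:
            raise SimulationError(f"unknown preset {name!r} (have {sorted(PRESETS)})")
        kw = dict(PRESETS[name])
        kw.update(overrides)
        return cls(sequence_labels=tuple(sequence_labels), **kw)


@dataclass(frozen=True)
class GroundTruth:
    """Per-residue true peak metrics of a simulated run (test oracle)."""

    labels: tuple[str, ...]
    w_true_s: tuple[float, ...]
    h_true_au: tuple[float, ...]
    area_true_au_s: tuple[float, ...]
    onset_label: str | None = None
    slow_coupling_label: str | None = None

    def __post_init__(self) -> None:
        n = len(self.labels)
        if not (len(self.w_true_s) == len(self.h_true_au) == len(self.area_true_au_s) == n):
            raise SimulationError("ground-truth arrays must match sequence length")
        if any(w <= 0 for w in self.w_true_s) or any(h <= 0 for h in self.h_true_au):
            raise SimulationError("true widths and heights must be positive")

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "w_true_s": list(self.w_true_s),
            "h_true_au": list(self.h_true_au),
            "area_true_au_s": list(self.area_true_au_s),
            "onset_label": self.onset_label,
            "slow_coupling_label": self.slow_coupling_label,
        }


def _unit_peak(t: np.ndarray, mu: float, sigma: float, tau: float | None) -> np.ndarray:
    """Unit-area peak density at times t."""
    if tau is None:
        return norm.pdf(t, loc=mu, scale=sigma)
    return exponnorm.pdf(t, K=tau / sigma, loc=mu, scale=sigma)


def _residue_shapes(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue (width_scale_i, area_i) under the aggregation model.

    Broadening dilates the whole time profile of the peak (both the
    Gaussian core and, for EMG, the exponential tail) by the same
    factor, so the FWHM grows by exactly (1+g) per aggregated residue
    whatever the shape — g is a *width* growth rate, and slowed
    deprotection kinetics stretch the entire release transient.
    """
    n = len(config.sequence_labels)
    tau = config.emg_tau_s if config.peak_model == "emg" else None
    # area that puts the unaggregated apex at base_height_au
    fine = np.arange(-10 * config.base_sigma_s,
                     10 * config.base_sigma_s + 8 * (tau or 0.0), 1e-3)
    peak_max = float(_unit_peak(fine, 0.0, config.base_sigma_s, tau).max())
    base_area = config.base_height_au / peak_max
    scale = np.ones(n)
    area = np.full(n, base_area)
    if config.onset_index is not None:
        g = config.broadening_rate
        for i in range(config.onset_index, n):
            k = i - config.onset_index + 1
            scale[i] = (1.0 + g) ** k
            area[i] = area[i - 1] * config.yield_per_residue if i > 0 else base_area * config.yield_per_residue
    if config.slow_coupling_index is not None:
        scale[config.slow_coupling_index] *= config.slow_coupling_width_factor
    return scale, area


def _measure_fine(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(height, FWHM) of a noiseless peak by half-height crossings."""
    imax = int(np.argmax(y))
    h = float(y[imax])
    half = h / 2.0
    below_left = np.flatnonzero(y[:imax] < half)
    below_right = np.flatnonzero(y[imax:] < half)
    if len(below_left) == 0 or len(below_right) == 0:
        raise SimulationError("peak exceeds cycle window")
    i = below_left[-1]
    tl = t[i] + (half - y[i]) * (t[i + 1] - t[i]) / (y[i + 1] - y[i])
    j = imax + below_right[0]
    tr = t[j - 1] + (half - y[j - 1]) * (t[j] - t[j - 1]) / (y[j] - y[j - 1])
    return h, float(tr - tl)


def simulate_deprotection_trace(
    config: SimulationConfig,
) -> tuple[UVTrace, CycleSchedule, GroundTruth]:
    """Generate one synthetic run: trace, schedule and ground truth.

    Raises
    ------
    SimulationError
        ``"peak exceeds cycle window"`` when a (possibly broadened)
        peak no longer fits its cycle — its tails would leak into the
        neighbouring window beyond 0.1% of the apex.
    """
    n = len(config.sequence_labels)
    cyc = config.cycle_duration_s
    dt = config.dt_s
    base_tau = config.emg_tau_s if config.peak_model == "emg" else None
    scale, area = _residue_shapes(config)

    n_samples = int(round(n * cyc / dt))
    t = np.arange(n_samples) * dt
    clean = np.zeros(n_samples)

    w_true, h_true = [], []
    fine_dt = dt / 20.0
    for i in range(n):
        start, end = i * cyc, (i + 1) * cyc
        mu = start + cyc / 2.0
        sel = (t >= start) & (t < end)
        sigma_i = config.base_sigma_s * scale[i]
        tau_i = base_tau * scale[i] if base_tau is not None else None
        peak_samples = area[i] * _unit_peak(t[sel], mu, sigma_i, tau_i)
        # fine-grid noiseless oracle for this residue
        tf = np.arange(start, end, fine_dt)
        yf = area[i] * _unit_peak(tf, mu, sigma_i, tau_i)
        apex = float(yf.max())
        if yf[0] > 1e-3 * apex or yf[-1] > 1e-3 * apex:
            raise SimulationError(
                f"peak exceeds cycle window at residue {config.sequence_labels[i]}"
            )
        h, w = _measure_fine(tf, yf)
        w_true.append(w)
        h_true.append(h)
        clean[sel] += peak_samples

    rng = np.random.default_rng(config.seed)
    y = clean + config.baseline_slope_au_per_s * t
    if config.noise_sd_au > 0:
        y = y + rng.normal(0.0, config.noise_sd_au, size=n_samples)

    trace = UVTrace(
        time_s=t,
        absorbance_au=y,
        wavelength_nm=310.0,
        run_id=f"sim-seed{config.seed}",
    )
    schedule = CycleSchedule(
        tuple(
            CycleWindow(label, i, i * cyc, (i + 1) * cyc)
            for i, label in enumerate(config.sequence_labels)
        )
    )
    truth = GroundTruth(
        labels=config.sequence_labels,
        w_true_s=tuple(w_true),
        h_true_au=tuple(h_true),
        area_true_au_s=tuple(area),
        onset_label=(
            config.sequence_labels[config.onset_index]
            if config.onset_index is not None
            else None
        ),
        slow_coupling_label=(
            config.sequence_labels[config.slow_coupling_index]
            if config.slow_coupling_index is not None
            else None
        ),
    )
    return trace, schedule, truth


@dataclass(frozen=True)
class ChromatogramTruth:
    """Known composition of a simulated chromatogram."""

    rt_min: tuple[float, ...]
    area_fractions: tuple[float, ...]
    product_index: int
    purity_percent: float


def simulate_chromatogram(
    components: list[tuple[float, float, float]],
    total_area: float = 1.0,
    dt_min: float = 0.002,
    noise_sd_au: float | None = None,
    product_index: int = 0,
    seed: int = 0,
    allow_overlap: bool = False,
) -> tuple[Chromatogram, ChromatogramTruth]:
    """Simulate a UHPLC chromatogram from known components.

    Parameters
    ----------
    components : list of (retention_time_min, area_fraction, sigma_min)
        Gaussian components; fractions must sum to 1 (±1e-9) and
        retention times must be separated by ≥ 3·(σ_a + σ_b) unless
        ``allow_overlap``.
    noise_sd_au : float, optional
        Detector noise; default 0.5% of the tallest component apex.
    """
    if not components:
        raise SimulationError("need at least one component")
    fracs = np.array([c[1] for c in components], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise SimulationError(f"area fractions sum to {fracs.sum()}, not 1")
    if np.any(fracs <= 0):
        raise SimulationError("area fractions must be positive")
    if not 0 <= product_index < len(components):
        raise SimulationError("product_index outside components")
    by_rt = sorted(components, key=lambda c: c[0])
    if not allow_overlap:
        for (rta, _, sa), (rtb, _, sb) in zip(by_rt, by_rt[1:]):
            if rtb - rta < 3.0 * (sa + sb):
                raise SimulationError(
                    f"overlapping components at {rta} and {rtb} min "
                    "(separation < 3·(σ_a+σ_b)); pass allow_overlap=True to force"
                )

    sigmas = np.array([c[2] for c in components], dtype=float)
    if np.any(sigmas <= 0):
        raise SimulationError("component sigmas must be positive")
    pad = max(1.0, 6.0 * float(sigmas.max()))
    t0 = max(0.0, min(c[0] for c in components) - pad)
    t1 = max(c[0] for c in components) + pad
    t = np.arange(t0, t1 + dt_min / 2, dt_min)
    y = np.zeros_like(t)
    heights = []
    for rt, frac, s in components:
        a = frac * total_area
        y += a * norm.pdf(t, loc=rt, scale=s)
        heights.append(a / (s * np.sqrt(2 * np.pi)))
    if noise_sd_au is None:
        noise_sd_au = 0.005 * max(heights)
    if noise_sd_au > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd_au, size=len(t))

    chrom = Chromatogram(
        time_min=t, absorbance_au=y, wavelength_nm=214.0, sample_id=f"sim-seed{seed}"
    )
    truth = ChromatogramTruth(
        rt_min=tuple(c[0] for c in components),
        area_fractions=tuple(fracs),
        product_index=product_index,
        purity_percent=100.0 * float(fracs[product_index]),
    )
    return chrom, truth


def synthesis_labels(sequence: str, first_residue_number: int) -> tuple[str, ...]:
    """Residue labels in synthesis (C→N) order for a numbered fragment.

    ``sequence`` is given N→C; residue i gets parent-protein number
    ``first_residue_number + i``, and the synthesis starts from the
    C-terminal residue, so labels come out reversed — e.g. a [75–90]
    fragment starts its synthesis at residue 90.
    """
    labels = [f"{aa}{first_residue_number + i}" for i, aa in enumerate(sequence)]
    return tuple(reversed(labels))


def make_fixture_sequences(
    barstar_75_90: str | None = None,
    myc_123_143: str | None = None,
):
    """Named peptide fixtures, tagged and untagged.

    GLP-1[7–37] (standard human sequence, free acid) is built in;
    the Barstar[75–90] and MYC[123–143] fragments must be supplied by
    the caller (their exact sequences are not bundled) and are then
    returned alongside their ArgTag variants.
    """
    from .peptide_mass import append_argtag, parse_sequence

    out = {}
    glp1 = parse_sequence(GLP1_7_37, c_terminus="acid", label="GLP-1[7-37]")
    out["GLP-1[7-37]"] = glp1
    out["GLP-1[7-37]-ArgTag"] = append_argtag(glp1, n=6)
    if barstar_75_90 is not None:
        b = parse_sequence(barstar_75_90, c_terminus="acid", label="Barstar[75-90]")
        out["Barstar[75-90]"] = b
        out["Barstar[75-90]-ArgTag"] = append_argtag(b, n=6)
    if myc_123_143 is not None:
        m = parse_sequence(myc_123_143, c_terminus="acid", label="MYC[123-143]")
        out["MYC[123-143]"] = m
        out["MYC[123-143]-ArgTag"] = append_argtag(m, n=6)
    return out


def write_run(
    trace: UVTrace,
    schedule: CycleSchedule,
    truth: GroundTruth,
    outdir: str | Path,
) -> dict:
    """Emit trace CSV, schedule CSV and ground-truth JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trace": outdir / "trace.csv",
        "schedule": outdir / "schedule.csv",
        "truth": outdir / "truth.json",
    }
    write_uv_trace(trace, paths["trace"])
    write_cycle_schedule(schedule, paths["schedule"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth.to_dict(), fh, indent=2)
    return {k: str(v) for k, v in paths.items()}


def read_ground_truth(path: str | Path) -> GroundTruth:
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    return GroundTruth(
        labels=tuple(d["labels"]),
        w_true_s=tuple(d["w_true_s"]),
        h_true_au=tuple(d["h_true_au"]),
        area_true_au_s=tuple(d["area_true_au_s"]),
        onset_label=d.get("onset_label"),
        slow_coupling_label=d.get("slow_coupling_label"),
    )
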