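"""Model/Results interface over the monitoring pipeline.

:class:`AggregationMonitor` is built from one run's data (UV trace +
cycle schedule) plus analysis settings; ``fit()`` performs baseline
correction, per-residue peak measurement, AF computation and onset
calling, returning an :class:`AggregationResults` that carries the peak
table, the AF profile, the onset call and a ``summary()`` table.
:class:`PurityModel` does the same for a UHPLC chromatogram.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import aggregation_factor as af_mod
from . import peak_analysis, purity, trace_io
from .aggregation_factor import AggregationProfile
from .purity import IntegrationParams, PurityResult

__all__ = ["AggregationMonitor", "AggregationResults", "PurityModel", "PurityResults"]


class AggregationMonitor:
    """Aggregation monitoring of one flow-SPPS run.

    Parameters
    ----------
    trace : UVTrace
        In-line 310 nm deprotection trace.
    schedule : CycleSchedule
        Mapping of trace time windows to residues (synthesis order).
    reference_label : str
        Residue to normalize width and height to; pick an early,
        clearly unaggregated cycle.
    exclusions : tuple of str
        Residues (e.g. a cold Cys coupling) flagged and skipped by
        onset calling.
    theta, m, baseline_n :
        Onset rule: first residue whose AF ≥ ``theta`` for ``m``
        consecutive residues, never within the first ``baseline_n``.
    convention : {"per-metric", "ratio"}
        AF normalization convention.

    Examples
    --------
    >>> model = AggregationMonitor(trace, schedule, reference_label="L89")
    >>> res = model.fit()
    >>> res.onset_label
    'T86'
    >>> print(res.summary())  # doctest: +SKIP
    """

    def __init__(
        self,
        trace: trace_io.UVTrace,
        schedule: trace_io.CycleSchedule,
        reference_label: str,
        exclusions: tuple[str, ...] = (),
        theta: float = af_mod.DEFAULT_THETA,
        m: int = af_mod.DEFAULT_PERSISTENCE,
        baseline_n: int = af_mod.DEFAULT_BASELINE_N,
        convention: str = "per-metric",
        name: str = "",
    ) -> None:
        self.trace = trace
        self.schedule = schedule
        self.reference_label = reference_label
        self.exclusions = tuple(exclusions)
        self.theta = theta
        self.m = m
        self.baseline_n = baseline_n
        self.convention = convention
        self.name = name or trace.run_id

    @classmethod
    def from_csv(
        cls, trace_path, schedule_path, reference_label: str, **kwargs
    ) -> "AggregationMonitor":
        """Build a monitor from trace and schedule CSV files."""
        return cls(
            trace_io.read_uv_trace(trace_path),
            trace_io.read_cycle_schedule(schedule_path),
            reference_label,
            **kwargs,
        )

    def config_dict(self) -> dict:
        return {
            "reference_label": self.reference_label,
            "exclusions": list(self.exclusions),
            "theta": self.theta,
            "m": self.m,
            "baseline_n": self.baseline_n,
            "convention": self.convention,
        }

    def fit(self) -> "AggregationResults":
        """Run the full analysis and return the results object."""
        peaks, failures = peak_analysis.analyze_run(
            self.trace, self.schedule, exclusions=self.exclusions
        )
        profile = af_mod.compute_af(
            peaks, self.reference_label, convention=self.convention, name=self.name
        )
        profile = af_mod.with_onset(profile, self.theta, self.m, self.baseline_n)
        return AggregationResults(
            model=self, peaks=peaks, failures=failures, profile=profile
        )


@dataclass
class AggregationResults:
    """Fitted per-residue peak metrics, AF profile and onset call."""

    model: AggregationMonitor
    peaks: list
    failures: list
    profile: AggregationProfile

    @property
    def onset_label(self) -> str | None:
        return self.profile.onset_label

    def to_frame(self) -> pd.DataFrame:
        """Peak metrics joined with the AF profile, one row per residue."""
        rows = []
        af_by_label = dict(zip(self.profile.labels, self.profile.af))
        for p in sorted(self.peaks, key=lambda q: q.cycle_index):
            rows.append(
                {
                    "residue_label": p.residue_label,
                    "cycle_index": p.cycle_index,
                    "apex_time_s": p.apex_time_s,
                    "height_au": p.height_au,
                    "fwhm_s": p.fwhm_s,
                    "area_au_s": p.area_au_s,
                    "af": af_by_label.get(p.residue_label),
                    "flags": ";".join(sorted(p.flags)),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable run summary."""
        df = self.to_frame()
        lines = [
            "Aggregation monitoring summary",
            "==============================",
            f"run:            {self.model.name or '(unnamed)'}",
            f"residues:       {len(df)} analyzed, {len(self.failures)} failed",
            f"reference:      {self.model.reference_label}",
            f"AF convention:  {self.model.convention}",
            f"onset rule:     theta={self.model.theta}, m={self.model.m}, "
            f"baseline_n={self.model.baseline_n}",
            f"onset residue:  {self.onset_label or 'none (no aggregation called)'}",
            "",
            df.to_string(
                index=False,
                float_format=lambda v: f"{v:.4f}",
                columns=[
                    "residue_label",
                    "height_au",
                    "fwhm_s",
                    "area_au_s",
                    "af",
                    "flags",
                ],
            ),
        ]
        if self.failures:
            lines.append("")
            lines.append("failed windows:")
            lines.extend(f"  {l}: {r}" for l, r in self.failures)
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "config": self.model.config_dict(),
            "onset_label": self.onset_label,
            "reference_label": self.profile.reference_label,
            "excluded_labels": sorted(self.profile.excluded_labels),
            "n_peaks": len(self.peaks),
            "failures": [{"residue_label": l, "reason": r} for l, r in self.failures],
        }

    def save(self, outdir: str | Path) -> dict:
        """Write peak table CSV, AF profile CSV and onset JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "peak_table": outdir / "peak_table.csv",
            "af_profile": outdir / "af_profile.csv",
            "onset": outdir / "onset.json",
        }
        trace_io.write_peak_table(self.peaks, paths["peak_table"])
        self.profile.to_frame().to_csv(paths["af_profile"], index=False, float_format="%.17g")
        with open(paths["onset"], "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)
        return {k: str(v) for k, v in paths.items()}

    def plot(self, ax=None):
        """AF-vs-residue plot with onset annotation."""
        from .plotting import plot_aggregation_profile

        return plot_aggregation_profile(self.profile, ax=ax)


class PurityModel:
    """Crude-purity analysis of one UHPLC chromatogram.

    The product peak is identified by retention time within
    ``rt_tol_min``; crude purity is its share of total integrated
    area, in percent.
    """

    def __init__(
        self,
        chromatogram: trace_io.Chromatogram,
        product_rt_min: float,
        rt_tol_min: float = 0.1,
        params: IntegrationParams | None = None,
    ) -> None:
        self.chromatogram = chromatogram
        self.product_rt_min = product_rt_min
        self.rt_tol_min = rt_tol_min
        self.params = params or IntegrationParams()

    @classmethod
    def from_csv(cls, path, product_rt_min: float, **kwargs) -> "PurityModel":
        return cls(trace_io.read_chromatogram(path), product_rt_min, **kwargs)

    def fit(self) -> "PurityResults":
        table = purity.integrate_chromatogram(self.chromatogram, self.params)
        result = purity.crude_purity(
            table, self.product_rt_min, self.rt_tol_min, params=self.params
        )
        return PurityResults(model=self, table=table, result=result)


@dataclass
class PurityResults:
    """Integrated peak table plus the crude-purity readout."""

    model: PurityModel
    table: list
    result: PurityResult

    @property
    def crude_purity_percent(self) -> float:
        return self.result.crude_purity_percent

    def to_frame(self) -> pd.DataFrame:
        return purity.peak_table_frame(
            self.table, self.model.product_rt_min, self.model.rt_tol_min
        )

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "Crude purity summary",
            "====================",
            f"sample:         {self.model.chromatogram.sample_id or '(unnamed)'}",
            f"peaks:          {len(df)} integrated",
            f"product RT:     {self.result.product_rt_min:.3f} min "
            f"(searched {self.model.product_rt_min} ± {self.model.rt_tol_min} min)",
            f"crude purity:   {self.result.crude_purity_percent:.1f} %",
            "",
            df.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "peak_table": outdir / "uhplc_peak_table.csv",
            "purity": outdir / "purity.json",
        }
        self.to_frame().to_csv(paths["peak_table"], index=False, float_format="%.17g")
        with open(paths["purity"], "w", encoding="utf-8") as fh:
            json.dump(self.result.to_dict(), fh, indent=2)
        return {k: str(v) for k, v in paths.items()}

    def plot(self, ax=None):
        from .plotting import plot_chromatogram

        return plot_chromatogram(self.model.chromatogram, self.table, ax=ax)
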