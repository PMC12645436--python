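"""The per-residue aggregation factor (AF) and aggregation-onset calling.

On-resin aggregation (β-sheet association of the growing protected
chains) broadens and flattens the Fmoc-deprotection peak, so the AF
combines peak width minus peak height into a single per-residue
descriptor: low AF means efficient deprotection on a well-solvated
resin, rising AF means aggregation.

Units reconciliation.  Width carries time units and height absorbance
units, so a raw ``w − h`` would depend on arbitrary instrument scales
(flow rate, path length, detector gain).  The default convention here
makes both commensurate by normalizing each to a reference residue
chosen before any aggregation starts (synthesis runs C→N, so the
reference is an early residue, e.g. L89 of a [75–90] fragment):

    AF_i = w_i / w_ref − h_i / h_ref

which is dimensionless, exactly 0 at the reference, invariant under
any uniform rescaling of either axis, and positive when peaks broaden
and flatten.  The alternative convention — divide the raw difference
by its reference value, AF_i = (w_i − h_i)/(w_ref − h_ref) — is kept
behind ``convention="ratio"`` (reference value 1, sign pinned to the
reference's own sign, not scale-free; not recommended).

Onset is called by threshold-plus-persistence, not by a derivative:
the first residue (synthesis order, skipping excluded residues) whose
AF reaches ``theta`` and *stays* there for ``m`` consecutive residues.
Persistence rejects single-cycle artifacts such as the deliberately
cold, slow Cys coupling, whose broadened peak is not an aggregation
event.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import AnalysisError
from .peak_analysis import FLAG_LOW_SNR, FLAG_SLOW_COUPLING, DeprotectionPeak

__all__ = [
    "AggregationProfile",
    "ProfileComparison",
    "compute_af",
    "detect_onset",
    "compare_profiles",
]

DEFAULT_THETA = 0.2
DEFAULT_PERSISTENCE = 2
DEFAULT_BASELINE_N = 3

#: categorical delay reported when a variant never aggregates but the
#: baseline does
SUPPRESSED = "suppressed"


@dataclass(frozen=True)
class AggregationProfile:
    """Per-residue normalized AF series in synthesis (C→N) order."""

    labels: tuple[str, ...]
    af: np.ndarray
    reference_label: str
    onset_label: str | None = None
    excluded_labels: frozenset = frozenset()
    name: str = ""

    def __post_init__(self) -> None:
        af = np.asarray(self.af, dtype=float)
        if len(af) != len(self.labels):
            raise AnalysisError("labels and af must have equal length")
        if self.reference_label not in self.labels:
            raise AnalysisError(f"reference {self.reference_label!r} not in profile")
        object.__setattr__(self, "af", af)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "excluded_labels", frozenset(self.excluded_labels))

    def __len__(self) -> int:
        return len(self.labels)

    def af_of(self, label: str) -> float:
        return float(self.af[self.labels.index(label)])

    def included(self) -> tuple[tuple[str, ...], np.ndarray]:
        """Labels and AF values with excluded residues removed."""
        keep = [i for i, l in enumerate(self.labels) if l not in self.excluded_labels]
        return tuple(self.labels[i] for i in keep), self.af[keep]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue_label": list(self.labels),
                "af": self.af,
                "excluded": [l in self.excluded_labels for l in self.labels],
            }
        )


def compute_af(
    peaks: Sequence[DeprotectionPeak],
    reference_label: str,
    convention: str = "per-metric",
    name: str = "",
) -> AggregationProfile:
    """Compute the reference-normalized AF profile from measured peaks.

    Parameters
    ----------
    peaks : sequence of DeprotectionPeak
        In synthesis order (sorted by cycle_index internally).
    reference_label : str
        Residue whose peak defines the normalization; must be present,
        not flagged low-SNR, and should precede any aggregation.
    convention : {"per-metric", "ratio"}
        ``"per-metric"`` (default): AF_i = w_i/w_ref − h_i/h_ref.
        ``"ratio"``: AF_i = (w_i − h_i)/(w_ref − h_ref).
    """
    if convention not in ("per-metric", "ratio"):
        raise AnalysisError(f"unknown AF convention {convention!r}")
    peaks = sorted(peaks, key=lambda p: p.cycle_index)
    by_label = {p.residue_label: p for p in peaks}
    if reference_label not in by_label:
        raise AnalysisError(f"reference residue {reference_label!r} missing from peaks")
    ref = by_label[reference_label]
    if FLAG_LOW_SNR in ref.flags:
        raise AnalysisError(f"unreliable reference: {reference_label} flagged low_snr")

    w = np.array([p.fwhm_s for p in peaks])
    h = np.array([p.height_au for p in peaks])
    if convention == "per-metric":
        af = w / ref.fwhm_s - h / ref.height_au
    else:
        denom = ref.fwhm_s - ref.height_au
        if denom == 0:
            raise AnalysisError(
                "ratio convention undefined: reference has w == h exactly"
            )
        af = (w - h) / denom

    excluded = frozenset(
        p.residue_label for p in peaks if FLAG_SLOW_COUPLING in p.flags
    )
    return AggregationProfile(
        labels=tuple(p.residue_label for p in peaks),
        af=af,
        reference_label=reference_label,
        excluded_labels=excluded,
        name=name,
    )


def detect_onset(
    profile: AggregationProfile,
    theta: float = DEFAULT_THETA,
    m: int = DEFAULT_PERSISTENCE,
    baseline_n: int = DEFAULT_BASELINE_N,
) -> str | None:
    """Call the aggregation-onset residue, or None if no onset.

    Onset is the first residue i (synthesis order, excluded residues
    skipped) with AF_j >= theta for all j in {i, ..., i+m−1}.  The
    first ``baseline_n`` positions can never be called — early cycles
    establish the unaggregated baseline.
    """
    if theta <= 0:
        raise AnalysisError("theta must be > 0")
    if m < 1:
        raise AnalysisError("persistence m must be >= 1")
    if baseline_n < 0:
        raise AnalysisError("baseline_n must be >= 0")
    labels, af = profile.included()
    if len(labels) < baseline_n + m:
        raise AnalysisError(
            f"profile too short: {len(labels)} usable residues < baseline_n + m = {baseline_n + m}"
        )
    for i in range(baseline_n, len(labels) - m + 1):
        if np.all(af[i : i + m] >= theta):
            return labels[i]
    return None


def with_onset(
    profile: AggregationProfile,
    theta: float = DEFAULT_THETA,
    m: int = DEFAULT_PERSISTENCE,
    baseline_n: int = DEFAULT_BASELINE_N,
) -> AggregationProfile:
    """Return a copy of ``profile`` with its onset call filled in."""
    return replace(profile, onset_label=detect_onset(profile, theta, m, baseline_n))


@dataclass(frozen=True)
class ProfileComparison:
    """Residue-aligned AF comparison of several runs (tagged vs untagged)."""

    table: pd.DataFrame
    onsets: dict
    delays: dict
    baseline_name: str


def compare_profiles(
    profiles: Sequence[AggregationProfile],
    baseline: int = 0,
    names: Sequence[str] | None = None,
) -> ProfileComparison:
    """Align AF profiles over their common residues and compare onsets.

    Tagged and untagged syntheses of the same parent fragment share the
    parent's residue labels; the tag's own residues appear only in the
    tagged run and are ignored by aligning on the label intersection.
    The delay of each profile's onset relative to the baseline profile
    is reported in residues (positions within the common region); a
    profile with no onset while the baseline has one is reported as
    ``"suppressed"`` — aggregation never started.
    """
    if len(profiles) < 1:
        raise AnalysisError("need at least one profile")
    if names is None:
        names = [p.name or f"profile_{i}" for i, p in enumerate(profiles)]
    base = profiles[baseline]
    common = [l for l in base.labels if all(l in p.labels for p in profiles)]
    if not common:
        raise AnalysisError("no common residue labels across profiles")

    data = {"residue_label": common}
    for name, p in zip(names, profiles):
        data[f"af_{name}"] = [p.af_of(l) for l in common]
    table = pd.DataFrame(data)

    pos = {l: i for i, l in enumerate(common)}
    onsets = {name: p.onset_label for name, p in zip(names, profiles)}
    base_onset = base.onset_label
    delays: dict = {}
    for name, p in zip(names, profiles):
        if base_onset is None or base_onset not in pos:
            delays[name] = None
        elif p.onset_label is None:
            delays[name] = SUPPRESSED
        elif p.onset_label in pos:
            delays[name] = pos[p.onset_label] - pos[base_onset]
        else:
            delays[name] = None
    return ProfileComparison(
        table=table, onsets=onsets, delays=delays, baseline_name=names[baseline]
    )
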