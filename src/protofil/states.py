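"""Conformational-state classification and the dimer-species census.

A subunit is relaxed (R) when its inter-domain distance has dropped by
strictly more than 2.5 Å relative to the tense (T) reference, tense when
the reduction is at most 1.0 Å, and indeterminate in the gap between —
the observed T/R separation is bimodal with a clear gap, so mid-gap
frames are not force-labelled.  An interface is closed above 1100 Å² of
buried surface, open below 1000 Å², intermediate between.  Trimer state
strings are ordered bottom-middle-top; dimer species letters are ordered
upper-then-lower subunit ("T-R" = tense upper over relaxed lower).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidSpecificationError
from .geometry import DomainDistanceSeries, RotationAngleSeries
from .surface import InterfaceSeries

__all__ = [
    "SubunitStateSeries",
    "InterfaceStateSeries",
    "TrimerTimeline",
    "SpeciesCensus",
    "classify_subunit",
    "classify_interface",
    "trimer_timeline",
    "species_census",
    "angle_peaks_by_interface",
]

R_THRESHOLD = 2.5        # Å reduction, strictly more → R
T_THRESHOLD = 1.0        # Å reduction, at most → T
CLOSED_THRESHOLD = 1100.0  # Å² buried, strictly more → closed
OPEN_THRESHOLD = 1000.0    # Å² buried, strictly less → open

INDETERMINATE = "?"


@dataclass
class SubunitStateSeries:
    subunit: str
    distances: np.ndarray
    reference_T: float
    reduction: np.ndarray
    labels: np.ndarray           # "T" | "R" | "?"


@dataclass
class InterfaceStateSeries:
    interface: str
    buried: np.ndarray
    labels: np.ndarray           # "closed" | "open" | "intermediate"


def classify_subunit(
    series: DomainDistanceSeries,
    reference_T: float | None = None,
    r_threshold: float = R_THRESHOLD,
    t_threshold: float = T_THRESHOLD,
    reference_fraction: float = 0.05,
) -> SubunitStateSeries:
    """Label each frame T/R/indeterminate from the inter-domain reduction.

    ``reference_T`` defaults to the mean distance over the first
    ``reference_fraction`` of frames (at least one), taken as the tense
    baseline.  R requires a reduction strictly greater than
    ``r_threshold``.
    """
    d = series.distances
    if reference_T is None:
        n0 = max(1, int(np.ceil(len(d) * reference_fraction)))
        reference_T = float(d[:n0].mean())
    if reference_T <= 0:
        raise InvalidSpecificationError("reference_T must be positive")
    if not r_threshold > t_threshold:
        raise InvalidSpecificationError("r_threshold must exceed t_threshold")
    reduction = reference_T - d
    labels = np.full(len(d), INDETERMINATE, dtype=object)
    labels[reduction > r_threshold] = "R"
    labels[reduction <= t_threshold] = "T"
    return SubunitStateSeries(subunit=series.subunit, distances=d,
                              reference_T=reference_T, reduction=reduction,
                              labels=labels)


def classify_interface(
    series: InterfaceSeries,
    closed_threshold: float = CLOSED_THRESHOLD,
    open_threshold: float = OPEN_THRESHOLD,
) -> InterfaceStateSeries:
    """Label each frame closed/open/intermediate from buried SASA."""
    if not closed_threshold > open_threshold:
        raise InvalidSpecificationError(
            f"closed threshold {closed_threshold} must exceed open "
            f"threshold {open_threshold}"
        )
    b = series.buried
    labels = np.full(len(b), "intermediate", dtype=object)
    labels[b > closed_threshold] = "closed"
    labels[b < open_threshold] = "open"
    return InterfaceStateSeries(interface=series.interface, buried=b,
                                labels=labels)


@dataclass
class TrimerTimeline:
    subunit_labels: list[str]            # ordered bottom → top
    interface_labels: list[str]
    state_strings: list[str]             # "T-T-R", "?" for indeterminate
    interface_strings: list[str]         # "closed-open"

    @property
    def n_frames(self) -> int:
        return len(self.state_strings)

    def to_dataframe(self, frame_dt: float = 0.1) -> pd.DataFrame:
        f = np.arange(self.n_frames)
        return pd.DataFrame({
            "frame": f, "time_ns": f * frame_dt,
            "state": self.state_strings,
            "interfaces": self.interface_strings,
        })


def trimer_timeline(
    subunit_records: list[SubunitStateSeries],
    interface_records: list[InterfaceStateSeries],
) -> TrimerTimeline:
    """Combine per-subunit and per-interface labels into per-frame strings
    (subunits ordered bottom → top as given)."""
    lengths = {len(r.labels) for r in subunit_records}
    lengths |= {len(r.labels) for r in interface_records}
    if len(lengths) != 1:
        raise InvalidSpecificationError(f"frame ranges differ: {sorted(lengths)}")
    (n,) = lengths
    states = ["-".join(str(r.labels[f]) for r in subunit_records)
              for f in range(n)]
    ifaces = ["-".join(str(r.labels[f]) for r in interface_records)
              for f in range(n)]
    return TrimerTimeline(
        subunit_labels=[r.subunit for r in subunit_records],
        interface_labels=[r.interface for r in interface_records],
        state_strings=states, interface_strings=ifaces,
    )


@dataclass
class SpeciesCensus:
    """Dimer-species frame counts per dimer position.

    Species keys are "T-T", "T-R", "R-T", "R-R" with the first letter the
    UPPER subunit of the pair; frames with an indeterminate member are
    excluded per position and counted separately.
    """

    positions: dict[str, Counter] = field(default_factory=dict)
    excluded: dict[str, int] = field(default_factory=dict)
    trimer_counts: Counter = field(default_factory=Counter)
    first_switch: dict[str, int | None] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for pos, counter in self.positions.items():
            for sp in ("T-T", "T-R", "R-T", "R-R"):
                rows.append({"dimer": pos, "species_upper_lower": sp,
                             "frames": counter.get(sp, 0)})
            rows.append({"dimer": pos, "species_upper_lower": "excluded",
                         "frames": self.excluded[pos]})
        return pd.DataFrame(rows)


def species_census(timeline: TrimerTimeline) -> SpeciesCensus:
    """Tally dimer species per position and the first T→R switch frame per
    subunit (the order of switching)."""
    if timeline.n_frames == 0:
        raise InvalidSpecificationError("empty timeline")
    labels = timeline.subunit_labels
    census = SpeciesCensus()
    per_frame = [s.split("-") for s in timeline.state_strings]

    for lower_i in range(len(labels) - 1):
        upper_i = lower_i + 1
        pos = f"{labels[lower_i]} dimer" if lower_i == 0 else f"{labels[upper_i]} dimer"
        counter: Counter = Counter()
        excluded = 0
        for states in per_frame:
            up, lo = states[upper_i], states[lower_i]
            if INDETERMINATE in (up, lo):
                excluded += 1
            else:
                counter[f"{up}-{lo}"] += 1
        census.positions[pos] = counter
        census.excluded[pos] = excluded

    census.trimer_counts = Counter(timeline.state_strings)
    for i, lab in enumerate(labels):
        switch = next((f for f, states in enumerate(per_frame)
                       if states[i] == "R"), None)
        census.first_switch[lab] = switch
    return census


@dataclass
class AnglePeak:
    category: str
    mode_deg: float              # nan if undersampled
    n_samples: int
    undersampled: bool


def _histogram_mode(samples: np.ndarray, bin_width: float = 1.0) -> float:
    """Histogram mode with parabolic refinement of the peak bin."""
    lo = np.floor(samples.min()) - bin_width
    hi = np.ceil(samples.max()) + 2 * bin_width
    edges = np.arange(lo, hi, bin_width)
    counts, edges = np.histogram(samples, bins=edges)
    m = int(np.argmax(counts))
    center = 0.5 * (edges[m] + edges[m + 1])
    if 0 < m < len(counts) - 1:
        cm, c0, cp = counts[m - 1], counts[m], counts[m + 1]
        denom = cm - 2 * c0 + cp
        if denom < 0:
            center += 0.5 * bin_width * (cm - cp) / denom
    return float(center)


def angle_peaks_by_interface(
    angle_series: list[RotationAngleSeries],
    interface_states: list[InterfaceStateSeries],
    nucleotide_tag: str,
    bin_width: float = 1.0,
    min_samples: int = 10,
) -> dict[str, AnglePeak]:
    """Modal θ1 per (nucleotide, interface-openness) category.

    θ1 samples are pooled over the given interfaces: closed frames feed
    "<tag>-IF1", open frames "<tag>-IF2" (intermediate frames are left
    out).  Categories with fewer than ``min_samples`` samples are
    reported as undersampled.
    """
    by_name = {s.interface: s for s in interface_states}
    pooled: dict[str, list[np.ndarray]] = {f"{nucleotide_tag}-IF1": [],
                                           f"{nucleotide_tag}-IF2": []}
    for ang in angle_series:
        st = by_name.get(ang.interface)
        if st is None:
            raise InvalidSpecificationError(
                f"no interface-state series for {ang.interface!r}"
            )
        if len(st.labels) != len(ang.theta1):
            raise InvalidSpecificationError("frame ranges differ")
        pooled[f"{nucleotide_tag}-IF1"].append(ang.theta1[st.labels == "closed"])
        pooled[f"{nucleotide_tag}-IF2"].append(ang.theta1[st.labels == "open"])

    out = {}
    for cat, chunks in pooled.items():
        samples = np.concatenate(chunks) if chunks else np.empty(0)
        if len(samples) < min_samples:
            out[cat] = AnglePeak(cat, np.nan, len(samples), True)
        else:
            out[cat] = AnglePeak(cat, _histogram_mode(samples, bin_width),
                                 len(samples), False)
    return out
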