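"""Missing-segment analysis of probed vs baseline TOF spectra.

The probe laser carves a depleted segment out of a species' TOF peak.  This
module locates that segment by per-bin fractional differencing, decides
whether the packet *centre* was hit (segment centroid close to the baseline
peak centroid), and refines the probed position z using the area ratio of the
forward and backward remnant peaks: ions that were spatially ahead of the
slab arrive earlier in a linear TOF, so the remnant asymmetry locates the
packet centre within the slab.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .constants import MM, NS
from .kinematics import InstrumentConfig, IonSpecies, time_of_flight
from .plume import ScenarioArchive, Spectrum

__all__ = [
    "DepletionProfile",
    "DepletionSegment",
    "ObservationPoint",
    "species_tof_window",
    "depletion_profile",
    "find_missing_segment",
    "peak_centroid_and_fwhm",
    "is_center_hit",
    "correct_z",
    "scan_to_observations",
    "observations_to_json",
    "observations_from_json",
    "observations_to_csv",
    "observations_from_csv",
]


@dataclass
class DepletionProfile:
    """Per-bin fractional depletion of a peak window.

    ``depletion[i] = max(0, (b_i - p_i) / b_i)`` on bins whose baseline count
    exceeds ``floor`` (a fraction of the window's peak maximum); bins below
    the floor are set to 0 so the tails cannot produce 0/0 artifacts.
    """

    bin_edges: np.ndarray  # window-restricted edges, s
    depletion: np.ndarray
    baseline: np.ndarray
    probed: np.ndarray

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass(frozen=True)
class DepletionSegment:
    """A contiguous depleted run inside a peak window."""

    tof_window: tuple  # (lo, hi), s
    depth: float  # max fractional depletion in the run
    centroid: float  # s, depletion-weighted
    area: float  # integrated depletion, s

    def __post_init__(self) -> None:
        if not 0.0 < self.depth <= 1.0:
            raise ValueError("depth must be in (0, 1]")
        if self.tof_window[1] <= self.tof_window[0]:
            raise ValueError("tof_window must be non-empty")


@dataclass(frozen=True)
class ObservationPoint:
    """A (probe delay, corrected position) pair where the packet centre was
    depleted — the unit record of the inverse analysis."""

    species: str
    voltage: float  # V
    delta_t: float  # s
    z_corrected: float  # m
    center_hit: bool = True
    fwd_fraction: float = 0.5  # remnant area fraction ahead of the segment

    def __post_init__(self) -> None:
        if not 0.0 <= self.fwd_fraction <= 1.0:
            raise ValueError("fwd_fraction must be in [0, 1]")


def species_tof_window(
    species: IonSpecies,
    instrument: InstrumentConfig,
    te_range=(0.0, 250e-9),
    v0_range=(0.0, 1500.0),
) -> tuple:
    """TOF window guaranteed to contain a species' peak.

    Flight time decreases with v0 and increases with t_E, so the window is
    [tof(te_min, v0_max), tof(te_max, v0_min)].
    """
    lo = time_of_flight(te_range[0], v0_range[1], species, instrument)
    hi = time_of_flight(te_range[1], v0_range[0], species, instrument)
    return (lo, hi)


def depletion_profile(
    baseline: Spectrum,
    probed: Spectrum,
    peak_window,
    floor: float = 0.01,
) -> DepletionProfile:
    """Fractional depletion (baseline - probed)/baseline inside *peak_window*.

    Raises
    ------
    ValueError
        On binning mismatch, or if the baseline has no counts in the window.
    """
    if len(baseline.bin_edges) != len(probed.bin_edges) or not np.allclose(
        baseline.bin_edges, probed.bin_edges
    ):
        raise ValueError("baseline and probed spectra must share binning")
    lo, hi = peak_window
    sel = (baseline.bin_edges[:-1] >= lo) & (baseline.bin_edges[1:] <= hi)
    b = baseline.counts[sel]
    p = probed.counts[sel]
    if b.size == 0 or b.max() <= 0:
        raise ValueError("baseline has no counts inside the peak window")
    edges_idx = np.flatnonzero(sel)
    edges = baseline.bin_edges[edges_idx[0] : edges_idx[-1] + 2]
    thresh = floor * b.max()
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(b > thresh, np.maximum(0.0, (b - p) / b), 0.0)
    return DepletionProfile(bin_edges=edges, depletion=d, baseline=b, probed=p)


def find_missing_segment(
    profile: DepletionProfile,
    min_depth: float = 0.15,
    min_width_bins: int = 3,
) -> DepletionSegment | None:
    """The deepest missing segment, or None.

    Returns the contiguous run of bins with depletion >= *min_depth* whose
    integrated depletion (area) is maximal, provided it spans at least
    *min_width_bins* bins; ties break toward the earliest run.
    """
    above = profile.depletion >= min_depth
    if not above.any():
        return None
    # run-length encode the boolean mask
    padded = np.concatenate([[False], above, [False]])
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])  # exclusive
    best = None
    best_area = -1.0
    w = profile.bin_width
    for s, e in zip(starts, ends):
        if e - s < min_width_bins:
            continue
        area = float(profile.depletion[s:e].sum() * w)
        if area > best_area + 1e-30:
            best_area = area
            best = (s, e)
    if best is None:
        return None
    s, e = best
    centres = profile.bin_centres[s:e]
    weights = profile.depletion[s:e]
    return DepletionSegment(
        tof_window=(float(profile.bin_edges[s]), float(profile.bin_edges[e])),
        depth=float(weights.max()),
        centroid=float(np.average(centres, weights=weights)),
        area=best_area,
    )


def peak_centroid_and_fwhm(spectrum_counts, bin_centres) -> tuple:
    """Centroid (intensity-weighted mean) and FWHM of a single peak.

    FWHM comes from linear interpolation of the half-maximum crossings on
    either side of the maximum bin.
    """
    c = np.asarray(spectrum_counts, float)
    t = np.asarray(bin_centres, float)
    if c.sum() <= 0:
        raise ValueError("empty peak")
    centroid = float(np.average(t, weights=c))
    i_max = int(np.argmax(c))
    half = c[i_max] / 2.0

    def _cross(idx_range, reverse):
        prev_i = i_max
        for i in idx_range:
            if c[i] < half:
                # interpolate between i and prev_i
                f = (half - c[i]) / (c[prev_i] - c[i])
                return t[i] + f * (t[prev_i] - t[i])
            prev_i = i
        return t[idx_range[-1]] if len(idx_range) else t[i_max]

    left = _cross(range(i_max - 1, -1, -1), True)
    right = _cross(range(i_max + 1, len(c)), False)
    return centroid, float(right - left)


def is_center_hit(
    profile: DepletionProfile,
    segment: DepletionSegment,
    tolerance: float = 0.5,
) -> bool:
    """Was the packet centre inside the slab when the probe fired?

    True iff the segment centroid lies within ``tolerance * FWHM`` of the
    baseline peak centroid.  The default of half a FWHM encodes "the packet
    centre lies somewhere inside the probed slab" — the slab's TOF image is
    about twice the peak FWHM at the default packet widths — leaving the
    area-ratio correction of :func:`correct_z` to refine the within-slab
    position.
    """
    centroid, fwhm = peak_centroid_and_fwhm(profile.baseline, profile.bin_centres)
    return abs(segment.centroid - centroid) <= tolerance * fwhm


def correct_z(
    slab,
    profile: DepletionProfile,
    segment: DepletionSegment,
) -> tuple:
    """Refine z from the forward/backward remnant-peak area ratio.

    With ``A_f`` the remnant (probed) area at TOF earlier than the segment —
    ions spatially ahead of the slab — and ``A_b`` the remnant area later,
    the packet centre is placed at ``z_low + w * A_f / (A_f + A_b)`` where
    ``w`` is the slab thickness: a symmetric remnant puts the centre at the
    slab midpoint, a forward-heavy remnant pushes it toward the slab top.

    Returns ``(z_corrected, fwd_fraction)``.
    """
    z_low, z_high = slab
    w = z_high - z_low
    if w <= 0:
        raise ValueError("slab must have positive thickness")
    centres = profile.bin_centres
    lo, hi = segment.tof_window
    a_f = float(profile.probed[centres < lo].sum())
    a_b = float(profile.probed[centres >= hi].sum())
    if a_f + a_b <= 0:
        raise ValueError("no remnant peaks to weigh (A_f + A_b = 0)")
    frac = a_f / (a_f + a_b)
    return z_low + w * frac, frac


def scan_to_observations(
    archive: ScenarioArchive,
    species_list,
    min_depth: float = 0.15,
    min_width_bins: int = 3,
    center_tolerance: float = 0.5,
    baseline_floor: float = 0.01,
    te_range=(0.0, 250e-9),
    v0_range=(0.0, 1500.0),
) -> list:
    """Scan a scenario archive for centre-hit cells.

    For every (voltage, species) the species' peak window is computed from
    flight-time bounds; each probed cell is differenced against the voltage's
    baseline, the missing segment located, and — when the segment centroid
    coincides with the peak centroid — the slab position corrected by the
    remnant area ratio.  One :class:`ObservationPoint` is emitted per
    qualifying (slab, delay, voltage, species) cell.
    """
    points = []
    for voltage, baseline in archive.baselines.items():
        instrument = archive.instruments.get(voltage)
        if instrument is None:
            raise ValueError(f"archive lacks instrument metadata for {voltage} V")
        for sp in species_list:
            window = species_tof_window(sp, instrument, te_range, v0_range)
            for (v, slab, delay), probed in archive.probed.items():
                if v != voltage or delay <= 0:
                    continue
                profile = depletion_profile(
                    baseline, probed, window, floor=baseline_floor
                )
                segment = find_missing_segment(profile, min_depth, min_width_bins)
                if segment is None:
                    continue
                if not is_center_hit(profile, segment, center_tolerance):
                    continue
                try:
                    z_corr, frac = correct_z(slab, profile, segment)
                except ValueError:
                    # probe removed the whole peak: no remnant to weigh, so
                    # no correction can be applied — use the slab midpoint
                    z_corr, frac = 0.5 * (slab[0] + slab[1]), 0.5
                points.append(
                    ObservationPoint(
                        species=sp.label,
                        voltage=voltage,
                        delta_t=delay,
                        z_corrected=z_corr,
                        center_hit=True,
                        fwd_fraction=frac,
                    )
                )
    return points


# -- observation-table I/O: JSON array / CSV with identical columns ---------

_COLS = ["species", "voltage_V", "delta_t_ns", "z_corrected_mm", "fwd_fraction"]


def _point_to_row(p: ObservationPoint) -> dict:
    return {
        "species": p.species,
        "voltage_V": p.voltage,
        "delta_t_ns": p.delta_t / NS,
        "z_corrected_mm": p.z_corrected / MM,
        "fwd_fraction": p.fwd_fraction,
    }


def _row_to_point(row: dict) -> ObservationPoint:
    return ObservationPoint(
        species=row["species"],
        voltage=float(row["voltage_V"]),
        delta_t=float(row["delta_t_ns"]) * NS,
        z_corrected=float(row["z_corrected_mm"]) * MM,
        fwd_fraction=float(row["fwd_fraction"]),
    )


def observations_to_json(points, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([_point_to_row(p) for p in points], indent=1), encoding="utf-8"
    )


def observations_from_json(path: str | Path) -> list:
    return [_row_to_point(r) for r in json.loads(Path(path).read_text("utf-8"))]


def observations_to_csv(points, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=_COLS)
        writer.writeheader()
        for p in points:
            writer.writerow(_point_to_row(p))


def observations_from_csv(path: str | Path) -> list:
    with Path(path).open(newline="", encoding="utf-8") as fh:
        return [_row_to_point(r) for r in csv.DictReader(fh)]
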