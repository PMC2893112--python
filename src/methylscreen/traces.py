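"""Electropherogram processing for quantitative bisulfite sequencing.

A sample is sequenced after bisulfite conversion, so the fluorescence
intensity of the cytosine signal at each CpG site is proportional to the
fraction of methylated molecules at that site.  Each amplicon carries a
constant normalization tag (the sequence CGTCGTCG appended to the reverse
primer) whose signal is methylation-independent.  The pipeline implemented
here converts one single-channel intensity series per sample x locus into
a scalar methylation score:

1. detect the normalization-tag signal by matched filtering,
2. shift the trace so every sample's tag sits at the same data point,
3. integrate the tag signal and divide every data point by that area,
4. read off each CpG site as the maximum of the normalized trace within
   +/- 30 data points of the peak position defined by a fully methylated
   reference trace,
5. average the per-site intensities into the methylation score.

Because the tag area scales with overall signal strength, the score is
invariant to global amplitude changes (loading, detector gain); the
alignment step makes it invariant to positional shifts between runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    EmptyMeasurementSet,
    NoNormalizationSignal,
    PeakCountMismatch,
    ShiftOutOfRange,
    ZeroNormalization,
)

#: The constant normalization-tag sequence appended to every reverse primer.
TAG_SEQUENCE = "CGTCGTCG"

#: Half-width (data points) of the CpG quantification window.
DEFAULT_CPG_HALF_WIDTH = 30


@dataclass(frozen=True)
class Trace:
    """A single-channel electropherogram for one sample x locus.

    ``intensities`` are arbitrary fluorescence units, one value per data
    point, indexed from 0.
    """

    sample_id: str
    locus_id: str
    intensities: np.ndarray
    is_reference: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("trace must be a non-empty 1-D intensity series")
        if not np.all(np.isfinite(arr)):
            raise ValueError("trace intensities must be finite")
        if np.any(arr < 0):
            raise ValueError("trace intensities must be non-negative")
        object.__setattr__(self, "intensities", arr)

    def __len__(self) -> int:
        return self.intensities.size


@dataclass(frozen=True)
class AmpliconSpec:
    """Static description of one sequenced PCR fragment.

    ``expected_tag_position`` is the data-point index of the first tag peak
    expected from the run geometry; detection searches a window around it.
    ``peak_spacing`` / ``peak_sigma`` describe the peak geometry (data
    points per base and Gaussian peak width) used to build the tag
    matched-filter template.
    """

    locus_id: str
    n_cpg_sites: int
    expected_tag_position: int
    tag_peak_count: int = 3
    tag_sequence: str = TAG_SEQUENCE
    peak_spacing: int = 12
    peak_sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.n_cpg_sites < 1:
            raise ValueError("n_cpg_sites must be >= 1")
        if self.tag_peak_count < 1:
            raise ValueError("tag_peak_count must be >= 1")


@dataclass(frozen=True)
class NormalizationInfo:
    """Where the tag was found, its integrated area, and any shift applied."""

    tag_position: int
    tag_area: float
    shift_applied: int = 0

    def __post_init__(self) -> None:
        if self.tag_area <= 0:
            raise ValueError("tag_area must be positive")


@dataclass(frozen=True)
class CpGMeasurement:
    """One CpG site's normalized intensity read from a sample trace."""

    site_index: int
    reference_peak_position: int
    window: tuple[int, int]
    normalized_intensity: float


@dataclass(frozen=True)
class MethylationScore:
    """Mean normalized CpG intensity for one sample x locus (unitless)."""

    sample_id: str
    locus_id: str
    score: float
    n_sites_used: int
    shift_applied: int = 0
    tag_area: float = float("nan")


@dataclass(frozen=True)
class TraceConfig:
    """Tunable knobs of the trace pipeline.

    ``search_half_width``: data points searched either side of the expected
    tag position.  ``signal_floor``: minimum matched-filter response; an
    all-zero search region falls below any non-negative floor.
    ``integrate_whole_tag``: integrate the full tag region (default) or a
    single peak-spacing window around the central tag peak.
    ``integration_width_factor``: tag integration width in units of the
    peak spacing, centered on the tag region.
    ``peak_floor_frac`` / ``min_peak_spacing``: detection floor (fraction of
    the reference maximum) and minimum spacing for reference CpG peaks.
    """

    search_half_width: int = 100
    signal_floor: float = 0.0
    integrate_whole_tag: bool = True
    integration_width_factor: float = 3.0
    peak_floor_frac: float = 0.05
    min_peak_spacing: int = 8
    cpg_half_width: int = DEFAULT_CPG_HALF_WIDTH


def gaussian_peak(length: int, center: float, sigma: float) -> np.ndarray:
    """Unit-amplitude Gaussian peak sampled on integer data points."""
    x = np.arange(length, dtype=float)
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def tag_template(spec: AmpliconSpec) -> np.ndarray:
    """Matched-filter template of the tag peak pattern.

    The template spans the tag region: ``tag_peak_count`` unit Gaussian
    peaks at ``peak_spacing`` intervals, with a 3-sigma margin either side.
    Index 0 of the template corresponds to the first tag peak center.
    """
    margin = int(np.ceil(3 * spec.peak_sigma))
    span = (spec.tag_peak_count - 1) * spec.peak_spacing
    length = span + 2 * margin + 1
    template = np.zeros(length)
    for i in range(spec.tag_peak_count):
        template += gaussian_peak(length, margin + i * spec.peak_spacing, spec.peak_sigma)
    return template


def _tag_integration_bounds(spec: AmpliconSpec, tag_position: int,
                            config: TraceConfig) -> tuple[int, int]:
    """Closed [lo, hi] bounds of the tag integration window."""
    span = (spec.tag_peak_count - 1) * spec.peak_spacing
    center = tag_position + span / 2.0
    if config.integrate_whole_tag:
        half = max(span / 2.0 + spec.peak_spacing / 2.0,
                   config.integration_width_factor * spec.peak_spacing / 2.0)
    else:
        # single central peak only
        center = tag_position + round(span / 2.0 / spec.peak_spacing) * spec.peak_spacing
        half = spec.peak_spacing / 2.0
    return int(np.floor(center - half)), int(np.ceil(center + half))


def find_normalization_signal(trace: Trace, spec: AmpliconSpec,
                              config: TraceConfig = TraceConfig()) -> NormalizationInfo:
    """Locate the normalization-tag signal and integrate it.

    The tag is found as the data-point index maximizing the matched-filter
    response (cross-correlation with :func:`tag_template`) within
    ``config.search_half_width`` points of the expected position.  The
    returned ``tag_area`` is the integrated raw intensity over the tag
    region.

    Raises
    ------
    NoNormalizationSignal
        If the best response does not exceed ``config.signal_floor`` or the
        integrated area is zero.
    """
    y = trace.intensities
    template = tag_template(spec)
    margin = int(np.ceil(3 * spec.peak_sigma))

    lo = max(0, spec.expected_tag_position - config.search_half_width)
    hi = min(len(y) - 1, spec.expected_tag_position + config.search_half_width)
    if lo > hi:
        raise NoNormalizationSignal(
            f"search window empty for trace {trace.sample_id}/{trace.locus_id}")

    # full cross-correlation, then restrict to candidate first-peak positions
    full = np.correlate(y, template, mode="full")
    # full[k] = sum_j y[j] * template[j - (k - len(template) + 1)];
    # the template start aligned at trace index s corresponds to k = s + len(template) - 1.
    # First tag peak center at position p means template start s = p - margin.
    positions = np.arange(lo, hi + 1)
    starts = positions - margin
    idx = starts + len(template) - 1
    valid = (idx >= 0) & (idx < full.size)
    if not np.any(valid):
        raise NoNormalizationSignal("no valid tag position in search window")
    responses = np.full(positions.shape, -np.inf)
    responses[valid] = full[idx[valid]]

    best = int(np.argmax(responses))
    best_response = responses[best]
    tag_position = int(positions[best])
    if not np.isfinite(best_response) or best_response <= config.signal_floor:
        raise NoNormalizationSignal(
            f"matched-filter response {best_response:.3g} below floor "
            f"{config.signal_floor:.3g}")

    a, b = _tag_integration_bounds(spec, tag_position, config)
    a = max(0, a)
    b = min(len(y) - 1, b)
    area = float(np.sum(y[a:b + 1]))
    if area <= 0:
        raise NoNormalizationSignal("integrated tag area is zero")
    return NormalizationInfo(tag_position=tag_position, tag_area=area)


def align_trace(trace: Trace, norm: NormalizationInfo,
                target_position: int) -> tuple[Trace, NormalizationInfo]:
    """Shift a trace so its tag sits at ``target_position``.

    Vacated positions are zero-filled.  Returns the shifted trace and a
    NormalizationInfo with the shift recorded and the tag position updated.

    Raises
    ------
    ShiftOutOfRange
        If the shift magnitude reaches the trace length (the whole signal,
        tag included, would be discarded).
    """
    shift = target_position - norm.tag_position
    n = len(trace)
    if abs(shift) >= n or not (0 <= target_position < n):
        raise ShiftOutOfRange(
            f"shift {shift} out of range for trace of length {n}")
    if shift == 0:
        shifted = trace.intensities.copy()
    else:
        shifted = np.zeros_like(trace.intensities)
        if shift > 0:
            shifted[shift:] = trace.intensities[:n - shift]
        else:
            shifted[:n + shift] = trace.intensities[-shift:]
    out = replace(trace, intensities=shifted)
    return out, NormalizationInfo(tag_position=target_position,
                                  tag_area=norm.tag_area,
                                  shift_applied=shift)


def normalize_trace(trace: Trace, norm: NormalizationInfo) -> Trace:
    """Divide every data point by the integrated tag area.

    Raises :class:`ZeroNormalization` if the area is not positive.
    """
    if norm.tag_area <= 0:
        raise ZeroNormalization("tag area must be positive")
    return replace(trace, intensities=trace.intensities / norm.tag_area)


def locate_cpg_positions(reference: Trace, spec: AmpliconSpec,
                         config: TraceConfig = TraceConfig(),
                         exclude_region: tuple[int, int] | None = None) -> np.ndarray:
    """Find the CpG peak positions in an aligned, normalized reference trace.

    The fully methylated reference shows every CpG site at full amplitude,
    so its peaks define where each site is read in the patient traces.
    Peaks are local maxima above ``peak_floor_frac`` of the trace maximum,
    at least ``min_peak_spacing`` points apart; ``exclude_region`` (closed
    bounds) masks the tag region out of the peak search.  If more peaks
    than ``n_cpg_sites`` are found, the tallest ones are kept.

    Returns the positions in ascending order.

    Raises
    ------
    PeakCountMismatch
        If fewer than ``spec.n_cpg_sites`` peaks exceed the floor.
    """
    from scipy.signal import find_peaks

    if not reference.is_reference:
        raise ValueError("locate_cpg_positions requires the fully methylated reference")
    y = reference.intensities.copy()
    if exclude_region is not None:
        a, b = exclude_region
        y[max(0, a):min(len(y), b + 1)] = 0.0
    if y.max() <= 0:
        raise PeakCountMismatch("reference trace has no signal outside the tag region")
    floor = config.peak_floor_frac * y.max()
    peaks, props = find_peaks(y, height=floor, distance=config.min_peak_spacing)
    if peaks.size < spec.n_cpg_sites:
        raise PeakCountMismatch(
            f"found {peaks.size} reference peaks, need {spec.n_cpg_sites}")
    if peaks.size > spec.n_cpg_sites:
        order = np.argsort(props["peak_heights"])[::-1][:spec.n_cpg_sites]
        peaks = peaks[np.sort(order)]
        peaks = np.sort(peaks)
    return peaks.astype(int)


def quantify_cpg_site(norm_trace: Trace, ref_position: int,
                      half_width: int = DEFAULT_CPG_HALF_WIDTH) -> float:
    """Maximum of the normalized trace within +/- ``half_width`` points of
    the reference peak position, window clipped to the trace bounds."""
    n = len(norm_trace)
    if not (0 <= ref_position < n):
        raise ValueError(f"ref_position {ref_position} outside trace of length {n}")
    lo = max(0, ref_position - half_width)
    hi = min(n - 1, ref_position + half_width)
    return float(np.max(norm_trace.intensities[lo:hi + 1]))


def compute_methylation_score(measurements: list[CpGMeasurement],
                              sample_id: str = "", locus_id: str = "",
                              shift_applied: int = 0,
                              tag_area: float = float("nan")) -> MethylationScore:
    """Average the per-site normalized intensities into the methylation score."""
    if len(measurements) == 0:
        raise EmptyMeasurementSet("methylation score needs >= 1 CpG measurement")
    values = [m.normalized_intensity for m in measurements]
    return MethylationScore(sample_id=sample_id, locus_id=locus_id,
                            score=float(np.mean(values)),
                            n_sites_used=len(values),
                            shift_applied=shift_applied, tag_area=tag_area)


class TraceScorer:
    """Scores sample traces against a processed fully methylated reference.

    The reference is processed once: its tag is detected, the trace aligned
    to the amplicon's expected tag position and normalized, and the CpG
    peak positions located.  Every sample trace is then detected, aligned
    to the same target, normalized, and read at those positions.
    """

    def __init__(self, reference: Trace, spec: AmpliconSpec,
                 config: TraceConfig = TraceConfig()):
        if not reference.is_reference:
            raise ValueError("TraceScorer requires a fully methylated reference trace")
        self.spec = spec
        self.config = config
        self.target_position = spec.expected_tag_position

        norm = find_normalization_signal(reference, spec, config)
        aligned, norm = align_trace(reference, norm, self.target_position)
        normalized = normalize_trace(aligned, norm)
        tag_lo, tag_hi = _tag_integration_bounds(spec, self.target_position, config)
        self.reference_norm = norm
        self.reference_trace = normalized
        self.cpg_positions = locate_cpg_positions(
            normalized, spec, config, exclude_region=(tag_lo, tag_hi))
        self._tag_region = (tag_lo, tag_hi)

    def measurements(self, trace: Trace) -> tuple[list[CpGMeasurement], NormalizationInfo]:
        norm = find_normalization_signal(trace, self.spec, self.config)
        aligned, norm = align_trace(trace, norm, self.target_position)
        normalized = normalize_trace(aligned, norm)
        hw = self.config.cpg_half_width
        out = []
        for i, pos in enumerate(self.cpg_positions):
            lo = max(0, int(pos) - hw)
            hi = min(len(normalized) - 1, int(pos) + hw)
            out.append(CpGMeasurement(
                site_index=i, reference_peak_position=int(pos),
                window=(lo, hi),
                normalized_intensity=quantify_cpg_site(normalized, int(pos), hw)))
        return out, norm

    def score(self, trace: Trace) -> MethylationScore:
        try:
            meas, norm = self.measurements(trace)
            return compute_methylation_score(
                meas, sample_id=trace.sample_id, locus_id=trace.locus_id,
                shift_applied=norm.shift_applied, tag_area=norm.tag_area)
        except Exception as exc:
            raise type(exc)(
                f"{exc} [sample={trace.sample_id}, locus={trace.locus_id}]"
            ) from exc


def score_sample(trace: Trace, reference: Trace, spec: AmpliconSpec,
                 config: TraceConfig = TraceConfig()) -> MethylationScore:
    """One-shot composition: detect -> align -> normalize -> quantify -> average."""
    return TraceScorer(reference, spec, config).score(trace)
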