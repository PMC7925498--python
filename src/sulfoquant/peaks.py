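"""MRM chromatogram traces: I/O, peak detection, integration, assignment.

Time is minutes end-to-end (mzML stores seconds; conversion happens on
read/write).  Channels are identified by the conventional SRM chromatogram
id ``"SRM SIC Q1=<precursor> Q3=<product>"`` both in mzML and in the
long-format trace CSV, so the same resolution against a transition panel
works for either source.

The mzML support is deliberately narrow: chromatogram lists with 32/64-bit
float, uncompressed or zlib-compressed binary arrays — the subset a triple
quadrupole acquisition converted with standard tools actually uses for SRM
data.
"""

from __future__ import annotations

import base64
import re
import warnings
import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lxml import etree
from scipy import ndimage, signal

from .transitions import Role, TransitionPanel, match_transition

_SRM_ID = re.compile(r"Q1\s*=\s*([0-9.]+)\s+Q3\s*=\s*([0-9.]+)")

MZML_NS = "http://psi.hupo.org/ms/mzml"

# PSI-MS controlled-vocabulary accessions used by the narrow mzML subset
_ACC_64BIT = "MS:1000523"
_ACC_32BIT = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NO_COMPRESSION = "MS:1000576"
_ACC_TIME_ARRAY = "MS:1000595"
_ACC_INTENSITY_ARRAY = "MS:1000515"
_ACC_MINUTE = "UO:0000031"
_ACC_SRM_CHROMATOGRAM = "MS:1001473"


class TraceError(ValueError):
    """Malformed trace file or trace invariant violation."""


@dataclass(frozen=True)
class Trace:
    """One transition channel: strictly increasing time, non-negative counts."""

    channel_id: str
    time_min: np.ndarray
    intensity: np.ndarray
    analyte: str | None = None
    role: Role | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise TraceError(f"{self.channel_id}: time/intensity shape mismatch")
        if t.size and np.any(np.diff(t) <= 0):
            raise TraceError(f"{self.channel_id}: time axis not strictly increasing")
        if np.any(y < 0):
            raise TraceError(f"{self.channel_id}: negative intensities")
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "intensity", y)

    @property
    def srm_q1q3(self) -> tuple[float, float] | None:
        m = _SRM_ID.search(self.channel_id)
        return (float(m.group(1)), float(m.group(2))) if m else None


def srm_channel_id(precursor_mz: float, product_mz: float) -> str:
    return f"SRM SIC Q1={precursor_mz} Q3={product_mz}"


@dataclass(frozen=True)
class Peak:
    apex_rt_min: float
    left_rt_min: float
    right_rt_min: float
    area_counts: float
    height_counts: float
    snr: float

    def __post_init__(self) -> None:
        if not self.left_rt_min < self.apex_rt_min < self.right_rt_min:
            raise ValueError("require left < apex < right")
        if self.area_counts < 0:
            raise ValueError("negative peak area")


# ---------------------------------------------------------------------------
# reading / writing

def read_traces(source: str | Path | IO, format: str | None = None) -> list[Trace]:
    """Read traces from a long-format CSV or an mzML chromatogram list."""
    if format is None:
        if not isinstance(source, (str, Path)):
            raise TraceError("format must be given for file-like sources")
        suffix = Path(source).suffix.lower()
        format = {".csv": "csv", ".mzml": "mzml"}.get(suffix)
        if format is None:
            raise TraceError(f"cannot infer format from suffix {suffix!r}")
    if format == "csv":
        return _read_traces_csv(source)
    if format == "mzml":
        return _read_traces_mzml(source)
    raise TraceError(f"unknown format {format!r} (expected 'csv' or 'mzml')")


def _read_traces_csv(source) -> list[Trace]:
    try:
        frame = pd.read_csv(source)
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise TraceError(f"cannot read trace CSV: {exc}") from exc
    required = {"transition_id", "time_min", "intensity"}
    if missing := required - set(frame.columns):
        raise TraceError(f"trace CSV missing columns: {sorted(missing)}")
    traces = []
    for channel, grp in frame.groupby("transition_id", sort=False):
        traces.append(Trace(
            channel_id=str(channel),
            time_min=grp["time_min"].to_numpy(dtype=float),
            intensity=grp["intensity"].to_numpy(dtype=float),
        ))
    if not traces:
        raise TraceError("trace CSV contains no data rows")
    return traces


def write_traces_csv(traces: Sequence[Trace], sink: str | Path | IO[str]) -> None:
    frames = [
        pd.DataFrame({
            "transition_id": tr.channel_id,
            "time_min": tr.time_min,
            "intensity": tr.intensity,
        })
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(sink, index=False)


def _cv_accessions(element) -> dict[str, str]:
    return {
        cv.get("accession"): cv.get("unitAccession") or ""
        for cv in element.findall(f"{{{MZML_NS}}}cvParam")
    }


def _decode_binary_array(bda) -> tuple[np.ndarray, dict[str, str]]:
    accs = _cv_accessions(bda)
    raw = base64.b64decode((bda.findtext(f"{{{MZML_NS}}}binary") or "").strip())
    if _ACC_ZLIB in accs:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_32BIT in accs else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float), accs


def _read_traces_mzml(source) -> list[Trace]:
    try:
        tree = etree.parse(source if not isinstance(source, Path) else str(source))
    except (OSError, etree.XMLSyntaxError) as exc:
        raise TraceError(f"cannot parse mzML: {exc}") from exc
    chroms = tree.findall(f".//{{{MZML_NS}}}chromatogram")
    if not chroms:
        raise TraceError("mzML contains no chromatograms")
    traces = []
    for chrom in chroms:
        time = intensity = None
        time_in_minutes = False
        for bda in chrom.findall(
            f"{{{MZML_NS}}}binaryDataArrayList/{{{MZML_NS}}}binaryDataArray"
        ):
            values, accs = _decode_binary_array(bda)
            if _ACC_TIME_ARRAY in accs:
                time = values
                time_in_minutes = accs[_ACC_TIME_ARRAY] == _ACC_MINUTE
            elif _ACC_INTENSITY_ARRAY in accs:
                intensity = values
        if time is None or intensity is None:
            raise TraceError(
                f"chromatogram {chrom.get('id')!r}: missing time or intensity array"
            )
        traces.append(Trace(
            channel_id=chrom.get("id") or f"chromatogram{chrom.get('index')}",
            time_min=time if time_in_minutes else time / 60.0,
            intensity=intensity,
        ))
    return traces


def write_traces_mzml(traces: Sequence[Trace], sink: str | Path | IO[bytes]) -> None:
    """Write traces as an mzML chromatogram list (seconds, 64-bit, zlib)."""
    nsmap = {None: MZML_NS}
    root = etree.Element(f"{{{MZML_NS}}}mzML", nsmap=nsmap, version="1.1.0")

    def cvparam(parent, accession, name, unit_acc=None, unit_name=None):
        attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": ""}
        if unit_acc:
            attrs.update(unitCvRef=unit_acc.split(":")[0], unitAccession=unit_acc,
                         unitName=unit_name or "")
        etree.SubElement(parent, f"{{{MZML_NS}}}cvParam", **attrs)

    cv_list = etree.SubElement(root, f"{{{MZML_NS}}}cvList", count="2")
    etree.SubElement(cv_list, f"{{{MZML_NS}}}cv", id="MS", fullName="PSI-MS",
                     URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo")
    etree.SubElement(cv_list, f"{{{MZML_NS}}}cv", id="UO", fullName="UNIT-ONTOLOGY",
                     URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo")
    fdesc = etree.SubElement(root, f"{{{MZML_NS}}}fileDescription")
    fcontent = etree.SubElement(fdesc, f"{{{MZML_NS}}}fileContent")
    cvparam(fcontent, _ACC_SRM_CHROMATOGRAM, "selected reaction monitoring chromatogram")
    soft_list = etree.SubElement(root, f"{{{MZML_NS}}}softwareList", count="1")
    etree.SubElement(soft_list, f"{{{MZML_NS}}}software", id="sulfoquant", version="0.1.0")
    icl = etree.SubElement(root, f"{{{MZML_NS}}}instrumentConfigurationList", count="1")
    etree.SubElement(icl, f"{{{MZML_NS}}}instrumentConfiguration", id="IC1")
    dpl = etree.SubElement(root, f"{{{MZML_NS}}}dataProcessingList", count="1")
    dp = etree.SubElement(dpl, f"{{{MZML_NS}}}dataProcessing", id="dp1")
    etree.SubElement(dp, f"{{{MZML_NS}}}processingMethod", order="1", softwareRef="sulfoquant")

    run = etree.SubElement(root, f"{{{MZML_NS}}}run", id="run1",
                           defaultInstrumentConfigurationRef="IC1")
    clist = etree.SubElement(run, f"{{{MZML_NS}}}chromatogramList",
                             count=str(len(traces)), defaultDataProcessingRef="dp1")
    for index, tr in enumerate(traces):
        chrom = etree.SubElement(clist, f"{{{MZML_NS}}}chromatogram",
                                 index=str(index), id=tr.channel_id,
                                 defaultArrayLength=str(tr.time_min.size))
        cvparam(chrom, _ACC_SRM_CHROMATOGRAM, "selected reaction monitoring chromatogram")
        bdal = etree.SubElement(chrom, f"{{{MZML_NS}}}binaryDataArrayList", count="2")
        for values, kind_acc, kind_name, unit in (
            (tr.time_min * 60.0, _ACC_TIME_ARRAY, "time array", ("UO:0000010", "second")),
            (tr.intensity, _ACC_INTENSITY_ARRAY, "intensity array", None),
        ):
            payload = base64.b64encode(
                zlib.compress(np.asarray(values, dtype="<f8").tobytes())
            ).decode()
            bda = etree.SubElement(bdal, f"{{{MZML_NS}}}binaryDataArray",
                                   encodedLength=str(len(payload)))
            cvparam(bda, _ACC_64BIT, "64-bit float")
            cvparam(bda, _ACC_ZLIB, "zlib compression")
            if unit:
                cvparam(bda, kind_acc, kind_name, unit_acc=unit[0], unit_name=unit[1])
            else:
                cvparam(bda, kind_acc, kind_name)
            etree.SubElement(bda, f"{{{MZML_NS}}}binary").text = payload

    data = etree.tostring(root, xml_declaration=True, encoding="utf-8",
                          pretty_print=True)
    if isinstance(sink, (str, Path)):
        Path(sink).write_bytes(data)
    else:
        sink.write(data)


def resolve_channels(
    traces: Iterable[Trace], panel: TransitionPanel, tolerance: float = 0.5
) -> list[Trace]:
    """Attach panel analyte/role to traces whose SRM channel id matches."""
    resolved = []
    for tr in traces:
        q1q3 = tr.srm_q1q3
        hit = match_transition(*q1q3, panel, tolerance) if q1q3 else None
        resolved.append(replace(tr, analyte=hit[0], role=hit[1]) if hit else tr)
    return resolved


# ---------------------------------------------------------------------------
# detection and integration

def _rolling_min_baseline(y: np.ndarray, t: np.ndarray, window_min: float) -> np.ndarray:
    if window_min <= 0 or y.size < 2:
        return np.zeros_like(y)
    dt = float(np.median(np.diff(t)))
    size = max(3, int(round(window_min / dt)) | 1)
    return ndimage.minimum_filter1d(y, size=size, mode="nearest")


def _moving_average(y: np.ndarray, width: int) -> np.ndarray:
    if width is None or width <= 1:
        return y
    width = int(width) | 1  # odd
    kernel = np.ones(width) / width
    return np.convolve(y, kernel, mode="same")


def detect_peaks(
    trace: Trace,
    min_snr: float = 3.0,
    min_width_min: float = 0.05,
    smooth_points: int | None = 5,
    baseline_window_min: float = 2.0,
    boundary_fraction: float = 0.01,
) -> list[Peak]:
    """Detect chromatographic peaks on one trace.

    Pipeline: rolling-minimum baseline subtraction, optional moving-average
    smoothing, local-maximum search with an SNR threshold, and boundary
    placement at the nearest valley or where the signal falls below
    ``boundary_fraction`` of the apex.  Noise is the scaled median absolute
    deviation of the smoothing residual; on an exactly noise-free trace it is
    zero and the SNR is reported as infinity.  Deterministic for fixed input.
    """
    t, y = trace.time_min, trace.intensity
    if t.size < 5:
        raise ValueError("peak detection requires at least 5 points")
    baseline = _rolling_min_baseline(y, t, baseline_window_min)
    sig = np.clip(y - baseline, 0.0, None)
    smooth = _moving_average(sig, smooth_points)
    residual = sig - smooth
    noise = 1.4826 * float(np.median(np.abs(residual - np.median(residual))))

    height_floor = min_snr * noise if noise > 0 else np.finfo(float).tiny
    idx, _ = signal.find_peaks(smooth, height=height_floor, prominence=height_floor)

    peaks = []
    for i in idx:
        apex_height = sig[i]
        if apex_height <= 0:
            continue
        cutoff = boundary_fraction * apex_height
        left = i
        while left > 0 and sig[left - 1] <= sig[left] and sig[left] > cutoff:
            left -= 1
        right = i
        while right < sig.size - 1 and sig[right + 1] <= sig[right] and sig[right] > cutoff:
            right += 1
        if left >= i or right <= i:
            continue
        width = t[right] - t[left]
        if width < min_width_min:
            continue
        area = float(np.trapezoid(sig[left:right + 1], t[left:right + 1]))
        peaks.append(Peak(
            apex_rt_min=float(t[i]),
            left_rt_min=float(t[left]),
            right_rt_min=float(t[right]),
            area_counts=area,
            height_counts=float(apex_height),
            snr=float(apex_height / noise) if noise > 0 else float("inf"),
        ))
    return peaks


def integrate(
    trace: Trace,
    left_rt_min: float,
    right_rt_min: float,
    baseline: float | str | None = None,
) -> float:
    """Trapezoidal integral of the trace between two retention times.

    ``baseline`` may be ``None`` (raw integral), a constant level, or
    ``"rolling"`` for the rolling-minimum estimate used by peak detection.
    Interval endpoints are interpolated so the integral is exact for
    piecewise-linear signals.
    """
    t, y = trace.time_min, trace.intensity
    if not (t[0] <= left_rt_min < right_rt_min <= t[-1]):
        raise ValueError(
            f"bounds [{left_rt_min}, {right_rt_min}] outside trace span "
            f"[{t[0]}, {t[-1]}]"
        )
    if baseline == "rolling":
        y = np.clip(y - _rolling_min_baseline(y, t, 2.0), 0.0, None)
    elif baseline is not None:
        y = np.clip(y - float(baseline), 0.0, None)
    inside = (t > left_rt_min) & (t < right_rt_min)
    grid = np.concatenate(([left_rt_min], t[inside], [right_rt_min]))
    values = np.interp(grid, t, y)
    return float(np.trapezoid(values, grid))


# ---------------------------------------------------------------------------
# retention-time assignment

PEAK_TABLE_COLUMNS = (
    "analyte", "role", "apex_rt", "area", "height", "snr", "assigned", "note",
)


def assign_peaks(
    peaks_by_channel: Mapping[tuple[str, Role], Sequence[Peak]],
    panel: TransitionPanel,
    rt_tolerance_min: float = 0.5,
) -> pd.DataFrame:
    """Assign detected peaks to panel analytes by retention-time window.

    A peak is assigned iff |apex − panel Rt| ≤ tolerance on its own channel.
    Several peaks in the window: the largest area wins with a note.  Analytes
    without a panel retention time (screening-only entries) are skipped and
    flagged.  Returns the peak table (one row per peak, plus a flagged row
    for skipped channels).
    """
    if rt_tolerance_min <= 0:
        raise ValueError("rt_tolerance_min must be positive")
    rows = []
    for (analyte, role), peaks in peaks_by_channel.items():
        panel_rt = panel[analyte].rt_min
        if panel_rt is None:
            rows.append(dict(analyte=analyte, role=role.value, apex_rt=np.nan,
                             area=np.nan, height=np.nan, snr=np.nan,
                             assigned=False, note="no_panel_rt"))
            continue
        in_window = [p for p in peaks if abs(p.apex_rt_min - panel_rt) <= rt_tolerance_min]
        winner = max(in_window, key=lambda p: p.area_counts, default=None)
        for p in peaks:
            if p is winner:
                note = "multiple_in_window" if len(in_window) > 1 else ""
                assigned = True
            else:
                note = "outside_window" if p not in in_window else "lower_area_in_window"
                assigned = False
            rows.append(dict(analyte=analyte, role=role.value,
                             apex_rt=p.apex_rt_min, area=p.area_counts,
                             height=p.height_counts, snr=p.snr,
                             assigned=assigned, note=note))
    return pd.DataFrame(rows, columns=PEAK_TABLE_COLUMNS)


def pick_panel_peaks(
    traces: Sequence[Trace],
    panel: TransitionPanel,
    rt_tolerance_min: float = 0.5,
    mz_tolerance: float = 0.5,
    **detect_kwargs,
) -> pd.DataFrame:
    """Full per-run pipeline: resolve channels, detect, and assign peaks."""
    resolved = resolve_channels(traces, panel, mz_tolerance)
    peaks_by_channel: dict[tuple[str, Role], list[Peak]] = {}
    for tr in resolved:
        if tr.analyte is None:
            warnings.warn(f"channel {tr.channel_id!r} not in panel; skipped",
                          stacklevel=2)
            continue
        peaks_by_channel[(tr.analyte, tr.role)] = detect_peaks(tr, **detect_kwargs)
    return assign_peaks(peaks_by_channel, panel, rt_tolerance_min)


def quantifier_areas(peak_table: pd.DataFrame) -> dict[str, float]:
    """Assigned quantifier-peak area per analyte, from a peak table."""
    sel = peak_table[(peak_table["role"] == Role.QUANTIFIER.value)
                     & peak_table["assigned"]]
    return dict(zip(sel["analyte"], sel["area"]))
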