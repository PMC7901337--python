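"""Marker-band tissue scoring and the specimen-level margin report.

QC-passing processed spectra are labelled by transparent band-height
rules built on well-established fingerprint markers: the lipid CH2
deformation at 1441 cm^-1 (adipose), the collagen proline/hydroxyproline
pair at 860 and 938 cm^-1 (stroma), and the phenylalanine ring-breathing
band at 1004 cm^-1, which dominates the weak collagen bands in tumour.

This rule set is deliberately NOT a clinical diagnostic model: it is a
simple, fully documented classifier calibrated on the synthetic phantom
only, sufficient to close the loop from screening to margin reporting in
software.  The decision rules are:

    adipose  if h(1441)/h(1004) > 2
    stroma   elif (h(860)+h(938))/h(1004) > 1
    tumour   otherwise

where h(v) is the local baseline-corrected band height (maximum within
+/-8 cm^-1 of v minus a straight line through the window edges).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import distance_transform_edt

from .ramanproc import RamanSpectrum
from .sampler import SamplingPlan

MARKER_BANDS_CM1 = (860.0, 938.0, 1004.0, 1441.0, 1655.0)


@dataclass(frozen=True)
class BandScoreThresholds:
    adipose_ratio: float = 2.0
    collagen_ratio: float = 1.0


@dataclass(frozen=True)
class BandScore:
    """Per-class marker scores and the resulting label for one spectrum."""

    label: str
    adipose_score: float
    collagen_score: float
    heights: dict[str, float]
    marker_bands_cm1: tuple[float, ...] = MARKER_BANDS_CM1
    confidence: float = 0.0


def band_height(
    s: RamanSpectrum, center_cm1: float, half_width_cm1: float = 8.0
) -> float:
    """Local baseline-corrected band height at one marker position.

    Height = window maximum minus the straight line through the window
    edges, evaluated at the maximum; clipped at zero so absent bands score
    zero rather than negative.
    """
    wn, y = s.wavenumber, s.counts
    m = (wn >= center_cm1 - half_width_cm1) & (wn <= center_cm1 + half_width_cm1)
    if m.sum() < 3:
        raise ValueError(f"window {center_cm1}+/-{half_width_cm1} cm^-1 not covered")
    w_wn, w_y = wn[m], y[m]
    i = int(np.argmax(w_y))
    slope = (w_y[-1] - w_y[0]) / (w_wn[-1] - w_wn[0])
    baseline = w_y[0] + slope * (w_wn[i] - w_wn[0])
    return float(max(w_y[i] - baseline, 0.0))


def band_scores(
    s: RamanSpectrum,
    thresholds: BandScoreThresholds | None = None,
    half_width_cm1: float = 8.0,
) -> BandScore:
    """Score one processed spectrum against the marker-band rules."""
    th = thresholds or BandScoreThresholds()
    h = {f"{int(b)}": band_height(s, b, half_width_cm1) for b in MARKER_BANDS_CM1}
    floor = 1e-9 * max(float(np.abs(s.counts).max()), 1.0)
    ref = max(h["1004"], floor)
    adipose_score = h["1441"] / ref
    collagen_score = (h["860"] + h["938"]) / ref
    if adipose_score > th.adipose_ratio:
        label, conf = "adipose", adipose_score - th.adipose_ratio
    elif collagen_score > th.collagen_ratio:
        label, conf = "stroma", collagen_score - th.collagen_ratio
    else:
        label, conf = "tumour", th.collagen_ratio - collagen_score
    return BandScore(
        label=label,
        adipose_score=float(adipose_score),
        collagen_score=float(collagen_score),
        heights=h,
        confidence=float(conf),
    )


@dataclass(frozen=True)
class MarginReport:
    """Specimen-level summary: point labels, tumour extent, margin distance.

    ``min_margin_mm`` is the minimum Euclidean distance from any
    tumour-labelled point to the specimen edge, converted to mm through
    the pixel size; it is absent when no point was labelled tumour.  The
    tumour extent is the union of segments containing at least two tumour
    calls; segments with a single call are flagged low-confidence rather
    than painted as tumour.
    """

    point_labels: tuple[tuple[int, int, int, str], ...]
    tumour_extent: np.ndarray
    min_margin_mm: float | None
    low_confidence_segments: tuple[int, ...]
    summary: dict = field(default_factory=dict)

    def to_json(self, path: Path | None = None) -> str:
        payload = {
            "points": [
                {"row": r, "col": c, "segment_id": sid, "label": lab}
                for r, c, sid, lab in self.point_labels
            ],
            "min_margin_mm": self.min_margin_mm,
            "low_confidence_segments": list(self.low_confidence_segments),
            "summary": self.summary,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def margin_distance_px(specimen_mask: np.ndarray) -> np.ndarray:
    """Distance (px) from each specimen pixel to the specimen edge.

    The edge is the outermost ring of specimen pixels (pixels adjacent to
    background or to the image border), which therefore sits at distance
    zero — a tumour point on the edge is a positive margin.  Computed as
    the Euclidean distance transform of the background-padded mask,
    minus one.
    """
    padded = np.pad(np.asarray(specimen_mask, bool), 1, constant_values=False)
    d = distance_transform_edt(padded)[1:-1, 1:-1]
    return np.maximum(d - 1.0, 0.0)


def margin_report(
    plan: SamplingPlan,
    scores: dict[tuple[int, int], BandScore],
    specimen_mask: np.ndarray,
    pixel_size_um: float,
    segment_id: np.ndarray | None = None,
    screening_summary: dict | None = None,
) -> MarginReport:
    """Assemble the margin report from per-point labels.

    ``scores`` maps measured (row, col) points to their band scores;
    points whose spectra were discarded by QC are simply absent and are
    counted in the summary.
    """
    if not plan.points:
        raise ValueError("empty sampling plan")
    point_labels = []
    tumour_pts = []
    seg_tumour: dict[int, int] = {}
    for r, c, sid in plan.points:
        sc = scores.get((r, c))
        if sc is None:
            continue
        point_labels.append((r, c, sid, sc.label))
        if sc.label == "tumour":
            tumour_pts.append((r, c))
            seg_tumour[sid] = seg_tumour.get(sid, 0) + 1
    dist = margin_distance_px(specimen_mask)
    min_margin = None
    if tumour_pts:
        px = min(dist[r, c] for r, c in tumour_pts)
        min_margin = float(px * pixel_size_um / 1000.0)
    extent = np.zeros(np.asarray(specimen_mask).shape, dtype=bool)
    low_conf = []
    if segment_id is not None:
        for sid, n in seg_tumour.items():
            if n >= 2:
                extent |= segment_id == sid
            else:
                low_conf.append(sid)
    summary = {
        "n_points_planned": len(plan.points),
        "n_points_measured": len(point_labels),
        "n_points_discarded": len(plan.points) - len(point_labels),
        "n_tumour_points": len(tumour_pts),
        "tumour_detected": bool(tumour_pts),
    }
    if screening_summary:
        summary["screening"] = screening_summary
    return MarginReport(
        point_labels=tuple(point_labels),
        tumour_extent=extent,
        min_margin_mm=min_margin,
        low_confidence_segments=tuple(sorted(low_conf)),
        summary=summary,
    )
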