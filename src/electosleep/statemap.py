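"""EMG-informed cluster-based sleep labeling on 2-D state maps.

Each 2 s window is placed on two scatter maps: map1 plots the reference
region's LFP root-mean-square against EMG power (sum of per-bin average power
over 30-60 Hz plus 60-250 Hz); map2 plots the spectral ratios
(0.5-4.5 Hz)/(0.5-9 Hz) against (0.5-20 Hz)/(0.5-55 Hz).  Wake separates by
high EMG power, NREM by low EMG with high LFP power, REM by low EMG and low
LFP power; map2's high-ratio_y cluster refines NREM only (wake and REM mix in
its lower cluster, so it is not used to separate them).  Polygons are either
supplied as JSON configs (replacing the original interactive drawing) or fit
automatically per 60 min segment by :func:`auto_polygons`.  Points outside
every polygon stay UNKNOWN.

State-map spectra use a full-window periodogram (0.5 Hz resolution at 2 s /
1 kHz) so the 0.5 Hz band edges are representable, unlike the coarser
classifier frequency grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps
from shapely.geometry import Point, Polygon
from sklearn.cluster import KMeans
from sklearn.metrics import cohen_kappa_score, silhouette_score

from .features import Recording, average_regions, WINDOW_S
from .hypnogram import Hypnogram
from .states import NREM, REM, UNKNOWN, WAKE, state_name, state_code

SEGMENT_S = 3600.0
#: multi-polygon hits resolve in this priority order
DEFAULT_PRIORITY = (NREM, WAKE, REM)


@dataclass
class StateMapPoints:
    """Per-window state-map coordinates (column arrays of equal length)."""

    window_index: np.ndarray
    emg_power: np.ndarray
    lfp_rms: np.ndarray
    ratio_x: np.ndarray
    ratio_y: np.ndarray
    window_s: float = WINDOW_S

    def __len__(self) -> int:
        return len(self.window_index)

    def segment_of(self, segment_s: float = SEGMENT_S) -> np.ndarray:
        return ((self.window_index * self.window_s) // segment_s).astype(int)


@dataclass
class PolygonSet:
    """Per-segment polygons: ``segments[seg]["map1"|"map2"] = [(state, verts)]``."""

    segments: dict[int, dict[str, list[tuple[int, np.ndarray]]]]
    segment_s: float = SEGMENT_S
    unlabelable: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        for seg, maps in self.segments.items():
            for mp, polys in maps.items():
                for state, verts in polys:
                    poly = Polygon(np.asarray(verts, dtype=float))
                    if not poly.is_valid:
                        raise ValueError(
                            f"polygon for {state_name(state)} in segment {seg}/{mp} "
                            "is not simple"
                        )

    def to_json(self, path) -> None:
        payload = {
            "segment_s": self.segment_s,
            "unlabelable": self.unlabelable,
            "segments": {
                str(seg): {
                    mp: [
                        {"state": state_name(st), "vertices": np.asarray(v).tolist()}
                        for st, v in polys
                    ]
                    for mp, polys in maps.items()
                }
                for seg, maps in self.segments.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "PolygonSet":
        payload = json.loads(Path(path).read_text())
        segments = {
            int(seg): {
                mp: [
                    (state_code(p["state"]), np.asarray(p["vertices"], dtype=float))
                    for p in polys
                ]
                for mp, polys in maps.items()
            }
            for seg, maps in payload["segments"].items()
        }
        return cls(segments, payload.get("segment_s", SEGMENT_S),
                   payload.get("unlabelable", []))


def _window_periodogram(trace: np.ndarray, fs: float, wlen: int):
    """Full-window periodogram per 2 s window: freqs, (n_windows, n_bins) PSD."""
    n = (len(trace) // wlen) * wlen
    wins = trace[:n].reshape(-1, wlen)
    # power-per-bin units ("spectrum" scaling): a pure sine of amplitude a
    # contributes a^2/2 to its bin, so band sums are band powers
    freqs, psd = sps.periodogram(wins, fs=fs, window="boxcar",
                                 detrend="constant", scaling="spectrum", axis=-1)
    return freqs, psd


def _band_sum(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float,
              lo_inclusive: bool = True, hi_inclusive: bool = True) -> np.ndarray:
    sel = (freqs > lo) | ((freqs == lo) if lo_inclusive else np.zeros_like(freqs, bool))
    sel &= (freqs < hi) | ((freqs == hi) if hi_inclusive else np.zeros_like(freqs, bool))
    return psd[:, sel].sum(axis=1)


def statemap_features(recording: Recording, reference_region: str) -> StateMapPoints:
    """Compute per-window state-map coordinates from a recording.

    Requires an EMG channel (use the SAE classifier for EMG-free recordings)
    and an existing reference region for the LFP-side features.
    """
    if recording.emg_channel is None:
        raise ValueError(
            "recording has no EMG channel; EMG-informed labeling is impossible — "
            "use the trained SAE classifier instead"
        )
    traces, order = average_regions(recording)
    if reference_region not in order:
        raise ValueError(f"reference region {reference_region!r} not in {order}")
    ref = traces[order.index(reference_region)]
    wlen = int(round(WINDOW_S * recording.fs))

    freqs_e, psd_e = _window_periodogram(recording.emg, recording.fs, wlen)
    emg_power = (
        _band_sum(freqs_e, psd_e, 30.0, 60.0, hi_inclusive=False)
        + _band_sum(freqs_e, psd_e, 60.0, 250.0)
    )

    n = (len(ref) // wlen) * wlen
    wins = ref[:n].reshape(-1, wlen)
    lfp_rms = np.sqrt(np.mean(wins ** 2, axis=1))

    freqs_r, psd_r = _window_periodogram(ref, recording.fs, wlen)
    eps = 1e-300
    ratio_x = _band_sum(freqs_r, psd_r, 0.5, 4.5) / (
        _band_sum(freqs_r, psd_r, 0.5, 9.0) + eps
    )
    ratio_y = _band_sum(freqs_r, psd_r, 0.5, 20.0) / (
        _band_sum(freqs_r, psd_r, 0.5, 55.0) + eps
    )
    return StateMapPoints(
        window_index=np.arange(len(lfp_rms)),
        emg_power=emg_power, lfp_rms=lfp_rms,
        ratio_x=ratio_x, ratio_y=ratio_y,
    )


def _covers(verts: np.ndarray, x: float, y: float) -> bool:
    # boundary points count as inside
    return Polygon(verts).covers(Point(x, y))


def assign_by_polygons(
    points: StateMapPoints,
    polygons: PolygonSet,
    priority: tuple[int, ...] = DEFAULT_PRIORITY,
) -> Hypnogram:
    """Label windows by polygon membership on map1, NREM-refined by map2.

    A window gets a state only if its (lfp_rms, emg_power) point lies in that
    state's map1 polygon; an NREM candidate additionally requires its
    (ratio_x, ratio_y) point inside the segment's map2 NREM polygon.  Points
    in multiple same-map polygons resolve by ``priority``; everything else is
    UNKNOWN.
    """
    n = len(points)
    labels = np.full(n, UNKNOWN, dtype=np.int64)
    segs = points.segment_of(polygons.segment_s)
    # pre-build shapely polygons per segment
    built: dict[int, dict[str, list[tuple[int, Polygon]]]] = {}
    for seg, maps in polygons.segments.items():
        built[seg] = {
            mp: [(st, Polygon(np.asarray(v, dtype=float))) for st, v in polys]
            for mp, polys in maps.items()
        }
    for i in range(n):
        seg = int(segs[i])
        maps = built.get(seg)
        if maps is None:
            continue
        hits = [
            st for st, poly in maps.get("map1", [])
            if poly.covers(Point(points.lfp_rms[i], points.emg_power[i]))
        ]
        if not hits:
            continue
        cand = min(hits, key=lambda s: priority.index(s) if s in priority else 99)
        if cand == NREM:
            m2 = [p for st, p in maps.get("map2", []) if st == NREM]
            if m2 and not any(
                p.covers(Point(points.ratio_x[i], points.ratio_y[i])) for p in m2
            ):
                continue
        labels[i] = cand
    return Hypnogram(labels=labels, window_s=points.window_s)


def _core_hull(xy: np.ndarray, keep_fraction: float = 0.9) -> np.ndarray:
    """Convex hull of the central ``keep_fraction`` of points (by centroid distance)."""
    from scipy.spatial import ConvexHull

    centroid = xy.mean(axis=0)
    dist = np.linalg.norm(xy - centroid, axis=1)
    k = max(3, int(np.ceil(keep_fraction * len(xy))))
    core = xy[np.argsort(dist)[:k]]
    hull = ConvexHull(core)
    return core[hull.vertices]


def auto_polygons(
    points: StateMapPoints,
    segment_s: float = SEGMENT_S,
    seed: int = 0,
    min_points: int = 100,
    min_silhouette: float = 0.45,
) -> PolygonSet:
    """Automatic polygon initialization per 60 min segment.

    Map1 coordinates (log LFP RMS, log EMG power, standardized) are clustered
    with 3-means; the highest-EMG centroid seeds wake, and of the two low-EMG
    centroids the higher-LFP-RMS one seeds NREM, the lower REM.  Polygons are
    convex hulls shrunk to each cluster's central 90%.  The map2 NREM polygon
    is the hull of the higher-ratio_y cluster of a 2-means on the ratio plane.
    Segments whose 3 clusters are not separable (silhouette below
    ``min_silhouette``) or too small are marked unlabelable.
    """
    segs = points.segment_of(segment_s)
    segments: dict[int, dict[str, list[tuple[int, np.ndarray]]]] = {}
    unlabelable: list[int] = []
    for seg in np.unique(segs):
        sel = segs == seg
        if sel.sum() < min_points:
            unlabelable.append(int(seg))
            continue
        x1 = np.log10(np.maximum(points.lfp_rms[sel], 1e-300))
        y1 = np.log10(np.maximum(points.emg_power[sel], 1e-300))
        XY = np.stack([x1, y1], axis=1)
        Z = (XY - XY.mean(axis=0)) / np.maximum(XY.std(axis=0), 1e-12)
        # deterministic, duplication-invariant init at the expected cluster spots:
        # wake = high EMG, NREM = high LFP RMS / low EMG, REM = low / low
        qx, qy = np.quantile(Z[:, 0], [0.1, 0.9]), np.quantile(Z[:, 1], [0.1, 0.9])
        init1 = np.array([[0.0, qy[1]], [qx[1], qy[0]], [qx[0], qy[0]]])
        km = KMeans(n_clusters=3, init=init1, n_init=1, random_state=seed).fit(Z)
        lab = km.labels_
        sizes = np.bincount(lab, minlength=3)
        if sizes.min() < 3 or silhouette_score(Z, lab) < min_silhouette:
            unlabelable.append(int(seg))
            continue
        cent = np.array([Z[lab == c].mean(axis=0) for c in range(3)])
        wake_c = int(np.argmax(cent[:, 1]))                 # highest EMG
        rest = [c for c in range(3) if c != wake_c]
        nrem_c = rest[int(np.argmax([cent[c, 0] for c in rest]))]  # higher LFP RMS
        rem_c = [c for c in rest if c != nrem_c][0]
        raw_xy = np.stack([points.lfp_rms[sel], points.emg_power[sel]], axis=1)
        map1 = [
            (WAKE, _core_hull(raw_xy[lab == wake_c])),
            (NREM, _core_hull(raw_xy[lab == nrem_c])),
            (REM, _core_hull(raw_xy[lab == rem_c])),
        ]
        # map2: 2-means on the ratio plane; high ratio_y cluster = NREM
        R = np.stack([points.ratio_x[sel], points.ratio_y[sel]], axis=1)
        init2 = np.stack([np.quantile(R, 0.1, axis=0), np.quantile(R, 0.9, axis=0)])
        km2 = KMeans(n_clusters=2, init=init2, n_init=1, random_state=seed).fit(R)
        hi = int(np.argmax([R[km2.labels_ == c][:, 1].mean() for c in range(2)]))
        map2 = [(NREM, _core_hull(R[km2.labels_ == hi]))]
        segments[int(seg)] = {"map1": map1, "map2": map2}
    return PolygonSet(segments, segment_s, unlabelable)


def cohen_kappa(labels_a, labels_b) -> float:
    """Cohen's kappa between two label sets, UNKNOWN windows dropped pairwise.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement p_e from the
    marginal label frequencies (scikit-learn's estimator).
    """
    a = labels_a.labels if isinstance(labels_a, Hypnogram) else np.asarray(labels_a)
    b = labels_b.labels if isinstance(labels_b, Hypnogram) else np.asarray(labels_b)
    if len(a) != len(b):
        raise ValueError("label sequences must have equal length")
    keep = (a != UNKNOWN) & (b != UNKNOWN)
    if not keep.any():
        raise ValueError("no overlapping labeled windows; kappa undefined")
    return float(cohen_kappa_score(a[keep], b[keep]))
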