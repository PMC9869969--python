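"""Multiparametric immunofluorescence analysis of DNA damage.

Implements the imaging arm of the workflow: registration of cyclic staining
rounds, nucleus segmentation from the DAPI channel, per-nucleus cell-cycle
phase assignment (EdU + DAPI, as in a flow cytometry analysis), 53BP1
damage-focus detection with background-subtracted integrated intensities,
micronucleus detection and nearest-nucleus association, 1D and
cell-cycle-resolved 2D focus-intensity histograms, and the condition-level
correlation between G0/G1 damage and micronucleus formation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.spatial import cKDTree
from scipy.stats import mannwhitneyu, pearsonr
from skimage.feature import blob_log, peak_local_max
from skimage.filters import gaussian, threshold_li
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.registration import phase_cross_correlation
from skimage.segmentation import watershed

from .gating import (
    PHASE_G1,
    PHASE_G2M,
    PHASE_S,
    DapiAnchors,
    assign_phases,
    estimate_dapi_anchors,
    gate_edu,
)

__all__ = [
    "FocusRecord",
    "NucleusRecord",
    "MicronucleusRecord",
    "FocusHistogram1D",
    "FocusMap2D",
    "MicronucleusPhaseStats",
    "RegistrationError",
    "align_rounds",
    "segment_nuclei",
    "detect_micronuclei",
    "detect_foci",
    "histogram_1d",
    "map_2d",
    "micronucleus_phase_stats",
    "damage_micronuclei_correlation",
    "analyze_scene",
]


class RegistrationError(RuntimeError):
    """Estimated inter-round shift exceeds the configured maximum."""


@dataclass(frozen=True)
class FocusRecord:
    """A detected damage focus: centroid (row, col), background-subtracted
    integrated intensity, and support area in pixels."""

    centroid: tuple[float, float]
    integrated_intensity: float
    area: int


@dataclass
class NucleusRecord:
    """A segmented nucleus with its per-channel measurements and phase."""

    id: int
    centroid: tuple[float, float]
    area: int
    dapi_total: float
    edu_mean: float
    patm_mean: float
    phase: str | None = None
    foci: list[FocusRecord] = field(default_factory=list)
    micronucleus_ids: list[int] = field(default_factory=list)

    @property
    def n_foci(self) -> int:
        return len(self.foci)

    @property
    def total_focus_intensity(self) -> float:
        return float(sum(f.integrated_intensity for f in self.foci))


@dataclass(frozen=True)
class MicronucleusRecord:
    """A detected micronucleus associated with its nearest nucleus."""

    id: int
    centroid: tuple[float, float]
    area: int
    nearest_nucleus_id: int
    distance: float  # edge-to-edge, pixels
    marker_content: float  # integrated DAPI, a.u.


# ---------------------------------------------------------------------------
# registration


def align_rounds(
    rounds: np.ndarray,
    reference: int = 0,
    *,
    dapi_channel: int = 0,
    max_shift: float | None = None,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Register cyclic staining rounds by DAPI cross-correlation.

    ``rounds`` has shape (n_rounds, n_channels, H, W).  Translation-only
    shifts are estimated between each round's DAPI channel and the reference
    round, then applied to every channel of the round.  Returns the aligned
    stack and the list of applied (row, col) shifts.

    Raises :class:`RegistrationError` when an estimated shift component
    exceeds ``max_shift`` (default: a quarter of the image size).
    """
    rounds = np.asarray(rounds, dtype=float)
    if rounds.ndim != 4:
        raise ValueError("expected (n_rounds, n_channels, H, W)")
    if max_shift is None:
        max_shift = min(rounds.shape[-2:]) / 4.0

    ref = rounds[reference, dapi_channel]
    aligned = rounds.copy()
    shifts: list[tuple[float, float]] = []
    for r in range(rounds.shape[0]):
        if r == reference:
            shifts.append((0.0, 0.0))
            continue
        shift, _, _ = phase_cross_correlation(ref, rounds[r, dapi_channel])
        if np.max(np.abs(shift)) > max_shift:
            raise RegistrationError(
                f"round {r}: estimated shift {tuple(shift)} exceeds maximum {max_shift}"
            )
        for c in range(rounds.shape[1]):
            aligned[r, c] = ndi.shift(rounds[r, c], shift, order=1, mode="constant")
        shifts.append((float(shift[0]), float(shift[1])))
    return aligned, shifts


# ---------------------------------------------------------------------------
# segmentation


def segment_nuclei(
    dapi: np.ndarray,
    size_window: tuple[float, float] = (150.0, 4000.0),
    *,
    threshold: float | None = None,
    smoothing_sigma: float = 2.0,
    min_peak_distance: int = 10,
) -> np.ndarray:
    """Segment nuclei from a DAPI image.

    Global threshold (Li's minimum cross-entropy unless given), hole
    filling, then a watershed
    split of touching objects seeded on the maxima of the smoothed distance
    transform.  Objects with area outside ``size_window`` are removed from
    the nucleus map (small DAPI-positive objects are handled separately by
    :func:`detect_micronuclei`).  A blank image yields an empty label map.
    """
    dapi = np.asarray(dapi, dtype=float)
    if dapi.ndim != 2:
        raise ValueError("expected a single-channel image")
    if threshold is None:
        if np.ptp(dapi) == 0:
            return np.zeros(dapi.shape, dtype=np.int32)
        # Li's minimum-cross-entropy threshold: robust to the large
        # background fraction that biases Otsu upward on sparse scenes
        threshold = threshold_li(dapi)
    binary = ndi.binary_fill_holes(dapi > threshold)
    if not binary.any():
        return np.zeros(dapi.shape, dtype=np.int32)

    distance = ndi.distance_transform_edt(binary)
    smoothed = gaussian(distance, smoothing_sigma)
    coords = peak_local_max(
        smoothed, min_distance=min_peak_distance, labels=binary, exclude_border=False
    )
    markers = np.zeros(dapi.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    labels = watershed(-smoothed, markers, mask=binary)

    # size filtering, then compact relabeling for stable ids
    out = np.zeros_like(labels, dtype=np.int32)
    next_id = 1
    for prop in regionprops(labels):
        if size_window[0] <= prop.area <= size_window[1]:
            out[labels == prop.label] = next_id
            next_id += 1
    return out


# ---------------------------------------------------------------------------
# micronuclei


def detect_micronuclei(
    dapi: np.ndarray,
    nucleus_labels: np.ndarray,
    size_window: tuple[float, float] | None = None,
    association_cutoff: float | None = None,
    *,
    threshold: float | None = None,
    return_discarded: bool = False,
) -> list[MicronucleusRecord] | tuple[list[MicronucleusRecord], int]:
    """Detect micronuclei and associate each with its nearest nucleus.

    DAPI-positive connected components outside the nucleus map whose area
    falls inside ``size_window`` (default 1%-15% of the median nucleus
    area) become candidate micronuclei.  Each candidate within
    ``association_cutoff`` (default half the median nucleus equivalent
    diameter) of a nucleus, measured edge-to-edge between pixel masks, is
    assigned to the nearest nucleus; exact distance ties are broken toward
    the lower nucleus id.  Farther candidates are discarded; their count is
    returned when ``return_discarded`` is set and reported in a warning
    otherwise.
    """
    dapi = np.asarray(dapi, dtype=float)
    nucleus_props = regionprops(nucleus_labels)
    if not nucleus_props:
        return ([], 0) if return_discarded else []
    areas = np.array([p.area for p in nucleus_props])
    med_area = float(np.median(areas))
    if size_window is None:
        size_window = (0.01 * med_area, 0.15 * med_area)
    if association_cutoff is None:
        association_cutoff = 0.5 * 2.0 * np.sqrt(med_area / np.pi)

    if threshold is None:
        threshold = threshold_li(dapi) if np.ptp(dapi) > 0 else np.inf
    candidates = cc_label((dapi > threshold) & (nucleus_labels == 0))

    pad = int(np.ceil(association_cutoff)) + 1
    records: list[MicronucleusRecord] = []
    n_discarded = 0
    for prop in regionprops(candidates):
        if not (size_window[0] <= prop.area <= size_window[1]):
            continue
        mn_coords = prop.coords.astype(float)
        tree = cKDTree(mn_coords)
        r0, c0, r1, c1 = prop.bbox
        r0, c0 = max(r0 - pad, 0), max(c0 - pad, 0)
        r1 = min(r1 + pad, dapi.shape[0])
        c1 = min(c1 + pad, dapi.shape[1])
        window = nucleus_labels[r0:r1, c0:c1]
        best: tuple[float, int] | None = None
        for nid in np.unique(window):
            if nid == 0:
                continue
            ncoords = np.argwhere(window == nid) + (r0, c0)
            d = float(tree.query(ncoords.astype(float))[0].min())
            if best is None or d < best[0] - 1e-12 or (abs(d - best[0]) <= 1e-12 and nid < best[1]):
                best = (d, int(nid))
        if best is None or best[0] > association_cutoff:
            n_discarded += 1
            continue
        records.append(
            MicronucleusRecord(
                id=len(records) + 1,
                centroid=tuple(map(float, prop.centroid)),
                area=int(prop.area),
                nearest_nucleus_id=best[1],
                distance=best[0],
                marker_content=float(dapi[tuple(prop.coords.T)].sum()),
            )
        )
    if return_discarded:
        return records, n_discarded
    if n_discarded:
        warnings.warn(f"{n_discarded} small object(s) beyond the association cutoff discarded",
                      stacklevel=2)
    return records


# ---------------------------------------------------------------------------
# foci


def detect_foci(
    marker: np.ndarray,
    nucleus_mask: np.ndarray,
    *,
    min_sigma: float = 1.0,
    max_sigma: float = 3.0,
    num_sigma: int = 5,
    threshold: float | None = None,
    support_factor: float = 4.0,
) -> list[FocusRecord]:
    """Detect damage foci inside one nucleus mask.

    Multiscale Laplacian-of-Gaussian blob detection restricted to the mask;
    overlapping detections are merged to the stronger maximum.  Each focus's
    integrated intensity is the pixel sum over its support (a disk of radius
    ``support_factor * sigma`` clipped to the mask; pixels claimed by
    several foci go to the nearest one) minus the local median background
    of the focus-free mask pixels times the support size.

    The detection threshold defaults to five times the robust (MAD-based)
    intensity spread of the mask pixels.
    """
    marker = np.asarray(marker, dtype=float)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if not nucleus_mask.any():
        raise ValueError("nucleus mask is empty")

    inside = marker[nucleus_mask]
    if threshold is None:
        # lower-quantile spread: foci only inflate the upper tail, so
        # q50 - q16 estimates the background noise sd even in crowded nuclei
        q16, q50 = np.quantile(inside, [0.1587, 0.5])
        threshold = max(5.0 * (q50 - q16), 1e-6)

    masked = np.where(nucleus_mask, marker, 0.0)
    blobs = blob_log(
        masked,
        min_sigma=min_sigma,
        max_sigma=max_sigma,
        num_sigma=num_sigma,
        threshold=threshold,
        overlap=0.5,
    )
    # keep detections whose center lies in the mask
    blobs = [b for b in blobs if nucleus_mask[int(round(b[0])), int(round(b[1]))]]
    if not blobs:
        return []

    centers = np.array([(b[0], b[1]) for b in blobs])
    sigmas = np.array([b[2] for b in blobs])

    mask_coords = np.argwhere(nucleus_mask)
    tree = cKDTree(centers)
    dist, owner = tree.query(mask_coords.astype(float))
    radius = support_factor * sigmas[owner]
    in_support = dist <= radius

    bg_pixels = marker[tuple(mask_coords[~in_support].T)]
    background = float(np.median(bg_pixels)) if len(bg_pixels) else 0.0

    records: list[FocusRecord] = []
    for k in range(len(blobs)):
        sup = mask_coords[in_support & (owner == k)]
        if len(sup) == 0:
            continue
        total = float(marker[tuple(sup.T)].sum()) - background * len(sup)
        if total <= 0:
            continue
        records.append(
            FocusRecord(
                centroid=(float(centers[k, 0]), float(centers[k, 1])),
                integrated_intensity=total,
                area=int(len(sup)),
            )
        )
    return records


# ---------------------------------------------------------------------------
# histograms


@dataclass(frozen=True)
class FocusHistogram1D:
    """Mean focus count per cell in log-spaced intensity bins."""

    bin_edges: np.ndarray
    mean_counts: np.ndarray
    n_cells: int

    @property
    def mean_foci_per_cell(self) -> float:
        return float(self.mean_counts.sum())


@dataclass(frozen=True)
class FocusMap2D:
    """Cell-cycle-resolved focus-intensity map.

    Cells are arranged along the x axis in order of increasing DAPI content
    and grouped into position bins; each matrix column holds the per-cell
    mean focus count in each intensity bin for that group.  Phase boundary
    indices mark the first S and first G2/M cell in DAPI order (cell index
    and column index).
    """

    bin_edges: np.ndarray
    counts: np.ndarray  # raw focus counts, (n_intensity_bins, n_cell_bins)
    cells_per_bin: np.ndarray
    boundary_s: int | None
    boundary_g2m: int | None

    @property
    def matrix(self) -> np.ndarray:
        return self.counts / np.maximum(self.cells_per_bin, 1)[None, :]

    @property
    def column_boundaries(self) -> tuple[int | None, int | None]:
        cum = np.cumsum(self.cells_per_bin)

        def col(i: int | None) -> int | None:
            return None if i is None else int(np.searchsorted(cum, i + 1))

        return col(self.boundary_s), col(self.boundary_g2m)

    def marginal(self) -> FocusHistogram1D:
        """Marginal over the cell axis; equals the 1D histogram exactly."""
        n = int(self.cells_per_bin.sum())
        return FocusHistogram1D(
            bin_edges=self.bin_edges,
            mean_counts=self.counts.sum(axis=1) / n,
            n_cells=n,
        )


def _default_edges(intensities: np.ndarray, n_bins: int) -> np.ndarray:
    lo = float(intensities.min())
    hi = float(intensities.max())
    if lo == hi:
        lo, hi = lo * 0.999, hi * 1.001
    return np.geomspace(lo, hi, n_bins + 1)


def histogram_1d(
    cells: list[NucleusRecord],
    bin_edges: np.ndarray | None = None,
    *,
    n_bins: int = 16,
) -> FocusHistogram1D:
    """Per-bin mean focus count per cell.

    With ``bin_edges`` omitted, 16 log-spaced bins spanning the observed
    focus-intensity range are used, so the bins sum to the mean number of
    foci per cell.
    """
    if not cells:
        raise ValueError("empty cell list")
    intensities = np.array(
        [f.integrated_intensity for c in cells for f in c.foci], dtype=float
    )
    if bin_edges is None:
        if len(intensities) == 0:
            bin_edges = np.geomspace(1.0, 2.0, n_bins + 1)
        else:
            bin_edges = _default_edges(intensities, n_bins)
    counts, _ = np.histogram(intensities, bins=bin_edges)
    return FocusHistogram1D(
        bin_edges=np.asarray(bin_edges, dtype=float),
        mean_counts=counts / len(cells),
        n_cells=len(cells),
    )


def map_2d(
    cells: list[NucleusRecord],
    bin_edges: np.ndarray | None = None,
    *,
    n_bins: int = 16,
    n_cell_bins: int | None = None,
) -> FocusMap2D:
    """Cell-cycle-resolved 2D focus-intensity map.

    Cells must carry phase labels.  ``n_cell_bins`` defaults to one column
    per cell.  The marginal over the cell axis reproduces
    :func:`histogram_1d` with the same edges exactly.
    """
    if not cells:
        raise ValueError("empty cell list")
    if any(c.phase is None for c in cells):
        raise ValueError("cells must have phase labels assigned")
    order = np.argsort([c.dapi_total for c in cells], kind="stable")
    ordered = [cells[i] for i in order]

    intensities = np.array(
        [f.integrated_intensity for c in ordered for f in c.foci], dtype=float
    )
    if bin_edges is None:
        if len(intensities) == 0:
            bin_edges = np.geomspace(1.0, 2.0, n_bins + 1)
        else:
            bin_edges = _default_edges(intensities, n_bins)
    bin_edges = np.asarray(bin_edges, dtype=float)

    if n_cell_bins is None:
        n_cell_bins = len(ordered)
    groups = np.array_split(np.arange(len(ordered)), n_cell_bins)
    counts = np.zeros((len(bin_edges) - 1, len(groups)), dtype=float)
    cells_per_bin = np.zeros(len(groups), dtype=int)
    for j, grp in enumerate(groups):
        vals = np.array(
            [f.integrated_intensity for i in grp for f in ordered[i].foci], dtype=float
        )
        counts[:, j], _ = np.histogram(vals, bins=bin_edges)
        cells_per_bin[j] = len(grp)

    phases = [c.phase for c in ordered]
    boundary_s = next((i for i, p in enumerate(phases) if p == PHASE_S), None)
    boundary_g2m = next((i for i, p in enumerate(phases) if p == PHASE_G2M), None)
    return FocusMap2D(
        bin_edges=bin_edges,
        counts=counts,
        cells_per_bin=cells_per_bin,
        boundary_s=boundary_s,
        boundary_g2m=boundary_g2m,
    )


# ---------------------------------------------------------------------------
# micronucleus / damage statistics


@dataclass(frozen=True)
class MicronucleusPhaseStats:
    """Per-phase micronucleus association and the G0/G1 damage contrast.

    ``phase_fractions`` gives, for each phase, the fraction of all
    micronuclei whose parent nucleus is in that phase (None when the scene
    has no micronuclei).  ``mannwhitney_p`` is the two-sided rank-test
    p-value comparing total 53BP1 focus intensity between
    micronucleus-bearing and non-bearing G0/G1 nuclei.
    """

    phase_fractions: dict[str, float] | None
    n_micronuclei: int
    mannwhitney_p: float | None
    n_bearing: int
    n_nonbearing: int
    median_bearing: float | None
    median_nonbearing: float | None


def micronucleus_phase_stats(
    cells: list[NucleusRecord],
    micronuclei: list[MicronucleusRecord],
) -> MicronucleusPhaseStats:
    """Associate micronuclei with phases and test the G0/G1 damage contrast."""
    by_id = {c.id: c for c in cells}
    if micronuclei:
        parent_phases = [by_id[m.nearest_nucleus_id].phase for m in micronuclei]
        fractions = {
            p: float(np.mean([q == p for q in parent_phases]))
            for p in (PHASE_G1, PHASE_S, PHASE_G2M)
        }
    else:
        fractions = None

    g1 = [c for c in cells if c.phase == PHASE_G1]
    bearing = [c.total_focus_intensity for c in g1 if c.micronucleus_ids]
    nonbearing = [c.total_focus_intensity for c in g1 if not c.micronucleus_ids]
    if bearing and nonbearing:
        p = float(mannwhitneyu(bearing, nonbearing, alternative="two-sided").pvalue)
    else:
        p = None
    return MicronucleusPhaseStats(
        phase_fractions=fractions,
        n_micronuclei=len(micronuclei),
        mannwhitney_p=p,
        n_bearing=len(bearing),
        n_nonbearing=len(nonbearing),
        median_bearing=float(np.median(bearing)) if bearing else None,
        median_nonbearing=float(np.median(nonbearing)) if nonbearing else None,
    )


def damage_micronuclei_correlation(
    pairs: np.ndarray | list[tuple[float, float]],
) -> tuple[float, float]:
    """Pearson correlation across conditions between mean G0/G1 focus
    intensity and mean micronuclei per cell.

    ``pairs`` holds one (mean G0/G1 focus intensity, mean micronuclei per
    cell) tuple per experimental condition; at least 3 are required.
    Returns ``(r, p)``.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected pairs of (focus intensity, micronuclei per cell)")
    if len(arr) < 3:
        raise ValueError("need at least 3 condition pairs")
    if np.ptp(arr[:, 0]) == 0 or np.ptp(arr[:, 1]) == 0:
        raise ValueError("zero variance in a condition summary")
    res = pearsonr(arr[:, 0], arr[:, 1])
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# scene-level pipeline


@dataclass
class ImagingResult:
    """Output of :func:`analyze_scene`."""

    nuclei: list[NucleusRecord]
    micronuclei: list[MicronucleusRecord]
    labels: np.ndarray
    anchors: DapiAnchors

    def nucleus_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [c.id for c in self.nuclei],
                "centroid_row": [c.centroid[0] for c in self.nuclei],
                "centroid_col": [c.centroid[1] for c in self.nuclei],
                "area": [c.area for c in self.nuclei],
                "dapi_total": [c.dapi_total for c in self.nuclei],
                "edu_mean": [c.edu_mean for c in self.nuclei],
                "patm_mean": [c.patm_mean for c in self.nuclei],
                "phase": [c.phase for c in self.nuclei],
                "n_foci": [c.n_foci for c in self.nuclei],
                "total_focus_intensity": [c.total_focus_intensity for c in self.nuclei],
                "n_micronuclei": [len(c.micronucleus_ids) for c in self.nuclei],
            }
        )

    def focus_table(self) -> pd.DataFrame:
        rows = [
            (c.id, f.centroid[0], f.centroid[1], f.integrated_intensity, f.area)
            for c in self.nuclei
            for f in c.foci
        ]
        return pd.DataFrame(
            rows, columns=["nucleus_id", "row", "col", "integrated_intensity", "area"]
        )

    def micronucleus_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [m.id for m in self.micronuclei],
                "row": [m.centroid[0] for m in self.micronuclei],
                "col": [m.centroid[1] for m in self.micronuclei],
                "area": [m.area for m in self.micronuclei],
                "nearest_nucleus_id": [m.nearest_nucleus_id for m in self.micronuclei],
                "distance": [m.distance for m in self.micronuclei],
                "marker_content": [m.marker_content for m in self.micronuclei],
            }
        )


def analyze_scene(
    stack: np.ndarray,
    *,
    channel_order: tuple[str, ...] = ("dapi", "edu", "53bp1", "patm"),
    anchors: DapiAnchors | None = None,
    nucleus_size_window: tuple[float, float] = (150.0, 4000.0),
    micronucleus_size_window: tuple[float, float] | None = None,
    association_cutoff: float | None = None,
    focus_threshold: float | None = None,
) -> ImagingResult:
    """Run the full imaging pipeline on one multichannel scene.

    Segments nuclei on the DAPI channel, measures per-nucleus DAPI / EdU /
    p-ATM, gates EdU positivity across the population, estimates 2n/4n
    anchors from the nucleus DAPI totals unless given, assigns phases under
    the imaging context, detects foci in the 53BP1 channel per nucleus, and
    detects and associates micronuclei.
    """
    chan = {name: stack[i] for i, name in enumerate(channel_order)}
    labels = segment_nuclei(chan["dapi"], nucleus_size_window)
    props = regionprops(labels)
    nuclei: list[NucleusRecord] = []
    for prop in props:
        mask_idx = tuple(prop.coords.T)
        nuclei.append(
            NucleusRecord(
                id=int(prop.label),
                centroid=tuple(map(float, prop.centroid)),
                area=int(prop.area),
                dapi_total=float(chan["dapi"][mask_idx].sum()),
                edu_mean=float(chan["edu"][mask_idx].mean()),
                patm_mean=float(chan["patm"][mask_idx].mean()),
            )
        )
    if not nuclei:
        raise ValueError("no nuclei segmented")

    table = pd.DataFrame(
        {
            "dapi_total": [c.dapi_total for c in nuclei],
            "edu_mean": [c.edu_mean for c in nuclei],
        }
    )
    edu_pos = gate_edu(table)
    if anchors is None:
        table["edu_positive"] = edu_pos
        anchors = estimate_dapi_anchors(
            table, use_edu_negative_only=True, min_events=min(200, max(len(nuclei) // 2, 4))
        )
    phases = assign_phases(
        table["dapi_total"].to_numpy(), edu_pos, anchors, context="imaging"
    )
    for c, ph in zip(nuclei, phases):
        c.phase = str(ph)

    for c in nuclei:
        mask = labels == c.id
        c.foci = detect_foci(chan["53bp1"], mask, threshold=focus_threshold)

    micronuclei = detect_micronuclei(
        chan["dapi"],
        labels,
        micronucleus_size_window,
        association_cutoff,
        return_discarded=False,
    )
    by_id = {c.id: c for c in nuclei}
    for m in micronuclei:
        by_id[m.nearest_nucleus_id].micronucleus_ids.append(m.id)
    return ImagingResult(nuclei=nuclei, micronuclei=micronuclei, labels=labels, anchors=anchors)
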