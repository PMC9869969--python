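"""Rendering of synthetic multiparametric immunofluorescence scenes.

Produces a four-channel image stack (DAPI, EdU, 53BP1, p-ATM) of elliptical
nuclei with known phase, DNA content, Gaussian 53BP1 damage foci, and
peri-nuclear micronuclei, together with the exact ground truth of every
rendered object.  Used as the test bed for segmentation, focus detection,
micronucleus association, and the cell-cycle-resolved damage histograms.

Conventions: pixel coordinates are 0-based (row, column); intensities are
arbitrary units; the total DAPI intensity of a nucleus is proportional to
its true DNA content.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

__all__ = [
    "SceneParams",
    "SceneTruth",
    "NucleusTruth",
    "FocusTruth",
    "MicronucleusTruth",
    "render_nuclei_scene",
    "CHANNELS",
]

#: Channel order of the rendered stack.
CHANNELS = ("dapi", "edu", "53bp1", "patm")


@dataclass(frozen=True)
class FocusTruth:
    centroid: tuple[float, float]
    integrated_intensity: float
    sigma: float


@dataclass(frozen=True)
class NucleusTruth:
    id: int
    centroid: tuple[float, float]
    area: int
    phase: str
    dna_content: float  # in units of the 2n content
    axes: tuple[float, float]
    orientation: float
    patm_mean: float
    foci: list[FocusTruth] = field(default_factory=list)


@dataclass(frozen=True)
class MicronucleusTruth:
    id: int
    centroid: tuple[float, float]
    area: int
    parent_nucleus_id: int


@dataclass
class SceneTruth:
    """Ground truth of a rendered scene.

    ``labels`` is the truth nucleus label map (0 = background); it is kept
    in memory only and omitted from the JSON sidecar.
    """

    nuclei: list[NucleusTruth]
    micronuclei: list[MicronucleusTruth]
    labels: np.ndarray | None = None

    def to_json(self) -> str:
        payload = {
            "nuclei": [asdict(n) for n in self.nuclei],
            "micronuclei": [asdict(m) for m in self.micronuclei],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SceneTruth":
        payload = json.loads(text)
        nuclei = [
            NucleusTruth(
                id=n["id"],
                centroid=tuple(n["centroid"]),
                area=n["area"],
                phase=n["phase"],
                dna_content=n["dna_content"],
                axes=tuple(n["axes"]),
                orientation=n["orientation"],
                patm_mean=n["patm_mean"],
                foci=[
                    FocusTruth(tuple(f["centroid"]), f["integrated_intensity"], f["sigma"])
                    for f in n["foci"]
                ],
            )
            for n in payload["nuclei"]
        ]
        micronuclei = [
            MicronucleusTruth(
                id=m["id"],
                centroid=tuple(m["centroid"]),
                area=m["area"],
                parent_nucleus_id=m["parent_nucleus_id"],
            )
            for m in payload["micronuclei"]
        ]
        return cls(nuclei=nuclei, micronuclei=micronuclei)


@dataclass(frozen=True)
class SceneParams:
    """Parameters of a rendered scene.

    Random layout is used unless explicit ``centers`` (and optionally
    ``phases``, ``focus_specs``, ``micronucleus_specs``) are given.

    Attributes
    ----------
    shape: image (rows, cols).
    n_nuclei: number of nuclei to place.
    nucleus_radius: mean equivalent radius, pixels.
    radius_jitter: relative sd of per-nucleus radius.
    min_gap: minimum edge-to-edge gap between random nuclei, pixels.
    phase_fractions: (G0/G1, S, G2/M) probabilities for random phases.
    intensity_2n: total DAPI intensity of a 2n nucleus.
    foci_per_nucleus: inclusive (min, max) of the per-nucleus focus count.
    focus_intensity_range: log-uniform range of integrated focus intensity.
    focus_sigma: Gaussian sd of rendered foci, pixels.
    min_focus_separation: minimum distance between focus centers, pixels.
    focus_background: uniform 53BP1 per-pixel level inside nuclei.
    micronucleus_rate: expected micronuclei per nucleus (random layout).
    micronucleus_radius: micronucleus disk radius, pixels.
    micronucleus_offset: (min, max) edge-to-edge distance from the parent.
    edu_mean_pos / edu_mean_neg: per-pixel EdU fill for S / non-S nuclei.
    patm_mean_range: per-nucleus mean p-ATM fill, drawn log-uniformly.
    noise_sd: additive Gaussian pixel noise on every channel.
    centers / phases / focus_specs / micronucleus_specs:
        explicit layout overrides; ``focus_specs`` is one list per nucleus
        of (row, col, integrated_intensity); ``micronucleus_specs`` is a
        list of (parent_index, edge_distance, angle_radians).
    """

    shape: tuple[int, int] = (600, 600)
    n_nuclei: int = 50
    nucleus_radius: float = 14.0
    radius_jitter: float = 0.12
    min_gap: float = 8.0
    phase_fractions: tuple[float, float, float] = (0.50, 0.35, 0.15)
    intensity_2n: float = 5000.0
    foci_per_nucleus: tuple[int, int] = (0, 10)
    focus_intensity_range: tuple[float, float] = (200.0, 2000.0)
    focus_sigma: float = 1.4
    # ~2.4x the rendered FWHM: discrete foci; closer pairs are optically
    # shoulder-merged and are exercised by dedicated merge tests instead
    min_focus_separation: float = 9.0
    focus_background: float = 0.5
    micronucleus_rate: float = 0.3
    micronucleus_radius: float = 3.0
    micronucleus_offset: tuple[float, float] = (3.0, 10.0)
    edu_mean_pos: float = 40.0
    edu_mean_neg: float = 2.0
    patm_mean_range: tuple[float, float] = (5.0, 20.0)
    noise_sd: float = 0.2
    seed: int = 0
    centers: tuple[tuple[float, float], ...] | None = None
    phases: tuple[str, ...] | None = None
    focus_specs: tuple[tuple[tuple[float, float, float], ...], ...] | None = None
    micronucleus_specs: tuple[tuple[int, float, float], ...] | None = None


_PHASE_CONTENT = {"G0/G1": 1.0, "S": 1.5, "G2/M": 2.0}


def _gaussian_spot(
    image: np.ndarray, center: tuple[float, float], intensity: float, sigma: float
) -> None:
    """Add a Gaussian spot normalized so its pixel sum equals ``intensity``."""
    r0, c0 = center
    rad = int(np.ceil(4.0 * sigma))
    rr = np.arange(int(round(r0)) - rad, int(round(r0)) + rad + 1)
    cc = np.arange(int(round(c0)) - rad, int(round(c0)) + rad + 1)
    rr = rr[(rr >= 0) & (rr < image.shape[0])]
    cc = cc[(cc >= 0) & (cc < image.shape[1])]
    kern = np.exp(
        -((rr[:, None] - r0) ** 2 + (cc[None, :] - c0) ** 2) / (2.0 * sigma**2)
    )
    image[np.ix_(rr, cc)] += intensity * kern / kern.sum()


def _place_random_centers(
    params: SceneParams, radii: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    h, w = params.shape
    centers: list[tuple[float, float]] = []
    for i, r in enumerate(radii):
        margin = r + params.micronucleus_offset[1] + 2 * params.micronucleus_radius + 2
        for _ in range(5000):
            cand = rng.uniform([margin, margin], [h - margin, w - margin])
            ok = all(
                np.hypot(cand[0] - cr, cand[1] - cc) > r + radii[j] + params.min_gap
                for j, (cr, cc) in enumerate(centers)
            )
            if ok:
                centers.append((cand[0], cand[1]))
                break
        else:
            raise ValueError(
                f"could not place nucleus {i}: image too small for "
                f"{params.n_nuclei} non-overlapping nuclei"
            )
    return np.asarray(centers)


def render_nuclei_scene(
    params: SceneParams,
    *,
    detector_size_window: tuple[float, float] | None = None,
) -> tuple[np.ndarray, SceneTruth]:
    """Render a scene and return ``(stack, truth)``.

    ``stack`` is a float32 array of shape (4, rows, cols) with channels in
    :data:`CHANNELS` order.  If ``detector_size_window`` (min, max
    micronucleus area in pixels) is given, a warning is raised when the
    rendered micronucleus size falls outside it, since such objects would be
    invisible to the downstream detector.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.shape
    n = params.n_nuclei

    if params.centers is not None:
        if len(params.centers) != n:
            raise ValueError("centers length must equal n_nuclei")
        centers = np.asarray(params.centers, dtype=float)
        radii = np.full(n, params.nucleus_radius)
    else:
        radii = params.nucleus_radius * np.exp(
            rng.normal(0.0, params.radius_jitter, n)
        )
        centers = _place_random_centers(params, radii, rng)

    if params.phases is not None:
        phases = list(params.phases)
    else:
        phases = list(
            rng.choice(["G0/G1", "S", "G2/M"], size=n, p=list(params.phase_fractions))
        )

    dapi = np.zeros((h, w), dtype=float)
    edu = np.zeros((h, w), dtype=float)
    bp53 = np.zeros((h, w), dtype=float)
    patm = np.zeros((h, w), dtype=float)
    labels = np.zeros((h, w), dtype=np.int32)

    nuclei: list[NucleusTruth] = []
    ecc = rng.uniform(0.85, 1.0, n)  # minor/major axis ratio
    orient = rng.uniform(0.0, np.pi, n)
    patm_means = np.exp(
        rng.uniform(np.log(params.patm_mean_range[0]), np.log(params.patm_mean_range[1]), n)
    )

    for i in range(n):
        a = radii[i] / np.sqrt(ecc[i])  # preserve area ~ pi * radius^2
        b = radii[i] * np.sqrt(ecc[i])
        rr, cc = draw_ellipse(
            centers[i, 0], centers[i, 1], a, b, shape=(h, w), rotation=orient[i]
        )
        area = len(rr)
        content = _PHASE_CONTENT[phases[i]]
        dapi[rr, cc] += content * params.intensity_2n / area
        edu[rr, cc] += params.edu_mean_pos if phases[i] == "S" else params.edu_mean_neg
        patm[rr, cc] += patm_means[i]
        bp53[rr, cc] += params.focus_background
        labels[rr, cc] = i + 1

        # --- damage foci -------------------------------------------------
        foci: list[FocusTruth] = []
        if params.focus_specs is not None:
            wanted = [(fr, fc, fi) for fr, fc, fi in params.focus_specs[i]]
        else:
            k = int(rng.integers(params.foci_per_nucleus[0], params.foci_per_nucleus[1] + 1))
            lo, hi = params.focus_intensity_range
            wanted = []
            placed: list[tuple[float, float]] = []
            for _ in range(k):
                for _ in range(200):
                    rho = np.sqrt(rng.uniform()) * 0.70
                    ang = rng.uniform(0, 2 * np.pi)
                    fr = centers[i, 0] + rho * a * np.cos(ang)
                    fc = centers[i, 1] + rho * b * np.sin(ang)
                    if all(
                        np.hypot(fr - pr, fc - pc) >= params.min_focus_separation
                        for pr, pc in placed
                    ):
                        placed.append((fr, fc))
                        inten = np.exp(rng.uniform(np.log(lo), np.log(hi)))
                        wanted.append((fr, fc, inten))
                        break
        for fr, fc, fi in wanted:
            _gaussian_spot(bp53, (fr, fc), fi, params.focus_sigma)
            foci.append(FocusTruth((fr, fc), float(fi), params.focus_sigma))

        nuclei.append(
            NucleusTruth(
                id=i + 1,
                centroid=(float(centers[i, 0]), float(centers[i, 1])),
                area=area,
                phase=phases[i],
                dna_content=content,
                axes=(float(a), float(b)),
                orientation=float(orient[i]),
                patm_mean=float(patm_means[i]),
                foci=foci,
            )
        )

    # --- micronuclei -----------------------------------------------------
    if params.micronucleus_specs is not None:
        mn_wanted = list(params.micronucleus_specs)
    else:
        mn_wanted = []
        for i in range(n):
            for _ in range(rng.poisson(params.micronucleus_rate)):
                d = rng.uniform(*params.micronucleus_offset)
                ang = rng.uniform(0, 2 * np.pi)
                mn_wanted.append((i, d, ang))

    mn_area_expect = np.pi * params.micronucleus_radius**2
    if detector_size_window is not None and not (
        detector_size_window[0] <= mn_area_expect <= detector_size_window[1]
    ):
        warnings.warn(
            f"rendered micronucleus area ~{mn_area_expect:.0f} px lies outside "
            f"the detector size window {detector_size_window}",
            stacklevel=2,
        )

    micronuclei: list[MicronucleusTruth] = []
    per_px = params.intensity_2n / (np.pi * params.nucleus_radius**2)
    for parent_idx, d, ang in mn_wanted:
        a, b = nuclei[parent_idx].axes
        th = nuclei[parent_idx].orientation
        # ellipse radius along the chosen direction (in the rotated frame)
        ca, sa = np.cos(ang - th), np.sin(ang - th)
        edge_r = 1.0 / np.sqrt((ca / a) ** 2 + (sa / b) ** 2)
        dist = edge_r + d + params.micronucleus_radius
        mr = centers[parent_idx, 0] + dist * np.cos(ang)
        mc = centers[parent_idx, 1] + dist * np.sin(ang)
        if not (0 <= mr < h and 0 <= mc < w):
            continue
        # the designated parent must remain the nearest nucleus: skip
        # positions whose edge distance to any foreign nucleus is not
        # clearly larger than the offset from the parent; likewise skip
        # overlap with other micronuclei (ambiguous ground truth)
        clash = any(
            np.hypot(mr - centers[j, 0], mc - centers[j, 1])
            - radii[j]
            - params.micronucleus_radius
            < d + 2
            for j in range(n)
            if j != parent_idx
        ) or any(
            np.hypot(mr - m.centroid[0], mc - m.centroid[1])
            < 2 * params.micronucleus_radius + 2
            for m in micronuclei
        )
        if clash:
            continue
        rr, cc = draw_disk((mr, mc), params.micronucleus_radius, shape=(h, w))
        dapi[rr, cc] += per_px
        micronuclei.append(
            MicronucleusTruth(
                id=len(micronuclei) + 1,
                centroid=(float(mr), float(mc)),
                area=len(rr),
                parent_nucleus_id=parent_idx + 1,
            )
        )

    stack = np.stack([dapi, edu, bp53, patm]).astype(np.float32)
    if params.noise_sd > 0:
        stack += rng.normal(0.0, params.noise_sd, stack.shape)
        np.clip(stack, 0.0, None, out=stack)
    truth = SceneTruth(nuclei=nuclei, micronuclei=micronuclei, labels=labels)
    return stack, truth
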