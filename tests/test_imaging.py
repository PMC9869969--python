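"""Tests for the multiparametric immunofluorescence pipeline."""

from __future__ import annotations


import numpy as np
import pytest
from scipy.spatial import cKDTree

from repstress.imaging import (
    FocusRecord,
    MicronucleusRecord,
    NucleusRecord,
    RegistrationError,
    align_rounds,
    damage_micronuclei_correlation,
    detect_foci,
    detect_micronuclei,
    histogram_1d,
    map_2d,
    micronucleus_phase_stats,
    segment_nuclei,
)
from repstress.simulate import (
    DamagePopulationParams,
    SceneParams,
    render_nuclei_scene,
    simulate_damage_population,
)


def _match_foci(truth, analysis, radius=3.0):
    """Pair truth foci with detections by centroid distance."""
    detected = [
        (f.centroid, f.integrated_intensity) for n in analysis.nuclei for f in n.foci
    ]
    tree = cKDTree([c for c, _ in detected])
    pairs = []
    missed = 0
    for n in truth.nuclei:
        for f in n.foci:
            d, j = tree.query(f.centroid)
            if d < radius:
                pairs.append((f.integrated_intensity, detected[j][1]))
            else:
                missed += 1
    return pairs, missed, len(detected)


# ---------------------------------------------------------------------------
# registration


class TestAlignRounds:
    def _rounds(self, shift=None):
        stack, _ = render_nuclei_scene(SceneParams(seed=6, n_nuclei=15))
        second = stack if shift is None else np.roll(stack, shift, axis=(1, 2))
        return np.stack([stack, second])

    def test_identical_rounds_zero_shift(self):
        _, shifts = align_rounds(self._rounds())
        assert shifts[1] == (0.0, 0.0)

    def test_known_translation_recovered(self):
        aligned, shifts = align_rounds(self._rounds(shift=(5, -3)))
        assert shifts[1] == (-5.0, 3.0)  # the correcting shift
        np.testing.assert_allclose(aligned[1, 0, 10:-10, 10:-10],
                                   aligned[0, 0, 10:-10, 10:-10], atol=1e-6)

    def test_excessive_shift_raises(self):
        with pytest.raises(RegistrationError):
            align_rounds(self._rounds(shift=(300, 0)))


# ---------------------------------------------------------------------------
# segmentation


class TestSegmentNuclei:
    def test_reference_scene_counts_and_overlap(self, reference_scene):
        stack, truth = reference_scene
        labels = segment_nuclei(stack[0])
        ids = np.unique(labels)
        assert len(ids[ids > 0]) == len(truth.nuclei)
        # IoU > 0.9 against each truth mask
        for n in truth.nuclei:
            tmask = truth.labels == n.id
            match = np.bincount(labels[tmask]).argmax()
            assert match > 0
            dmask = labels == match
            iou = np.logical_and(tmask, dmask).sum() / np.logical_or(tmask, dmask).sum()
            assert iou > 0.9

    def test_blank_image_yields_empty_map(self):
        labels = segment_nuclei(np.zeros((64, 64)))
        assert labels.max() == 0

    def test_touching_nuclei_split_in_two(self):
        r = 16.0
        params = SceneParams(
            shape=(128, 128), n_nuclei=2, nucleus_radius=r,
            centers=((64.0, 54.0), (64.0, 54.0 + 1.2 * r)),
            phases=("G0/G1", "G0/G1"), focus_specs=((), ()),
            micronucleus_specs=(), noise_sd=0.0, seed=0,
        )
        stack, _ = render_nuclei_scene(params)
        labels = segment_nuclei(stack[0])
        assert labels.max() == 2


# ---------------------------------------------------------------------------
# micronuclei


class TestDetectMicronuclei:
    def test_scene_without_small_objects_yields_empty_list(self):
        params = SceneParams(n_nuclei=5, micronucleus_specs=(), seed=1)
        stack, _ = render_nuclei_scene(params)
        labels = segment_nuclei(stack[0])
        assert detect_micronuclei(stack[0], labels) == []

    def test_assigned_to_nearest_nucleus(self):
        # micronucleus 3 px from nucleus A, ~20 px from nucleus B
        params = SceneParams(
            shape=(200, 200), n_nuclei=2, nucleus_radius=14.0,
            centers=((100.0, 60.0), (100.0, 130.0)),
            phases=("G0/G1", "G0/G1"), focus_specs=((), ()),
            micronucleus_specs=((0, 3.0, 0.0),),  # off nucleus A, toward +row
            noise_sd=0.0, seed=0,
        )
        stack, truth = render_nuclei_scene(params)
        labels = segment_nuclei(stack[0])
        records = detect_micronuclei(stack[0], labels, association_cutoff=10.0)
        assert len(records) == 1
        mn = records[0]
        # identify which label is nucleus A by centroid
        from skimage.measure import regionprops

        props = {p.label: p.centroid for p in regionprops(labels)}
        label_a = min(props, key=lambda k: abs(props[k][1] - 60.0))
        assert mn.nearest_nucleus_id == label_a
        assert mn.distance == pytest.approx(3.0, abs=1.5)

    def test_far_objects_discarded_with_count(self):
        params = SceneParams(
            shape=(200, 200), n_nuclei=1, centers=((100.0, 60.0),),
            phases=("G0/G1",), focus_specs=((),),
            micronucleus_specs=((0, 40.0, 0.0),), noise_sd=0.0, seed=0,
        )
        stack, _ = render_nuclei_scene(params)
        labels = segment_nuclei(stack[0])
        records, discarded = detect_micronuclei(
            stack[0], labels, association_cutoff=10.0, return_discarded=True
        )
        assert records == []
        assert discarded == 1

    def test_size_window_excludes_large_objects(self, reference_scene):
        stack, truth = reference_scene
        labels = segment_nuclei(stack[0])
        records = detect_micronuclei(stack[0], labels, size_window=(1.0, 5.0))
        assert records == []  # rendered micronuclei are ~28 px

    def test_association_permutation_invariant(self, reference_scene):
        stack, _ = reference_scene
        labels = segment_nuclei(stack[0])
        a = detect_micronuclei(stack[0], labels)
        b = detect_micronuclei(stack[0], labels)
        assert [(m.nearest_nucleus_id, m.centroid) for m in a] == [
            (m.nearest_nucleus_id, m.centroid) for m in b
        ]


# ---------------------------------------------------------------------------
# foci


class TestDetectFoci:
    def _single_nucleus_scene(self, focus_specs):
        params = SceneParams(
            shape=(120, 120), n_nuclei=1, nucleus_radius=20.0,
            centers=((60.0, 60.0),), phases=("G0/G1",),
            focus_specs=(focus_specs,), micronucleus_specs=(), seed=0,
        )
        return render_nuclei_scene(params)

    def test_blank_nucleus_has_no_foci(self):
        stack, truth = self._single_nucleus_scene(())
        assert detect_foci(stack[2], truth.labels == 1) == []

    def test_five_spots_recovered_within_ten_percent(self):
        specs = tuple(
            (60.0 + 12 * np.cos(a), 60.0 + 12 * np.sin(a), i)
            for a, i in zip(np.linspace(0, 2 * np.pi, 6)[:-1], (200, 500, 900, 1400, 2000))
        )
        stack, truth = self._single_nucleus_scene(specs)
        records = detect_foci(stack[2], truth.labels == 1)
        assert len(records) == 5
        got = sorted(f.integrated_intensity for f in records)
        for g, want in zip(got, (200, 500, 900, 1400, 2000)):
            assert g == pytest.approx(want, rel=0.10)

    def test_sub_scale_pair_merges_to_one_focus(self):
        # two spots 2 px apart, below the smallest detection scale: the
        # documented behavior is a single merged focus carrying ~both masses
        specs = ((60.0, 59.0, 400.0), (60.0, 61.0, 600.0))
        stack, truth = self._single_nucleus_scene(specs)
        records = detect_foci(stack[2], truth.labels == 1)
        assert len(records) == 1
        assert records[0].integrated_intensity == pytest.approx(1000.0, rel=0.10)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            detect_foci(np.zeros((32, 32)), np.zeros((32, 32), dtype=bool))


# ---------------------------------------------------------------------------
# histograms


def _toy_cells(foci_per_cell):
    cells = []
    for i, intensities in enumerate(foci_per_cell):
        cells.append(
            NucleusRecord(
                id=i + 1, centroid=(0.0, 0.0), area=100,
                dapi_total=100.0 + i, edu_mean=1.0, patm_mean=1.0, phase="G0/G1",
                foci=[
                    FocusRecord(centroid=(0.0, 0.0), integrated_intensity=v, area=10)
                    for v in intensities
                ],
            )
        )
    return cells


class TestHistograms:
    def test_no_foci_all_bins_zero(self):
        hist = histogram_1d(_toy_cells([[], [], []]))
        assert hist.mean_counts.sum() == 0.0

    def test_single_bin_concentration(self):
        cells = _toy_cells([[100.0]] * 10)
        edges = np.array([1.0, 10.0, 50.0, 150.0, 1000.0])
        hist = histogram_1d(cells, edges)
        np.testing.assert_allclose(hist.mean_counts, [0.0, 0.0, 1.0, 0.0])

    def test_bins_match_brute_force_tally(self):
        rng = np.random.default_rng(0)
        cells = _toy_cells([rng.lognormal(5, 1, rng.integers(0, 8)) for _ in range(40)])
        hist = histogram_1d(cells)
        all_i = np.array([f.integrated_intensity for c in cells for f in c.foci])
        brute = np.array(
            [
                np.sum(
                    (all_i >= lo) & ((all_i < hi) | (hi == hist.bin_edges[-1]) & (all_i <= hi))
                )
                for lo, hi in zip(hist.bin_edges[:-1], hist.bin_edges[1:])
            ]
        )
        np.testing.assert_allclose(hist.mean_counts, brute / len(cells))
        assert hist.mean_foci_per_cell == pytest.approx(len(all_i) / len(cells), abs=1e-9)

    def test_map_marginal_reproduces_histogram(self):
        rng = np.random.default_rng(1)
        cells = _toy_cells([rng.lognormal(5, 1, rng.integers(0, 6)) for _ in range(30)])
        for c, phase in zip(cells, rng.choice(["G0/G1", "S", "G2/M"], len(cells))):
            c.phase = str(phase)
        fmap = map_2d(cells, n_cell_bins=7)
        hist = histogram_1d(cells, fmap.bin_edges)
        np.testing.assert_allclose(
            fmap.marginal().mean_counts, hist.mean_counts, atol=1e-9
        )

    def test_damage_confined_between_phase_boundaries(self):
        # noise-free DAPI ordering: G1 < S < G2/M; only S cells carry foci
        cells = []
        layout = [("G0/G1", 100.0, 0)] * 10 + [("S", 150.0, 3)] * 8 + [("G2/M", 200.0, 0)] * 6
        for i, (phase, dapi, k) in enumerate(layout):
            cells.append(
                NucleusRecord(
                    id=i + 1, centroid=(0.0, 0.0), area=100, dapi_total=dapi + i * 0.01,
                    edu_mean=1.0, patm_mean=1.0, phase=phase,
                    foci=[
                        FocusRecord((0.0, 0.0), 500.0 + j, 10) for j in range(k)
                    ],
                )
            )
        fmap = map_2d(cells)
        assert fmap.boundary_s == 10
        assert fmap.boundary_g2m == 18
        col_s, col_g2 = fmap.column_boundaries
        nonzero_cols = np.flatnonzero(fmap.counts.sum(axis=0))
        assert nonzero_cols.min() >= col_s
        assert nonzero_cols.max() < col_g2

    def test_single_cell_single_column(self):
        cells = _toy_cells([[100.0, 200.0]])
        fmap = map_2d(cells)
        assert fmap.counts.shape[1] == 1

    def test_empty_cell_list_rejected(self):
        with pytest.raises(ValueError):
            histogram_1d([])
        with pytest.raises(ValueError):
            map_2d([])


# ---------------------------------------------------------------------------
# micronucleus statistics


class TestMicronucleusPhaseStats:
    def test_all_micronuclei_on_g1_nuclei(self):
        cells, mns = simulate_damage_population(
            1.0, DamagePopulationParams(seed=0, mn_phase_odds=1e9)
        )
        stats = micronucleus_phase_stats(cells, mns)
        assert stats.phase_fractions["G0/G1"] == pytest.approx(1.0)

    def test_zero_micronuclei_reported_absent(self):
        cells, _ = simulate_damage_population(0.0, DamagePopulationParams(seed=1))
        stats = micronucleus_phase_stats(cells, [])
        assert stats.phase_fractions is None
        assert stats.n_micronuclei == 0

    def test_g1_enrichment_recovered_with_significant_contrast(self):
        # 5x higher micronucleus rate for G0/G1 plus intensity-linked
        # shedding: enrichment above the phase base rate and a significant
        # rank test at n = 500 cells
        params = DamagePopulationParams(n_cells=500, seed=7, mn_phase_odds=5.0)
        cells, mns = simulate_damage_population(1.5, params)
        stats = micronucleus_phase_stats(cells, mns)
        assert stats.phase_fractions["G0/G1"] > params.phase_fractions[0] + 0.15
        assert stats.mannwhitney_p is not None and stats.mannwhitney_p < 0.05

    def test_null_pvalues_roughly_uniform(self):
        # calibration: when bearing status is independent of focus
        # intensity the exact rank test must produce uniform p-values;
        # checked against the permutation-null mean and rejection rate
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(300):
            intensities = rng.lognormal(5, 0.5, 24)
            cells = _toy_cells([[v] for v in intensities])
            bearing = rng.choice(24, size=10, replace=False)
            for i in bearing:
                cells[i].micronucleus_ids.append(1)
            mns = [
                MicronucleusRecord(
                    id=k + 1, centroid=(0, 0), area=20,
                    nearest_nucleus_id=int(i) + 1, distance=3.0, marker_content=10.0,
                )
                for k, i in enumerate(bearing)
            ]
            stats = micronucleus_phase_stats(cells, mns)
            pvals.append(stats.mannwhitney_p)
        pvals = np.array(pvals)
        assert abs(pvals.mean() - 0.5) < 0.06
        assert np.mean(pvals < 0.05) < 0.10


class TestDamageCorrelation:
    def test_perfectly_linear_pairs(self):
        pairs = [(i, 2.0 * i + 1.0) for i in range(1, 6)]
        r, _ = damage_micronuclei_correlation(pairs)
        assert r == pytest.approx(1.0)
        r_dec, _ = damage_micronuclei_correlation([(i, -i) for i in range(1, 6)])
        assert r_dec == pytest.approx(-1.0)

    def test_dose_series_r_within_resampling_interval(self):
        # Monte-Carlo resampling oracle: regenerate the identical dose
        # series under many seeds and require the observed correlation to
        # fall inside the central 95% of the resampled distribution
        doses = np.linspace(0.0, 2.0, 8)

        def series_r(seed0):
            pairs = []
            for i, dose in enumerate(doses):
                cells, mns = simulate_damage_population(
                    dose, DamagePopulationParams(seed=seed0 + i)
                )
                g1 = [c.total_focus_intensity for c in cells if c.phase == "G0/G1"]
                pairs.append((np.mean(g1), len(mns) / len(cells)))
            return damage_micronuclei_correlation(pairs)[0]

        observed = series_r(1000)
        resampled = np.array([series_r(2000 + 100 * k) for k in range(30)])
        lo, hi = np.quantile(resampled, [0.025, 0.975])
        assert lo <= observed <= hi
        assert observed > 0.8  # the configured effect size encodes a strong link

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            damage_micronuclei_correlation([(1.0, 2.0), (2.0, 3.0)])
        with pytest.raises(ValueError):
            damage_micronuclei_correlation([(1.0, 2.0), (1.0, 3.0), (1.0, 4.0)])


# ---------------------------------------------------------------------------
# end-to-end on the reference scene


class TestPipelineRecovery:
    def test_nucleus_count_exact(self, reference_scene, reference_analysis):
        _, truth = reference_scene
        assert len(reference_analysis.nuclei) == len(truth.nuclei)

    def test_focus_recall_and_intensities(self, reference_scene, reference_analysis):
        _, truth = reference_scene
        pairs, missed, n_detected = _match_foci(truth, reference_analysis)
        total = len(pairs) + missed
        assert len(pairs) / total >= 0.95
        for want, got in pairs:
            assert got == pytest.approx(want, rel=0.10)

    def test_micronucleus_parents_all_correct(self, reference_scene, reference_analysis):
        _, truth = reference_scene
        res = reference_analysis
        assert len(res.micronuclei) == len(truth.micronuclei)
        det_nuclei = {n.id: n for n in res.nuclei}
        for m in res.micronuclei:
            tm = min(
                truth.micronuclei,
                key=lambda t: (t.centroid[0] - m.centroid[0]) ** 2
                + (t.centroid[1] - m.centroid[1]) ** 2,
            )
            tn = truth.nuclei[tm.parent_nucleus_id - 1]
            dn = det_nuclei[m.nearest_nucleus_id]
            assert np.hypot(
                tn.centroid[0] - dn.centroid[0], tn.centroid[1] - dn.centroid[1]
            ) < 3.0

    def test_phases_match_truth(self, reference_scene, reference_analysis):
        _, truth = reference_scene
        for n in reference_analysis.nuclei:
            tn = min(
                truth.nuclei,
                key=lambda t: (t.centroid[0] - n.centroid[0]) ** 2
                + (t.centroid[1] - n.centroid[1]) ** 2,
            )
            assert n.phase == tn.phase
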