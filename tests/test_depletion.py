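"""Missing-segment detection, centre-hit decision and z-correction."""

import numpy as np
import pytest

from plumetrace.depletion import (
    DepletionProfile,
    DepletionSegment,
    ObservationPoint,
    correct_z,
    depletion_profile,
    find_missing_segment,
    is_center_hit,
    observations_from_csv,
    observations_from_json,
    observations_to_csv,
    observations_to_json,
    peak_centroid_and_fwhm,
    scan_to_observations,
    species_tof_window,
)
from plumetrace.kinematics import propagate_distance, time_of_flight
from plumetrace.plume import Spectrum
from plumetrace.species import DIMER, MONOMER

NS = 1e-9


def make_spectrum(counts, t0=15e-6, width=10e-9):
    counts = np.asarray(counts, float)
    edges = t0 + width * np.arange(len(counts) + 1)
    return Spectrum(bin_edges=edges, counts=counts)


def gaussian_peak(n=100, centre=50, sd=8.0, amp=100.0):
    x = np.arange(n)
    return amp * np.exp(-0.5 * ((x - centre) / sd) ** 2)


class TestDepletionProfile:
    def test_identical_spectra_give_zeros(self):
        base = make_spectrum(gaussian_peak())
        prof = depletion_profile(base, base, (base.bin_edges[0], base.bin_edges[-1]))
        assert np.all(prof.depletion == 0)

    def test_fully_probed_window_gives_ones(self):
        c = gaussian_peak()
        base = make_spectrum(c)
        probed = make_spectrum(np.zeros_like(c))
        prof = depletion_profile(base, probed, (base.bin_edges[0], base.bin_edges[-1]))
        above_floor = c > 0.01 * c.max()
        assert np.all(prof.depletion[above_floor] == 1.0)
        assert np.all(prof.depletion[~above_floor] == 0.0)

    def test_binning_mismatch_rejected(self):
        base = make_spectrum(gaussian_peak())
        probed = make_spectrum(gaussian_peak(), t0=15.1e-6)
        with pytest.raises(ValueError, match="binning"):
            depletion_profile(base, probed, (base.bin_edges[0], base.bin_edges[-1]))

    def test_empty_window_rejected(self):
        base = make_spectrum(gaussian_peak())
        with pytest.raises(ValueError, match="no counts"):
            depletion_profile(base, base, (1e-6, 2e-6))

    def test_simulated_centre_hit_gives_unimodal_bump(self, small_archive):
        """At (0.6-1.6 mm, 150 ns) the monomer peak carries one contiguous
        depletion bump containing the peak centre."""
        grid, archive = small_archive
        base = archive.baselines[4500.0]
        inst = archive.instruments[4500.0]
        probed = archive.probed[(4500.0, grid.slabs[0], 150e-9)]
        window = species_tof_window(MONOMER, inst)
        prof = depletion_profile(base, probed, window)
        seg = find_missing_segment(prof)
        assert seg is not None
        centroid, _ = peak_centroid_and_fwhm(prof.baseline, prof.bin_centres)
        lo, hi = seg.tof_window
        assert lo < centroid < hi


class TestFindMissingSegment:
    def test_flat_zero_profile_gives_none(self):
        base = make_spectrum(gaussian_peak())
        prof = depletion_profile(base, base, (base.bin_edges[0], base.bin_edges[-1]))
        assert find_missing_segment(prof) is None

    def test_larger_area_run_wins(self):
        c = np.full(60, 100.0)
        p = c.copy()
        p[10:14] = 40.0  # area ~ 0.6*4
        p[30:40] = 50.0  # area ~ 0.5*10  -> larger
        base, probed = make_spectrum(c), make_spectrum(p)
        prof = depletion_profile(base, probed, (base.bin_edges[0], base.bin_edges[-1]))
        seg = find_missing_segment(prof, min_depth=0.15, min_width_bins=3)
        assert prof.bin_edges[30] <= seg.centroid <= prof.bin_edges[40]

    def test_min_width_filters_narrow_runs(self):
        c = np.full(60, 100.0)
        p = c.copy()
        p[10:12] = 0.0  # only 2 bins wide
        base, probed = make_spectrum(c), make_spectrum(p)
        prof = depletion_profile(base, probed, (base.bin_edges[0], base.bin_edges[-1]))
        assert find_missing_segment(prof, min_width_bins=3) is None
        assert find_missing_segment(prof, min_width_bins=2) is not None

    def test_translation_covariance(self):
        """Shifting both spectra by k bins shifts the segment by k bins."""
        c = gaussian_peak(n=120, centre=40)
        p = c.copy()
        p[35:45] *= 0.2
        k = 17
        seg0 = find_missing_segment(
            depletion_profile(make_spectrum(c), make_spectrum(p),
                              (15e-6, 15e-6 + 120 * 10e-9))
        )
        seg1 = find_missing_segment(
            depletion_profile(make_spectrum(np.roll(c, k)), make_spectrum(np.roll(p, k)),
                              (15e-6, 15e-6 + 120 * 10e-9))
        )
        shift = 10e-9 * k
        assert seg1.centroid - seg0.centroid == pytest.approx(shift, abs=1e-12)
        assert seg1.tof_window[0] - seg0.tof_window[0] == pytest.approx(shift, abs=1e-12)

    def test_monomer_segments_confined_to_printed_window(self, small_archive):
        """In the first slab the monomer's missing segments occur only at
        delays in the 100-200 ns window."""
        grid, archive = small_archive
        base = archive.baselines[4500.0]
        inst = archive.instruments[4500.0]
        window = species_tof_window(MONOMER, inst)
        found = []
        for d in grid.delays:
            if d == 0:
                continue
            prof = depletion_profile(base, archive.probed[(4500.0, grid.slabs[0], d)],
                                     window)
            if find_missing_segment(prof) is not None:
                found.append(d)
        assert found  # the packet does transit the slab
        assert all(100e-9 <= d <= 200e-9 for d in found)


class TestIsCenterHit:
    def _profile(self, centre=50):
        c = gaussian_peak(centre=centre)
        base = make_spectrum(c)
        return depletion_profile(base, make_spectrum(c * 0.5),
                                 (base.bin_edges[0], base.bin_edges[-1]))

    def segment_at(self, prof, centroid):
        return DepletionSegment(tof_window=(centroid - 2e-8, centroid + 2e-8),
                                depth=0.5, centroid=centroid, area=1e-8)

    def test_segment_on_peak_centroid_is_hit(self):
        prof = self._profile()
        centroid, _ = peak_centroid_and_fwhm(prof.baseline, prof.bin_centres)
        assert is_center_hit(prof, self.segment_at(prof, centroid))

    def test_segment_at_fwhm_offset_is_not(self):
        prof = self._profile()
        centroid, fwhm = peak_centroid_and_fwhm(prof.baseline, prof.bin_centres)
        assert not is_center_hit(prof, self.segment_at(prof, centroid + fwhm))

    def test_centre_hit_delay_sequence_in_first_slab(self, small_archive):
        """Scanning delays at the first slab: 150 ns is a centre hit, the
        neighbouring 100/200-ns cells are edge hits (or no segment)."""
        grid, archive = small_archive
        base = archive.baselines[4500.0]
        inst = archive.instruments[4500.0]
        window = species_tof_window(MONOMER, inst)
        verdict = {}
        for d in (100e-9, 150e-9, 200e-9):
            prof = depletion_profile(base, archive.probed[(4500.0, grid.slabs[0], d)],
                                     window)
            seg = find_missing_segment(prof)
            verdict[d] = bool(seg and is_center_hit(prof, seg))
        assert verdict[150e-9]
        assert not verdict[100e-9]
        assert not verdict[200e-9]


class TestCorrectZ:
    def _profile_with_remnants(self, a_f, a_b):
        # forward remnant, fully-depleted hole, backward remnant; remnants
        # are undepleted (probed == baseline) so only the hole is a segment
        c = np.concatenate([np.full(10, a_f / 10.0), np.full(10, 100.0),
                            np.full(10, a_b / 10.0)])
        p = c.copy()
        p[10:20] = 0.0
        base, probed = make_spectrum(c), make_spectrum(p)
        prof = depletion_profile(base, probed, (base.bin_edges[0], base.bin_edges[-1]))
        seg = find_missing_segment(prof, min_depth=0.5)
        return prof, seg

    def test_symmetric_remnant_gives_midpoint(self):
        prof, seg = self._profile_with_remnants(300.0, 300.0)
        z, frac = correct_z((0.6e-3, 1.6e-3), prof, seg)
        assert z == pytest.approx(1.1e-3)
        assert frac == pytest.approx(0.5)

    def test_three_to_one_ratio(self):
        prof, seg = self._profile_with_remnants(300.0, 100.0)
        z, frac = correct_z((0.6e-3, 1.6e-3), prof, seg)
        assert z == pytest.approx(0.6e-3 + 0.75e-3)
        assert frac == pytest.approx(0.75)

    def test_no_remnant_is_an_error(self):
        prof, seg = self._profile_with_remnants(0.0, 0.0)
        with pytest.raises(ValueError, match="remnant"):
            correct_z((0.6e-3, 1.6e-3), prof, seg)

    def test_output_always_inside_slab(self):
        for a_f, a_b in [(1.0, 500.0), (500.0, 1.0), (250.0, 250.0)]:
            prof, seg = self._profile_with_remnants(a_f, a_b)
            z, _ = correct_z((0.6e-3, 1.6e-3), prof, seg)
            assert 0.6e-3 <= z <= 1.6e-3

    def test_correction_beats_slab_midpoint_in_closed_loop(self, small_archive):
        """Against simulator ground truth, the area-ratio correction lands
        closer to the true packet centre than the slab midpoint in most
        centre-hit cells."""
        grid, archive = small_archive
        inst = archive.instruments[4500.0]
        base = archive.baselines[4500.0]
        window = species_tof_window(MONOMER, inst)
        wins = total = 0
        for slab in grid.slabs:
            for d in grid.delays:
                if d == 0:
                    continue
                prof = depletion_profile(base, archive.probed[(4500.0, slab, d)],
                                         window)
                seg = find_missing_segment(prof)
                if seg is None or not is_center_hit(prof, seg):
                    continue
                z_true = propagate_distance(46e-9, 500.0, MONOMER, inst.field, d)
                z_corr, _ = correct_z(slab, prof, seg)
                midpoint = 0.5 * (slab[0] + slab[1])
                total += 1
                if abs(z_corr - z_true) <= abs(midpoint - z_true):
                    wins += 1
        assert total >= 2
        assert wins / total >= 0.5


class TestScanToObservations:
    def test_default_archive_yields_points_for_both_species(self, small_archive):
        grid, archive = small_archive
        points = scan_to_observations(archive, [MONOMER, DIMER])
        mono = [p for p in points if p.species == MONOMER.label]
        dim = [p for p in points if p.species == DIMER.label]
        assert len(mono) >= 2
        assert len(dim) >= 2
        for p in points:
            assert 0.6e-3 <= p.z_corrected <= 4.6e-3
            assert p.delta_t > 0

    def test_dimer_delays_exceed_monomer_delays_per_slab(self, small_archive):
        """The heavier dimer transits each slab later than the monomer."""
        grid, archive = small_archive
        points = scan_to_observations(archive, [MONOMER, DIMER])

        def centre_delay(label, slab):
            ds = [p.delta_t for p in points
                  if p.species == label and slab[0] <= p.z_corrected <= slab[1]]
            return np.mean(ds) if ds else None

        compared = 0
        for slab in grid.slabs:
            m = centre_delay(MONOMER.label, slab)
            d = centre_delay(DIMER.label, slab)
            if m is not None and d is not None:
                assert d > m
                compared += 1
        assert compared >= 1

    def test_empty_archive_gives_empty_list(self):
        from plumetrace.plume import ScenarioArchive

        empty = ScenarioArchive(baselines={}, probed={}, instruments={},
                                provenance={})
        assert scan_to_observations(empty, [MONOMER]) == []

    def test_missing_instrument_metadata_is_an_error(self, small_archive):
        from plumetrace.plume import ScenarioArchive

        _, archive = small_archive
        broken = ScenarioArchive(baselines=dict(archive.baselines),
                                 probed=archive.probed, instruments={},
                                 provenance={})
        with pytest.raises(ValueError, match="instrument"):
            scan_to_observations(broken, [MONOMER])


class TestObservationIO:
    def points(self):
        return [
            ObservationPoint("(CHCA)H+", 4500.0, 150e-9, 1.07e-3,
                             fwd_fraction=0.47),
            ObservationPoint("(CHCA)2H+", 3500.0, 250e-9, 2.2e-3,
                             fwd_fraction=0.61),
        ]

    def test_json_round_trip(self, tmp_path):
        path = tmp_path / "obs.json"
        observations_to_json(self.points(), path)
        back = observations_from_json(path)
        assert back == self.points()

    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "obs.csv"
        observations_to_csv(self.points(), path)
        back = observations_from_csv(path)
        for a, b in zip(back, self.points()):
            assert a.species == b.species
            assert a.z_corrected == pytest.approx(b.z_corrected)
            assert a.delta_t == pytest.approx(b.delta_t)

    def test_fwd_fraction_validated(self):
        with pytest.raises(ValueError):
            ObservationPoint("x", 4500.0, 1e-7, 1e-3, fwd_fraction=1.5)
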