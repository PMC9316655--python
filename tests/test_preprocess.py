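"""Preprocessing chain: scaling, filtering, merging, binning, and the
intensity-conservation / filter-monotonicity invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specfid.preprocess import (
    BinningSpec,
    DegenerateSpectrumError,
    PreprocessConfig,
    Rejection,
    attach_context,
    bin_spectrum,
    drop_zero_bins,
    filter_spectrum,
    merge_spectra,
    preprocess_corpus,
    scale_intensities,
)
from specfid.models import InstrumentContext
from specfid.spectra_io import Peak, SpectrumRecord


def record_with(intensities, precursor=500.0, mz_start=100.0, **kwargs):
    peaks = [Peak(mz_start + i, x) for i, x in enumerate(intensities)]
    defaults = dict(
        peaks=peaks,
        precursor_mz=precursor,
        exact_mass=(precursor - 1.007276) if precursor is not None else None,
        adduct="[M+H]+",
        ionization_mode="positive",
        spectrum_id="t",
    )
    defaults.update(kwargs)
    return SpectrumRecord(**defaults)


class TestScaling:
    def test_max_normalization_arithmetic(self):
        scaled = scale_intensities([Peak(1, 10), Peak(2, 20), Peak(3, 40)])
        assert [p.intensity for p in scaled] == [25.0, 50.0, 100.0]

    def test_single_peak_hits_ceiling(self):
        assert scale_intensities([Peak(1, 0.003)])[0].intensity == 100.0

    def test_idempotent_at_ceiling(self):
        peaks = [Peak(1, 0.0), Peak(2, 37.5), Peak(3, 100.0)]
        assert scale_intensities(peaks) == peaks

    def test_all_zero_is_degenerate(self):
        with pytest.raises(DegenerateSpectrumError):
            scale_intensities([Peak(1, 0.0)])


class TestFilter:
    def test_five_peaks_above_two_percent_retained(self):
        rec = record_with([100, 50, 30, 10, 3, 1])
        out = filter_spectrum(rec)
        assert not isinstance(out, Rejection)

    def test_too_few_significant_peaks_rejected(self):
        rec = record_with([100, 50, 1, 1, 1, 1])
        out = filter_spectrum(rec)
        assert isinstance(out, Rejection) and out.reason == "few-peaks"

    def test_super_precursor_peaks_dropped(self):
        rec = record_with([10, 20, 30, 40, 50], precursor=300.0)
        rec.peaks.extend([Peak(299.0, 60.0), Peak(301.0, 70.0)])
        rec.peaks.sort()
        out = filter_spectrum(rec)
        assert max(p.mz for p in out.peaks) == 299.0

    def test_mass_window(self):
        light = record_with([10, 20, 30, 40, 50], precursor=90.0, mz_start=50.0)
        out = filter_spectrum(light, PreprocessConfig())
        assert isinstance(out, Rejection) and out.reason == "mass-range"

    def test_disallowed_instrument_rejected(self):
        rec = record_with([10, 20, 30, 40, 50], instrument_type="FTICR")
        out = filter_spectrum(rec, PreprocessConfig(allow_unknown_instrument=False))
        assert isinstance(out, Rejection) and out.reason == "instrument-type"

    def test_missing_precursor_reason_code(self):
        rec = record_with([10, 20, 30, 40, 50], precursor=None)
        out = filter_spectrum(rec)
        assert isinstance(out, Rejection) and out.reason == "missing-precursor"

    def test_monotone_in_thresholds(self, rng):
        """Loosening min_peaks / min_rel_intensity never rejects a
        previously accepted spectrum."""
        for _ in range(50):
            n = int(rng.integers(3, 12))
            rec = record_with(rng.uniform(0.5, 100, size=n))
            strict = PreprocessConfig(min_peaks=5, min_rel_intensity=2.0)
            loose_peaks = PreprocessConfig(min_peaks=3, min_rel_intensity=2.0)
            loose_rel = PreprocessConfig(min_peaks=5, min_rel_intensity=0.5)
            if not isinstance(filter_spectrum(rec, strict), Rejection):
                assert not isinstance(filter_spectrum(rec, loose_peaks), Rejection)
                assert not isinstance(filter_spectrum(rec, loose_rel), Rejection)


class TestMerge:
    KEY = "AAAAAAAAAAAAAA-BBBBBBBBBB-N"

    def test_same_compound_collapses_to_one(self):
        recs = [record_with([100, 50, 30, 10, 5], inchikey=self.KEY, spectrum_id=f"s{i}") for i in range(3)]
        assert len(merge_spectra(recs)) == 1

    def test_disjoint_compounds_untouched(self):
        a = record_with([100, 50], inchikey=self.KEY)
        b = record_with([100, 50], inchikey="CCCCCCCCCCCCCC-DDDDDDDDDD-N")
        assert len(merge_spectra([a, b])) == 2

    def test_coincident_peaks_accumulate_before_rescale(self):
        a = record_with([100.0], mz_start=100.2, inchikey=self.KEY, spectrum_id="a")
        b = record_with([40.0], mz_start=100.7, inchikey=self.KEY, spectrum_id="b")
        b.peaks.append(Peak(200.0, 100.0))
        b.peaks.sort()
        merged = merge_spectra([a, b])[0]
        by_bin = {int(p.mz): p.intensity for p in merged.peaks}
        # bin 100 accumulates 100+40=140, bin 200 holds 100; rescale puts 140 -> 100
        assert by_bin[100] == pytest.approx(100.0)
        assert by_bin[200] == pytest.approx(100.0 / 140.0 * 100.0)

    def test_no_inchikey_passes_through_flagged(self):
        rec = record_with([100, 50], inchikey=None)
        out = merge_spectra([rec, rec])
        assert len(out) == 2
        assert all(r.extras.get("unmerged") == "no-inchikey" for r in out)


class TestBinning:
    def test_floor_accumulation(self):
        peaks = [Peak(150.2, 60), Peak(150.9, 40), Peak(151.1, 100)]
        out = bin_spectrum(peaks, BinningSpec(bin_start=1, bin_count=200))
        assert out.values[149] == 100  # bin 150 (start 1)
        assert out.values[150] == 100  # bin 151
        assert out.values.sum() == 200

    def test_empty_peaks_zero_vector(self):
        out = bin_spectrum([], BinningSpec())
        assert out.values.shape == (1174,) and not out.values.any()

    def test_out_of_range_dropped_and_counted(self):
        out = bin_spectrum([Peak(2000.0, 5.0), Peak(50.5, 1.0)], BinningSpec())
        assert out.n_dropped_peaks == 1
        assert out.values.sum() == 1.0

    def test_conservation_and_oracle_equivalence(self, rng):
        """Binning conserves in-range intensity and matches a naive
        double-loop accumulator on 1,000 random spectra."""
        spec = BinningSpec(bin_start=1, bin_count=300)
        for _ in range(1000):
            n = int(rng.integers(1, 30))
            peaks = [Peak(float(m), float(x)) for m, x in zip(rng.uniform(0.5, 400, n), rng.uniform(0, 100, n))]
            out = bin_spectrum(peaks, spec)
            naive = np.zeros(spec.bin_count)
            in_range = 0.0
            for p in peaks:
                for i in range(spec.bin_count):
                    b = spec.bin_start + i
                    if b <= p.mz < b + 1:
                        naive[i] += p.intensity
                        in_range += p.intensity
            assert np.allclose(out.values, naive)
            assert out.values.sum() == pytest.approx(in_range, abs=1e-9)


class TestDropZeroBins:
    def test_removes_only_all_zero_columns(self):
        m = np.array([[1.0, 0, 2], [0, 0, 3]])
        reduced, kept = drop_zero_bins(m)
        assert list(kept) == [0, 2]
        assert reduced.shape == (2, 2)

    def test_identity_when_no_zero_columns(self):
        m = np.ones((3, 4))
        reduced, kept = drop_zero_bins(m)
        assert np.array_equal(reduced, m) and list(kept) == [0, 1, 2, 3]

    def test_all_zero_matrix_warns(self):
        with pytest.warns(UserWarning):
            reduced, kept = drop_zero_bins(np.zeros((2, 5)))
        assert reduced.shape == (2, 0) and kept.size == 0

    def test_projection_of_new_spectra(self):
        m = np.array([[1.0, 0, 2], [0, 0, 3]])
        _, kept = drop_zero_bins(m)
        new = np.array([5.0, 6.0, 7.0])
        assert list(new[kept]) == [5.0, 7.0]


class TestAttachContext:
    CTX = InstrumentContext(energy="high", resolution="high", mode="positive")

    def test_appends_three_bits_in_order(self):
        from specfid.preprocess import BinnedSpectrum

        binned = BinnedSpectrum(values=np.zeros(1174))
        out = attach_context(binned, self.CTX, bin_count=1174)
        assert out.values.shape == (1177,)
        assert list(out.values[-3:]) == [1, 1, 1]

    def test_all_low_negative_encodes_zeros(self):
        from specfid.preprocess import BinnedSpectrum

        ctx = InstrumentContext(energy="low", resolution="low", mode="negative")
        out = attach_context(BinnedSpectrum(values=np.zeros(10)), ctx, bin_count=10)
        assert list(out.values[-3:]) == [0, 0, 0]

    def test_double_application_guarded(self):
        from specfid.preprocess import BinnedSpectrum

        binned = BinnedSpectrum(values=np.zeros(10))
        once = attach_context(binned, self.CTX, bin_count=10)
        with pytest.raises(ValueError):
            attach_context(once, self.CTX, bin_count=10)


class TestPipeline:
    def test_merge_skipped_in_evaluation_mode(self):
        key = "AAAAAAAAAAAAAA-BBBBBBBBBB-N"
        recs = [record_with([100, 50, 30, 10, 5], inchikey=key, spectrum_id=f"s{i}") for i in range(3)]
        merged = preprocess_corpus(recs, merge=True)
        unmerged = preprocess_corpus(recs, merge=False)
        assert merged.matrix.shape[0] == 1
        assert unmerged.matrix.shape[0] == 3
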