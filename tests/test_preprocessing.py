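"""Artifact-rejection chain: thresholding, trial rejection, interpolation, referencing."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from munet.epochs import EpochSet
from munet.preprocessing import (
    PreprocessingError,
    average_reference,
    detect_bad,
    highpass,
    interpolate_channels,
    preprocess,
    qc_min_trials,
    qc_report,
    reject_trials,
)
from munet.spline import interpolation_matrix


def _epochs(data, **kw):
    return EpochSet(data=np.asarray(data, dtype=float), **kw)


class TestHighpass:
    def test_dc_removed(self, rng):
        es = _epochs(np.full((2, 3, 1200), 50.0))
        out = highpass(es, 0.3)
        assert np.max(np.abs(out.data)) < 1e-6

    def test_mu_band_untouched(self):
        t = np.arange(1200) / 500.0
        sig = np.sin(2 * np.pi * 7.0 * t)
        es = _epochs(sig[None, None, :])
        out = highpass(es, 0.3)
        mid = slice(200, 1000)
        atten = 1 - np.abs(out.data[0, 0, mid]).max() / np.abs(sig[mid]).max()
        assert atten < 0.01

    def test_nyquist_violation(self, rng):
        es = _epochs(rng.standard_normal((1, 2, 100)))
        with pytest.raises(PreprocessingError):
            highpass(es, 300.0)

    def test_timing_metadata_unchanged(self, rng):
        es = _epochs(rng.standard_normal((2, 3, 1200)))
        out = highpass(es, 0.3)
        assert out.fs == es.fs and out.t0_ms == es.t0_ms


class TestDetectBad:
    def test_single_excursion_flags_channel(self, rng):
        data = rng.uniform(-50, 50, (3, 10, 100))
        data[1, 7, 42] = 201.0
        flags = detect_bad(_epochs(data), 200.0)
        assert flags.bad[1, 7]
        assert flags.bad.sum() == 1

    def test_within_limits_no_flags(self, rng):
        data = rng.uniform(-199, 199, (3, 10, 100))
        flags = detect_bad(_epochs(data), 200.0)
        assert not flags.bad.any()

    def test_boundary_equality_kept(self):
        data = np.zeros((1, 2, 10))
        data[0, 0, 5] = 200.0
        data[0, 1, 5] = -200.0
        flags = detect_bad(_epochs(data), 200.0)
        assert not flags.bad.any()


class TestRejectTrials:
    @pytest.mark.parametrize(
        "n_bad,expect_rejected", [(20, True), (19, False), (0, False)]
    )
    def test_fifteen_percent_rule_on_128(self, n_bad, expect_rejected):
        bad = np.zeros((1, 128), dtype=bool)
        bad[0, :n_bad] = True
        from munet.preprocessing import ArtifactFlags

        flags = reject_trials(ArtifactFlags(bad=bad), 0.15)
        assert (0 in flags.rejected_trials) == expect_rejected
        if not expect_rejected and n_bad:
            assert flags.interpolated[0] == set(range(n_bad))
        if n_bad == 0:
            assert flags.interpolated == {}

    @given(frac1=st.floats(0.05, 0.9), frac2=st.floats(0.05, 0.9))
    def test_monotone_in_threshold(self, frac1, frac2):
        """Raising the allowed bad fraction never rejects more trials."""
        from munet.preprocessing import ArtifactFlags

        rng = np.random.default_rng(0)
        bad = rng.random((20, 30)) < 0.3
        lo, hi = sorted((frac1, frac2))
        r_lo = reject_trials(ArtifactFlags(bad=bad), lo).rejected_trials
        r_hi = reject_trials(ArtifactFlags(bad=bad), hi).rejected_trials
        assert r_hi <= r_lo


class TestInterpolation:
    def test_spline_consistent_channel_restored(self, montage128, rng):
        """A channel equal to the spline prediction of its peers is recovered."""
        idx = 40
        good = [i for i in range(128) if i != idx]
        field = rng.standard_normal(128) @ np.linalg.qr(rng.standard_normal((128, 128)))[0]
        # build a smooth field so the spline model applies
        theta = np.arccos(np.clip(montage128.positions @ montage128.positions[10], -1, 1))
        field = 30.0 * np.exp(-(theta**2) / (2 * np.deg2rad(35) ** 2))
        M = interpolation_matrix(
            montage128.positions[good], montage128.positions[[idx]]
        )
        field[idx] = (M @ field[good])[0]  # make it exactly spline-consistent
        data = np.tile(field[None, :, None], (1, 1, 20))
        corrupted = data.copy()
        corrupted[0, idx] = 500.0
        from munet.preprocessing import ArtifactFlags

        flags = ArtifactFlags(
            bad=np.zeros((1, 128), bool), interpolated={0: {idx}}
        )
        out, _ = interpolate_channels(_epochs(corrupted), flags, montage128)
        rms = np.sqrt(np.mean((out.data[0, idx] - data[0, idx]) ** 2))
        assert rms / np.sqrt(np.mean(data[0, idx] ** 2)) < 0.05

    def test_no_flags_is_identity(self, montage128, rng):
        data = rng.standard_normal((2, 128, 10))
        from munet.preprocessing import ArtifactFlags

        flags = ArtifactFlags(bad=np.zeros((2, 128), bool))
        out, _ = interpolate_channels(_epochs(data), flags, montage128)
        assert np.array_equal(out.data, data)

    def test_constant_field_reproduced(self, montage128):
        data = np.full((1, 128, 5), 7.5)
        data[0, 60] = -100.0
        from munet.preprocessing import ArtifactFlags

        flags = ArtifactFlags(bad=np.zeros((1, 128), bool), interpolated={0: {60}})
        out, _ = interpolate_channels(_epochs(data), flags, montage128)
        assert np.allclose(out.data[0, 60], 7.5, atol=1e-6)

    def test_too_few_good_channels_unrecoverable(self, montage128, rng):
        data = rng.standard_normal((1, 128, 5))
        from munet.preprocessing import ArtifactFlags

        flags = ArtifactFlags(
            bad=np.zeros((1, 128), bool), interpolated={0: set(range(125))}
        )
        _, out_flags = interpolate_channels(_epochs(data), flags, montage128)
        assert 0 in out_flags.unrecoverable


class TestAverageReference:
    def test_constant_channels_centred(self):
        data = np.zeros((1, 3, 4))
        data[0, 0], data[0, 1], data[0, 2] = 1.0, 2.0, 3.0
        out = average_reference(_epochs(data))
        assert np.allclose(out.data[0, :, 0], [-1.0, 0.0, 1.0])
        assert out.reference_state == "average"

    def test_channel_mean_zero_everywhere(self, rng):
        out = average_reference(_epochs(rng.standard_normal((3, 8, 50))))
        assert np.max(np.abs(out.data.mean(axis=1))) < 1e-9

    def test_double_application_errors(self, rng):
        out = average_reference(_epochs(rng.standard_normal((1, 4, 10))))
        with pytest.raises(PreprocessingError):
            average_reference(out)


class TestQcMinTrials:
    @pytest.mark.parametrize(
        "counts,minimum,expected",
        [
            ({"happiness": 5, "anger": 5, "neutral": 5}, 5, True),
            ({"happiness": 5, "anger": 4, "neutral": 9}, 5, False),
            ({"happiness": 1, "anger": 2, "neutral": 3}, 1, True),
        ],
    )
    def test_rule(self, counts, minimum, expected):
        assert qc_min_trials(counts, minimum) is expected


def test_full_chain_order_logged_and_clean_data_unflagged(montage128):
    """On clean synthetic data the chain is order-preserving and inert."""
    rng = np.random.default_rng(0)
    t = np.arange(1200) / 500.0
    data = 10 * np.sin(2 * np.pi * 7 * t)[None, None, :] * np.ones((6, 128, 1))
    data += rng.standard_normal((6, 128, 1200))
    es = _epochs(data)
    log: list = []
    clean, flags = preprocess(es, montage128, log=log)
    assert log == [
        "highpass",
        "detect_bad",
        "reject_trials",
        "interpolate_channels",
        "average_reference",
    ]
    assert clean.n_trials == 6
    assert not flags.bad.any()
    # interpolation then re-detection creates no new flags
    assert not detect_bad(clean, 200.0).bad.any()


def test_qc_report_columns():
    df = qc_report(
        [
            {
                "subject": "S01",
                "condition": "dynamic",
                "emotion": "anger",
                "trials_in": 8,
                "trials_rejected": 2,
                "channels_interpolated_mean": 1.5,
            }
        ]
    )
    assert list(df.columns) == [
        "subject",
        "condition",
        "emotion",
        "trials_in",
        "trials_rejected",
        "channels_interpolated_mean",
    ]
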