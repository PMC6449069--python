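"""SNR, best channel, cross-correlation latencies, SSA singular values and
ring aggregation."""

import numpy as np
import pytest

import mfvepcad as m
from mfvepcad.errors import DegenerateInputError
from mfvepcad.features import feature_names, select_feature_indices, xcorr_lag
from mfvepcad.records import N_CHANNELS, N_SAMPLES, N_SECTORS

from conftest import make_record, noise_record

FS = 1200.0
T_MS = np.arange(N_SAMPLES) * 1000.0 / FS


def pulse(delay_ms: float = 0.0) -> np.ndarray:
    """In-band test response peaking ~97 ms, shifted by ``delay_ms``."""
    t = T_MS - delay_ms
    env = np.exp(-0.5 * ((t - 97.5) / 20.0) ** 2)
    return env * np.sin(2 * np.pi * 14.0 * (t - 45.0) / 1000.0)


def waveform_record(delay_samples: int = 0, amp: float = 3.0, **kw):
    """Every sector/channel: shifted pulse + deterministic noise-window tone."""
    trace = amp * pulse(delay_samples * 1000.0 / FS)
    noise_tone = 0.1 * np.sin(2 * np.pi * 20.0 * T_MS / 1000.0)
    mask = np.zeros(N_SAMPLES)
    mask[390:516] = 1.0   # noise window only
    sig = np.tile(trace + noise_tone * mask, (N_SECTORS, N_CHANNELS, 1))
    return make_record(sig, **kw)


# ---------------------------------------------------------------------------
# SNR / best channel
# ---------------------------------------------------------------------------

class TestSnr:
    def test_constant_windows_give_exact_ratio(self, cfg):
        sig = np.zeros((N_SECTORS, N_CHANNELS, N_SAMPLES))
        sig[:, :, 54:180] = 2.0    # signal window constant 2 uV
        sig[:, :, 390:516] = 1.0   # every noise window constant 1 uV
        rec = make_record(sig)
        assert m.snr(rec, sector=1, channel=0, cfg=cfg) == pytest.approx(2.0)
        assert m.snr(rec, sector=60, channel=5, cfg=cfg) == pytest.approx(2.0)

    def test_white_noise_normalises_to_unit_mean(self, cfg):
        # i.i.d. noise everywhere: the ratio normalisation centres SNR at 1
        rng = np.random.default_rng(10)
        values = []
        for _ in range(17):   # 17 x 60 = 1020 sectors
            values.append(m.snr_map(noise_record(rng), cfg)[:, 0])
        assert np.mean(np.concatenate(values)) == pytest.approx(1.0, abs=0.05)

    def test_zero_noise_window_is_degenerate(self, cfg):
        sig = np.zeros((N_SECTORS, N_CHANNELS, N_SAMPLES))
        sig[:, :, 54:180] = 1.0
        with pytest.raises(DegenerateInputError):
            m.snr_map(make_record(sig), cfg)

    def test_best_channel_finds_signal_channel(self, cfg):
        rng = np.random.default_rng(11)
        sig = rng.normal(0, 1.0, size=(N_SECTORS, N_CHANNELS, N_SAMPLES))
        sig[:, 3, :] += 5.0 * pulse()
        rec = make_record(sig)
        ch, s, ok = m.best_channel(rec, sector=17, cfg=cfg)
        assert ch == 3 and ok and s >= cfg.snr_threshold

    def test_best_channel_tie_breaks_to_lowest_index(self, cfg):
        sig = np.zeros((N_SECTORS, N_CHANNELS, N_SAMPLES))
        sig[:, :, 390:516] = 1.0
        sig[:, :, 54:180] = 1.0
        sig[:, [2, 4], 54:180] = 3.0   # channels 2 and 4 identical winners
        ch, s, ok = m.best_channel(make_record(sig), sector=1, cfg=cfg)
        assert ch == 2 and s == pytest.approx(3.0)

    def test_pure_noise_is_mostly_non_analysable(self, cfg):
        rng = np.random.default_rng(12)
        analysable = []
        for _ in range(4):    # 240 sector draws
            smap = m.snr_map(noise_record(rng), cfg)
            analysable.extend(smap.max(axis=1) >= cfg.snr_threshold)
        assert np.mean(analysable) <= 0.10

    def test_scaling_leaves_best_channel_unchanged(self, cfg):
        rng = np.random.default_rng(13)
        rec = noise_record(rng)
        scaled = rec.copy_with_signal(7.5 * rec.signal)
        a = m.snr_map(rec, cfg)
        b = m.snr_map(scaled, cfg)
        assert np.array_equal(a.argmax(axis=1), b.argmax(axis=1))
        assert np.allclose(a, b)   # common scale cancels entirely


# ---------------------------------------------------------------------------
# latencies
# ---------------------------------------------------------------------------

class TestLatency:
    def test_identical_traces_zero_lag(self, cfg):
        tr = pulse()
        assert m.interocular_latency(tr, tr, cfg, fs=FS) == 0.0

    @pytest.mark.parametrize("d", [12, -12])
    def test_interocular_shift_recovered_unsigned(self, cfg, d):
        a, b = pulse(), pulse(d * 1000.0 / FS)
        assert m.interocular_latency(b, a, cfg, fs=FS) == pytest.approx(10.0)

    def test_monocular_sign_convention(self, cfg):
        trace, template = pulse(), pulse(6 * 1000.0 / FS)  # template later
        assert m.monocular_latency(trace, template, cfg, fs=FS) == \
            pytest.approx(-5.0)
        assert m.monocular_latency(template, trace, cfg, fs=FS) == \
            pytest.approx(5.0)

    @pytest.mark.parametrize("d", [-40, -17, -1, 0, 1, 5, 23, 40])
    def test_delay_equivariance_noisy(self, cfg, d):
        # injected integer-sample delay recovered to one sample under noise
        rng = np.random.default_rng(100 + d)
        a = pulse() + 0.05 * rng.normal(size=N_SAMPLES)
        b = pulse(d * 1000.0 / FS) + 0.05 * rng.normal(size=N_SAMPLES)
        lag = m.monocular_latency(b, a, cfg, fs=FS) * FS / 1000.0
        assert abs(lag - d) <= 1

    def test_flat_trace_degenerate(self, cfg):
        with pytest.raises(DegenerateInputError):
            m.interocular_latency(np.zeros(N_SAMPLES), pulse(), cfg, fs=FS)

    def test_lag_search_is_bounded(self, cfg):
        # a 70 ms shift lies outside the +/-50 ms search range
        lag = xcorr_lag(pulse(70.0)[54:180], pulse()[54:180],
                        cfg.max_lag_samples(FS))
        assert abs(lag) <= cfg.max_lag_samples(FS)


# ---------------------------------------------------------------------------
# singular spectrum analysis
# ---------------------------------------------------------------------------

class TestSsa:
    def test_constant_trace_closed_form(self):
        c = 3.0
        sv = m.ssa_singular_values(np.full(126, c), L=7, n_sv=7)
        assert sv[0] == pytest.approx(c * np.sqrt(7 * 120), rel=1e-12)
        assert np.all(sv[1:] <= 1e-9 * sv[0])

    def test_sinusoid_is_rank_two(self):
        n = np.arange(126)
        sv = m.ssa_singular_values(np.sin(2 * np.pi * 0.1731 * n), L=7, n_sv=7)
        assert sv[2] / sv[0] < 1e-8
        assert sv[1] > 1e-6 * sv[0]

    def test_energy_conservation_frobenius_oracle(self):
        rng = np.random.default_rng(21)
        trace = rng.normal(size=126)
        sv = m.ssa_singular_values(trace, L=7, n_sv=7)
        # independent oracle: build the Hankel matrix by brute force
        H = np.array([[trace[i + j] for j in range(120)] for i in range(7)])
        frob2 = float(np.sum(H ** 2))
        assert np.sum(sv ** 2) == pytest.approx(frob2, rel=1e-10)

    def test_descending_order_and_scaling(self):
        rng = np.random.default_rng(22)
        trace = rng.normal(size=126)
        sv = m.ssa_singular_values(trace, L=7, n_sv=7)
        assert np.all(np.diff(sv) <= 1e-12)
        assert np.allclose(m.ssa_singular_values(4.0 * trace, 7, 7), 4.0 * sv,
                           rtol=1e-12)

    @pytest.mark.parametrize("L, n_sv", [(0, 1), (126, 1), (7, 8), (7, 0)])
    def test_bad_embedding_rejected(self, L, n_sv):
        with pytest.raises(ValueError):
            m.ssa_singular_values(np.ones(126), L=L, n_sv=n_sv)


# ---------------------------------------------------------------------------
# control template
# ---------------------------------------------------------------------------

class TestTemplate:
    def test_mean_identity_and_cancellation(self):
        rng = np.random.default_rng(30)
        r_od = noise_record(rng, subject_id="c1", eye="OD")
        r_os = noise_record(rng, subject_id="c1", eye="OS")
        tpl = m.build_template([r_od, r_os,
                                r_od.copy_with_signal(r_od.signal),
                                r_os.copy_with_signal(r_os.signal)])
        assert np.allclose(tpl.waveforms["OD"], r_od.signal)
        neg = r_od.copy_with_signal(-r_od.signal)
        tpl2 = m.build_template([r_od, neg, r_os, r_os])
        assert np.allclose(tpl2.waveforms["OD"], 0.0)

    def test_noise_averaging_follows_clt(self):
        rng = np.random.default_rng(31)
        recs = []
        for i in range(100):
            for eye in ("OD", "OS"):
                recs.append(noise_record(rng, sd=1.0, subject_id=f"c{i}", eye=eye))
        tpl = m.build_template(recs)
        sd = tpl.waveforms["OD"].std()
        assert sd == pytest.approx(1.0 / np.sqrt(100), rel=0.10)

    def test_requires_controls(self):
        rng = np.random.default_rng(32)
        with pytest.raises(Exception):
            m.build_template([noise_record(rng, label="MS-ON")])
        with pytest.raises(DegenerateInputError):
            m.build_template([])

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(33)
        tpl = m.build_template([noise_record(rng, eye="OD"),
                                noise_record(rng, eye="OS")])
        tpl.save(tmp_path / "tpl.npz")
        back = m.ControlTemplate.load(tmp_path / "tpl.npz")
        assert np.allclose(back.waveforms["OS"], tpl.waveforms["OS"])
        assert back.n_eyes == tpl.n_eyes


# ---------------------------------------------------------------------------
# ring aggregation
# ---------------------------------------------------------------------------

class TestEyeFeatures:
    @pytest.mark.parametrize("i_sv, length", [(0, 24), (4, 48), (7, 66)])
    def test_vector_length(self, cfg, i_sv, length):
        rec = waveform_record()
        feats = m.extract_eye_features(rec, cfg=cfg, i_sv=i_sv)
        assert feats.values.size == length
        head = min(5, 4 + i_sv)
        assert feature_names(i_sv)[:head] == \
            ["P1R1", "P2R1", "P3R1", "P4R1", "P5R1"][:head]

    def test_all_nas_boundary_imputation(self, cfg):
        rec = noise_record(np.random.default_rng(40))
        feats = m.extract_eye_features(rec, cfg=cfg, i_sv=2)
        block = 4 + 2
        for ring, size in enumerate(cfg.ring_sizes):
            p1, p2, p3, p4 = feats.values[ring * block: ring * block + 4]
            assert p2 == size                 # every sector in the ring is NAS
            assert p1 == cfg.snr_threshold    # imputed mean SNR
            assert p3 == 0.0 and p4 == 0.0
        assert feats.nas_total == 60

    def test_interocular_ring_features_from_fellow(self, cfg):
        od = waveform_record(subject_id="p1", eye="OD")
        osin = waveform_record(12, subject_id="p1", eye="OS")
        feats = m.extract_cohort_features([od, osin], cfg=cfg, i_sv=0)
        for f in feats:
            p3 = f.values[2::4]
            assert np.allclose(p3, 10.0)      # 12 samples at 1200 Hz
        # same value assigned to both eyes
        assert np.allclose(feats[0].values[2::4], feats[1].values[2::4])

    def test_monocular_against_template(self, cfg):
        rec = waveform_record(6, subject_id="p1", eye="OD")
        ctrl_od = waveform_record(subject_id="c", eye="OD")
        ctrl_os = waveform_record(subject_id="c", eye="OS")
        tpl = m.build_template([ctrl_od, ctrl_os])
        feats = m.extract_eye_features(rec, template=tpl, cfg=cfg, i_sv=0)
        assert np.allclose(feats.values[3::4], 5.0)   # subject 6 samples later

    def test_feature_subset_indices(self):
        idx = select_feature_indices(7, (1, 2, 3))
        assert idx.size == 6 * 7
        assert list(idx[:7]) == [0, 1, 2, 3, 4, 5, 6]
        base = select_feature_indices(7, ())
        assert base.size == 24
        with pytest.raises(ValueError):
            select_feature_indices(4, (5,))

    def test_frame_round_trip(self, cfg):
        recs = [waveform_record(subject_id="a", eye="OD"),
                waveform_record(3, subject_id="a", eye="OS")]
        feats = m.extract_cohort_features(recs, cfg=cfg, i_sv=3)
        df = m.features_to_frame(feats)
        back = m.frame_to_features(df)
        for f, g in zip(feats, back):
            assert (f.subject_id, f.eye, f.label, f.i_sv) == \
                (g.subject_id, g.eye, g.label, g.i_sv)
            assert np.allclose(f.values, g.values)
            assert f.nas_total == g.nas_total
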