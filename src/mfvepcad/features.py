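"""Per-sector and ring-aggregated features of an mfVEP recording.

For each of the 60 visual-field sectors the pipeline derives, on the best of
the 6 channels:

* **SNR** — RMS amplitude in the signal window (45-150 ms) divided by the
  mean over all 60 sectors of the RMS amplitude in the noise window
  (325-430 ms) for the same channel.  Sectors whose best-channel SNR falls
  below 1.7 are *non-analysable sectors* (NAS) and are excluded from the
  latency and singular-value averages.
* **Interocular latency** — absolute cross-correlation lag (ms) between the
  two eyes' best-channel responses for the same sector; the same value is
  assigned to both eyes.
* **Monocular latency** — signed cross-correlation lag (ms) between the
  response and a control-population template (subject later than template is
  positive).
* **Singular values** σ1..σ7 — singular spectrum analysis of the
  signal-window segment: the trace is embedded into an L x (N-L+1) Hankel
  trajectory matrix (L = 7 by default, so exactly 7 singular values exist)
  whose singular values summarise the signal's energy by component.

Sector features are then averaged within six concentric eccentricity rings
to form the per-eye feature vector: per ring, mean SNR, NAS count, mean
absolute interocular latency, mean monocular latency and the mean of each
σk, giving ``6 * (4 + i_sv)`` features for ``i_sv`` singular values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import hankel, svdvals

from .config import PipelineConfig
from .errors import DegenerateInputError, FormatError
from .records import EYES, N_CHANNELS, N_SECTORS, MfVEPRecord

logger = logging.getLogger(__name__)

#: Eye-level summary parameters reported per group (Table-style statistics).
SUMMARY_PARAMS = ("SNR", "NAS", "LAT_INTER", "LAT_MONO",
                  "S1", "S2", "S3", "S4", "S5", "S6", "S7")


# ---------------------------------------------------------------------------
# amplitude / SNR
# ---------------------------------------------------------------------------

def _rms(x: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.sqrt(np.mean(np.square(x), axis=axis))


def snr_map(record: MfVEPRecord, cfg: PipelineConfig) -> np.ndarray:
    """SNR for every (sector, channel): shape (60, 6).

    The denominator is channel-specific: the mean over all 60 sectors of the
    noise-window RMS of that channel, so a uniformly noisy channel
    normalises to SNR ~= 1.
    """
    sig = record.signal[:, :, cfg.signal_slice(record.fs)]
    noi = record.signal[:, :, cfg.noise_slice(record.fs)]
    noise_rms = _rms(noi)                      # (60, 6)
    denom = noise_rms.mean(axis=0)             # (6,) per-channel mean
    if np.any(denom <= 0):
        raise DegenerateInputError("zero noise-window RMS: SNR denominator degenerate")
    return _rms(sig) / denom[None, :]


def snr(record: MfVEPRecord, sector: int, channel: int, cfg: PipelineConfig) -> float:
    """SNR of one sector (1-60) / channel (0-5)."""
    if not (1 <= sector <= N_SECTORS and 0 <= channel < N_CHANNELS):
        raise ValueError(f"sector {sector} / channel {channel} out of range")
    return float(snr_map(record, cfg)[sector - 1, channel])


def best_channel(record: MfVEPRecord, sector: int, cfg: PipelineConfig) -> tuple[int, float, bool]:
    """Channel with the highest SNR in a sector; ties go to the lowest index.

    Returns ``(channel, snr, analysable)`` where ``analysable`` is whether
    the best-channel SNR reaches the 1.7 threshold.
    """
    row = snr_map(record, cfg)[sector - 1]
    ch = int(np.argmax(row))
    s = float(row[ch])
    return ch, s, s >= cfg.snr_threshold


# ---------------------------------------------------------------------------
# cross-correlation latency
# ---------------------------------------------------------------------------

def xcorr_lag(x: np.ndarray, y: np.ndarray, max_lag: int) -> int:
    """Integer lag (samples) maximising the Pearson correlation of ``x[t]``
    against ``y[t - lag]`` over their overlap, searched in ``[-max_lag, max_lag]``.

    Positive lag means ``x`` is delayed relative to ``y``.  Ties are broken
    towards the smallest absolute lag, then the smaller (more negative) lag.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = x.size
    if y.size != n:
        raise ValueError("traces must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("flat trace: cross-correlation undefined")
    L = int(min(max_lag, n - 2))
    lags = np.arange(-L, L + 1)
    sxy = np.correlate(x, y, mode="full")[lags + n - 1]
    cx = np.concatenate(([0.0], np.cumsum(x)))
    cy = np.concatenate(([0.0], np.cumsum(y)))
    cxx = np.concatenate(([0.0], np.cumsum(x * x)))
    cyy = np.concatenate(([0.0], np.cumsum(y * y)))
    lpos = np.maximum(lags, 0)
    lneg = np.maximum(-lags, 0)
    m = n - np.abs(lags)
    sx = cx[n - lneg] - cx[lpos]
    sxx = cxx[n - lneg] - cxx[lpos]
    sy = cy[n - lpos] - cy[lneg]
    syy = cyy[n - lpos] - cyy[lneg]
    varx = m * sxx - sx * sx
    vary = m * syy - sy * sy
    denom = np.sqrt(np.maximum(varx, 0.0) * np.maximum(vary, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (m * sxy - sx * sy) / np.where(denom > 0, denom, 1.0), -np.inf)
    if not np.any(np.isfinite(r)):
        raise DegenerateInputError("cross-correlation undefined at every lag")
    best = r.max()
    cand = lags[r >= best - 1e-12]
    order = np.lexsort((cand, np.abs(cand)))
    return int(cand[order[0]])


def interocular_latency(od_trace: np.ndarray, os_trace: np.ndarray,
                        cfg: PipelineConfig, fs: float = 1200.0) -> float:
    """Absolute lag (ms) between the two eyes' responses for one sector.

    Both full-epoch traces are cut to the signal window before correlation;
    the sign (which eye is slower) is discarded.
    """
    sl = cfg.signal_slice(fs)
    lag = xcorr_lag(np.asarray(od_trace)[sl], np.asarray(os_trace)[sl],
                    cfg.max_lag_samples(fs))
    return abs(lag) * 1000.0 / fs


def monocular_latency(trace: np.ndarray, template_trace: np.ndarray,
                      cfg: PipelineConfig, fs: float = 1200.0) -> float:
    """Signed lag (ms) of a response against the control template.

    Positive values mean the subject's response is later than the template.
    """
    sl = cfg.signal_slice(fs)
    lag = xcorr_lag(np.asarray(trace)[sl], np.asarray(template_trace)[sl],
                    cfg.max_lag_samples(fs))
    return lag * 1000.0 / fs


# ---------------------------------------------------------------------------
# singular spectrum analysis
# ---------------------------------------------------------------------------

def ssa_singular_values(trace: np.ndarray, L: int, n_sv: int) -> np.ndarray:
    """Largest ``n_sv`` singular values of the SSA trajectory matrix.

    The trajectory matrix is the L x (N-L+1) Hankel matrix whose columns are
    the length-L sliding windows of the trace.  Values are returned in
    non-increasing order; they scale linearly with the trace amplitude.
    """
    trace = np.asarray(trace, dtype=np.float64)
    N = trace.size
    if not (1 <= L < N):
        raise ValueError(f"embedding length L={L} out of range for N={N}")
    if not (1 <= n_sv <= L):
        raise ValueError(f"n_sv={n_sv} must lie in [1, L={L}]")
    traj = hankel(trace[:L], trace[L - 1:])
    return svdvals(traj)[:n_sv]


# ---------------------------------------------------------------------------
# control template
# ---------------------------------------------------------------------------

@dataclass
class ControlTemplate:
    """Mean control waveform per (sector, channel) for each eye side."""

    waveforms: dict  # eye -> (60, 6, 600) ndarray
    n_eyes: dict     # eye -> number of control eyes averaged
    fs: float = 1200.0

    def trace(self, sector: int, channel: int, eye: str) -> np.ndarray:
        if eye not in self.waveforms:
            raise FormatError(f"template has no entry for eye {eye!r}")
        return self.waveforms[eye][sector - 1, channel]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        np.savez(path, fs=self.fs,
                 **{f"wave_{e}": w for e, w in self.waveforms.items()},
                 **{f"n_{e}": n for e, n in self.n_eyes.items()})
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "ControlTemplate":
        with np.load(path) as z:
            waves = {e: z[f"wave_{e}"] for e in EYES if f"wave_{e}" in z}
            ns = {e: int(z[f"n_{e}"]) for e in EYES if f"n_{e}" in z}
            return cls(waveforms=waves, n_eyes=ns, fs=float(z["fs"]))


def build_template(controls: list[MfVEPRecord]) -> ControlTemplate:
    """Average control responses pointwise per (sector, channel, eye side).

    Stands in for a normative template averaged over a large control
    population; only Controls-labelled records are accepted.
    """
    if not controls:
        raise DegenerateInputError("empty control set: cannot build a template")
    bad = [r.subject_id for r in controls if r.label != "Controls"]
    if bad:
        raise FormatError(f"template must be built from Controls only, got {sorted(set(bad))}")
    waves, ns = {}, {}
    for eye in EYES:
        recs = [r for r in controls if r.eye == eye]
        if not recs:
            raise DegenerateInputError(f"no control records for eye {eye}")
        waves[eye] = np.mean([r.signal for r in recs], axis=0)
        ns[eye] = len(recs)
    return ControlTemplate(waveforms=waves, n_eyes=ns, fs=controls[0].fs)


# ---------------------------------------------------------------------------
# per-eye feature vector
# ---------------------------------------------------------------------------

@dataclass
class SectorFeature:
    """Features of a single visual-field sector (best channel)."""

    sector: int
    best_channel: int
    snr: float
    analysable: bool
    lat_inter_ms: float | None = None
    lat_mono_ms: float | None = None
    sigma: np.ndarray | None = None


def feature_names(i_sv: int) -> list[str]:
    """Column names of the ring feature vector, ring-major (P1R1..PiR1, P1R2, ...)."""
    return [f"P{p}R{ring}" for ring in range(1, 7) for p in range(1, 5 + i_sv)]


def select_feature_indices(i_sv_total: int, sv_subset: tuple[int, ...] = ()) -> np.ndarray:
    """Indices into a full ring vector keeping the 24 base ring parameters
    (mean SNR, NAS count, both latencies per ring) plus the requested σk."""
    block = 4 + i_sv_total
    idx = []
    for ring in range(6):
        idx.extend(ring * block + p for p in range(4))
        for k in sv_subset:
            if not (1 <= k <= i_sv_total):
                raise ValueError(f"σ{k} not available with i_sv={i_sv_total}")
            idx.append(ring * block + 3 + k)
    return np.asarray(idx, dtype=int)


@dataclass
class EyeFeatures:
    """Ring-aggregated feature vector of one eye plus eye-level summaries."""

    subject_id: str
    eye: str
    label: str
    i_sv: int
    values: np.ndarray
    mean_snr: float
    nas_total: int
    summary: dict = field(default_factory=dict)
    sectors: list = field(default_factory=list, repr=False)

    @property
    def names(self) -> list[str]:
        return feature_names(self.i_sv)

    @property
    def subject_class(self) -> str:
        from .records import to_subject_class
        return to_subject_class(self.label)


def _sector_interocular(record: MfVEPRecord, fellow: MfVEPRecord,
                        best: np.ndarray, analysable: np.ndarray,
                        cfg: PipelineConfig) -> np.ndarray:
    """Per-sector |interocular lag| in ms; NaN where either eye is NAS."""
    f_map = snr_map(fellow, cfg)
    f_best = np.argmax(f_map, axis=1)
    f_snr = f_map[np.arange(N_SECTORS), f_best]
    f_ok = f_snr >= cfg.snr_threshold
    out = np.full(N_SECTORS, np.nan)
    for s in range(N_SECTORS):
        if analysable[s] and f_ok[s]:
            out[s] = interocular_latency(record.signal[s, best[s]],
                                         fellow.signal[s, f_best[s]],
                                         cfg, fs=record.fs)
    return out


def extract_eye_features(record: MfVEPRecord,
                         template: ControlTemplate | None = None,
                         cfg: PipelineConfig | None = None,
                         i_sv: int | None = None,
                         fellow: MfVEPRecord | None = None) -> EyeFeatures:
    """Compute the per-eye ring feature vector.

    Parameters
    ----------
    record : MfVEPRecord
        Band-pass filtered recording of one eye.
    template : ControlTemplate, optional
        Control template for monocular latency; without it the monocular
        latency ring features are imputed with 0.
    cfg : PipelineConfig
    i_sv : int, optional
        Number of singular values kept per ring (0-7); defaults to
        ``cfg.n_singular_values``.  Vector length is ``6 * (4 + i_sv)``.
    fellow : MfVEPRecord, optional
        The fellow eye of the same subject, required for interocular
        latency; without it the interocular ring features are imputed with 0.

    Ring imputation for rings where every sector is NAS (or no value is
    available): mean SNR takes the 1.7 threshold, latencies and σ means take
    0; the NAS count itself carries the information.
    """
    cfg = cfg or PipelineConfig()
    i_sv = cfg.n_singular_values if i_sv is None else int(i_sv)
    if not (0 <= i_sv <= cfg.ssa_window):
        raise ValueError(f"i_sv={i_sv} must lie in [0, {cfg.ssa_window}]")

    smap = snr_map(record, cfg)
    best = np.argmax(smap, axis=1)
    best_snr = smap[np.arange(N_SECTORS), best]
    analysable = best_snr >= cfg.snr_threshold
    sl = cfg.signal_slice(record.fs)

    inter = np.full(N_SECTORS, np.nan)
    if fellow is not None:
        if fellow.subject_id != record.subject_id:
            raise FormatError("fellow eye belongs to a different subject")
        inter = _sector_interocular(record, fellow, best, analysable, cfg)

    mono = np.full(N_SECTORS, np.nan)
    sigma = np.full((N_SECTORS, cfg.ssa_window), np.nan)
    sectors = []
    for s in range(N_SECTORS):
        lat_m = None
        sig = None
        if analysable[s]:
            tr = record.signal[s, best[s]]
            sig = ssa_singular_values(tr[sl], cfg.ssa_window, cfg.ssa_window)
            sigma[s] = sig
            if template is not None:
                lat_m = monocular_latency(tr, template.trace(s + 1, best[s], record.eye),
                                          cfg, fs=record.fs)
                mono[s] = lat_m
        sectors.append(SectorFeature(
            sector=s + 1, best_channel=int(best[s]), snr=float(best_snr[s]),
            analysable=bool(analysable[s]),
            lat_inter_ms=float(inter[s]) if np.isfinite(inter[s]) else None,
            lat_mono_ms=lat_m, sigma=sig))

    ring = cfg.ring_map
    values = []
    for x in range(1, 7):
        in_ring = ring == x
        ok = in_ring & analysable
        values.append(float(np.mean(best_snr[ok])) if ok.any() else cfg.snr_threshold)
        values.append(float(np.sum(in_ring & ~analysable)))
        iv = inter[in_ring]
        iv = iv[np.isfinite(iv)]
        values.append(float(iv.mean()) if iv.size else 0.0)
        mv = mono[in_ring]
        mv = mv[np.isfinite(mv)]
        values.append(float(mv.mean()) if mv.size else 0.0)
        for k in range(i_sv):
            values.append(float(np.mean(sigma[ok, k])) if ok.any() else 0.0)

    snr_for_fusion = (float(best_snr[analysable].mean()) if analysable.any()
                      else float(best_snr.mean())) if cfg.eye_snr_over_analysable \
        else float(best_snr.mean())
    iv_all = inter[np.isfinite(inter)]
    mv_all = mono[np.isfinite(mono)]
    summary = {
        "SNR": float(best_snr.mean()),
        "NAS": float(np.sum(~analysable)),
        "LAT_INTER": float(iv_all.mean()) if iv_all.size else np.nan,
        "LAT_MONO": float(mv_all.mean()) if mv_all.size else np.nan,
    }
    for k in range(cfg.ssa_window):
        col = sigma[analysable, k] if analysable.any() else np.array([])
        summary[f"S{k + 1}"] = float(col.mean()) if col.size else np.nan

    return EyeFeatures(
        subject_id=record.subject_id, eye=record.eye, label=record.label,
        i_sv=i_sv, values=np.asarray(values, dtype=np.float64),
        mean_snr=snr_for_fusion, nas_total=int(np.sum(~analysable)),
        summary=summary, sectors=sectors)


def extract_cohort_features(records: list[MfVEPRecord],
                            template: ControlTemplate | None = None,
                            cfg: PipelineConfig | None = None,
                            i_sv: int | None = None) -> list[EyeFeatures]:
    """Extract features for every eye, pairing fellow eyes for interocular latency."""
    cfg = cfg or PipelineConfig()
    by_subject: dict[str, dict[str, MfVEPRecord]] = {}
    for r in records:
        by_subject.setdefault(r.subject_id, {})[r.eye] = r
    out = []
    for r in records:
        fellow_eye = "OS" if r.eye == "OD" else "OD"
        fellow = by_subject[r.subject_id].get(fellow_eye)
        out.append(extract_eye_features(r, template=template, cfg=cfg, i_sv=i_sv,
                                        fellow=fellow))
    return out


# ---------------------------------------------------------------------------
# tabular round trip
# ---------------------------------------------------------------------------

def features_to_frame(feats: list[EyeFeatures]) -> pd.DataFrame:
    """One row per eye: identifiers, eye-level SNR, then the ring features."""
    if not feats:
        raise ValueError("no features to tabulate")
    i_sv = feats[0].i_sv
    names = feature_names(i_sv)
    rows = []
    for f in feats:
        if f.i_sv != i_sv:
            raise ValueError("mixed i_sv in feature set")
        row = {"subject_id": f.subject_id, "eye": f.eye, "label": f.label,
               "mean_snr": f.mean_snr}
        row.update(zip(names, f.values))
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_features(df: pd.DataFrame) -> list[EyeFeatures]:
    """Inverse of :func:`features_to_frame` (summaries are not preserved)."""
    cols = [c for c in df.columns if c.startswith("P")]
    if len(cols) % 6:
        raise FormatError(f"feature column count {len(cols)} is not a multiple of 6")
    i_sv = len(cols) // 6 - 4
    expected = feature_names(i_sv)
    if cols != expected:
        raise FormatError("feature columns do not match the ring-major layout")
    out = []
    for _, row in df.iterrows():
        vals = row[expected].to_numpy(dtype=np.float64)
        nas = int(sum(vals[r * (4 + i_sv) + 1] for r in range(6)))
        out.append(EyeFeatures(
            subject_id=str(row["subject_id"]), eye=str(row["eye"]),
            label=str(row["label"]), i_sv=i_sv, values=vals,
            mean_snr=float(row.get("mean_snr", np.nan)), nas_total=nas))
    return out


def summaries_to_frame(feats: list[EyeFeatures]) -> pd.DataFrame:
    """Eye-level parameter summaries (SNR, NAS, latencies, σ1..σ7) per eye."""
    rows = []
    for f in feats:
        row = {"subject_id": f.subject_id, "eye": f.eye, "label": f.label}
        row.update(f.summary)
        rows.append(row)
    return pd.DataFrame(rows)
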