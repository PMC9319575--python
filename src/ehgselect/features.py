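"""EHG window features and the record-level feature table.

Each 120 s analysis window is characterised by temporal (peak-to-peak
amplitude in four bands), spectral (dominant/mean frequency, sub-band
energies, spectrum deciles, Teager energy, spectral moment ratio over
0.2-1 Hz) and non-linear measures (Lempel-Ziv, time reversibility, Katz
fractal dimension, Poincare ellipse metrics and five entropies, each in
the same four bands as the amplitude). Window values are median-aggregated
per record and the five obstetric covariates are appended, giving

    3 channels x (4 temporal + 18 spectral + 52 non-linear) = 222 signal
    features + 5 covariates = 227 classifier inputs.

Parameter defaults (entropy tolerances, quantiser classes, embedding
dimensions) follow the measures' original formulations and are exposed as
keyword arguments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.spatial.distance import pdist
from scipy.stats import norm

from .preprocessing import aggregate_median, bandpass, segment

logger = logging.getLogger("ehgselect")

#: analysis bands (Hz) for the temporal and non-linear measures
AMPLITUDE_BANDS: tuple[tuple[float, float], ...] = (
    (0.1, 4.0), (0.2, 0.34), (0.34, 4.0), (0.34, 1.0),
)
#: band (Hz) for all spectral measures
SPECTRAL_BAND: tuple[float, float] = (0.2, 1.0)

NONLINEAR_MEASURES = (
    "LZBin", "LZMulti", "TimeRev", "KFD", "SD1", "SD2", "SDRR", "SD1SD2",
    "SampEn", "FuzEn", "SpEn", "DispEn", "BubbEn",
)
SPECTRAL_MEASURES = (
    "MeanF", "DF1", "DF2", "NormEn_0.2-0.34", "NormEn_0.34-0.6",
    "NormEn_0.6-1", "HLRatio", "D1", "D2", "D3", "D4", "D5", "D6", "D7",
    "D8", "D9", "Teager", "SpMR",
)
OBSTETRIC_NAMES = ("maternal_age", "parity", "abortions", "weight",
                   "weeks_of_gestation")
CHANNEL_NAMES = ("S1", "S2", "S3")


def _band_tag(band: tuple[float, float]) -> str:
    def fmt(v: float) -> str:
        return f"{v:g}"
    return f"{fmt(band[0])}-{fmt(band[1])}Hz"


def feature_names() -> list[str]:
    """Canonical ordered names of the 227 classifier inputs."""
    names: list[str] = []
    for ch in CHANNEL_NAMES:
        for band in AMPLITUDE_BANDS:
            names.append(f"{ch}_App_{_band_tag(band)}")
        for m in SPECTRAL_MEASURES:
            names.append(f"{ch}_{m}")
        for m in NONLINEAR_MEASURES:
            for band in AMPLITUDE_BANDS:
                names.append(f"{ch}_{m}_{_band_tag(band)}")
    names.extend(OBSTETRIC_NAMES)
    return names


FEATURE_NAMES: list[str] = feature_names()
N_EHG_FEATURES = len(FEATURE_NAMES) - len(OBSTETRIC_NAMES)


# ---------------------------------------------------------------------------
# temporal
# ---------------------------------------------------------------------------

def app(window: np.ndarray) -> float:
    """Peak-to-peak amplitude (max - min) of a band-filtered window."""
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("empty window")
    return float(window.max() - window.min())


# ---------------------------------------------------------------------------
# spectral
# ---------------------------------------------------------------------------

def welch_psd(window: np.ndarray, fs: float, nperseg: int = 600) -> tuple[np.ndarray, np.ndarray]:
    """Averaged modified periodogram (Welch, Hann, 50 % segment overlap)."""
    window = np.asarray(window, dtype=float)
    nperseg = min(nperseg, window.size)
    return sps.welch(window, fs=fs, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2, detrend="constant")


def _band_mask(f: np.ndarray, band: tuple[float, float],
               half_open: bool = False) -> np.ndarray:
    """Bins within ``band``; ``half_open`` excludes the upper edge so that
    adjacent sub-bands tile a band without double-counting boundary bins."""
    upper = (f < band[1]) if half_open else (f <= band[1])
    return (f >= band[0]) & upper


def spectral_features(
    window: np.ndarray,
    fs: float,
    teager_window: np.ndarray | None = None,
    nperseg: int = 600,
) -> dict[str, float]:
    """The 18 spectral measures of one window (band 0.2-1 Hz).

    ``teager_window`` is the same window filtered to 0.2-1 Hz; when omitted
    it is computed here. Dominant frequencies DF1/DF2 are the bins of
    maximum Welch power in 0.2-1 / 0.34-1 Hz; deciles D1..D9 are linearly
    interpolated frequencies at cumulative-energy tenths; SpMR is the
    dimensionless moment ratio m0*m2/m1^2 over the band.
    """
    window = np.asarray(window, dtype=float)
    f, P = welch_psd(window, fs, nperseg=nperseg)
    band = _band_mask(f, SPECTRAL_BAND)
    fb, Pb = f[band], P[band]
    total = Pb.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("zero-energy window: spectral features undefined")

    out: dict[str, float] = {}
    out["MeanF"] = float((fb * Pb).sum() / total)
    out["DF1"] = float(fb[np.argmax(Pb)])
    m2 = _band_mask(f, (0.34, 1.0))
    out["DF2"] = float(f[m2][np.argmax(P[m2])])

    e_low = P[_band_mask(f, (0.2, 0.34), half_open=True)].sum()
    e_mid = P[_band_mask(f, (0.34, 0.6), half_open=True)].sum()
    e_high = P[_band_mask(f, (0.6, 1.0))].sum()
    out["NormEn_0.2-0.34"] = float(e_low / total)
    out["NormEn_0.34-0.6"] = float(e_mid / total)
    out["NormEn_0.6-1"] = float(e_high / total)
    e_hl_num = P[_band_mask(f, (0.34, 1.0))].sum()
    out["HLRatio"] = float(e_hl_num / e_low) if e_low > 0 else float("inf")

    # deciles: cumulative energy interpolated on bin edges (each bin's
    # energy is attributed up to its right edge, starting from zero)
    df = fb[1] - fb[0] if fb.size > 1 else 0.0
    edges = np.concatenate([[fb[0] - df / 2.0], fb + df / 2.0])
    cum = np.concatenate([[0.0], np.cumsum(Pb)])
    for k in range(1, 10):
        out[f"D{k}"] = float(np.clip(np.interp(k / 10.0 * total, cum, edges),
                                     *SPECTRAL_BAND))

    if teager_window is None:
        teager_window = bandpass(window, fs, *SPECTRAL_BAND)
    x = np.asarray(teager_window, dtype=float)
    out["Teager"] = float(np.mean(x[1:-1] ** 2 - x[:-2] * x[2:]))

    m0 = total
    m1 = (fb * Pb).sum()
    sp_m2 = (fb**2 * Pb).sum()
    out["SpMR"] = float(m0 * sp_m2 / m1**2)
    return out


# ---------------------------------------------------------------------------
# non-linear
# ---------------------------------------------------------------------------

def _lz76_phrases(symbols: np.ndarray) -> int:
    """Phrase count of the LZ76 exhaustive production parsing."""
    s = symbols.tolist()
    n = len(s)
    if n == 0:
        raise ValueError("empty sequence")
    c = 1
    i, k, l = 0, 1, 1
    k_max = 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            k_max = max(k, k_max)
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i, k, k_max = 0, 1, 1
            else:
                k = 1
    return c


def quantize(window: np.ndarray, n_states: int) -> np.ndarray:
    """Quantise a window for Lempel-Ziv parsing.

    Binary: threshold at the window median. Multistate: ``n_states``
    equal-probability bins from the window's order statistics.
    """
    window = np.asarray(window, dtype=float)
    if n_states == 2:
        return (window > np.median(window)).astype(np.int8)
    qs = np.quantile(window, np.linspace(0, 1, n_states + 1)[1:-1])
    return np.searchsorted(qs, window, side="right").astype(np.int8)


def lempel_ziv(window: np.ndarray, n_states: int = 2) -> float:
    """Normalised Lempel-Ziv (LZ76) complexity of the quantised window.

    The phrase count c is normalised by its asymptotic random-sequence
    value n * log(n_states) / log(n): complexity = c * log(n) /
    (n * log(n_states)). A constant window parses into the 2-phrase
    minimum and returns the corresponding (small) value.
    """
    if n_states not in (2, 6):
        raise ValueError("n_states must be 2 (binary) or 6 (multistate)")
    symbols = quantize(window, n_states)
    n = symbols.size
    c = _lz76_phrases(symbols)
    return float(c * np.log(n) / (n * np.log(n_states)))


def time_reversibility(window: np.ndarray, lag: int = 1) -> float:
    """Third moment of lag differences: mean((x[n] - x[n-lag])^3).

    Zero for time-symmetric signals; flips sign under time reversal.
    """
    x = np.asarray(window, dtype=float)
    if x.size <= lag:
        raise ValueError("window shorter than lag")
    d = x[lag:] - x[:-lag]
    return float(np.mean(d**3))


def katz_fd(window: np.ndarray) -> float:
    """Katz fractal dimension of the waveform.

    KFD = log10(L/a) / log10(d/a) with L the total (ordinate) curve
    length, a the mean step length and d the maximum distance from the
    first point; scale-invariant and exactly 1 for a straight line.
    """
    x = np.asarray(window, dtype=float)
    if x.size < 2:
        raise ValueError("window too short")
    dists = np.abs(np.diff(x))
    L = dists.sum()
    if L == 0:
        return 1.0
    n = x.size - 1
    d = np.abs(x - x[0]).max()
    if d == 0:
        return 1.0
    return float(np.log10(n) / (np.log10(n) + np.log10(d / L)))


def poincare(window: np.ndarray) -> dict[str, float]:
    """Poincare-plot ellipse metrics of successive sample pairs.

    SD1 (minor axis) = sqrt(var(x[n+1]-x[n]) / 2); SD2 (major axis) =
    sqrt(2 var(x) - SD1^2); SDRR = sqrt((SD1^2+SD2^2)/2); the SD1/SD2
    ratio is NaN when SD2 = 0.
    """
    x = np.asarray(window, dtype=float)
    if x.size < 2:
        raise ValueError("window too short")
    sd1_sq = np.var(x[1:] - x[:-1]) / 2.0
    sd2_sq = max(2.0 * np.var(x) - sd1_sq, 0.0)
    sd1, sd2 = np.sqrt(sd1_sq), np.sqrt(sd2_sq)
    ratio = float(sd1 / sd2) if sd2 > 0 else float("nan")
    return {
        "SD1": float(sd1),
        "SD2": float(sd2),
        "SDRR": float(np.sqrt((sd1_sq + sd2_sq) / 2.0)),
        "SD1SD2": ratio,
    }


def _embed(x: np.ndarray, m: int, delay: int = 1) -> np.ndarray:
    n = x.size - (m - 1) * delay
    idx = np.arange(m) * delay + np.arange(n)[:, None]
    return x[idx]


def sample_entropy(window: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy: -ln(A/B) with A, B the m+1 / m template-match counts.

    r defaults to 0.15 x window SD (Chebyshev distance, self-matches
    excluded). When no m+1 template pair matches, the upper-bound sentinel
    log(number of pairs) is returned instead of infinity.
    """
    x = np.asarray(window, dtype=float)
    if x.size < m + 2:
        raise ValueError("window too short for sample entropy")
    if r is None:
        r = 0.15 * float(np.std(x))
    # templates of length m truncated to align with the m+1 count
    emb_m = _embed(x, m)[:-1]
    emb_m1 = _embed(x, m + 1)
    b = int(np.sum(pdist(emb_m, metric="chebyshev") <= r))
    a = int(np.sum(pdist(emb_m1, metric="chebyshev") <= r))
    n_pairs = emb_m.shape[0] * (emb_m.shape[0] - 1) / 2.0
    if b == 0:
        return float(np.log(n_pairs))
    if a == 0:
        return float(np.log(n_pairs))
    return float(-np.log(a / b))


def fuzzy_entropy(
    window: np.ndarray, m: int = 2, r: float | None = None, p: float = 2.0
) -> float:
    """Fuzzy entropy with exponential membership exp(-(d/r)^p), p = 2.

    Templates are locally centred (their own mean removed) as in the
    original formulation; r defaults to 0.15 x window SD.
    """
    x = np.asarray(window, dtype=float)
    if x.size < m + 2:
        raise ValueError("window too short for fuzzy entropy")
    if r is None:
        r = 0.15 * float(np.std(x))

    def phi(mm: int) -> float:
        emb = _embed(x, mm)
        emb = emb - emb.mean(axis=1, keepdims=True)
        d = pdist(emb, metric="chebyshev")
        if r == 0:
            return float(np.mean(d == 0))
        return float(np.mean(np.exp(-((d / r) ** p))))

    ph_m, ph_m1 = phi(m), phi(m + 1)
    if ph_m == 0 or ph_m1 == 0:
        return float(np.log(x.size))
    return float(-np.log(ph_m1 / ph_m))


def spectral_entropy(
    window: np.ndarray, fs: float, band: tuple[float, float] = SPECTRAL_BAND,
    nperseg: int = 600,
) -> float:
    """Shannon entropy of the normalised Welch spectrum over ``band``,
    normalised to [0, 1] by log(#bins)."""
    f, P = welch_psd(window, fs, nperseg=nperseg)
    Pb = P[_band_mask(f, band)]
    total = Pb.sum()
    if total <= 0:
        raise ValueError("zero-energy window: spectral entropy undefined")
    prob = Pb / total
    prob = prob[prob > 0]
    if prob.size <= 1:
        return 0.0
    return float(-(prob * np.log(prob)).sum() / np.log(Pb.size))


def dispersion_entropy(
    window: np.ndarray, n_classes: int = 6, m: int = 2, delay: int = 1
) -> float:
    """Normalised dispersion entropy (normal-CDF mapping to 6 classes).

    Shannon entropy of the dispersion-pattern distribution divided by
    log(n_classes^m); 0 for a constant window (single pattern).
    """
    x = np.asarray(window, dtype=float)
    mu, sigma = x.mean(), x.std()
    if sigma == 0:
        return 0.0
    z = norm.cdf((x - mu) / sigma)
    classes = np.minimum(np.maximum(np.ceil(z * n_classes), 1), n_classes).astype(int)
    patterns = _embed(classes, m, delay)
    # encode each pattern as one integer
    codes = patterns @ (n_classes ** np.arange(m))
    _, counts = np.unique(codes, return_counts=True)
    prob = counts / counts.sum()
    return float(-(prob * np.log(prob)).sum() / np.log(float(n_classes) ** m))


def _inversion_counts(emb: np.ndarray) -> np.ndarray:
    m = emb.shape[1]
    iu, ju = np.triu_indices(m, k=1)
    return (emb[:, iu] > emb[:, ju]).sum(axis=1)


def bubble_entropy(window: np.ndarray, m: int = 10) -> float:
    """Bubble entropy: growth of the Renyi-2 entropy of bubble-sort swap
    counts between embedding dimensions m and m+1, normalised by
    log((m+1)/m)."""
    x = np.asarray(window, dtype=float)
    if x.size < m + 2:
        raise ValueError("window too short for bubble entropy")

    def renyi2(mm: int) -> float:
        swaps = _inversion_counts(_embed(x, mm))
        _, counts = np.unique(swaps, return_counts=True)
        prob = counts / counts.sum()
        return float(-np.log((prob**2).sum()))

    return float((renyi2(m + 1) - renyi2(m)) / np.log((m + 1) / m))


def entropies(
    window: np.ndarray,
    fs: float,
    band: tuple[float, float] = SPECTRAL_BAND,
) -> dict[str, float]:
    """All five entropy measures of one (band-filtered) window."""
    x = np.asarray(window, dtype=float)
    if x.size < 100:
        raise ValueError("window shorter than 100 samples")
    return {
        "SampEn": sample_entropy(x),
        "FuzEn": fuzzy_entropy(x),
        "SpEn": spectral_entropy(x, fs, band=band),
        "DispEn": dispersion_entropy(x),
        "BubbEn": bubble_entropy(x),
    }


def nonlinear_features(window: np.ndarray, fs: float,
                       band: tuple[float, float]) -> dict[str, float]:
    """The 13 non-linear measures of one band-filtered window."""
    out: dict[str, float] = {
        "LZBin": lempel_ziv(window, 2),
        "LZMulti": lempel_ziv(window, 6),
        "TimeRev": time_reversibility(window),
        "KFD": katz_fd(window),
    }
    out.update(poincare(window))
    out.update(entropies(window, fs, band=band))
    return out


# ---------------------------------------------------------------------------
# record-level extraction and the feature table
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Records x named features with binary labels (1 = preterm).

    ``standardization`` holds per-feature (mean, sd) learned from rows
    flagged as training; it is never computed from the full table.
    """

    X: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    record_ids: list[str] = field(default_factory=list)
    standardization: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.X.shape[0] != self.labels.shape[0]:
            raise ValueError("X and labels row counts differ")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("X column count does not match feature_names")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not self.record_ids:
            self.record_ids = [f"r{i:04d}" for i in range(self.X.shape[0])]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def fit_standardization(self, train_idx: np.ndarray) -> None:
        mu = self.X[train_idx].mean(axis=0)
        sd = self.X[train_idx].std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        self.standardization = (mu, sd)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names, index=self.record_ids)
        df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="record_id")

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, index_col="record_id")
        labels = df.pop("label").to_numpy()
        return cls(df.to_numpy(), list(df.columns), labels,
                   record_ids=[str(i) for i in df.index])


def impute_obstetrics(table: "FeatureTable", train_idx: np.ndarray) -> "FeatureTable":
    """Median-impute missing obstetric covariates from training rows only.

    Real databases have gaps in the clinical columns; signal features are
    never imputed. Returns a new table; raises if a covariate is missing
    in every training row.
    """
    X = table.X.copy()
    train_idx = np.asarray(train_idx, dtype=int)
    for j, name in enumerate(table.feature_names):
        if name not in OBSTETRIC_NAMES:
            continue
        col = X[:, j]
        nan = np.isnan(col)
        if not nan.any():
            continue
        ref = col[train_idx]
        ref = ref[~np.isnan(ref)]
        if ref.size == 0:
            raise ValueError(f"covariate {name!r} missing in all training rows")
        col[nan] = np.median(ref)
    return FeatureTable(X, list(table.feature_names), table.labels.copy(),
                        record_ids=list(table.record_ids))


def standardize(X: np.ndarray, train_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score all rows with mean/SD learned from ``train_idx`` rows only.

    Returns (X_standardized, mean, sd); zero-variance features get sd 1.
    """
    mu = X[train_idx].mean(axis=0)
    sd = X[train_idx].std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, mu, sd


def extract_record(record, filter_order: int = 5) -> dict[str, float]:
    """The 227 named classifier inputs of one EHG record.

    The raw signals are filtered to each analysis band once, windows are
    cut on the clean-interval grid, every window-level feature is computed
    per band/channel and median-aggregated, and the obstetric covariates
    are appended.
    """
    ws = segment(record)
    fs = float(record.fs)
    n_win = ws.n_samples
    signals = np.asarray(record.signals, dtype=float)

    banded = {band: bandpass(signals, fs, *band, order=filter_order)
              for band in AMPLITUDE_BANDS}
    base = banded[(0.1, 4.0)]
    spec_band_sig = bandpass(signals, fs, *SPECTRAL_BAND, order=filter_order)

    values: dict[str, float] = {}
    for ci, ch in enumerate(CHANNEL_NAMES):
        starts = ws.start_samples
        # temporal: App per band
        for band in AMPLITUDE_BANDS:
            sig = banded[band][ci]
            apps = [app(sig[s:s + n_win]) for s in starts]
            values[f"{ch}_App_{_band_tag(band)}"] = aggregate_median(apps)
        # spectral (0.2-1 Hz), Teager on the 0.2-1 Hz filtered window
        per_window = [
            spectral_features(base[ci, s:s + n_win], fs,
                              teager_window=spec_band_sig[ci, s:s + n_win])
            for s in starts
        ]
        for m in SPECTRAL_MEASURES:
            values[f"{ch}_{m}"] = aggregate_median([w[m] for w in per_window])
        # non-linear per band
        for band in AMPLITUDE_BANDS:
            sig = banded[band][ci]
            per_window_nl = [nonlinear_features(sig[s:s + n_win], fs, band)
                             for s in starts]
            for m in NONLINEAR_MEASURES:
                values[f"{ch}_{m}_{_band_tag(band)}"] = aggregate_median(
                    [w[m] for w in per_window_nl])

    for name in OBSTETRIC_NAMES:
        values[name] = float(record.obstetrics[name])

    out = {name: values[name] for name in FEATURE_NAMES}
    assert len(out) == 227
    return out


def extract_cohort(records) -> FeatureTable:
    """Extract every record of a cohort into one FeatureTable."""
    rows, labels, ids = [], [], []
    for rec in records:
        vals = extract_record(rec)
        rows.append([vals[n] for n in FEATURE_NAMES])
        labels.append(1 if rec.label == "preterm" else 0)
        ids.append(rec.record_id)
    return FeatureTable(np.array(rows), list(FEATURE_NAMES),
                        np.array(labels), record_ids=ids)
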