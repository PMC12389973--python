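"""Multi-band cortical features: PLV graphs, graph metrics, signal statistics.

Per ROI and band (theta 4-8, alpha 8-13, beta 13-30, gamma 30-80 Hz) the
feature vector is, in fixed order:

    [clustering_coefficient, local_efficiency, peak, skewness,
     band_power, relative_power, sample_entropy, fuzzy_entropy]

giving a feature matrix X of shape [N x 32]. Graph metrics are computed on
the binarized phase-locking-value (PLV) graph of the band; amplitude
statistics and entropies on the band-filtered ROI series; spectral powers by
integrating the Welch PSD of the broadband ROI series over the band.

Band note: the gamma band starts at 30 Hz (not 31) so the four bands tile
[4, 80] Hz without a spectral dead zone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.spatial.distance import cdist
from scipy.sparse.csgraph import shortest_path
from scipy.stats import skew

MIN_PLV_LENGTH = 64

FEATURE_NAMES = (
    "clustering_coefficient",
    "local_efficiency",
    "peak",
    "skewness",
    "band_power",
    "relative_power",
    "sample_entropy",
    "fuzzy_entropy",
)


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 80.0),
)

TOTAL_BAND = (4.0, 80.0)


@dataclass(frozen=True)
class FeatureParams:
    plv_threshold: float = 0.5
    entropy_m: int = 2
    entropy_r_factor: float = 0.2
    welch_window_seconds: float = 1.0
    total_band: tuple[float, float] = TOTAL_BAND


@dataclass
class ConnectivityGraph:
    plv: np.ndarray  # symmetric [N x N] in [0, 1], unit diagonal
    adjacency: np.ndarray  # binary symmetric [N x N], zero diagonal
    band: BandDefinition


@dataclass
class FeatureMatrix:
    x: np.ndarray  # [N x D]
    column_names: list[tuple[str, str]]  # (band, feature)


def band_filter(x: np.ndarray, fs: float, band: BandDefinition) -> np.ndarray:
    """Zero-phase Butterworth band-pass of a series (or rows of a matrix)."""
    high = min(band.high, 0.499 * fs)
    sos = sps.butter(4, [band.low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def _instantaneous_phase(x: np.ndarray) -> np.ndarray:
    return np.angle(sps.hilbert(x, axis=-1))


def plv(x: np.ndarray, y: np.ndarray, fs: float, band: BandDefinition) -> float:
    """Phase-locking value of two series in a band: |mean_t exp(i dphi)|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("plv requires two equal-length 1-D series")
    if x.size < MIN_PLV_LENGTH:
        raise ValueError(f"series too short for plv (need >= {MIN_PLV_LENGTH})")
    px = _instantaneous_phase(band_filter(x, fs, band))
    py = _instantaneous_phase(band_filter(y, fs, band))
    return float(np.abs(np.mean(np.exp(1j * (px - py)))))


def plv_matrix(roi_series: np.ndarray, fs: float, band: BandDefinition) -> np.ndarray:
    """All-pairs PLV of the rows of ``roi_series``; unit diagonal."""
    filt = band_filter(np.asarray(roi_series, dtype=float), fs, band)
    phases = _instantaneous_phase(filt)
    z = np.exp(1j * phases)
    # PLV_pq = |mean_t z_p conj(z_q)|
    m = np.abs(z @ z.conj().T) / phases.shape[1]
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 1.0)
    return np.clip(m, 0.0, 1.0)


def binarize_plv(plv_mat: np.ndarray, threshold: float) -> np.ndarray:
    """adjacency[i, j] = 1 iff plv[i, j] >= threshold and i != j."""
    adj = (np.asarray(plv_mat) >= threshold).astype(np.int64)
    np.fill_diagonal(adj, 0)
    return adj


def _check_binary_symmetric(adj: np.ndarray) -> np.ndarray:
    adj = np.asarray(adj)
    if not np.array_equal(adj, adj.T) or not np.isin(adj, (0, 1)).all():
        raise ValueError("adjacency must be binary and symmetric")
    return adj


def clustering_coefficient(adjacency: np.ndarray, node: int) -> float:
    """Cp(i) = 2 E_i / (k_i (k_i - 1)); 0 for degree < 2."""
    adj = _check_binary_symmetric(adjacency)
    nbrs = np.flatnonzero(adj[node])
    k = nbrs.size
    if k < 2:
        return 0.0
    e = adj[np.ix_(nbrs, nbrs)].sum() / 2
    return float(2.0 * e / (k * (k - 1)))


def local_efficiency(adjacency: np.ndarray, node: int) -> float:
    """Mean inverse shortest-path length within the neighbor-induced subgraph.

    Disconnected neighbor pairs contribute 0 (1/inf); degree < 2 returns 0.
    """
    adj = _check_binary_symmetric(adjacency)
    nbrs = np.flatnonzero(adj[node])
    k = nbrs.size
    if k < 2:
        return 0.0
    sub = adj[np.ix_(nbrs, nbrs)].astype(float)
    d = shortest_path(sub, method="D", unweighted=True)
    inv = np.zeros_like(d)
    finite = np.isfinite(d) & (d > 0)
    inv[finite] = 1.0 / d[finite]
    return float(inv.sum() / (k * (k - 1)))


def peak_value(series: np.ndarray) -> float:
    """Absolute peak of the signal."""
    return float(np.max(np.abs(series)))


def skewness(series: np.ndarray) -> float:
    """Population skewness: central third moment over sigma^3 (0 if constant)."""
    x = np.asarray(series, dtype=float)
    if x.std() == 0:
        return 0.0
    return float(skew(x, bias=True))


def _welch_psd(series: np.ndarray, fs: float, params: FeatureParams):
    nperseg = min(int(round(params.welch_window_seconds * fs)), series.shape[-1])
    return sps.welch(series, fs=fs, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2, axis=-1)


def band_power(series: np.ndarray, fs: float, band: BandDefinition,
               params: FeatureParams = FeatureParams()) -> float:
    """Integrated Welch PSD over [low, high) of the band."""
    f, psd = _welch_psd(np.asarray(series, dtype=float), fs, params)
    mask = (f >= band.low) & (f < band.high)
    df = f[1] - f[0]
    return float(psd[mask].sum() * df)


def relative_power(series: np.ndarray, fs: float, band: BandDefinition,
                   params: FeatureParams = FeatureParams()) -> float:
    """Band power normalized by total power over the 4-80 Hz analysis band."""
    f, psd = _welch_psd(np.asarray(series, dtype=float), fs, params)
    df = f[1] - f[0]
    lo, hi = params.total_band
    total = psd[(f >= lo) & (f <= hi)].sum() * df
    if total <= 0:
        raise ValueError("zero-total-power")
    bp = psd[(f >= band.low) & (f < band.high)].sum() * df
    return float(bp / total)


def _templates(x: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """First N-m templates of lengths m and m+1 (matched counts)."""
    n = x.size - m
    tm = np.lib.stride_tricks.sliding_window_view(x, m)[:n]
    tm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    return tm, tm1


def sample_entropy(series: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r): -ln(A/B) with Chebyshev distance, self-matches excluded.

    Both template sets use the first N-m windows so A and B share their
    normalization (a constant series gives A = B, hence entropy 0). ``r``
    defaults to 0.2 x population standard deviation of the series.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 10 * (m + 1):
        raise ValueError("series too short for sample entropy")
    if r is None:
        r = 0.2 * x.std()
    tm, tm1 = _templates(x, m)
    db = cdist(tm, tm, metric="chebyshev")
    da = cdist(tm1, tm1, metric="chebyshev")
    b = (db <= r).sum() - tm.shape[0]  # exclude self-matches
    a = (da <= r).sum() - tm1.shape[0]
    if b == 0 or a == 0:
        return np.inf
    return float(-np.log(a / b))


def fuzzy_entropy(series: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """FuzzyEn(m, r): smooth-membership analogue of sample entropy.

    Templates are mean-removed; similarity is exp(-(d/r)^2) with Chebyshev d.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 10 * (m + 1):
        raise ValueError("series too short for fuzzy entropy")
    if r is None:
        r = 0.2 * x.std()
    if r == 0:
        return 0.0
    tm, tm1 = _templates(x, m)

    def phi(t: np.ndarray) -> float:
        t = t - t.mean(axis=1, keepdims=True)
        d = cdist(t, t, metric="chebyshev")
        sim = np.exp(-((d / r) ** 2))
        n = t.shape[0]
        return (sim.sum() - n) / (n * (n - 1))

    return float(np.log(phi(tm)) - np.log(phi(tm1)))


def assemble_features(roi_series: np.ndarray, fs: float,
                      bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
                      params: FeatureParams = FeatureParams()) -> FeatureMatrix:
    """Build the [N x (len(bands) * 8)] feature matrix for one epoch."""
    roi_series = np.asarray(roi_series, dtype=float)
    n = roi_series.shape[0]
    cols: list[tuple[str, str]] = []
    blocks: list[np.ndarray] = []
    for band in bands:
        filt = band_filter(roi_series, fs, band)
        plv_m = plv_matrix(roi_series, fs, band)
        adj = binarize_plv(plv_m, params.plv_threshold)
        # No-match SampEn is infinite; cap at the largest resolvable value so
        # the feature matrix stays finite.
        t = roi_series.shape[1]
        samp_cap = np.log((t - params.entropy_m) * (t - params.entropy_m - 1))
        block = np.empty((n, len(FEATURE_NAMES)))
        for i in range(n):
            x = filt[i]
            samp = sample_entropy(x, params.entropy_m,
                                  params.entropy_r_factor * x.std())
            block[i] = (
                clustering_coefficient(adj, i),
                local_efficiency(adj, i),
                peak_value(x),
                skewness(x),
                band_power(roi_series[i], fs, band, params),
                relative_power(roi_series[i], fs, band, params),
                min(samp, samp_cap),
                fuzzy_entropy(x, params.entropy_m,
                              params.entropy_r_factor * x.std()),
            )
        blocks.append(block)
        cols.extend((band.name, f) for f in FEATURE_NAMES)
    return FeatureMatrix(x=np.hstack(blocks), column_names=cols)


def connectivity_graph(roi_series: np.ndarray, fs: float, band: BandDefinition,
                       params: FeatureParams = FeatureParams()) -> ConnectivityGraph:
    plv_m = plv_matrix(roi_series, fs, band)
    return ConnectivityGraph(plv=plv_m, adjacency=binarize_plv(plv_m, params.plv_threshold),
                             band=band)
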