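"""Per-segment feature catalog for 5-s scalp-EEG windows.

Each channel of each 5-s segment (1280 samples at 256 Hz) is summarized
by 92 features drawn from four families:

* ``time_stat`` (18): moments, amplitude statistics, line length,
  zero crossings about the mean, Hjorth activity/mobility/complexity.
* ``entropy_profile`` (12): secondary descriptors of the sample-entropy
  profile, i.e. SampEn(m=2, r) evaluated over a sweep of tolerances
  ``r_j = j * d_max / R`` where ``d_max`` is the largest pairwise
  template (Chebyshev) distance in the window.
* ``band_stat`` (5 bands x 8): statistics of the band-limited signal
  (delta 0.5-4, theta 4-8, alpha 8-13, beta 13-30, gamma 30-80 Hz).
* ``spectral`` (22): Welch-spectrum descriptors of the raw window
  (entropies, edge frequencies, shape moments, band-power ratios).

A per-segment vector concatenates all 22 channels channel-major, giving
22 x 92 = 2024 columns.  Non-finite feature values (degenerate spectra,
undefined SampEn) are replaced by 0 and counted ("NaN policy"), keeping
chi-squared scoring and tree learners well defined.

Band limiting is applied to a filtered copy used for features only; the
stored signal stays raw.  The catalog is registry-driven so a different
verified feature list can be swapped in without code changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

from .io import SubjectTimeline, ValidationError
from .segment import WINDOW_S, segment_record

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "TOTAL_BAND",
    "EntropyProfile",
    "FeatureDef",
    "default_catalog",
    "catalog_names",
    "sample_entropy",
    "entropy_profile",
    "profile_secondary_features",
    "compute_features",
    "band_statistics",
    "spectral_features",
    "extract_table",
    "feature_columns",
]

logger = logging.getLogger(__name__)

FS = 256


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValidationError(f"invalid band {self.name}: [{self.f_lo},{self.f_hi}]")


#: Conventional EEG sub-bands (Hz).
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 80.0),
)

#: Denominator band for relative powers and the spectral family.
TOTAL_BAND = BandDefinition("total", 0.5, 80.0)


@dataclass(frozen=True)
class FeatureDef:
    """One catalog entry; ``func`` allows registry extensions."""

    name: str
    group: str  # time_stat | entropy_profile | band_stat | spectral
    band: BandDefinition | None = None
    func: Callable[[np.ndarray], float] | None = None


_TIME_STAT_NAMES = (
    "mean", "median", "std", "variance", "skewness", "kurtosis", "rms",
    "peak_to_peak", "min", "max", "mad", "iqr", "energy", "line_length",
    "zero_crossings", "hjorth_activity", "hjorth_mobility", "hjorth_complexity",
)

_ENTROPY_NAMES = (
    "ep_max", "ep_mean", "ep_median", "ep_std", "ep_skewness", "ep_kurtosis",
    "ep_area", "ep_range", "ep_argmax_frac", "ep_value_at_r02sd",
    "ep_n_finite", "ep_terminal",
)

_BAND_STAT_NAMES = (
    "power", "rel_power", "mean_abs", "std", "skewness", "kurtosis",
    "line_length", "peak_psd",
)

_SPECTRAL_NAMES = (
    "total_power", "spectral_entropy", "renyi_entropy", "tsallis_entropy",
    "sef50", "sef75", "sef90", "sef95", "peak_freq", "spectral_centroid",
    "spectral_spread", "spectral_skewness", "spectral_kurtosis",
    "spectral_flatness", "spectral_crest", "ratio_delta_theta",
    "ratio_theta_alpha", "ratio_alpha_beta", "ratio_beta_gamma",
    "ratio_slow_fast", "ratio_mid_rest", "median_power",
)


def default_catalog(
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
) -> list[FeatureDef]:
    """The default 92-entry catalog: 18 + 12 + 5*8 + 22 features."""
    cat = [FeatureDef(n, "time_stat") for n in _TIME_STAT_NAMES]
    cat += [FeatureDef(n, "entropy_profile") for n in _ENTROPY_NAMES]
    for b in bands:
        cat += [FeatureDef(f"{b.name}_{n}", "band_stat", band=b) for n in _BAND_STAT_NAMES]
    cat += [FeatureDef(n, "spectral") for n in _SPECTRAL_NAMES]
    names = [f.name for f in cat]
    if len(names) != len(set(names)):
        raise ValidationError("catalog feature names must be unique")
    return cat


def catalog_names(catalog: Sequence[FeatureDef] | None = None) -> list[str]:
    return [f.name for f in (catalog if catalog is not None else default_catalog())]


# ---------------------------------------------------------------------------
# Sample entropy and entropy profiling
# ---------------------------------------------------------------------------


_TRIU_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _template_distances(x: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Condensed pairwise Chebyshev distances for length-m and m+1 templates.

    Uses the N - m templates comparable at both lengths, self-matches
    excluded.  Returns (d_m, d_m1) as flat float32 arrays over i < j.
    """
    x = np.asarray(x, dtype=np.float32)
    n = len(x) - m  # number of templates comparable at both lengths
    if n < 2:
        raise ValidationError(f"signal too short for m={m}: need >= {m + 2} samples")
    diff = np.abs(x[:, None] - x[None, :])
    dm = diff[:n, :n].copy()
    for k in range(1, m):
        np.maximum(dm, diff[k : n + k, k : n + k], out=dm)
    dm1 = np.maximum(dm, diff[m : n + m, m : n + m])
    if n not in _TRIU_CACHE:
        if len(_TRIU_CACHE) > 8:
            _TRIU_CACHE.clear()
        _TRIU_CACHE[n] = np.triu_indices(n, k=1)
    iu = _TRIU_CACHE[n]
    return dm[iu], dm1[iu]


def sample_entropy(x: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """Sample entropy SampEn(m, r) with Chebyshev matching.

    ``-ln(A/B)`` where B counts template pairs of length m within
    tolerance r (inclusive) and A the same for length m+1.  Returns
    ``inf`` when A = 0 and B > 0, ``nan`` when B = 0; downstream feature
    assembly maps non-finite values to 0.
    """
    if r < 0:
        raise ValidationError("tolerance r must be non-negative")
    dm, dm1 = _template_distances(np.asarray(x, dtype=float), m)
    b = int((dm <= r).sum())
    a = int((dm1 <= r).sum())
    if b == 0:
        return float("nan")
    if a == 0:
        return float("inf")
    return float(-np.log(a / b))


@dataclass
class EntropyProfile:
    """SampEn evaluated on an ascending tolerance grid."""

    m: int
    tolerances: np.ndarray  # r_j = j * d_max / R, j = 1..R
    values: np.ndarray      # SampEn(m, r_j); may contain inf/nan
    d_max: float

    def __len__(self) -> int:
        return len(self.values)


try:  # JIT pair-counting kernels; numba is a hard dependency of the package
    from numba import njit
except ImportError:  # pragma: no cover - degraded pure-numpy fallback
    njit = None


def _py_pair_dmax(x: np.ndarray, m: int) -> float:
    dm, _ = _template_distances(x, m)
    return float(dm.max())


def _py_pair_hist(x: np.ndarray, m: int, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    dm, dm1 = _template_distances(x, m)
    R = len(grid)
    hb = np.bincount(np.searchsorted(grid, dm, side="left"), minlength=R + 1)
    ha = np.bincount(np.searchsorted(grid, dm1, side="left"), minlength=R + 1)
    return hb, ha


if njit is not None:

    @njit(cache=False, fastmath=False)
    def _nb_pair_dmax(x: np.ndarray, m: int) -> np.float32:  # pragma: no cover - jitted
        n = x.shape[0] - m
        d_max = np.float32(0.0)
        for i in range(n):
            for j in range(i + 1, n):
                d = np.float32(0.0)
                for k in range(m):
                    a = abs(x[i + k] - x[j + k])
                    if a > d:
                        d = a
                if d > d_max:
                    d_max = d
        return d_max

    @njit(cache=False, fastmath=False)
    def _nb_pair_hist(x: np.ndarray, m: int, grid: np.ndarray, scale: float):  # pragma: no cover - jitted
        # Bin index = first grid point >= d (bisect_left).  The grid is
        # uniform, so arithmetic gives the bin up to +-1 and one exact
        # comparison fixes the boundary, matching float comparisons of
        # the brute-force counter bit for bit.
        n = x.shape[0] - m
        R = grid.shape[0]
        hist_b = np.zeros(R + 1, dtype=np.int64)
        hist_a = np.zeros(R + 1, dtype=np.int64)
        for i in range(n):
            for j in range(i + 1, n):
                d = np.float32(0.0)
                for k in range(m):
                    a = abs(x[i + k] - x[j + k])
                    if a > d:
                        d = a
                d1 = d
                a = abs(x[i + m] - x[j + m])
                if a > d1:
                    d1 = a
                q = int(d * scale)
                if q > R:
                    q = R
                if q > 0 and grid[q - 1] >= d:
                    q -= 1
                elif q < R and grid[q] < d:
                    q += 1
                hist_b[q] += 1
                q = int(d1 * scale)
                if q > R:
                    q = R
                if q > 0 and grid[q - 1] >= d1:
                    q -= 1
                elif q < R and grid[q] < d1:
                    q += 1
                hist_a[q] += 1
        return hist_b, hist_a


def entropy_profile(x: np.ndarray, m: int = 2, R: int = 50) -> EntropyProfile:
    """Sample-entropy profile over ``r_j = j * d_max / R``, j = 1..R.

    ``d_max`` is the maximum pairwise length-m template distance, so the
    grid always spans the full matching range of the window.  All R
    values come from one pass over the pairwise distances (cumulative
    histogram counts), not per-tolerance recomputation; values agree
    exactly with :func:`sample_entropy` at every grid point.
    """
    x32 = np.ascontiguousarray(np.asarray(x), dtype=np.float32)
    if len(x32) - m < 2:
        raise ValidationError(f"signal too short for m={m}: need >= {m + 2} samples")
    if njit is not None:
        d_max = float(_nb_pair_dmax(x32, m))
    else:  # pragma: no cover
        d_max = _py_pair_dmax(x32, m)
    grid = (np.arange(1, R + 1) / R * d_max).astype(np.float32)
    if njit is not None:
        scale = R / d_max if d_max > 0 else 0.0
        hb, ha = _nb_pair_hist(x32, m, grid, scale)
    else:  # pragma: no cover
        hb, ha = _py_pair_hist(x32, m, grid)
    b = np.cumsum(hb)[:R].astype(float)
    a = np.cumsum(ha)[:R].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = -np.log(a / b)
        vals[(a == 0) & (b > 0)] = np.inf
        vals[b == 0] = np.nan
    return EntropyProfile(m=m, tolerances=grid.astype(float), values=vals, d_max=d_max)


def profile_secondary_features(
    p: EntropyProfile, signal_sd: float = 0.0
) -> np.ndarray:
    """12 secondary descriptors of a sample-entropy profile.

    Statistics are taken over the finite profile points; an all-undefined
    profile yields zeros (NaN policy).  ``signal_sd`` is the SD of the
    originating window, used for the conventional read-out at
    r = 0.2 * SD.
    """
    finite = np.isfinite(p.values)
    out = np.zeros(len(_ENTROPY_NAMES))
    out[10] = float(finite.sum())
    if not finite.any():
        return out
    v = p.values[finite]
    r = p.tolerances[finite]
    mu = v.mean()
    m2 = np.mean((v - mu) ** 2)
    out[0] = v.max()
    out[1] = mu
    out[2] = float(np.median(v))
    out[3] = np.sqrt(m2)
    # biased moment ratios (the scipy defaults), written out for speed
    if m2 > 0:
        out[4] = np.mean((v - mu) ** 3) / m2**1.5 if len(v) > 2 else 0.0
        out[5] = np.mean((v - mu) ** 4) / m2**2 - 3.0 if len(v) > 3 else 0.0
    out[6] = np.trapezoid(v, r) if len(v) > 1 else 0.0
    out[7] = v.max() - v.min()
    out[8] = r[int(np.argmax(v))] / p.d_max if p.d_max > 0 else 0.0
    out[9] = float(np.interp(0.2 * signal_sd, r, v))
    out[11] = v[-1]
    return np.where(np.isfinite(out), out, 0.0)


# ---------------------------------------------------------------------------
# Vectorized family blocks (rows = segments of one channel)
# ---------------------------------------------------------------------------


def _nan_to_zero(a: np.ndarray) -> np.ndarray:
    bad = ~np.isfinite(a)
    if bad.any():
        logger.debug("NaN policy: zeroing %d non-finite feature values", int(bad.sum()))
        a = np.where(bad, 0.0, a)
    return a


def _time_stat_block(S: np.ndarray) -> np.ndarray:
    n = S.shape[0]
    out = np.empty((n, 18))
    mean = S.mean(axis=1)
    var = S.var(axis=1)
    centred = S - mean[:, None]
    d1 = np.diff(S, axis=1)
    # Hjorth mobility/complexity from raw second moments of the derivatives
    d2 = np.diff(d1, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mob = np.sqrt(np.mean(d1**2, axis=1) / var)
        mob2 = np.sqrt(np.mean(d2**2, axis=1) / np.mean(d1**2, axis=1))
        comp = mob2 / mob
    out[:, 0] = mean
    out[:, 1] = np.median(S, axis=1)
    out[:, 2] = np.sqrt(var)
    out[:, 3] = var
    with np.errstate(invalid="ignore", divide="ignore"):
        out[:, 4] = spstats.skew(S, axis=1)
        out[:, 5] = spstats.kurtosis(S, axis=1)
    out[:, 6] = np.sqrt(np.mean(S**2, axis=1))
    out[:, 7] = S.max(axis=1) - S.min(axis=1)
    out[:, 8] = S.min(axis=1)
    out[:, 9] = S.max(axis=1)
    out[:, 10] = np.mean(np.abs(centred), axis=1)
    q75, q25 = np.percentile(S, [75, 25], axis=1)
    out[:, 11] = q75 - q25
    out[:, 12] = np.sum(S**2, axis=1)
    out[:, 13] = np.sum(np.abs(d1), axis=1)
    out[:, 14] = np.sum(centred[:, :-1] * centred[:, 1:] < 0, axis=1)
    out[:, 15] = var
    out[:, 16] = mob
    out[:, 17] = comp
    return _nan_to_zero(out)


def _entropy_block(S: np.ndarray, m: int, R: int, stride: int) -> np.ndarray:
    out = np.empty((S.shape[0], 12))
    for i in range(S.shape[0]):
        x = S[i, ::stride] if stride > 1 else S[i]
        out[i] = profile_secondary_features(
            entropy_profile(x, m=m, R=R), signal_sd=float(S[i].std())
        )
    return _nan_to_zero(out)


def _sos_cache(bands: Sequence[BandDefinition], fs: float) -> dict[str, np.ndarray]:
    cache = {}
    for b in tuple(bands) + (TOTAL_BAND,):
        hi = min(b.f_hi, 0.499 * fs)
        cache[b.name] = sps.butter(4, [b.f_lo, hi], btype="bandpass", fs=fs, output="sos")
    return cache


def _welch(S: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    nper = min(int(fs), S.shape[1])
    return sps.welch(S, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2, axis=-1)


def _band_stat_block(
    S: np.ndarray,
    bands: Sequence[BandDefinition],
    fs: float,
    sos: dict[str, np.ndarray],
    freqs: np.ndarray,
    psd: np.ndarray,
) -> np.ndarray:
    n = S.shape[0]
    total = sps.sosfiltfilt(sos["total"], S, axis=-1)
    total_power = np.mean(total**2, axis=1)
    out = np.empty((n, 8 * len(bands)))
    for k, b in enumerate(bands):
        f = sps.sosfiltfilt(sos[b.name], S, axis=-1)
        power = np.mean(f**2, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(total_power > 0, power / total_power, 0.0)
            sk = spstats.skew(f, axis=1)
            ku = spstats.kurtosis(f, axis=1)
        mask = (freqs >= b.f_lo) & (freqs <= b.f_hi)
        blk = out[:, 8 * k : 8 * (k + 1)]
        blk[:, 0] = power
        blk[:, 1] = rel
        blk[:, 2] = np.mean(np.abs(f), axis=1)
        blk[:, 3] = f.std(axis=1)
        blk[:, 4] = sk
        blk[:, 5] = ku
        blk[:, 6] = np.sum(np.abs(np.diff(f, axis=1)), axis=1)
        blk[:, 7] = psd[:, mask].max(axis=1) if mask.any() else 0.0
    return _nan_to_zero(out)


def _spectral_block(
    freqs: np.ndarray, psd: np.ndarray, bands: Sequence[BandDefinition]
) -> np.ndarray:
    n = psd.shape[0]
    mask = (freqs >= TOTAL_BAND.f_lo) & (freqs <= TOTAL_BAND.f_hi)
    f = freqs[mask]
    P = psd[:, mask]
    tot = P.sum(axis=1)
    ok = tot > 0
    out = np.zeros((n, 22))
    if not ok.any():
        return out
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(ok[:, None], P / np.where(ok, tot, 1.0)[:, None], 0.0)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
        out[:, 0] = tot
        out[:, 1] = -plogp.sum(axis=1) / np.log(P.shape[1])
        sum_p2 = (p**2).sum(axis=1)
        out[:, 2] = np.where(sum_p2 > 0, -np.log(sum_p2), 0.0)
        out[:, 3] = 1.0 - sum_p2
        cum = np.cumsum(P, axis=1)
        for j, frac in enumerate((0.50, 0.75, 0.90, 0.95)):
            idx = np.argmax(cum >= frac * tot[:, None] - 1e-12, axis=1)
            out[:, 4 + j] = f[idx]
        out[:, 8] = f[np.argmax(P, axis=1)]
        c = (p * f).sum(axis=1)
        out[:, 9] = c
        dev = f[None, :] - c[:, None]
        spread = np.sqrt((p * dev**2).sum(axis=1))
        out[:, 10] = spread
        with np.errstate(divide="ignore", invalid="ignore"):
            z = dev / spread[:, None]
            out[:, 11] = (p * z**3).sum(axis=1)
            out[:, 12] = (p * z**4).sum(axis=1)
        gm = np.where(
            (P > 0).all(axis=1), np.exp(np.mean(np.log(np.where(P > 0, P, 1.0)), axis=1)), 0.0
        )
        am = P.mean(axis=1)
        out[:, 13] = np.where(am > 0, gm / am, 0.0)
        out[:, 14] = np.where(am > 0, P.max(axis=1) / am, 0.0)

        bp = {}
        for b in bands:
            bm = (freqs >= b.f_lo) & (freqs <= b.f_hi)
            bp[b.name] = psd[:, bm].sum(axis=1)

        def ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
            return np.where(den > 0, num / den, 0.0)

        out[:, 15] = ratio(bp["delta"], bp["theta"])
        out[:, 16] = ratio(bp["theta"], bp["alpha"])
        out[:, 17] = ratio(bp["alpha"], bp["beta"])
        out[:, 18] = ratio(bp["beta"], bp["gamma"])
        out[:, 19] = ratio(bp["delta"] + bp["theta"], bp["alpha"] + bp["beta"])
        out[:, 20] = ratio(bp["alpha"] + bp["beta"], bp["delta"] + bp["theta"] + bp["gamma"])
        out[:, 21] = np.median(P, axis=1)
    out[~ok] = 0.0
    return _nan_to_zero(out)


def _feature_matrix(
    S: np.ndarray,
    bands: Sequence[BandDefinition],
    fs: float,
    *,
    m: int = 2,
    R: int = 50,
    entropy_stride: int = 1,
    sos: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """(n_segments, 92) default-catalog feature matrix for one channel."""
    S = np.asarray(S, dtype=np.float64)
    if sos is None:
        sos = _sos_cache(bands, fs)
    freqs, psd = _welch(S, fs)
    return np.hstack(
        [
            _time_stat_block(S),
            _entropy_block(S, m, R, entropy_stride),
            _band_stat_block(S, bands, fs, sos, freqs, psd),
            _spectral_block(freqs, psd, bands),
        ]
    )


# ---------------------------------------------------------------------------
# Public single-segment and table-level entry points
# ---------------------------------------------------------------------------


def compute_features(
    x: np.ndarray,
    catalog: Sequence[FeatureDef] | None = None,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    *,
    fs: float = FS,
    entropy_stride: int = 1,
    key: str = "",
) -> np.ndarray:
    """Feature vector of one channel window, in catalog order.

    Deterministic; non-finite inputs raise (naming the segment ``key``
    when given); non-finite outputs are zeroed per the NaN policy.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValidationError("compute_features expects a 1-D window")
    if not np.isfinite(x).all():
        raise ValidationError(f"non-finite samples in segment {key or '<unnamed>'}")
    full = _feature_matrix(x[None, :], bands, fs, entropy_stride=entropy_stride)[0]
    if catalog is None:
        return full
    lut = dict(zip(catalog_names(default_catalog(bands)), full))
    out = np.empty(len(catalog))
    for i, fd in enumerate(catalog):
        if fd.func is not None:
            v = float(fd.func(x))
            out[i] = v if np.isfinite(v) else 0.0
        else:
            out[i] = lut[fd.name]
    return out


def band_statistics(
    x: np.ndarray, band: BandDefinition, *, fs: float = FS
) -> np.ndarray:
    """The 8 band-limited statistics for one window and one band."""
    x = np.asarray(x, dtype=np.float64)[None, :]
    sos = _sos_cache([band], fs)
    freqs, psd = _welch(x, fs)
    return _band_stat_block(x, [band], fs, sos, freqs, psd)[0]


def spectral_features(x: np.ndarray, *, fs: float = FS) -> np.ndarray:
    """The 22 Welch-spectrum descriptors for one raw window."""
    x = np.asarray(x, dtype=np.float64)[None, :]
    freqs, psd = _welch(x, fs)
    return _spectral_block(freqs, psd, DEFAULT_BANDS)[0]


def feature_columns(
    channel_labels: Sequence[str], catalog: Sequence[FeatureDef] | None = None
) -> list[str]:
    """Channel-major column names ``<channel>/<feature>``."""
    names = catalog_names(catalog)
    return [f"{ch}/{n}" for ch in channel_labels for n in names]


def extract_table(
    timelines: SubjectTimeline | Sequence[SubjectTimeline],
    catalog: Sequence[FeatureDef] | None = None,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    *,
    entropy_stride: int = 1,
    window_s: float = WINDOW_S,
) -> pd.DataFrame:
    """Feature table over every segment of one or more subject timelines.

    Rows are keyed by (subject, record, index) and ordered by subject and
    temporal order; columns are the 2024 channel-major features plus
    ``label``.  Values for each (segment, channel) equal
    :func:`compute_features` on the sliced raw samples.
    """
    if isinstance(timelines, SubjectTimeline):
        timelines = [timelines]
    cat = list(catalog) if catalog is not None else default_catalog(bands)
    frames = []
    for tl in timelines:
        ch_labels = tl.records[0].channels.labels
        cols = feature_columns(ch_labels, cat)
        for rec in tl.records:
            segs = segment_record(rec, window_s)
            if not segs:
                continue
            n = len(segs)
            L = int(round(window_s * rec.fs))
            sos = _sos_cache(bands, rec.fs)
            block = np.empty((n, len(cols)))
            sig = np.asarray(rec.signal, dtype=np.float64)
            if not np.isfinite(sig).all():
                raise ValidationError(f"non-finite samples in record {rec.record_id}")
            windows = sig[:, : n * L].reshape(len(ch_labels), n, L)
            for c in range(len(ch_labels)):
                fm = _feature_matrix(
                    windows[c], bands, rec.fs, entropy_stride=entropy_stride, sos=sos
                )
                if catalog is not None:
                    full_names = catalog_names(default_catalog(bands))
                    idx = []
                    for fd in cat:
                        if fd.func is not None:
                            idx = None
                            break
                        idx.append(full_names.index(fd.name))
                    if idx is None:
                        fm = np.vstack(
                            [
                                compute_features(
                                    windows[c, i], cat, bands, fs=rec.fs,
                                    entropy_stride=entropy_stride,
                                )
                                for i in range(n)
                            ]
                        )
                    else:
                        fm = fm[:, idx]
                block[:, c * len(cat) : (c + 1) * len(cat)] = fm
            df = pd.DataFrame(block, columns=cols)
            df.insert(0, "subject", tl.subject_id)
            df.insert(1, "record", rec.record_id)
            df.insert(2, "index", [s.index for s in segs])
            df["label"] = np.array([s.label for s in segs], dtype=np.int8)
            frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out
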