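"""Per-window texture features of uptake regions.

Four families, all computed slice-wise on 2D windows (pseudo-3D):

* descriptive / histogram statistics, with quantiles taken from a diffusion
  kernel density estimate so small windows still give stable values;
* Haralick gray-level co-occurrence (GLCM) features;
* gray-level run-length (Galloway/Chu/Dasarathy) features;
* Gaussian Markov random field (GMRF) least-squares parameters, a
  rotation-symmetric conditional-autoregression texture descriptor.

Gray levels are quantized to 1..G (G = 64 by default) over the lesion's
min-max range; masked (outside-lesion) pixels never pair in the GLCM and
terminate runs in the run-length scan.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .kde import estimate_density

log = logging.getLogger(__name__)

#: default in-plane displacement set: 0, 45, 90, 135 degrees at distance 1
DEFAULT_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))
#: GMRF n=6 neighborhood as 3 symmetric pixel pairs
DEFAULT_GMRF_PAIRS = ((1, 0), (0, 1), (1, 1))

DESCRIPTIVE_NAMES = (
    "AVGint", "SDint", "MEDIANint", "MADint", "MAXDEVint", "IRQint",
    "SKEWNESSint", "KURTOSISint",
)
GLCM_NAMES = (
    "ENTROPY", "ENERGY", "CONTRAST", "CORRELATION", "ACORR", "CSHADE",
    "HOMOG", "DIFFENTROPY", "MAX.PR", "SUM.SQR", "SUM.AVG", "SUM.VAR",
)
RLM_NAMES = (
    "SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE",
    "SRLGE", "SRHGE", "LRLGE", "LRHGE",
)
GMRF_NAMES = ("GMRFa1", "GMRFa2", "GMRFa3", "GMRF.SIGMA")

FEATURE_REGISTRY = DESCRIPTIVE_NAMES + GLCM_NAMES + RLM_NAMES + GMRF_NAMES


class DegenerateModelError(RuntimeError):
    """Raised when a texture model cannot be fit (e.g. constant image)."""


# ---------------------------------------------------------------- quantize

@dataclass
class QuantizedWindow:
    """2D integer gray-level grid in 1..G with a valid-pixel mask."""

    levels: np.ndarray
    G: int
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.G < 2:
            raise ValueError("G must be >= 2")
        v = self.levels[self.mask]
        if v.size and (v.min() < 1 or v.max() > self.G):
            raise ValueError("quantized levels out of [1, G]")


def quantize(image, G: int = 64, mask=None, value_range=None) -> QuantizedWindow:
    """Equal-width quantization of a 2D window to levels 1..G.

    ``value_range`` fixes (lo, hi) externally (e.g. the whole-lesion min-max
    so every window of a lesion shares one gray scale); by default the range
    of the valid pixels is used. The minimum maps to level 1 and the maximum
    to level G; a constant window maps entirely to level 1 (logged).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("quantize expects a 2D window")
    mask = np.ones_like(img, dtype=bool) if mask is None else np.asarray(mask, bool)
    vals = img[mask]
    if vals.size == 0:
        raise ValueError("no valid pixel to quantize")
    if value_range is None:
        lo, hi = float(vals.min()), float(vals.max())
    else:
        lo, hi = map(float, value_range)
    levels = np.ones_like(img, dtype=np.int64)
    if hi > lo:
        levels = 1 + np.floor((img - lo) / (hi - lo) * G).astype(np.int64)
        levels = np.clip(levels, 1, G)
    else:
        log.debug("constant window; all pixels quantized to level 1")
    return QuantizedWindow(levels=levels, G=G, mask=mask)


# ------------------------------------------------------------- descriptive

def descriptive_features(values) -> dict[str, float]:
    """Descriptive and histogram statistics of a sample of SUVs.

    Mean, SD (sample, n-1), median and the median absolute deviation are
    computed directly; the interquartile range comes from the diffusion-KDE
    CDF (robust at small n) and skewness / excess kurtosis from the sample
    moments. Fewer than 4 values flags the higher-order entries as NaN.
    ``MAXDEVint`` is the maximum absolute deviation from the median,
    reported alongside the median absolute deviation ``MADint``.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("descriptive_features needs at least one value")
    med = float(np.median(x))
    absdev = np.abs(x - med)
    out = {
        "AVGint": float(np.mean(x)),
        "SDint": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        "MEDIANint": med,
        "MADint": float(np.median(absdev)),
        "MAXDEVint": float(absdev.max()),
    }
    if x.size >= 4:
        if np.ptp(x) > 0:
            kde = estimate_density(x)
            q25, q75 = kde.quantile([0.25, 0.75])
            out["IRQint"] = float(q75 - q25)
        else:
            out["IRQint"] = 0.0
        sd = np.std(x)
        out["SKEWNESSint"] = float(sps.skew(x)) if sd > 0 else 0.0
        out["KURTOSISint"] = float(sps.kurtosis(x)) if sd > 0 else 0.0
    else:
        out.update({"IRQint": math.nan, "SKEWNESSint": math.nan,
                    "KURTOSISint": math.nan})
    return out


# -------------------------------------------------------------------- GLCM

@dataclass
class GlcmMatrix:
    """Normalized gray-level co-occurrence matrix (sums to 1)."""

    P: np.ndarray
    offsets: tuple

    def __post_init__(self) -> None:
        s = self.P.sum()
        if not math.isclose(s, 1.0, abs_tol=1e-9):
            raise ValueError(f"GLCM must be normalized, sums to {s}")


def compute_glcm(win: QuantizedWindow, offsets=DEFAULT_OFFSETS,
                 symmetric: bool = True) -> GlcmMatrix:
    """Co-occurrence counts of valid pixel pairs, accumulated over offsets.

    Pairs in which either pixel is masked are skipped. With ``symmetric``
    the transpose is added (each pair counted in both orders) before
    normalization to a joint probability matrix.
    """
    lev, mask, G = win.levels, win.mask, win.G
    counts = np.zeros((G, G), dtype=float)
    nr, nc = lev.shape
    for di, dj in offsets:
        sl_a = (slice(max(0, -di), nr - max(0, di)),
                slice(max(0, -dj), nc - max(0, dj)))
        sl_b = (slice(max(0, di), nr + min(0, di)),
                slice(max(0, dj), nc + min(0, dj)))
        a = lev[sl_a]
        b = lev[sl_b]
        valid = mask[sl_a] & mask[sl_b]
        if valid.any():
            np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1.0)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid co-occurring pixel pair in the window")
    return GlcmMatrix(P=counts / total, offsets=tuple(offsets))


def glcm_features(M: GlcmMatrix) -> dict[str, float]:
    """Haralick statistics of a normalized co-occurrence matrix.

    Entropies are in bits (log base 2, with 0 log 0 := 0). SUM.AVG/SUM.VAR
    and DIFFENTROPY use the standard sum and difference distributions
    p_{x+y} and p_{x-y}; SUM.SQR is the variance about the marginal mean.
    """
    p = M.P
    G = p.shape[0]
    i = np.arange(1, G + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    nz = p > 0

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_i = float((i * px).sum())
    mu_j = float((i * py).sum())
    sd_i = math.sqrt(max(((i - mu_i) ** 2 * px).sum(), 0.0))
    sd_j = math.sqrt(max(((i - mu_j) ** 2 * py).sum(), 0.0))

    acorr = float((ii * jj * p).sum())
    if sd_i > 0 and sd_j > 0:
        correlation = (acorr - mu_i * mu_j) / (sd_i * sd_j)
    else:
        correlation = 0.0

    # sum (k = i+j in 2..2G) and difference (k = |i-j| in 0..G-1) distributions
    p_sum = np.zeros(2 * G + 1)
    np.add.at(p_sum, (ii + jj).ravel(), p.ravel())
    k_sum = np.arange(2 * G + 1)
    sum_avg = float((k_sum * p_sum).sum())
    sum_var = float(((k_sum - sum_avg) ** 2 * p_sum).sum())

    p_diff = np.zeros(G)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())
    nzd = p_diff > 0

    return {
        "ENTROPY": float(-(p[nz] * np.log2(p[nz])).sum()),
        "ENERGY": float((p ** 2).sum()),
        "CONTRAST": float(((ii - jj) ** 2 * p).sum()),
        "CORRELATION": float(correlation),
        "ACORR": acorr,
        "CSHADE": float(((ii + jj - mu_i - mu_j) ** 3 * p).sum()),
        "HOMOG": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "DIFFENTROPY": float(-(p_diff[nzd] * np.log2(p_diff[nzd])).sum()),
        "MAX.PR": float(p.max()),
        "SUM.SQR": float(((ii - mu_i) ** 2 * p).sum()),
        "SUM.AVG": sum_avg,
        "SUM.VAR": sum_var,
    }


# ------------------------------------------------------------ run lengths

@dataclass
class RunLengthMatrix:
    """Run counts r[level, length] along one direction."""

    r: np.ndarray          # (G, Lmax)
    direction: tuple[int, int]
    n_pixels: int          # valid pixels scanned
    n_runs: int


def compute_rlm(win: QuantizedWindow, direction=(0, 1)) -> RunLengthMatrix:
    """Maximal equal-level runs of valid pixels along ``direction``.

    A masked pixel terminates the current run, so runs never bridge gaps
    in the lesion mask. Directions are in-plane unit steps such as (0,1),
    (1,0), (1,1), (1,-1).
    """
    lev, mask, G = win.levels, win.mask, win.G
    nr, nc = lev.shape
    di, dj = direction
    if (di, dj) == (0, 0):
        raise ValueError("direction must be a nonzero step")
    lmax = max(nr, nc)
    counts = np.zeros((G, lmax), dtype=np.int64)

    # enumerate scan-line start points: cells with no in-bounds predecessor
    starts = []
    for r0 in range(nr):
        for c0 in range(nc):
            pr, pc = r0 - di, c0 - dj
            if not (0 <= pr < nr and 0 <= pc < nc):
                starts.append((r0, c0))
    n_pixels = 0
    n_runs = 0
    for r0, c0 in starts:
        run_level, run_len = None, 0
        r, c = r0, c0
        while 0 <= r < nr and 0 <= c < nc:
            if mask[r, c]:
                n_pixels += 1
                if lev[r, c] == run_level:
                    run_len += 1
                else:
                    if run_level is not None:
                        counts[run_level - 1, run_len - 1] += 1
                        n_runs += 1
                    run_level, run_len = int(lev[r, c]), 1
            else:
                if run_level is not None:
                    counts[run_level - 1, run_len - 1] += 1
                    n_runs += 1
                run_level, run_len = None, 0
            r += di
            c += dj
        if run_level is not None:
            counts[run_level - 1, run_len - 1] += 1
            n_runs += 1
    return RunLengthMatrix(r=counts.astype(float), direction=(di, dj),
                           n_pixels=n_pixels, n_runs=n_runs)


def rlm_features(R: RunLengthMatrix) -> dict[str, float]:
    """The 11 run-length statistics (Galloway, Chu, Dasarathy)."""
    if R.n_runs < 1:
        raise ValueError("run-length matrix holds no run")
    r = R.r
    G, lmax = r.shape
    i = np.arange(1, G + 1)[:, None].astype(float)     # gray level
    j = np.arange(1, lmax + 1)[None, :].astype(float)  # run length
    nr = float(R.n_runs)
    return {
        "SRE": float((r / j ** 2).sum() / nr),
        "LRE": float((r * j ** 2).sum() / nr),
        "GLN": float((r.sum(axis=1) ** 2).sum() / nr),
        "RLN": float((r.sum(axis=0) ** 2).sum() / nr),
        "RP": nr / float(R.n_pixels),
        "LGRE": float((r / i ** 2).sum() / nr),
        "HGRE": float((r * i ** 2).sum() / nr),
        "SRLGE": float((r / (i ** 2 * j ** 2)).sum() / nr),
        "SRHGE": float((r * i ** 2 / j ** 2).sum() / nr),
        "LRLGE": float((r * j ** 2 / i ** 2).sum() / nr),
        "LRHGE": float((r * i ** 2 * j ** 2).sum() / nr),
    }


def rlm_features_averaged(win: QuantizedWindow,
                          directions=((0, 1), (1, 0), (1, 1), (1, -1))
                          ) -> dict[str, float]:
    """Run-length features averaged over the four in-plane directions."""
    feats = []
    for d in directions:
        R = compute_rlm(win, d)
        if R.n_runs >= 1:
            feats.append(rlm_features(R))
    if not feats:
        raise ValueError("no direction produced any run")
    return {k: float(np.mean([f[k] for f in feats])) for k in feats[0]}


# --------------------------------------------------------------------- GMRF

@dataclass
class GmrfModel:
    """Least-squares conditional-autoregression texture parameters."""

    theta: np.ndarray
    sigma: float
    pairs: tuple


def gmrf_design(window, mask=None, pairs=DEFAULT_GMRF_PAIRS
                ) -> tuple[np.ndarray, np.ndarray]:
    """Regression design (X, y) for the GMRF conditional model on one slice.

    Rows are interior pixels whose entire symmetric neighborhood is in
    bounds (and inside ``mask``, when given); column z holds the neighbor
    pair sum S_xy;z of centered intensities. Returns empty arrays when no
    pixel qualifies.
    """
    img = np.asarray(window, dtype=float)
    if img.ndim != 2:
        raise ValueError("gmrf design expects a 2D window")
    mask = np.ones_like(img, bool) if mask is None else np.asarray(mask, bool)
    pr = max(abs(p[0]) for p in pairs)
    pc = max(abs(p[1]) for p in pairs)
    if img.shape[0] <= 2 * pr or img.shape[1] <= 2 * pc or not mask.any():
        return np.empty((0, len(pairs))), np.empty(0)
    centered = np.where(mask, img - img[mask].mean(), 0.0)
    core = (slice(pr, img.shape[0] - pr), slice(pc, img.shape[1] - pc))
    valid = mask[core].copy()
    cols = []
    for di, dj in pairs:
        sh_p = (slice(pr + di, img.shape[0] - pr + di),
                slice(pc + dj, img.shape[1] - pc + dj))
        sh_m = (slice(pr - di, img.shape[0] - pr - di),
                slice(pc - dj, img.shape[1] - pc - dj))
        valid &= mask[sh_p] & mask[sh_m]
        cols.append((centered[sh_p] + centered[sh_m]))
    y = centered[core][valid]
    X = np.column_stack([c[valid] for c in cols])
    return X, y


def fit_gmrf(window, pairs=DEFAULT_GMRF_PAIRS, mask=None) -> GmrfModel:
    """Fit the Gaussian MRF conditional model by ordinary least squares.

    The model: a centered pixel value I_xy is predicted by the sums
    S_xy;z of its n = 2 * len(pairs) symmetric neighbors (one coefficient
    per pair), with Gaussian residual of SD sigma. Only interior pixels
    with all neighbors in bounds (and in ``mask``) enter the regression.
    Rotating the image by 180 degrees leaves theta unchanged by
    construction.
    """
    X, y = gmrf_design(window, mask=mask, pairs=pairs)
    return fit_gmrf_design(X, y, pairs)


def fit_gmrf_design(X: np.ndarray, y: np.ndarray,
                    pairs=DEFAULT_GMRF_PAIRS) -> GmrfModel:
    """Solve the GMRF least-squares system for stacked (pseudo-3D) designs."""
    if y.size <= X.shape[1] + 1:
        raise DegenerateModelError("not enough interior pixels")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateModelError("rank-deficient design (constant texture?)")
    theta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ theta
    dof = max(y.size - X.shape[1], 1)
    sigma = float(np.sqrt((resid ** 2).sum() / dof))
    return GmrfModel(theta=theta, sigma=sigma, pairs=tuple(pairs))


def simulate_gmrf(theta, sigma: float, shape=(64, 64), sweeps: int = 100,
                  seed: int | None = None,
                  pairs=DEFAULT_GMRF_PAIRS) -> np.ndarray:
    """Gibbs-sample a texture from the GMRF conditional model.

    Checkerboard-partitioned Gibbs updates: each pixel is redrawn from
    N(sum_z theta_z S_xy;z, sigma^2) given its current neighbors, using
    periodic boundary conditions. Requires 2 * sum|theta| < 1 for a valid
    joint distribution.
    """
    theta = np.asarray(theta, dtype=float)
    if 2 * np.abs(theta).sum() >= 1:
        raise ValueError("unstable GMRF: need 2*sum(|theta|) < 1")
    rng = np.random.default_rng(seed)
    img = rng.normal(0.0, sigma, size=shape)
    rows, cols = np.indices(shape)
    parity = (rows + cols) % 2
    for _ in range(sweeps):
        for par in (0, 1):
            mean = np.zeros(shape)
            for t, (di, dj) in zip(theta, pairs):
                mean += t * (np.roll(img, (di, dj), axis=(0, 1))
                             + np.roll(img, (-di, -dj), axis=(0, 1)))
            upd = parity == par
            img[upd] = mean[upd] + rng.normal(0.0, sigma, size=int(upd.sum()))
    return img


# ------------------------------------------------------------ full vector

def window_features(window, mask=None, G: int = 64, value_range=None,
                    with_gmrf: bool = True) -> dict[str, float]:
    """All texture features of one 2D window (see FEATURE_REGISTRY).

    GMRF features use only pixels whose whole neighborhood is valid; they
    are reported as NaN when the fit degenerates.
    """
    img = np.asarray(window, dtype=float)
    mask = np.ones_like(img, bool) if mask is None else np.asarray(mask, bool)
    vals = img[mask]
    out = descriptive_features(vals)
    win = quantize(img, G=G, mask=mask, value_range=value_range)
    try:
        out.update(glcm_features(compute_glcm(win)))
    except ValueError:
        out.update({k: math.nan for k in GLCM_NAMES})
    try:
        out.update(rlm_features_averaged(win))
    except ValueError:
        out.update({k: math.nan for k in RLM_NAMES})
    out.update({k: math.nan for k in GMRF_NAMES})
    if with_gmrf:
        try:
            model = fit_gmrf(img, mask=mask)
            for k, t in zip(GMRF_NAMES[:3], model.theta):
                out[k] = float(t)
            out["GMRF.SIGMA"] = model.sigma
        except DegenerateModelError:
            pass
    return out
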