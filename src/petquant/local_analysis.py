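"""Local windowing of segmented lesions and global + local-SD aggregation.

A segmented 3D lesion is processed slice-by-slice (pseudo-3D): each slice
is tiled into non-overlapping square blocks (3x3 .. 11x11 pixels) anchored
at the lesion bounding-box corner, and every texture feature is computed
both globally (pooled over the whole lesion) and as the standard deviation
of its per-window values — the "local SD" companions that capture textural
heterogeneity across the lesion.

Two data-driven window-size selectors are provided: maximum mutual
information between adjacent windows (descriptive/GLCM families) and
maximum autocorrelation of adjacent windows' run-length distributions
(run-length family).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .image_model import PetVolume
from . import texture_features as tf

log = logging.getLogger(__name__)

DEFAULT_BLOCK_CANDIDATES = (3, 5, 7, 9, 11)


@dataclass
class Window:
    """One in-plane window: slice index, bbox and valid-pixel mask."""

    z: int
    bbox: tuple[int, int, int, int]  # (x0, y0, x1, y1) half-open
    valid: np.ndarray                # (x1-x0, y1-y0) bool
    grid_pos: tuple[int, int]        # (row, col) in the tiling grid

    @property
    def coverage(self) -> float:
        return float(self.valid.mean())

    def extract(self, volume_values: np.ndarray) -> np.ndarray:
        x0, y0, x1, y1 = self.bbox
        return volume_values[x0:x1, y0:y1, self.z]


@dataclass
class LocalWindowGrid:
    """Non-overlapping tiling of a lesion mask, per slice."""

    block_size: int
    windows: list[Window]
    fallback: bool = False  # whole-lesion windows when no tile qualified


def tile_mask(mask: np.ndarray, block_size: int,
              min_coverage: float = 0.5) -> LocalWindowGrid:
    """Tile a 3D lesion mask into in-plane non-overlapping blocks.

    Per slice, a regular ``block_size``-square grid is anchored at the
    lesion's in-plane bounding-box corner; tiles whose lesion coverage is
    below ``min_coverage`` are dropped. If no tile anywhere qualifies the
    tiling falls back to one whole-lesion window per slice (logged), so
    small lesions still produce features.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty lesion mask")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    xs, ys, zs = np.nonzero(mask)
    x_lo, y_lo = xs.min(), ys.min()
    x_hi, y_hi = xs.max() + 1, ys.max() + 1

    windows: list[Window] = []
    for z in np.unique(zs):
        sl = mask[:, :, z]
        for gr, x0 in enumerate(range(x_lo, x_hi, block_size)):
            for gc, y0 in enumerate(range(y_lo, y_hi, block_size)):
                x1 = min(x0 + block_size, mask.shape[0])
                y1 = min(y0 + block_size, mask.shape[1])
                valid = sl[x0:x1, y0:y1]
                if valid.sum() / float(block_size ** 2) >= min_coverage:
                    windows.append(Window(z=int(z), bbox=(x0, y0, x1, y1),
                                          valid=valid.copy(),
                                          grid_pos=(gr, gc)))
    if windows:
        return LocalWindowGrid(block_size=block_size, windows=windows)

    log.info("no %dx%d tile reached %.0f%% coverage; whole-lesion fallback",
             block_size, block_size, 100 * min_coverage)
    for z in np.unique(zs):
        sl = mask[:, :, z]
        xi, yi = np.nonzero(sl)
        bbox = (int(xi.min()), int(yi.min()), int(xi.max()) + 1, int(yi.max()) + 1)
        valid = sl[bbox[0]:bbox[2], bbox[1]:bbox[3]]
        windows.append(Window(z=int(z), bbox=bbox, valid=valid.copy(),
                              grid_pos=(0, 0)))
    return LocalWindowGrid(block_size=block_size, windows=windows,
                           fallback=True)


def _adjacent_pairs(grid: LocalWindowGrid):
    """In-slice grid-adjacent window pairs (share a grid edge)."""
    by_slice: dict[int, dict[tuple[int, int], Window]] = {}
    for w in grid.windows:
        by_slice.setdefault(w.z, {})[w.grid_pos] = w
    for z, d in by_slice.items():
        for (r, c), w in d.items():
            for nb in ((r + 1, c), (r, c + 1)):
                if nb in d:
                    yield w, d[nb]


def _mutual_information(a: np.ndarray, b: np.ndarray, G: int) -> float:
    """MI (bits) of two equal-length level sequences from the joint histogram."""
    joint = np.zeros((G, G))
    np.add.at(joint, (a - 1, b - 1), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log2(joint[nz] / (px @ py)[nz])).sum())


def select_window_size(vol: PetVolume, mask: np.ndarray,
                       candidates=DEFAULT_BLOCK_CANDIDATES,
                       G: int = 16) -> int:
    """Maximum-mutual-information (MMI) block-size selection.

    For each candidate size the lesion is tiled, SUVs are quantized at
    G = 16 over the lesion range, and the mutual information between the
    raster-paired level sequences of every in-slice adjacent window pair
    is summed; the size with the highest sum wins (ties go to the smaller
    size). With no adjacent pair for any candidate, the median candidate
    is returned (logged).
    """
    candidates = sorted(candidates)
    if not candidates:
        raise ValueError("need at least one candidate block size")
    lesion_vals = vol.values[np.asarray(mask, bool)]
    vrange = (float(lesion_vals.min()), float(lesion_vals.max()))
    best, best_score = None, -np.inf
    any_pair = False
    for size in candidates:
        grid = tile_mask(mask, size)
        total = 0.0
        n_pairs = 0
        for wa, wb in _adjacent_pairs(grid):
            qa = tf.quantize(wa.extract(vol.values), G=G, mask=wa.valid,
                             value_range=vrange)
            qb = tf.quantize(wb.extract(vol.values), G=G, mask=wb.valid,
                             value_range=vrange)
            # raster-offset pixel pairing over the common sub-shape
            # (windows at the grid edge may be truncated)
            h = min(qa.levels.shape[0], qb.levels.shape[0])
            w = min(qa.levels.shape[1], qb.levels.shape[1])
            paired = wa.valid[:h, :w] & wb.valid[:h, :w]
            if paired.sum() < 2:
                continue
            total += _mutual_information(qa.levels[:h, :w][paired],
                                         qb.levels[:h, :w][paired], G)
            n_pairs += 1
        if n_pairs:
            any_pair = True
            if total > best_score:
                best, best_score = size, total
    if not any_pair:
        fallback = candidates[len(candidates) // 2]
        log.info("no adjacent window pair for any candidate; "
                 "falling back to median size %d", fallback)
        return fallback
    return best


def select_rl_window_size(vol: PetVolume, mask: np.ndarray,
                          candidates=DEFAULT_BLOCK_CANDIDATES,
                          G: int = 16) -> int:
    """Run-length window selection by adjacent-window autocorrelation.

    Each window's run-length matrix (summed over the four in-plane
    directions and over gray levels) gives a run-length distribution;
    the candidate maximizing the mean Pearson correlation between
    adjacent windows' distributions is selected (ties to the smaller).
    """
    candidates = sorted(candidates)
    if not candidates:
        raise ValueError("need at least one candidate block size")
    lesion_vals = vol.values[np.asarray(mask, bool)]
    vrange = (float(lesion_vals.min()), float(lesion_vals.max()))
    best, best_score = None, -np.inf
    any_pair = False
    for size in candidates:
        grid = tile_mask(mask, size)
        dists: dict[int, np.ndarray] = {}

        def rl_dist(w: Window) -> np.ndarray:
            key = id(w)
            if key not in dists:
                q = tf.quantize(w.extract(vol.values), G=G, mask=w.valid,
                                value_range=vrange)
                total = None
                for d in ((0, 1), (1, 0), (1, 1), (1, -1)):
                    r = tf.compute_rlm(q, d).r.sum(axis=0)
                    total = r if total is None else total + r
                s = total.sum()
                dists[key] = total / s if s > 0 else total
            return dists[key]

        cors = []
        for wa, wb in _adjacent_pairs(grid):
            da, db = rl_dist(wa), rl_dist(wb)
            n = max(len(da), len(db))
            da = np.pad(da, (0, n - len(da)))
            db = np.pad(db, (0, n - len(db)))
            if da.std() == 0 or db.std() == 0:
                cors.append(1.0 if np.allclose(da, db) else 0.0)
            else:
                cors.append(float(np.corrcoef(da, db)[0, 1]))
        if cors:
            any_pair = True
            score = float(np.mean(cors))
            if score > best_score:
                best, best_score = size, score
    if not any_pair:
        fallback = candidates[len(candidates) // 2]
        log.info("no adjacent window pair; median fallback %d", fallback)
        return fallback
    return best


@dataclass
class AggregatedFeature:
    """Global value plus across-window standard deviation of one feature."""

    name: str
    global_value: float
    local_sd: float
    n_windows: int


def aggregate(vol: PetVolume, mask: np.ndarray, grid: LocalWindowGrid,
              feature_fn) -> AggregatedFeature:
    """Aggregate a value-based feature into a global value + local SD.

    ``feature_fn(values) -> float`` is applied to the pooled lesion voxels
    for the global value and to each window's valid pixels for the local
    values; the local SD is the sample (n-1) standard deviation over
    windows (0 when fewer than 2 windows). Windows where the feature
    errors are skipped with a log entry.
    """
    pooled = vol.values[np.asarray(mask, bool)]
    global_value = float(feature_fn(pooled))
    locals_: list[float] = []
    for w in grid.windows:
        try:
            v = float(feature_fn(w.extract(vol.values)[w.valid]))
            if math.isfinite(v):
                locals_.append(v)
        except Exception as exc:  # feature errors skip the window
            log.debug("window at z=%d failed: %s", w.z, exc)
    if not locals_:
        raise RuntimeError("feature failed on every window")
    sd = float(np.std(locals_, ddof=1)) if len(locals_) > 1 else 0.0
    return AggregatedFeature(name=getattr(feature_fn, "__name__", "feature"),
                             global_value=global_value, local_sd=sd,
                             n_windows=len(locals_))


def extract_lesion_features(
    vol: PetVolume,
    mask: np.ndarray,
    block_size: int | None = None,
    rl_block_size: int | None = None,
    G: int = 64,
    candidates=DEFAULT_BLOCK_CANDIDATES,
) -> dict[str, float]:
    """Full pseudo-3D texture feature vector of one segmented lesion.

    Global values pool the whole lesion: descriptive statistics over all
    lesion voxels, GLCM counts and run matrices accumulated over slices
    before feature computation, and the GMRF system stacked across slices.
    Local SDs (suffix ``.SD``) are taken over the non-overlapping windows
    of the selected block size (MMI-selected for descriptive/GLCM, runs
    autocorrelation-selected for run lengths, unless given explicitly).

    Also reports ``SUVmax``/``SUVmean`` of the lesion and the selected
    block sizes (``BLOCK``, ``BLOCK.RL``).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty lesion mask")
    if block_size is None:
        block_size = select_window_size(vol, mask, candidates)
    if rl_block_size is None:
        rl_block_size = select_rl_window_size(vol, mask, candidates)

    pooled = vol.values[mask]
    vrange = (float(pooled.min()), float(pooled.max()))
    out: dict[str, float] = {
        "SUVmax": float(pooled.max()),
        "SUVmean": float(pooled.mean()),
        "BLOCK": float(block_size),
        "BLOCK.RL": float(rl_block_size),
    }

    # ---- global values (pseudo-3D pooling over slices)
    out.update(tf.descriptive_features(pooled))
    zs = np.unique(np.nonzero(mask)[2])
    glcm_counts = np.zeros((G, G))
    rlm_by_dir: dict[tuple[int, int], np.ndarray] = {}
    rlm_meta = {d: [0, 0] for d in ((0, 1), (1, 0), (1, 1), (1, -1))}
    Xs, ys = [], []
    for z in zs:
        sl_mask = mask[:, :, z]
        xi, yi = np.nonzero(sl_mask)
        bx = (slice(xi.min(), xi.max() + 1), slice(yi.min(), yi.max() + 1))
        img = vol.values[bx[0], bx[1], z]
        m2 = sl_mask[bx]
        q = tf.quantize(img, G=G, mask=m2, value_range=vrange)
        try:
            P = tf.compute_glcm(q)
            # re-accumulate as counts via the slice's pair total
            glcm_counts += P.P * _glcm_pair_total(q)
        except ValueError:
            pass
        for d in rlm_meta:
            R = tf.compute_rlm(q, d)
            prev = rlm_by_dir.get(d)
            r = R.r
            if prev is not None:
                n = max(prev.shape[1], r.shape[1])
                prev = np.pad(prev, ((0, 0), (0, n - prev.shape[1])))
                r = np.pad(r, ((0, 0), (0, n - r.shape[1])))
                r = prev + r
            rlm_by_dir[d] = r
            rlm_meta[d][0] += R.n_pixels
            rlm_meta[d][1] += R.n_runs
        X, yv = tf.gmrf_design(img, mask=m2)
        if len(yv):
            Xs.append(X)
            ys.append(yv)

    total = glcm_counts.sum()
    if total > 0:
        out.update(tf.glcm_features(tf.GlcmMatrix(P=glcm_counts / total,
                                                  offsets=tf.DEFAULT_OFFSETS)))
    else:
        out.update({k: math.nan for k in tf.GLCM_NAMES})
    rl_feats = []
    for d, r in rlm_by_dir.items():
        n_pix, n_runs = rlm_meta[d]
        if n_runs >= 1:
            R = tf.RunLengthMatrix(r=r, direction=d, n_pixels=n_pix,
                                   n_runs=n_runs)
            rl_feats.append(tf.rlm_features(R))
    if rl_feats:
        out.update({k: float(np.mean([f[k] for f in rl_feats]))
                    for k in rl_feats[0]})
    else:
        out.update({k: math.nan for k in tf.RLM_NAMES})
    out.update({k: math.nan for k in tf.GMRF_NAMES})
    if Xs:
        try:
            model = tf.fit_gmrf_design(np.vstack(Xs), np.concatenate(ys))
            for k, t in zip(tf.GMRF_NAMES[:3], model.theta):
                out[k] = float(t)
            out["GMRF.SIGMA"] = model.sigma
        except tf.DegenerateModelError:
            pass

    # ---- local SDs over windows
    def window_sds(grid: LocalWindowGrid, names) -> dict[str, float]:
        per: dict[str, list[float]] = {n: [] for n in names}
        for w in grid.windows:
            img = w.extract(vol.values)
            feats = tf.window_features(img, mask=w.valid, G=G,
                                       value_range=vrange)
            for n in names:
                v = feats.get(n, math.nan)
                if math.isfinite(v):
                    per[n].append(v)
        sds = {}
        for n, vals in per.items():
            sds[n + ".SD"] = (float(np.std(vals, ddof=1))
                              if len(vals) > 1 else 0.0)
        return sds

    main_grid = tile_mask(mask, block_size)
    out.update(window_sds(main_grid,
                          tf.DESCRIPTIVE_NAMES + tf.GLCM_NAMES + tf.GMRF_NAMES))
    rl_grid = (main_grid if rl_block_size == block_size
               else tile_mask(mask, rl_block_size))
    out.update(window_sds(rl_grid, tf.RLM_NAMES))
    return out


def _glcm_pair_total(q: tf.QuantizedWindow) -> float:
    """Number of (symmetrized) valid co-occurring pairs in a window."""
    lev, mask = q.levels, q.mask
    nr, nc = lev.shape
    total = 0
    for di, dj in tf.DEFAULT_OFFSETS:
        sl_a = (slice(max(0, -di), nr - max(0, di)),
                slice(max(0, -dj), nc - max(0, dj)))
        sl_b = (slice(max(0, di), nr + min(0, di)),
                slice(max(0, dj), nc + min(0, dj)))
        total += int((mask[sl_a] & mask[sl_b]).sum())
    return 2.0 * total
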