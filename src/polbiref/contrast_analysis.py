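"""Orientation-contrast ratio R and its ROI-based image analysis.

The statistic compares fiber-to-background contrast between two illumination
orientations 45 deg apart:

    R = (I_B^P1 / I_N^P1) / (I_B^P2 / I_N^P2)

where ``I_B`` and ``I_N`` are mean crossed-detected intensities sampled from
the birefringent fiber and the non-birefringent background.  R = 1 means the
contrast does not depend on orientation (the hallmark of circular and radial
illumination); linear illumination gives R far from 1 wherever birefringence
is expressed.  Intensities are sampled as pooled statistics over a few small
randomly placed rectangular regions (by default three of 25 x 25 um, i.e.
35 x 30 px at the modelled instrument scale) and normalized by the optical
power of each arm before the ratio is formed.

By convention the reported ``R`` takes P1 as the higher-contrast orientation
so ``R >= 1``; the raw signed ratio is reported alongside.  Uncertainty on R
is first-order (delta-method) propagation of the four ROI-mean standard
errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ROISet",
    "ContrastResult",
    "DEFAULT_ROI_SHAPE",
    "select_rois",
    "roi_stats",
    "normalize_power",
    "ratio_R",
    "contrast_depth_curve",
    "results_to_frame",
]

#: 25 x 25 um at the default confocal sampling: (rows, cols) pixels
DEFAULT_ROI_SHAPE: tuple[int, int] = (30, 35)


@dataclass
class ROISet:
    """Non-overlapping rectangular regions: list of (row0, col0, height, width)."""

    rects: list[tuple[int, int, int, int]]
    seed: int | None = None
    roi_shape: tuple[int, int] = DEFAULT_ROI_SHAPE

    def __len__(self) -> int:
        return len(self.rects)

    def pixels(self, image: np.ndarray) -> np.ndarray:
        """All ROI pixel values pooled into one flat array."""
        chunks = []
        for r0, c0, h, w in self.rects:
            if r0 < 0 or c0 < 0 or r0 + h > image.shape[0] or c0 + w > image.shape[1]:
                raise ValueError(f"ROI {(r0, c0, h, w)} outside image {image.shape}")
            chunks.append(image[r0:r0 + h, c0:c0 + w].ravel())
        if not chunks:
            raise ValueError("empty ROI set")
        return np.concatenate(chunks)


@dataclass
class ContrastResult:
    """R at one depth, with its components and propagated uncertainty."""

    depth: float
    R: float  # convention: >= 1 (P1 = higher-contrast orientation)
    R_raw: float  # signed ratio with the caller's P1/P2 labelling
    sd: float
    components: dict = field(default_factory=dict)
    power_normalized: bool = True


def _valid_top_lefts(mask: np.ndarray, h: int, w: int) -> np.ndarray:
    """Boolean map of top-left corners whose full h x w rectangle lies in mask."""
    m = mask.astype(np.int64)
    # integral image with zero padding
    ii = np.zeros((m.shape[0] + 1, m.shape[1] + 1), dtype=np.int64)
    ii[1:, 1:] = m.cumsum(0).cumsum(1)
    rows = m.shape[0] - h + 1
    cols = m.shape[1] - w + 1
    if rows <= 0 or cols <= 0:
        return np.zeros((0, 0), dtype=bool)
    window = (ii[h:h + rows, w:w + cols] - ii[:rows, w:w + cols]
              - ii[h:h + rows, :cols] + ii[:rows, :cols])
    return window == h * w


def select_rois(region_mask: np.ndarray, n: int = 3,
                roi_shape: tuple[int, int] = DEFAULT_ROI_SHAPE,
                seed: int | None = 0, max_tries: int = 10_000) -> ROISet:
    """Randomly place ``n`` non-overlapping rectangles fully inside ``region_mask``.

    Placement is uniform over feasible top-left corners with rejection of
    overlaps; deterministic for a given seed.  Raises if ``n`` disjoint
    rectangles cannot be placed within ``max_tries`` draws.
    """
    h, w = roi_shape
    ok = _valid_top_lefts(np.asarray(region_mask, dtype=bool), h, w)
    candidates = np.argwhere(ok)
    if len(candidates) == 0:
        raise ValueError(f"region cannot contain a single {h}x{w} ROI")
    rng = np.random.default_rng(seed)
    occupied = np.zeros_like(region_mask, dtype=bool)
    rects: list[tuple[int, int, int, int]] = []
    tries = 0
    stalled = 0
    # greedy placement can dead-end (earlier ROIs fragment the free space),
    # so a long run without progress restarts the layout from scratch
    stall_limit = max(100, max_tries // 20)
    while len(rects) < n:
        if tries >= max_tries:
            raise ValueError(
                f"could not place {n} non-overlapping {h}x{w} ROIs "
                f"after {max_tries} tries (placed {len(rects)})"
            )
        tries += 1
        r0, c0 = candidates[rng.integers(len(candidates))]
        if occupied[r0:r0 + h, c0:c0 + w].any():
            stalled += 1
            if stalled >= stall_limit:
                occupied[:] = False
                rects.clear()
                stalled = 0
            continue
        occupied[r0:r0 + h, c0:c0 + w] = True
        rects.append((int(r0), int(c0), h, w))
        stalled = 0
    return ROISet(rects, seed, roi_shape)


def roi_stats(image: np.ndarray, rois: ROISet) -> tuple[float, float]:
    """Pooled mean and standard deviation of intensity over all ROI pixels."""
    px = rois.pixels(np.asarray(image, dtype=float))
    return float(px.mean()), float(px.std(ddof=0))


def normalize_power(mean_intensity: float, power: float) -> float:
    """Divide a mean intensity by the optical power of its acquisition arm."""
    if power <= 0:
        raise ValueError("optical power must be > 0")
    return mean_intensity / power


def ratio_R(i_b_p1: float, i_n_p1: float, i_b_p2: float, i_n_p2: float) -> float:
    """R = (I_B^P1 / I_N^P1) / (I_B^P2 / I_N^P2); all inputs must be > 0."""
    vals = (i_b_p1, i_n_p1, i_b_p2, i_n_p2)
    if any(v <= 0 for v in vals):
        raise ValueError(f"ratio contrast undefined for non-positive intensities {vals}")
    return (i_b_p1 / i_n_p1) / (i_b_p2 / i_n_p2)


def _delta_sd(r: float, means, sds, counts) -> float:
    """First-order propagation: Var(ln R) = sum (se_i / mean_i)^2."""
    var_log = 0.0
    for m, s, n in zip(means, sds, counts):
        var_log += (s / (m * np.sqrt(n))) ** 2
    return float(abs(r) * np.sqrt(var_log))


def contrast_depth_curve(series_p1, series_p2, fiber_mask, bg_mask,
                         n: int = 3, roi_shape: tuple[int, int] = DEFAULT_ROI_SHAPE,
                         seed: int | None = 0, powers=None) -> list[ContrastResult]:
    """Evaluate R at every depth of two matched image series.

    ``series_p1``/``series_p2`` are depth-matched lists of ``ConfocalImage``
    (or objects with ``.intensity`` and ``.metadata['depth']``/``['power']``)
    taken at two illumination orientations 45 deg apart.  ROIs are re-drawn
    per depth (seed offset by the depth index) and, for a shared mask, the
    *same* ROI set is used in both orientation arms so the comparison is
    paired pixel-for-pixel.  ``fiber_mask``/``bg_mask`` may each be a single
    boolean array shared by both arms, or a ``(mask_p1, mask_p2)`` pair when
    the fiber itself was rotated between the arms (the ROI seed is still
    shared, so placement is as paired as the masks allow).
    ``powers`` overrides the per-arm optical power as ``(p1, p2)`` scalars or
    per-depth sequences; defaults to each image's recorded power.
    """
    if len(series_p1) != len(series_p2):
        raise ValueError("orientation series have different lengths")

    def _pair(mask):
        if isinstance(mask, (tuple, list)) and len(mask) == 2:
            return (np.asarray(mask[0], dtype=bool), np.asarray(mask[1], dtype=bool))
        m = np.asarray(mask, dtype=bool)
        return (m, m)

    fiber_1, fiber_2 = _pair(fiber_mask)
    bg_1, bg_2 = _pair(bg_mask)
    results: list[ContrastResult] = []
    for i, (im1, im2) in enumerate(zip(series_p1, series_p2)):
        depth = im1.metadata.get("depth", float(i)) if hasattr(im1, "metadata") else float(i)
        base = 0 if seed is None else seed
        rois_f1 = select_rois(fiber_1, n, roi_shape, base + 2 * i)
        rois_f2 = rois_f1 if fiber_2 is fiber_1 or np.array_equal(fiber_1, fiber_2) \
            else select_rois(fiber_2, n, roi_shape, base + 2 * i)
        rois_b1 = select_rois(bg_1, n, roi_shape, base + 2 * i + 1)
        rois_b2 = rois_b1 if bg_2 is bg_1 or np.array_equal(bg_1, bg_2) \
            else select_rois(bg_2, n, roi_shape, base + 2 * i + 1)

        a1 = np.asarray(getattr(im1, "intensity", im1), dtype=float)
        a2 = np.asarray(getattr(im2, "intensity", im2), dtype=float)
        mb1, sb1 = roi_stats(a1, rois_f1)
        mn1, sn1 = roi_stats(a1, rois_b1)
        mb2, sb2 = roi_stats(a2, rois_f2)
        mn2, sn2 = roi_stats(a2, rois_b2)

        if powers is not None:
            p1, p2 = powers
            p1 = p1[i] if np.ndim(p1) else p1
            p2 = p2[i] if np.ndim(p2) else p2
        else:
            p1 = im1.metadata.get("power", 1.0) if hasattr(im1, "metadata") else 1.0
            p2 = im2.metadata.get("power", 1.0) if hasattr(im2, "metadata") else 1.0
        nb1, nn1 = normalize_power(mb1, p1), normalize_power(mn1, p1)
        nb2, nn2 = normalize_power(mb2, p2), normalize_power(mn2, p2)

        r_raw = ratio_R(nb1, nn1, nb2, nn2)
        r = max(r_raw, 1.0 / r_raw)
        n_f = sum(h * w for _, _, h, w in rois_f1.rects)
        n_b = sum(h * w for _, _, h, w in rois_b1.rects)
        sd = _delta_sd(r, (nb1, nn1, nb2, nn2),
                       (sb1 / p1, sn1 / p1, sb2 / p2, sn2 / p2),
                       (n_f, n_b, n_f, n_b))
        results.append(ContrastResult(
            depth=float(depth), R=float(r), R_raw=float(r_raw), sd=sd,
            components={
                "I_B_P1": nb1, "I_N_P1": nn1, "I_B_P2": nb2, "I_N_P2": nn2,
                "sd_B_P1": sb1 / p1, "sd_N_P1": sn1 / p1,
                "sd_B_P2": sb2 / p2, "sd_N_P2": sn2 / p2,
            },
            power_normalized=True,
        ))
    return results


def results_to_frame(results: list[ContrastResult]) -> pd.DataFrame:
    """Tabulate a depth curve as a tidy DataFrame (plot/CSV-ready)."""
    rows = []
    for res in results:
        row = {"depth": res.depth, "R": res.R, "R_raw": res.R_raw, "sd": res.sd}
        row.update({k: v for k, v in res.components.items() if k.startswith("I_")})
        rows.append(row)
    return pd.DataFrame(rows)
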