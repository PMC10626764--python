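"""Straightforward per-pixel reference implementations used as test oracles.

Deliberately written as slow double loops, independent of the vectorized
implementations they validate.
"""

import numpy as np


def gradients_loops(image):
    """Central differences with replicate borders, one pixel at a time."""
    img = np.asarray(image, dtype=np.float64)
    H, W = img.shape
    gx = np.zeros((H, W))
    gy = np.zeros((H, W))
    for r in range(H):
        for c in range(W):
            cl, cr = max(c - 1, 0), min(c + 1, W - 1)
            ru, rd = max(r - 1, 0), min(r + 1, H - 1)
            gx[r, c] = img[r, cr] - img[r, cl]
            gy[r, c] = img[rd, c] - img[ru, c]
    mag = np.sqrt(gx ** 2 + gy ** 2)
    ori = np.zeros((H, W))
    for r in range(H):
        for c in range(W):
            if mag[r, c] > 0:
                a = np.degrees(np.arctan2(gy[r, c], gx[r, c])) % 180.0
                ori[r, c] = a
    return gx, gy, mag, ori


def cell_histograms_loops(mag, ori, cell_w, cell_h, n_bins, angle_range=180.0):
    """Nearest-bin magnitude voting, cell by cell, pixel by pixel."""
    H, W = mag.shape
    ncx, ncy = W // cell_w, H // cell_h
    hist = np.zeros((ncy, ncx, n_bins))
    bin_width = angle_range / n_bins
    for cy in range(ncy):
        for cx in range(ncx):
            for r in range(cy * cell_h, (cy + 1) * cell_h):
                for c in range(cx * cell_w, (cx + 1) * cell_w):
                    b = int(ori[r, c] // bin_width)
                    if b == n_bins:  # orientation exactly at angle_range
                        b = n_bins - 1
                    hist[cy, cx, b] += mag[r, c]
    return hist


def block_normalize_loops(hist, block_cells, block_stride, norm_eps):
    """Sliding-block L2 normalization and row-major concatenation."""
    ncy, ncx, k = hist.shape
    segments = []
    for by in range(0, ncy - block_cells + 1, block_stride):
        for bx in range(0, ncx - block_cells + 1, block_stride):
            v = []
            for iy in range(block_cells):
                for ix in range(block_cells):
                    v.extend(hist[by + iy, bx + ix, :])
            v = np.asarray(v)
            segments.append(v / np.sqrt(np.sum(v * v) + norm_eps ** 2))
    return np.concatenate(segments)


def hog_descriptor_loops(gray, config):
    """Full descriptor from an already-resized grayscale grid."""
    _, _, mag, ori = gradients_loops(gray)
    hist = cell_histograms_loops(mag, ori, config.cell_width,
                                 config.cell_height, config.n_bins,
                                 config.angle_range)
    return block_normalize_loops(hist, config.block_cells,
                                 config.block_stride, config.norm_eps)


def iou_sets_loops(pred, gt, n_classes):
    """Set-based per-class IoU: |P∩G| / |P∪G| over pixel index sets."""
    out = {}
    pred = np.asarray(pred).ravel()
    gt = np.asarray(gt).ravel()
    for c in range(n_classes):
        p = set(np.flatnonzero(pred == c))
        g = set(np.flatnonzero(gt == c))
        union = p | g
        if union:
            out[c] = len(p & g) / len(union)
    return out
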