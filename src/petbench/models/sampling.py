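"""Volume-to-sample plumbing: 2.5D slice stacking, 3D chunking, residual
wrapping and intensity normalization."""

from __future__ import annotations

import numpy as np


def stack_slices(values: np.ndarray, k: int) -> np.ndarray:
    """Stack 2k+1 adjacent axial slices as channels, one sample per slice.

    Boundary slices use replicate padding; channel k (the center) is the
    slice itself, so a "select central channel" model makes the pipeline an
    identity.  Returns an array of shape (n_slices, 2k+1, H, W).
    """
    values = np.asarray(values)
    if k < 0:
        raise ValueError("k must be non-negative")
    n = values.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the slice count")
    padded = np.pad(values, ((k, k), (0, 0), (0, 0)), mode="edge")
    return np.stack([padded[i:i + 2 * k + 1] for i in range(n)], axis=0)


def chunk_starts(n_slices: int, chunk: int, overlap: int) -> list[int]:
    """Start indices of overlapping chunks covering [0, n_slices)."""
    if not 0 <= overlap < chunk:
        raise ValueError("overlap must satisfy 0 <= overlap < chunk")
    if chunk >= n_slices:
        return [0]
    step = chunk - overlap
    starts = list(range(0, n_slices - chunk + 1, step))
    if starts[-1] != n_slices - chunk:
        starts.append(n_slices - chunk)  # tail-aligned final chunk
    return starts


def chunk_volume(values: np.ndarray, chunk: int = 32, overlap: int = 0):
    """Split along the slice axis into overlapping chunks.

    Volumes shorter than ``chunk`` are replicate-padded up to it.  Returns
    ``(chunks, reassembly)`` where ``reassembly`` maps a list of same-shape
    (possibly modified) chunks back to a volume, averaging overlaps.
    """
    values = np.asarray(values)
    n = values.shape[0]
    pad = max(0, chunk - n)
    padded = np.pad(values, ((0, pad), (0, 0), (0, 0)), mode="edge") \
        if pad else values
    starts = chunk_starts(padded.shape[0], chunk, overlap)
    chunks = [padded[s:s + chunk] for s in starts]

    def reassemble(out_chunks) -> np.ndarray:
        acc = np.zeros(padded.shape, dtype=np.float64)
        cnt = np.zeros(padded.shape[0], dtype=np.float64)
        for s, c in zip(starts, out_chunks):
            acc[s:s + chunk] += c
            cnt[s:s + chunk] += 1.0
        acc /= cnt[:, None, None]
        return acc[:n]

    return chunks, reassemble


def residual_wrap(network):
    """Turn a residual-predicting callable into a denoiser ``x + net(x)``.

    The wrapped callable must preserve shape; a shape-changing network is
    rejected at call time.
    """

    def denoiser(x):
        r = network(x)
        r_shape = r.shape if not hasattr(r, "data") else r.data.shape
        x_shape = x.shape if not hasattr(x, "data") else x.data.shape
        if tuple(r_shape) != tuple(x_shape):
            raise ValueError(
                f"residual network changed shape {x_shape} -> {r_shape}")
        return x + r

    return denoiser


def normalization_scale(ft_values, percentile: float = 99.9) -> float:
    """Fixed intensity scale for training: high percentile of FT values."""
    scale = float(np.percentile(np.asarray(ft_values).ravel(), percentile))
    return scale if scale > 0 else 1.0
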