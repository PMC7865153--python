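"""Diagnostic views of (descrambled) weight matrices.

Once a layer's signal basis has been descrambled, standard linear-algebra
views become informative: the SVD splits the weight matrix into the
conjugate input signals it expects to receive, their amplification
coefficients, and the output signals it emits; conjugating by unitary
DFTs shows the layer's action in frequency space (a filter appears as a
banded frequency-frequency map); the centered magnitude of the 2-D FFT
reveals oscillatory structure in the matrix itself; and row/column Gram
matrices quantify how close the matrix is to an orthogonal dictionary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SvdBreakdown",
    "FrequencyMap",
    "svd_breakdown",
    "frequency_conjugate",
    "sym_abs_fft2",
    "orthogonality_score",
    "chebyshev_similarity",
]


@dataclass(frozen=True)
class SvdBreakdown:
    """W = U diag(s) V^T: output signal library, amplifications, conjugate inputs."""

    u: np.ndarray
    s: np.ndarray
    v: np.ndarray

    def reconstruct(self) -> np.ndarray:
        return self.u @ (self.s[:, None] * self.v.T)


@dataclass(frozen=True)
class FrequencyMap:
    """Zero-centered frequency-domain conjugation F_+ W F_- of a weight matrix."""

    matrix: np.ndarray      # complex
    magnitude: np.ndarray
    row_freqs: np.ndarray   # output-side frequency axis (shifted)
    col_freqs: np.ndarray   # input-side frequency axis (shifted)


def svd_breakdown(W: np.ndarray) -> SvdBreakdown:
    """SVD with a deterministic sign convention: the largest-magnitude entry
    of each left singular vector is made positive (V adjusted to match)."""
    W = np.asarray(W, dtype=float)
    u, s, vt = np.linalg.svd(W, full_matrices=False)
    signs = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(u.shape[1])])
    signs[signs == 0] = 1.0
    return SvdBreakdown(u=u * signs, s=s, v=(vt.T) * signs)


def frequency_conjugate(W: np.ndarray) -> FrequencyMap:
    """Unitary DFT conjugation ``F_+ W F_-`` with zero frequency centered.

    Rectangular matrices are supported: the output side uses the DFT of the
    row dimension and the input side the inverse DFT of the column dimension,
    so the Frobenius norm is preserved either way.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2:
        raise ValueError("expected a 2-D weight matrix")
    M = np.fft.fft(W, axis=0, norm="ortho")
    M = np.fft.ifft(M, axis=1, norm="ortho")
    M = np.fft.fftshift(M)
    row_freqs = np.fft.fftshift(np.fft.fftfreq(W.shape[0])) * W.shape[0]
    col_freqs = np.fft.fftshift(np.fft.fftfreq(W.shape[1])) * W.shape[1]
    return FrequencyMap(matrix=M, magnitude=np.abs(M),
                        row_freqs=row_freqs, col_freqs=col_freqs)


def sym_abs_fft2(W: np.ndarray) -> np.ndarray:
    """Zero-frequency-centered magnitude of the 2-D unitary DFT of W.

    For real W the map is point-symmetric about the zero-frequency bin
    (conjugate symmetry of the real-input DFT)."""
    W = np.asarray(W, dtype=float)
    return np.abs(np.fft.fftshift(np.fft.fft2(W, norm="ortho")))


def orthogonality_score(W: np.ndarray, axis: str = "rows"):
    """How orthogonal the rows (or columns) of W are.

    Returns ``(score, gram)`` where ``gram`` is the Gram matrix of the
    unit-normalized vectors and ``score = 1 - mean |off-diagonal|``; 1 for
    an exactly orthogonal family, 0 for identical rows.  Zero-norm vectors
    are excluded with a warning.
    """
    W = np.asarray(W, dtype=float)
    vectors = W if axis == "rows" else W.T if axis in ("cols", "columns") else None
    if vectors is None:
        raise ValueError("axis must be 'rows' or 'cols'")
    norms = np.linalg.norm(vectors, axis=1)
    keep = norms > 0
    if not np.all(keep):
        warnings.warn(f"excluding {np.sum(~keep)} zero-norm vectors from the Gram matrix")
    vectors = vectors[keep] / norms[keep][:, None]
    gram = vectors @ vectors.T
    n = gram.shape[0]
    if n < 2:
        return 1.0, gram
    off = np.abs(gram[~np.eye(n, dtype=bool)])
    return float(1.0 - off.mean()), gram


def chebyshev_similarity(vectors: np.ndarray, n_polys: int = None) -> np.ndarray:
    """Descriptive diagnostic: cosine similarity of each column of ``vectors``
    to its best-matching Chebyshev polynomial sampled on the output grid.

    The solver networks' output signal libraries resemble (distorted)
    Chebyshev polynomials; this measures, without asserting, how close.
    """
    V = np.asarray(vectors, dtype=float)
    d, n_cols = V.shape
    if n_polys is None:
        n_polys = n_cols
    x = np.linspace(-1.0, 1.0, d)
    basis = np.polynomial.chebyshev.chebvander(x, n_polys - 1)  # d x n_polys
    basis = basis / np.linalg.norm(basis, axis=0)
    cols = V / np.linalg.norm(V, axis=0)
    return np.max(np.abs(basis.T @ cols), axis=0)
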