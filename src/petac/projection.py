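"""2-D parallel-beam projector with a matched adjoint.

The simulator is 2-D-slice-stacked: each axial slice is forward projected
independently with a parallel-beam geometry. The projector is a sparse
matrix built pixel-driven — every pixel center is projected onto the
detector for each view and its value split linearly between the two nearest
detector bins — so the adjoint used in iterative reconstruction is the
exact matrix transpose of the forward model. Detector pitch equals pixel
pitch and views cover [0, pi).
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

_CACHE: dict[tuple, "ParallelProjector"] = {}


class ParallelProjector:
    """Sparse-matrix parallel-beam projector for ``n x n`` slices.

    Parameters
    ----------
    n : image side (pixels); the detector has ``n`` bins at pixel pitch.
    n_angles : number of views over [0, pi).
    spacing_mm : in-plane pixel size; line integrals are returned in
        value-times-mm so attenuation maps in 1/cm need a factor 0.1.
    """

    def __init__(self, n: int, n_angles: int, spacing_mm: float):
        self.n = int(n)
        self.n_angles = int(n_angles)
        self.n_det = int(n)
        self.spacing_mm = float(spacing_mm)
        self.angles = np.linspace(0.0, np.pi, self.n_angles, endpoint=False)
        self._A = self._build()
        self._AT = self._A.T.tocsr()

    def _build(self) -> sparse.csr_matrix:
        n, ndet = self.n, self.n_det
        c = np.arange(n) - (n - 1) / 2.0
        X = np.repeat(c, n)      # pixel x, C-order raveled (x major)
        Y = np.tile(c, n)        # pixel y
        rows, cols, vals = [], [], []
        pix = np.arange(n * n)
        for ai, th in enumerate(self.angles):
            u = X * np.cos(th) + Y * np.sin(th) + (ndet - 1) / 2.0
            i0 = np.floor(u).astype(np.int64)
            frac = u - i0
            for off, w in ((0, 1.0 - frac), (1, frac)):
                ii = i0 + off
                ok = (ii >= 0) & (ii < ndet) & (w > 0)
                rows.append(ai * ndet + ii[ok])
                cols.append(pix[ok])
                vals.append(w[ok])
        A = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_angles * self.n_det, n * n),
        )
        return A.tocsr()

    # ------------------------------------------------------------------
    def forward(self, image: np.ndarray) -> np.ndarray:
        """Line integrals (value x mm) of an ``(n, n)`` slice; shape (n_angles, n_det)."""
        out = self._A @ image.reshape(-1)
        return (out * self.spacing_mm).reshape(self.n_angles, self.n_det)

    def back(self, sino: np.ndarray) -> np.ndarray:
        """Exact adjoint of :meth:`forward` (unfiltered backprojection)."""
        out = self._AT @ sino.reshape(-1)
        return (out * self.spacing_mm).reshape(self.n, self.n)

    def subset_rows(self, angle_idx: np.ndarray) -> np.ndarray:
        base = np.asarray(angle_idx, dtype=np.int64)[:, None] * self.n_det
        return (base + np.arange(self.n_det)[None, :]).reshape(-1)

    def subset_matrices(self, subsets: int):
        """Interleaved angle subsets and their (A_s, A_s^T) sparse pairs."""
        if self.n_angles % subsets:
            raise ValueError(f"{subsets} subsets do not divide {self.n_angles} angles")
        out = []
        for s in range(subsets):
            idx = np.arange(s, self.n_angles, subsets)
            rows = self.subset_rows(idx)
            A_s = self._A[rows]
            out.append((idx, A_s, A_s.T.tocsr()))
        return out

    # ------------------------------------------------------------------
    def fbp(self, sino: np.ndarray) -> np.ndarray:
        """Filtered backprojection of one sinogram (ramp filter, Hann rolloff).

        Used for reconstructing artifact terms in the CT surrogate; absolute
        scaling follows the standard parallel-beam normalization.
        """
        n_angles, ndet = sino.shape
        size = int(2 ** np.ceil(np.log2(2 * ndet)))
        freqs = np.fft.rfftfreq(size)
        ramp = 2.0 * np.abs(freqs)
        window = 0.5 * (1 + np.cos(np.pi * freqs / freqs.max()))
        filt = ramp * window
        padded = np.zeros((n_angles, size))
        padded[:, :ndet] = sino
        filtered = np.fft.irfft(np.fft.rfft(padded, axis=1) * filt[None, :], n=size, axis=1)
        filtered = filtered[:, :ndet]
        img = self.back(filtered)
        return img * np.pi / (2.0 * n_angles) / self.spacing_mm ** 2


def default_n_angles(n: int) -> int:
    """View count ~0.94 n, rounded to a multiple of 15 (divisible by 3 and 5)."""
    return 15 * max(2, int(round(n * 0.9375 / 15)))


def get_projector(n: int, n_angles: int | None = None,
                  spacing_mm: float = 4.0) -> ParallelProjector:
    """Cached projector lookup; building the sparse matrix is the costly part."""
    if n_angles is None:
        n_angles = default_n_angles(n)
    key = (int(n), int(n_angles), round(float(spacing_mm), 6))
    if key not in _CACHE:
        _CACHE[key] = ParallelProjector(*key)
    return _CACHE[key]
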