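"""Functional connectivity dynamics (FCD) and the variance-based
multi-stability measure.

FC: in each sliding window (2 s wide, 90% overlap by default) the
pairwise phase agreement FC_kl = <| (e^{i phi_k} + e^{i phi_l}) / 2 |>_t
is computed for all node pairs — 1 for locked pairs, 0 for antiphase,
|cos(lag/2)| for a constant lag.

FCD: each FC matrix is vectorized (strict lower triangle, excluding the
first sub-diagonal) and all window pairs are compared by Pearson
correlation.  Patches of high correlation away from the diagonal reveal
transiently recurring synchronization patterns (multi-stability); the
variance of the FCD entries outside a band around the diagonal (where
overlapping windows are trivially correlated) summarizes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synchrony import PhaseEnsemble

__all__ = ["FCSeries", "FCDMatrix", "fc_windows", "fcd_matrix",
           "multistability_variance", "InsufficientDataError"]

# at 90% overlap, windows i and j share samples for |i-j| <= 9
DEFAULT_EXCLUDE_BAND = 9
_DEGENERATE_STD = 1e-12


class InsufficientDataError(ValueError):
    pass


@dataclass
class FCSeries:
    windows: list[tuple[float, float]]      # (start_ms, end_ms)
    fc: np.ndarray                          # (M, N, N), entries in [0, 1]

    @property
    def M(self) -> int:
        return self.fc.shape[0]


@dataclass
class FCDMatrix:
    fcd: np.ndarray                         # (M, M) Pearson correlations
    degenerate: np.ndarray                  # (M,) True where FC vector is constant
    exclude_subdiag: int

    @property
    def M(self) -> int:
        return self.fcd.shape[0]


def fc_windows(ens: PhaseEnsemble | np.ndarray, fs: float | None = None,
               width_ms: float = 2000.0, overlap: float = 0.9) -> FCSeries:
    """Windowed pairwise phase-agreement matrices.

    Window stride is width * (1 - overlap); windows must fit at least
    twice in the series.  The diagonal is exactly 1.
    """
    if isinstance(ens, PhaseEnsemble):
        phases, fs = ens.phases, ens.fs
    else:
        phases = np.atleast_2d(np.asarray(ens, dtype=float))
        if fs is None:
            raise ValueError("fs required when passing a bare phase array")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    N, T = phases.shape
    w = int(round(width_ms * fs / 1000.0))
    stride = max(1, int(round(w * (1.0 - overlap))))
    if T < w:
        raise InsufficientDataError(f"series of {T} samples shorter than one "
                                    f"{w}-sample window")
    M = (T - w) // stride + 1
    if M < 2:
        raise InsufficientDataError("need at least 2 windows")
    cos_p, sin_p = np.cos(phases), np.sin(phases)
    windows = [(m * stride * 1000.0 / fs, (m * stride + w) * 1000.0 / fs)
               for m in range(M)]
    # |(e^{i a}+e^{i b})/2| = sqrt((1 + cos(a-b)) / 2), averaged over the
    # window.  Overlapping windows share samples, so accumulate prefix
    # sums of the per-sample agreement at stride boundaries and take
    # differences — each sample is touched once instead of w/stride times.
    if w % stride == 0:
        n_pos = (M - 1) + w // stride + 1
        csum = np.empty((n_pos, N, N))
        csum[0] = 0.0
        running = np.zeros((N, N))
        for pos in range(n_pos - 1):
            a = pos * stride
            c, s = cos_p[:, a:a + stride], sin_p[:, a:a + stride]
            cosd = c[:, None, :] * c[None, :, :] + s[:, None, :] * s[None, :, :]
            running += np.sqrt(np.clip((1.0 + cosd) / 2.0, 0.0, 1.0)).sum(axis=2)
            csum[pos + 1] = running
        k = w // stride
        fc = (csum[k:k + M] - csum[:M]) / w
    else:
        fc = np.empty((M, N, N))
        for m in range(M):
            a = m * stride
            c, s = cos_p[:, a:a + w], sin_p[:, a:a + w]
            cosd = c[:, None, :] * c[None, :, :] + s[:, None, :] * s[None, :, :]
            fc[m] = np.sqrt(np.clip((1.0 + cosd) / 2.0, 0.0, 1.0)).mean(axis=2)
    for m in range(M):
        np.fill_diagonal(fc[m], 1.0)
    return FCSeries(windows=windows, fc=fc)


def _vectorize(fc: np.ndarray, exclude_subdiag: int) -> np.ndarray:
    """Strict lower triangle of each FC, dropping ``exclude_subdiag``
    sub-diagonals next to the main diagonal."""
    N = fc.shape[-1]
    rows, cols = np.tril_indices(N, k=-(exclude_subdiag + 1))
    return fc[..., rows, cols]


def fcd_matrix(fcs: FCSeries, exclude_subdiag: int = 1) -> FCDMatrix:
    """Pearson-correlation comparison of all FC pairs.

    Fully synchronized epochs give constant FC vectors with zero variance;
    the correlation of two such vectors is defined as 1 when they are
    identical and 0 otherwise, and those windows are flagged degenerate.
    """
    if fcs.M < 3:
        raise InsufficientDataError("need at least 3 windows for an FCD")
    X = _vectorize(fcs.fc, exclude_subdiag)          # (M, n_pairs)
    mu = X.mean(axis=1, keepdims=True)
    Xc = X - mu
    sd = Xc.std(axis=1)
    degen = sd < _DEGENERATE_STD
    sd_safe = np.where(degen, 1.0, sd)
    C = (Xc @ Xc.T) / X.shape[1] / np.outer(sd_safe, sd_safe)
    if np.any(degen):
        di = np.flatnonzero(degen)
        for i in di:
            same = np.all(np.abs(X - X[i]) < 1e-9, axis=1)
            C[i, :] = np.where(same, 1.0, 0.0)
            C[:, i] = C[i, :]
    C = np.clip(C, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return FCDMatrix(fcd=C, degenerate=degen, exclude_subdiag=exclude_subdiag)


def multistability_variance(fcd: FCDMatrix | np.ndarray,
                            exclude_band: int = DEFAULT_EXCLUDE_BAND) -> float:
    """Variance of FCD entries with |i - j| > exclude_band.

    The band removes the trivial correlation of time-overlapping windows
    (9 off-diagonals at 2 s / 90% overlap).
    """
    F = fcd.fcd if isinstance(fcd, FCDMatrix) else np.asarray(fcd)
    M = F.shape[0]
    if M <= exclude_band + 1:
        raise InsufficientDataError("FCD too small for the exclusion band")
    i, j = np.indices(F.shape)
    vals = F[np.abs(i - j) > exclude_band]
    return float(np.var(vals))
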