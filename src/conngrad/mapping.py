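"""Connectopic mapping: voxelwise connectivity gradients within a region.

The pipeline characterizes the spatial organization of functional
connectivity inside a region of interest (ROI) by

1. rearranging the 4D time series into a time-by-voxel matrix ``A`` (ROI)
   and ``B`` (voxels outside the ROI),
2. losslessly reducing ``B`` by singular value decomposition (``B~``),
3. correlating every ROI voxel with the SVD components to obtain a
   connectivity *fingerprint* per voxel (matrix ``C``),
4. quantifying fingerprint similarity between voxel pairs with the
   eta-squared coefficient (matrix ``S``), and
5. applying Laplacian-eigenmap manifold learning to ``S``, yielding
   spatially continuous *connectivity modes* (gradients) over the ROI.

Modes are indexed by ascending nonzero eigenvalue (1 = first-order,
2 = second-order), min-max rescaled to [0, 1], sign-aligned against a
group reference, and quality-controlled by spatial correlation with that
reference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelTimeSeriesDataset",
    "ReducedData",
    "ConnectivityMode",
    "CombinedGradient",
    "extract_timeseries",
    "svd_reduce",
    "compute_fingerprints",
    "eta_squared_matrix",
    "laplacian_eigenmaps",
    "align_sign",
    "group_reference",
    "qc_spatial_corr",
    "combine_subregions",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class VoxelTimeSeriesDataset:
    """ROI and out-of-ROI time series with voxel coordinates.

    Attributes
    ----------
    A : ndarray, shape (T, V_roi)
        Time-by-voxel matrix of ROI signals (arbitrary BOLD units).
    B : ndarray, shape (T, V_out)
        Time-by-voxel matrix of signals outside the ROI.
    roi_coords : ndarray, shape (V_roi, 3)
        Millimeter coordinates of ROI voxel centers (from the affine).
    tr_seconds : float
        Repetition time of the acquisition.
    roi_voxels : ndarray, shape (V_roi, 3)
        Integer voxel indices of the retained ROI columns.
    """

    A: np.ndarray
    B: np.ndarray
    roi_coords: np.ndarray
    tr_seconds: float = 1.0
    roi_voxels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.A.shape[0] != self.B.shape[0]:
            raise ValueError(
                "A and B must share the same number of time points "
                f"(got {self.A.shape[0]} and {self.B.shape[0]})"
            )
        if not np.all(np.isfinite(self.roi_coords)):
            raise ValueError("ROI coordinates must be finite")


@dataclass
class ReducedData:
    """SVD-reduced out-of-ROI data.

    ``timeseries`` holds the component time series U*s (time by component);
    ``right_basis`` the matching right-singular vectors, so that
    ``timeseries @ right_basis`` reconstructs the de-meaned input.
    """

    timeseries: np.ndarray
    right_basis: np.ndarray
    singular_values: np.ndarray

    @property
    def n_components(self) -> int:
        return self.timeseries.shape[1]


@dataclass
class ConnectivityMode:
    """One connectivity gradient over the ROI voxels.

    ``values`` are min-max rescaled to [0, 1]; ``raw`` keeps the
    eigenvector (D-orthonormal scaling) so that sign flips commute with
    rescaling. ``mode_index`` counts nonzero-eigenvalue eigenvectors in
    ascending order: 1 = first-order mode, 2 = second-order mode.
    """

    values: np.ndarray
    raw: np.ndarray
    mode_index: int
    eigenvalue: float
    sign_aligned: bool = False
    qc_spatial_r: float | None = None

    def flipped(self) -> "ConnectivityMode":
        """Return the mode with inverted polarity (raw negated, values 1-x)."""
        return replace(self, raw=-self.raw, values=_rescale01(-self.raw))


@dataclass
class CombinedGradient:
    """Gradient values concatenated across subregions, with provenance."""

    values: np.ndarray
    coords: np.ndarray
    subregion: np.ndarray  # per-voxel label of the source subregion


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _rescale01(x: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return np.zeros_like(x, dtype=float)
    return (x - lo) / (hi - lo)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("zero-variance input to Pearson correlation")
    return float(np.dot(xc, yc) / (nx * ny))


def _img_data(img) -> tuple[np.ndarray, np.ndarray | None]:
    """Accept a nibabel spatial image or a plain array; return (data, affine)."""
    if hasattr(img, "get_fdata") and hasattr(img, "affine"):
        return np.asarray(img.get_fdata()), np.asarray(img.affine)
    return np.asarray(img), None


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def extract_timeseries(
    image4d,
    roi_mask,
    brain_mask,
    affine: np.ndarray | None = None,
    tr_seconds: float = 1.0,
) -> VoxelTimeSeriesDataset:
    """Rearrange a 4D image into ROI and out-of-ROI time-by-voxel matrices.

    Parameters
    ----------
    image4d : nibabel image or ndarray, shape (X, Y, Z, T)
        The 4D time-series image.
    roi_mask, brain_mask : nibabel image or ndarray, shape (X, Y, Z)
        Binary masks. ``brain_mask`` marks the voxels used as the
        out-of-ROI signal source; any overlap with the ROI is removed
        from it (full-brain masks are accepted).
    affine : ndarray, shape (4, 4), optional
        Voxel-to-millimeter affine. Taken from ``image4d`` when it is a
        nibabel image; defaults to identity otherwise.
    tr_seconds : float
        Repetition time recorded on the returned dataset.

    Notes
    -----
    Columns follow a fixed raster scan of voxel indices (C order).
    Constant (zero-variance) columns are dropped with a logged warning;
    coordinates are computed by applying the affine to voxel indices
    (voxel centers).
    """
    data, img_affine = _img_data(image4d)
    roi, _ = _img_data(roi_mask)
    brain, _ = _img_data(brain_mask)
    if affine is None:
        affine = img_affine if img_affine is not None else np.eye(4)
    affine = np.asarray(affine, dtype=float)

    if data.ndim != 4:
        raise ValueError(f"expected a 4D image, got shape {data.shape}")
    if roi.shape != data.shape[:3] or brain.shape != data.shape[:3]:
        raise ValueError(
            "mask voxel outside image bounds: mask shape "
            f"{roi.shape if roi.shape != data.shape[:3] else brain.shape} "
            f"does not match image grid {data.shape[:3]}"
        )
    roi = roi.astype(bool)
    brain = brain.astype(bool)
    overlap = roi & brain
    if overlap.any():
        logger.info(
            "removing %d ROI voxels from the out-of-ROI mask", int(overlap.sum())
        )
        brain = brain & ~roi

    roi_idx = np.argwhere(roi)  # raster (C) order
    out_idx = np.argwhere(brain)
    if len(roi_idx) < 2:
        raise ValueError("ROI mask must contain at least 2 voxels")
    if len(out_idx) < 2:
        raise ValueError("out-of-ROI mask must contain at least 2 voxels")

    A = data[roi].astype(float).T  # (T, V_roi); boolean indexing is raster order
    B = data[brain].astype(float).T

    def _drop_constant(M: np.ndarray, which: str, keep_aux=None):
        sd = M.std(axis=0)
        const = sd == 0.0
        if const.all():
            raise ValueError(f"all {which} columns are constant")
        if const.any():
            msg = f"dropping {int(const.sum())} constant {which} column(s)"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=3)
            M = M[:, ~const]
            if keep_aux is not None:
                keep_aux = keep_aux[~const]
        return M, keep_aux

    A, roi_idx = _drop_constant(A, "ROI", roi_idx)
    B, _ = _drop_constant(B, "out-of-ROI")

    hom = np.c_[roi_idx, np.ones(len(roi_idx))]
    coords = (hom @ affine.T)[:, :3]

    return VoxelTimeSeriesDataset(
        A=A, B=B, roi_coords=coords, tr_seconds=tr_seconds, roi_voxels=roi_idx
    )


def svd_reduce(B: np.ndarray, rel_tol: float | None = None) -> ReducedData:
    """Losslessly reduce the out-of-ROI data by SVD.

    The input is de-meaned column-wise and decomposed as ``B = U s Vt``;
    all components with nonnegligible singular value are retained, so the
    reduction is lossless: ``timeseries @ right_basis`` reproduces the
    de-meaned input to machine precision. Component time series are
    mutually orthogonal.
    """
    B = np.asarray(B, dtype=float)
    if B.ndim != 2 or B.shape[0] < 2:
        raise ValueError("B must be a 2D matrix with at least 2 time points")
    Bc = B - B.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Bc, full_matrices=False)
    if rel_tol is None:
        rel_tol = max(Bc.shape) * np.finfo(float).eps
    if s.size == 0 or s[0] == 0.0:
        raise ValueError("B has rank 0 after de-meaning")
    rank = int(np.sum(s > rel_tol * s[0]))
    if rank == 0:
        raise ValueError("B has rank 0 after de-meaning")
    return ReducedData(
        timeseries=U[:, :rank] * s[:rank],
        right_basis=Vt[:rank],
        singular_values=s[:rank],
    )


def compute_fingerprints(A: np.ndarray, reduced: ReducedData | np.ndarray) -> np.ndarray:
    """Correlate each ROI voxel with every SVD component: fingerprint matrix C.

    ``C[v, k]`` is the Pearson correlation between ROI voxel ``v``'s time
    series and component ``k`` of the SVD-transformed out-of-ROI data.
    """
    Bt = reduced.timeseries if isinstance(reduced, ReducedData) else np.asarray(reduced)
    A = np.asarray(A, dtype=float)
    Bt = np.asarray(Bt, dtype=float)
    if A.shape[0] != Bt.shape[0]:
        raise ValueError("A and B~ must share the same number of time points")
    T = A.shape[0]

    def _zscore(M: np.ndarray, which: str) -> np.ndarray:
        sd = M.std(axis=0)
        if np.any(sd == 0.0):
            raise ValueError(
                f"constant column encountered in {which}; drop it upstream"
            )
        return (M - M.mean(axis=0)) / sd

    C = _zscore(A, "A").T @ _zscore(Bt, "B~") / T
    return np.clip(C, -1.0, 1.0)


def eta_squared_matrix(C: np.ndarray) -> np.ndarray:
    """Pairwise eta-squared similarity between fingerprint rows.

    For fingerprint rows ``a`` and ``b`` with pairwise means
    ``m_i = (a_i + b_i)/2`` and grand mean ``M = mean_i(m_i)``::

        eta2 = 1 - sum_i[(a_i - m_i)^2 + (b_i - m_i)^2]
                 / sum_i[(a_i - M)^2 + (b_i - M)^2]

    The result is symmetric with unit diagonal and entries in [0, 1]
    (the pairwise mean minimizes the numerator, so within <= total).
    A pair of identical constant rows has a zero denominator; eta-squared
    is defined as 1 there, with a warning.
    """
    C = np.asarray(C, dtype=float)
    if not np.all(np.isfinite(C)):
        raise ValueError("fingerprints must be finite")
    n = C.shape[1]
    G = C @ C.T
    q = np.diag(G).copy()
    s = C.sum(axis=1)
    # within_ab = ||a - b||^2 / 2 ; total_ab = q_a + q_b - (s_a + s_b)^2 / (2n)
    within = 0.5 * (q[:, None] + q[None, :] - 2.0 * G)
    total = q[:, None] + q[None, :] - (s[:, None] + s[None, :]) ** 2 / (2.0 * n)
    zero = total <= 0.0
    if np.any(zero & (within > 0)):  # pragma: no cover - defensive
        raise ValueError("inconsistent eta-squared sums")
    if np.any(zero):
        n_offdiag = int(np.sum(zero) - np.sum(np.diag(zero)))
        if n_offdiag:
            warnings.warn(
                "identical constant fingerprints: eta-squared defined as 1",
                stacklevel=2,
            )
    S = np.ones_like(within)
    np.divide(within, total, out=within, where=~zero)
    S[~zero] = 1.0 - within[~zero]
    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def laplacian_eigenmaps(
    S: np.ndarray,
    n_modes: int = 2,
    n_neighbors: int | None = None,
    zero_tol: float = 1e-10,
) -> list[ConnectivityMode]:
    """Extract connectivity modes from a similarity matrix.

    Builds graph weights ``W`` from ``S`` by subtracting the global
    minimum (nonnegativity) and zeroing the diagonal, optionally
    sparsifies to a symmetrized k-nearest-neighbor graph, forms the graph
    Laplacian ``L = D - W`` and solves the generalized problem
    ``L v = lambda D v``. Internally the equivalent symmetric normalized
    problem ``D^{-1/2} L D^{-1/2} u = lambda u`` is solved and mapped
    back via ``v = D^{-1/2} u``. Eigenvectors for the ``n_modes``
    smallest *nonzero* eigenvalues are returned, each min-max rescaled to
    [0, 1]; the constant zero-eigenvalue solution is excluded.

    Raises
    ------
    ValueError
        If the induced graph is disconnected, or ``n_modes`` exceeds the
        number of available nonzero eigenvalues.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be symmetric")
    if np.any(S < 0):
        raise ValueError("S must be nonnegative")
    n = S.shape[0]
    if not 1 <= n_modes <= n - 1:
        raise ValueError(f"n_modes must be in 1..{n - 1}")

    W = S - S.min()
    np.fill_diagonal(W, 0.0)
    if n_neighbors is not None:
        if not 1 <= n_neighbors < n:
            raise ValueError("n_neighbors must be in 1..n_voxels-1")
        keep = np.zeros_like(W, dtype=bool)
        order = np.argsort(W, axis=1)[:, ::-1][:, :n_neighbors]
        rows = np.repeat(np.arange(n), n_neighbors)
        keep[rows, order.ravel()] = True
        keep |= keep.T  # symmetrize: union of neighborhoods
        W = np.where(keep, W, 0.0)

    n_comp, _ = connected_components(W > 0, directed=False)
    if n_comp != 1:
        raise ValueError("similarity graph not connected")

    d = W.sum(axis=1)
    if np.any(d <= 0):  # pragma: no cover - implied by connectivity
        raise ValueError("similarity graph not connected")
    inv_sqrt_d = 1.0 / np.sqrt(d)
    L_sym = -(W * inv_sqrt_d[:, None]) * inv_sqrt_d[None, :]
    np.fill_diagonal(L_sym, L_sym.diagonal() + 1.0)
    L_sym = (L_sym + L_sym.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(L_sym)

    nonzero = np.flatnonzero(eigvals > zero_tol)
    if len(nonzero) < n_modes:
        raise ValueError(
            f"requested {n_modes} modes but only {len(nonzero)} nonzero "
            "eigenvalues are available"
        )

    modes: list[ConnectivityMode] = []
    for order_idx, j in enumerate(nonzero[:n_modes], start=1):
        v = eigvecs[:, j] * inv_sqrt_d
        # canonical polarity: largest-magnitude centered element positive
        peak = int(np.argmax(np.abs(v - v.mean())))
        if v[peak] - v.mean() < 0:
            v = -v
        modes.append(
            ConnectivityMode(
                values=_rescale01(v),
                raw=v,
                mode_index=order_idx,
                eigenvalue=float(eigvals[j]),
            )
        )
    return modes


def align_sign(mode: ConnectivityMode, reference: np.ndarray) -> ConnectivityMode:
    """Resolve eigenvector sign ambiguity against a reference map.

    The mode is negated (before rescaling) iff its Pearson correlation
    with the reference is negative; the post-alignment correlation is
    recorded as ``qc_spatial_r``. An exactly zero correlation leaves the
    mode unchanged, with a warning.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != mode.raw.shape:
        raise ValueError("mode and reference must live on identical voxel sets")
    if np.std(reference) == 0.0:
        raise ValueError("zero-variance reference")
    r = _pearson(mode.raw, reference)
    if r < 0:
        out = mode.flipped()
        r = -r
    else:
        if r == 0.0:
            warnings.warn(
                "mode uncorrelated with reference; polarity left unchanged",
                stacklevel=2,
            )
        out = replace(mode)
    return replace(out, sign_aligned=True, qc_spatial_r=r)


def group_reference(
    maps: Sequence[np.ndarray], max_iter: int = 10
) -> np.ndarray:
    """Iteratively sign-align subject maps and average them.

    Starting from the first subject's map, each map's polarity is chosen
    by the sign of its correlation with the current reference; aligned
    maps (values in [0, 1], so a flip is ``1 - x``) are averaged and the
    mean rescaled to [0, 1]. Iteration stops when the polarity
    assignment stabilizes (at most ``max_iter`` sweeps).
    """
    maps = [np.asarray(m, dtype=float) for m in maps]
    if len(maps) < 2:
        raise ValueError("group reference requires at least 2 subjects")
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("all maps must live on identical voxel sets")

    reference = maps[0]
    signs = np.ones(len(maps), dtype=int)
    for _ in range(max_iter):
        new_signs = np.array(
            [1 if _pearson(m, reference) >= 0 else -1 for m in maps], dtype=int
        )
        aligned = [m if s > 0 else 1.0 - m for m, s in zip(maps, new_signs)]
        reference = _rescale01(np.mean(aligned, axis=0))
        if np.array_equal(new_signs, signs):
            return reference
        signs = new_signs
    raise RuntimeError(
        f"group reference alignment did not stabilize in {max_iter} iterations"
    )


def qc_spatial_corr(
    mode: ConnectivityMode,
    reference: np.ndarray | None = None,
    threshold: float = 0.5,
) -> bool:
    """Quality-control a mode by spatial correlation with the group reference.

    Returns ``True`` (keep) iff the correlation is at least ``threshold``;
    a map correlating strictly below the threshold is flagged for
    exclusion. Uses ``qc_spatial_r`` recorded at alignment when no
    reference is passed.
    """
    if reference is not None:
        r = _pearson(mode.values, np.asarray(reference, dtype=float))
    elif mode.qc_spatial_r is not None:
        r = mode.qc_spatial_r
    else:
        raise ValueError("no reference given and mode has no recorded qc_spatial_r")
    keep = r >= threshold
    if not keep:
        logger.info("mode excluded: spatial correlation %.3f < %.3f", r, threshold)
    return bool(keep)


def combine_subregions(
    values_a: np.ndarray,
    coords_a: np.ndarray,
    values_b: np.ndarray,
    coords_b: np.ndarray,
    labels: tuple[str, str] = ("A", "B"),
) -> CombinedGradient:
    """Concatenate two subregion gradient maps into one structure-level map.

    Voxel order is preserved within each subregion; per-voxel provenance
    labels are retained. Overlapping voxel coordinates are an error.
    """
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    coords_a = np.asarray(coords_a, dtype=float)
    coords_b = np.asarray(coords_b, dtype=float)
    if len(values_a) != len(coords_a) or len(values_b) != len(coords_b):
        raise ValueError("values and coordinates must have matching lengths")
    set_a = {tuple(np.round(c, 6)) for c in coords_a}
    set_b = {tuple(np.round(c, 6)) for c in coords_b}
    if set_a & set_b:
        raise ValueError("subregions overlap: voxel sets must be disjoint")
    return CombinedGradient(
        values=np.concatenate([values_a, values_b]),
        coords=np.vstack([coords_a, coords_b]),
        subregion=np.array(
            [labels[0]] * len(values_a) + [labels[1]] * len(values_b)
        ),
    )
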