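"""Two-stage-PCA group ICA with Extended Infomax and GICA back-reconstruction.

The multi-subject decomposition follows the standard temporal-concatenation
group ICA scheme: each subject's (time x voxels) data is reduced temporally
to the model order by PCA, the reduced data are concatenated across
subjects and reduced again, and spatial sources are separated by the
Extended Infomax algorithm (natural-gradient information maximization with
per-component switching between super- and sub-Gaussian nonlinearities by
estimated kurtosis sign).  Subject-specific maps and time courses are
recovered by projecting the aggregate unmixing matrix through the
pseudo-inverses of the retained reduction operators restricted to each
subject's block.

The model order is either fixed or estimated by the minimum description
length criterion (Wax-Kailath form on covariance eigenvalues), computed per
subject and aggregated by the median.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .cohort import SubjectBold

__all__ = [
    "ICADecomposition",
    "ComponentMatch",
    "estimate_order_mdl",
    "two_stage_pca",
    "extended_infomax",
    "back_reconstruct",
    "match_components",
    "GroupICA",
]

log = logging.getLogger(__name__)

_EIG_FLOOR = 1e-12


@dataclass
class ICADecomposition:
    """Aggregate and per-subject spatial maps and time courses."""

    order: int
    aggregate_maps: np.ndarray  # components x in-mask voxels (z-scored)
    aggregate_timecourses: np.ndarray  # time x components (mean over subjects)
    subject_maps: list  # per subject, components x voxels (z-scored)
    subject_timecourses: list  # per subject, time x components
    reduction_operators: dict
    mask: np.ndarray  # 3D boolean


@dataclass
class ComponentMatch:
    network: str
    component_index: int
    spatial_correlation: float


# ---------------------------------------------------------------------------
# model-order selection


def _mdl_curve(eigvals: np.ndarray, n_samples: int) -> np.ndarray:
    """Wax-Kailath MDL as a function of candidate order k = 0..p-1."""
    lam = np.sort(np.asarray(eigvals, dtype=float))[::-1]
    lam = np.maximum(lam, _EIG_FLOOR * lam.max())
    p = lam.size
    log_lam = np.log(lam)
    mdl = np.empty(p)
    for k in range(p):
        tail = lam[k:]
        log_geo = log_lam[k:].mean()
        log_arith = np.log(tail.mean())
        n_params = k * (2 * p - k) + 1
        mdl[k] = -n_samples * (p - k) * (log_geo - log_arith) \
            + 0.5 * n_params * np.log(n_samples)
    return mdl


def estimate_order_mdl(X: np.ndarray, min_order: int = 1,
                       max_order: int | None = None,
                       return_curve: bool = False):
    """Estimate the number of signal components of a (channels x samples) matrix.

    For fMRI the channels are time points and the samples are in-mask
    voxels.  Returns the argmin of the MDL criterion over k, clamped to
    ``[min_order, max_order]``; a criterion minimized at k=0 (pure noise)
    is clamped up with a warning.
    """
    X = np.asarray(X, dtype=float)
    p, n = X.shape
    if max_order is None:
        max_order = p - 1
    if not 1 <= min_order <= max_order < p:
        raise ValueError("need 1 <= min_order <= max_order < n_channels")
    Xc = X - X.mean(axis=1, keepdims=True)
    cov = Xc @ Xc.T / n
    eigvals = np.linalg.eigvalsh(cov)
    # restrict to the numerical rank: directions removed exactly by earlier
    # linear operations (detrending, mean removal) carry no order
    # information and would otherwise dominate the tail of the criterion
    keep = eigvals > 1e-9 * eigvals.max()
    if not keep.all():
        log.warning("rank-deficient covariance: %d null eigenvalues dropped, "
                    "rest floored", int((~keep).sum()))
        eigvals = eigvals[keep]
    mdl = _mdl_curve(eigvals, n)
    max_order = min(max_order, eigvals.size - 1)
    k_hat = int(np.argmin(mdl[: max_order + 1]))
    if k_hat < min_order:
        warnings.warn(
            f"MDL minimized at k={k_hat}; clamped to minimum order {min_order}",
            RuntimeWarning,
        )
        k_hat = min_order
    if return_curve:
        return k_hat, mdl
    return k_hat


# ---------------------------------------------------------------------------
# two-stage PCA reduction


def two_stage_pca(subject_data: list, order: int):
    """Temporal PCA per subject, concatenate, reduce again, whiten.

    ``subject_data`` is a list of (time x voxels) arrays on a common voxel
    grid.  Returns ``(white, ops)`` where ``white`` is the (order x voxels)
    whitened group data (identity covariance over voxels) and ``ops`` holds
    the retained reduction operators needed for back-reconstruction.
    """
    order = int(order)
    reduced, bases = [], []
    n_voxels = subject_data[0].shape[1]
    for X in subject_data:
        X = np.asarray(X, dtype=float)
        if order > X.shape[0]:
            raise ValueError(
                f"order {order} exceeds subject time dimension {X.shape[0]}"
            )
        if X.shape[1] != n_voxels:
            raise ValueError("all subjects must share one voxel grid")
        cov_t = X @ X.T / n_voxels
        w, U = np.linalg.eigh(cov_t)
        F = U[:, ::-1][:, :order]  # time x order, descending eigenvalues
        bases.append(F)
        reduced.append(F.T @ X)
    R = np.vstack(reduced)  # (n_subjects*order) x voxels
    cov_g = R @ R.T / n_voxels
    w2, U2 = np.linalg.eigh(cov_g)
    idx = np.argsort(w2)[::-1][:order]
    G = U2[:, idx]
    lam = np.maximum(w2[idx], _EIG_FLOOR * w2.max())
    whiten = (G / np.sqrt(lam)).T  # order x (n_subjects*order)
    white = whiten @ R
    ops = {
        "subject_bases": bases,
        "subject_reduced": reduced,
        "group_basis": G,
        "group_eigvals": lam,
        "whiten": whiten,
        "dewhiten": G * np.sqrt(lam),
        "order": order,
        "n_subjects": len(subject_data),
    }
    return white, ops


# ---------------------------------------------------------------------------
# Extended Infomax


def extended_infomax(
    white: np.ndarray,
    random_state=0,
    l_rate: float | None = None,
    max_iter: int = 2000,
    tol: float = 1e-6,
    anneal: float = 0.9,
    kurt_momentum: float = 0.9,
):
    """Separate whitened data into independent sources.

    Full-batch natural-gradient updates
    ``dW = lr * (I - K tanh(u) u'/N - u u'/N) W`` with the diagonal sign
    matrix K set per component from a moving-average kurtosis estimate
    (+1 super-Gaussian, -1 sub-Gaussian).  The learning rate anneals when
    the weight change blows up; convergence is declared when the maximum
    absolute weight change drops below ``tol``.

    Returns ``(unmixing, sources, converged)``.  Deterministic given
    ``random_state`` (random orthonormal initialization).
    """
    X = np.asarray(white, dtype=float)
    k, n = X.shape
    if n < 10 * k:
        warnings.warn("fewer than 10x samples per component; ICA may be unstable",
                      RuntimeWarning)
    rng = np.random.default_rng(random_state)
    W, _ = np.linalg.qr(rng.standard_normal((k, k)))
    if l_rate is None:
        l_rate = 0.1  # full-batch natural gradient tolerates a large step
    eye = np.eye(k)
    signs = np.ones(k)
    kurt_ma = None
    last_change = np.inf
    converged = False
    best_W, best_change = W.copy(), np.inf
    for _ in range(max_iter):
        U = W @ X
        m2 = (U**2).mean(axis=1)
        m4 = (U**4).mean(axis=1)
        kurt = m4 / np.maximum(m2**2, 1e-12) - 3.0
        kurt_ma = kurt if kurt_ma is None else \
            kurt_momentum * kurt_ma + (1 - kurt_momentum) * kurt
        signs = np.where(kurt_ma >= 0, 1.0, -1.0)
        Y = np.tanh(U)
        grad = eye - (signs[:, None] * Y) @ U.T / n - U @ U.T / n
        dW = l_rate * grad @ W
        change = np.abs(dW).max()
        if not np.isfinite(change):
            l_rate *= anneal
            W = best_W.copy()
            last_change = np.inf
            continue
        W = W + dW
        if change < best_change:
            best_change, best_W = change, W.copy()
        if change > 1.25 * last_change:
            l_rate *= anneal
        last_change = change
        if change < tol:
            converged = True
            break
    if not converged:
        W = best_W
        log.warning("Extended Infomax did not reach tol=%g within %d steps "
                    "(best weight change %.3g); returning best iterate",
                    tol, max_iter, best_change)
    return W, W @ X, converged


# ---------------------------------------------------------------------------
# back-reconstruction (GICA pseudo-inverse formulation)


def back_reconstruct(unmixing: np.ndarray, ops: dict, subject_index: int):
    """Subject-specific maps and time courses from the aggregate unmixing.

    With B = W @ whiten partitioned into per-subject blocks B_i, the
    subject maps are ``M * B_i @ R_i`` (M = number of subjects, R_i the
    subject's stage-1 reduced data) and the subject time courses are
    ``F_i @ pinv(B_i)``.
    """
    m = ops["n_subjects"]
    if not 0 <= subject_index < m:
        raise IndexError(f"unknown subject index {subject_index}")
    k = ops["order"]
    B = unmixing @ ops["whiten"]  # k x (m*k)
    B_i = B[:, subject_index * k:(subject_index + 1) * k]
    R_i = ops["subject_reduced"][subject_index]
    maps = m * (B_i @ R_i)
    timecourses = ops["subject_bases"][subject_index] @ np.linalg.pinv(B_i)
    return maps, timecourses


# ---------------------------------------------------------------------------
# template matching


def _zscore_rows(a: np.ndarray) -> np.ndarray:
    centered = a - a.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1, keepdims=True)
    return centered / np.where(sd > 0, sd, 1.0)


def match_components(maps: np.ndarray, templates: dict, mask: np.ndarray,
                     min_corr: float = 0.2):
    """Greedy assignment of components to network templates.

    ``maps`` is (components x in-mask voxels); each template is a 3D map on
    the same grid.  Assignments are made greedily in descending absolute
    spatial correlation, without replacement.  Returns
    ``(matches, flip_signs)`` where ``flip_signs[c] = -1`` marks components
    whose sign must be flipped to make their matched correlation positive.
    Raises if any network's best remaining correlation is below ``min_corr``.
    """
    labels = list(templates)
    tmpl = np.stack([np.asarray(templates[l])[mask] for l in labels]).astype(float)
    tmpl = _zscore_rows(tmpl)
    comp = _zscore_rows(np.asarray(maps, dtype=float))
    corr = tmpl @ comp.T / comp.shape[1]  # networks x components
    flip = np.ones(comp.shape[0])
    matches = {}
    avail_n = set(range(len(labels)))
    avail_c = set(range(comp.shape[0]))
    while avail_n:
        sub = np.abs(corr)
        best, best_pair = -np.inf, None
        for i in avail_n:
            for j in avail_c:
                if sub[i, j] > best:
                    best, best_pair = sub[i, j], (i, j)
        i, j = best_pair
        if best < min_corr:
            raise ValueError(
                f"no component matches network {labels[i]!r} "
                f"(best |correlation| {best:.3f} < {min_corr})"
            )
        if corr[i, j] < 0:
            flip[j] = -1.0
        matches[labels[i]] = ComponentMatch(labels[i], j, float(abs(corr[i, j])))
        avail_n.discard(i)
        avail_c.discard(j)
    ordered = [matches[l] for l in labels]
    return ordered, flip


# ---------------------------------------------------------------------------
# estimator


class GroupICA(BaseEstimator):
    """Temporal-concatenation group ICA estimator.

    Parameters
    ----------
    n_components : int or "mdl"
        Model order; "mdl" estimates it per subject by MDL and takes the
        median (clamped to ``[min_order, max_order]``).
    min_order, max_order : bounds for the estimated order.
    random_state : seed for the Infomax initialization.
    l_rate, max_iter, tol : Extended Infomax hyperparameters (defaults:
        0.1, 2000, 1e-6).
    remove_voxel_means : subtract each voxel's temporal mean before
        reduction (GIFT-like; no variance normalization).

    Fitted attributes
    -----------------
    order_, components_ (z-scored aggregate maps, components x voxels),
    mask_, decomposition_ (full :class:`ICADecomposition`), converged_.
    """

    def __init__(self, n_components="mdl", min_order: int = 2,
                 max_order: int | None = None, random_state=0,
                 l_rate: float | None = None, max_iter: int = 2000,
                 tol: float = 1e-6, remove_voxel_means: bool = True):
        self.n_components = n_components
        self.min_order = min_order
        self.max_order = max_order
        self.random_state = random_state
        self.l_rate = l_rate
        self.max_iter = max_iter
        self.tol = tol
        self.remove_voxel_means = remove_voxel_means

    def _as_matrices(self, X):
        if isinstance(X[0], SubjectBold):
            mask = X[0].mask
            for b in X:
                if b.mask.shape != mask.shape or not np.array_equal(b.mask, mask):
                    raise ValueError("all subjects must share one mask")
            return [b.timeseries() for b in X], mask
        mats = [np.asarray(x, dtype=float) for x in X]
        mask = np.ones((mats[0].shape[1], 1, 1), dtype=bool)
        return mats, mask

    def fit(self, X, y=None):
        """Fit on a list of SubjectBold (or (time x voxels) arrays)."""
        data, mask = self._as_matrices(X)
        if self.remove_voxel_means:
            data = [d - d.mean(axis=0, keepdims=True) for d in data]
        if self.n_components == "mdl":
            orders = [
                estimate_order_mdl(
                    d, min_order=self.min_order,
                    max_order=self.max_order or d.shape[0] - 1)
                for d in data
            ]
            order = int(np.median(orders))
            order = max(self.min_order, order)
        else:
            order = int(self.n_components)
        white, ops = two_stage_pca(data, order)
        W, S, converged = extended_infomax(
            white, random_state=self.random_state, l_rate=self.l_rate,
            max_iter=self.max_iter, tol=self.tol)
        # resolve permutation/sign indeterminacy deterministically:
        # order components by explained variance in the concatenated reduced
        # data, then flip each so its maximum-|z| voxel is positive.
        mixing = np.linalg.pinv(W)
        contrib = ops["dewhiten"] @ mixing  # (m*order) x order
        ev = (contrib**2).sum(axis=0) * S.var(axis=1)
        rank = np.argsort(ev)[::-1]
        W = W[rank]
        S = S[rank]
        zs = _zscore_rows(S)
        flips = np.where(zs[np.arange(order), np.abs(zs).argmax(axis=1)] >= 0,
                         1.0, -1.0)
        W = flips[:, None] * W
        S = flips[:, None] * S
        subj_maps, subj_tcs = [], []
        for i in range(len(data)):
            maps_i, tc_i = back_reconstruct(W, ops, i)
            subj_maps.append(_zscore_rows(maps_i))
            subj_tcs.append(tc_i)
        agg_tc = np.mean(subj_tcs, axis=0)
        self.order_ = order
        self.unmixing_ = W
        self.converged_ = converged
        self.mask_ = mask
        self.components_ = _zscore_rows(S)
        self.subject_maps_ = subj_maps
        self.subject_timecourses_ = subj_tcs
        self.reduction_ops_ = ops
        self.decomposition_ = ICADecomposition(
            order=order,
            aggregate_maps=self.components_,
            aggregate_timecourses=agg_tc,
            subject_maps=subj_maps,
            subject_timecourses=subj_tcs,
            reduction_operators=ops,
            mask=mask,
        )
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).components_

    def match_components(self, templates: dict, min_corr: float = 0.2):
        """Assign fitted components to templates; flips signs in place."""
        matches, flip = match_components(self.components_, templates,
                                         self.mask_, min_corr=min_corr)
        if np.any(flip < 0):
            self.components_ = flip[:, None] * self.components_
            self.unmixing_ = flip[:, None] * self.unmixing_
            self.subject_maps_ = [flip[:, None] * m for m in self.subject_maps_]
            self.subject_timecourses_ = [tc * flip[None, :]
                                         for tc in self.subject_timecourses_]
            self.decomposition_.aggregate_maps = self.components_
            self.decomposition_.subject_maps = self.subject_maps_
            self.decomposition_.subject_timecourses = self.subject_timecourses_
            self.decomposition_.aggregate_timecourses = \
                np.mean(self.subject_timecourses_, axis=0)
        self.matches_ = matches
        return matches
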