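"""Support vector regression lesion-symptom mapping (SVR-LSM).

A single epsilon-SVR models behavior as a function of the lesion status
of every included voxel at once, so voxel importance reflects the joint
lesion pattern rather than one voxel at a time. The per-voxel statistic
(the "beta map") is the back-projection of the dual solution onto voxel
space,

    beta_j = sum_i alpha_i x_ij

over support vectors i, which for a linear kernel equals the primal
weight vector exactly and for the RBF kernel is the standard lesion-
mapping readout of voxel importance.

Nuisance covariates (age, gender, lesion volume, and optionally a
domain-specific long-term-memory score) are z-normalized and regressed
out of the behavioral score by ordinary least squares before the SVR is
fitted. Optionally each participant's lesion vector can be scaled to
unit Euclidean norm (direct total lesion volume control, dTLVC) instead
of, or in addition to, covarying lesion volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.svm import SVR
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .behavioral import z_normalize
from .exceptions import DegenerateCovariateError, InvalidInputError

__all__ = ["SVRLSM", "residualize", "residualize_matrix", "dtlvc_scale",
           "make_covariate_table"]


def dtlvc_scale(X: np.ndarray) -> np.ndarray:
    """Scale each lesion row to unit Euclidean norm (empty rows untouched)."""
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return X / norms


def make_covariate_table(df, columns, ddof: int = 0):
    """z-normalize the named covariate columns of a DataFrame.

    Returns an (n, k) float array in column order. Gender (or any
    binary indicator) is treated like every other covariate: demeaned
    and divided by the group standard deviation.
    """
    cols = []
    for name in columns:
        try:
            cols.append(z_normalize(np.asarray(df[name], dtype=float), ddof=ddof))
        except DegenerateCovariateError as err:
            raise DegenerateCovariateError(f"covariate {name!r}: {err}") from err
    return np.column_stack(cols) if cols else np.empty((len(df), 0))


def residualize(y, covariates, ddof: int = 0) -> np.ndarray:
    """OLS residuals of a behavioral score on z-normalized covariates.

    The design is an intercept plus each covariate column z-normalized
    (demeaned, divided by the group standard deviation). Residuals have
    zero mean by construction. Raises if the covariate matrix is
    rank-deficient, since a silently dropped covariate would change the
    analysis meaning.
    """
    y = np.asarray(y, dtype=float).ravel()
    Z = np.asarray(covariates, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    n, k = Z.shape
    if len(y) != n:
        raise InvalidInputError("y and covariates have different lengths")
    if n < k + 2:
        raise InvalidInputError(f"need at least {k + 2} participants for {k} covariates")
    Zn = np.column_stack([z_normalize(Z[:, j], ddof=ddof) for j in range(k)]) if k else np.empty((n, 0))
    design = np.column_stack([np.ones(n), Zn])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DegenerateCovariateError("covariate matrix is rank-deficient")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def residualize_matrix(X, covariates, ddof: int = 0) -> np.ndarray:
    """Regress the covariates out of every voxel column of the lesion
    matrix (lesion-side nuisance control, an alternative to covarying
    the behavioral score). Returns a float matrix of residual columns.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    Z = np.asarray(covariates, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    Zn = np.column_stack([z_normalize(Z[:, j], ddof=ddof) for j in range(Z.shape[1])])
    design = np.column_stack([np.ones(n), Zn])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DegenerateCovariateError("covariate matrix is rank-deficient")
    coef, *_ = np.linalg.lstsq(design, X, rcond=None)
    return X - design @ coef


class SVRLSM(RegressorMixin, BaseEstimator):
    """Multivariate lesion-symptom mapping via epsilon-SVR.

    Parameters
    ----------
    kernel : {'rbf', 'linear'}, default 'rbf'
        SVR kernel. The RBF kernel captures non-linear and interactive
        lesion effects; the linear kernel makes the beta map equal the
        primal weight vector.
    C : float, default 30.0
        Regularization strength (larger fits the training scores harder).
    gamma : float, default 5.0
        RBF kernel width, as exp(-gamma * ||x - x'||^2). With dTLVC
        scaling lesion vectors lie on the unit sphere, so squared
        distances are bounded by 2 and this width is meaningful.
    epsilon : float, default 0.1
        Width of the insensitive tube, on the scale of the (typically
        z-scored or residualized) behavioral variable.
    tol : float, default 1e-3
        Solver stopping tolerance (libsvm convention).
    dtlvc : bool, default False
        Scale each lesion row to unit norm before fitting. Off by
        default; lesion volume is usually controlled as a behavioral
        covariate instead.

    Attributes
    ----------
    beta_ : ndarray of shape (n_voxels,)
        Dual-coefficient back-projection onto voxel space.
    svr_ : fitted sklearn.svm.SVR
    residuals_ : training residuals y - predict(X).
    n_features_in_ : number of voxels.

    The fit is deterministic: libsvm's solver involves no randomness
    for epsilon-SVR with these options, so identical inputs give
    identical maps.
    """

    def __init__(
        self,
        kernel: Literal["rbf", "linear"] = "rbf",
        C: float = 30.0,
        gamma: float = 5.0,
        epsilon: float = 0.1,
        dtlvc: bool = False,
        tol: float = 1e-3,
    ):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.epsilon = epsilon
        self.dtlvc = dtlvc
        self.tol = tol

    def _validate_config(self):
        if self.kernel not in ("rbf", "linear"):
            raise InvalidInputError(f"kernel must be 'rbf' or 'linear', got {self.kernel!r}")
        if self.C <= 0 or self.gamma <= 0 or self.epsilon < 0:
            raise InvalidInputError("need C > 0, gamma > 0, epsilon >= 0")

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return dtlvc_scale(X) if self.dtlvc else X

    def gram(self, X: np.ndarray) -> np.ndarray:
        """Kernel Gram matrix of (prepared) lesion rows.

        Exposed so permutation engines can precompute it once: the
        kernel depends only on the lesion data, not on the behavioral
        scores being permuted.
        """
        self._validate_config()
        Xp = self._prepare(X)
        if self.kernel == "linear":
            return Xp @ Xp.T
        return rbf_kernel(Xp, Xp, gamma=self.gamma)

    def fit(self, X, y):
        """Fit the SVR and compute the voxelwise beta map."""
        self._validate_config()
        X, y = check_X_y(X, y, dtype=float)
        Xp = self._prepare(X)
        svr = SVR(kernel=self.kernel, C=self.C, epsilon=self.epsilon, tol=self.tol,
                  gamma=self.gamma if self.kernel == "rbf" else "scale")
        svr.fit(Xp, y)
        self.svr_ = svr
        self.X_prepared_ = Xp
        self.n_features_in_ = X.shape[1]
        self.beta_ = self._back_project(svr, Xp)
        self.residuals_ = y - svr.predict(Xp)
        self.support_ = svr.support_
        self.dual_coef_ = svr.dual_coef_.ravel()
        return self

    @staticmethod
    def _back_project(svr: SVR, Xp: np.ndarray) -> np.ndarray:
        alpha = svr.dual_coef_.ravel()
        return alpha @ Xp[svr.support_]

    def fit_permuted_beta(self, gram: np.ndarray, Xp: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Beta map for one (possibly permuted) score vector, reusing a
        precomputed Gram matrix. ``Xp`` must already be dTLVC-scaled if
        applicable."""
        svr = SVR(kernel="precomputed", C=self.C, epsilon=self.epsilon, tol=self.tol)
        svr.fit(gram, y)
        return self._back_project(svr, Xp)

    def predict(self, X):
        check_is_fitted(self, "svr_")
        X = check_array(X, dtype=float)
        return self.svr_.predict(self._prepare(X))
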