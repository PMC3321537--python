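"""Per-class Mahalanobis spaces via Gram-Schmidt orthogonalization (Stage 1).

A Mahalanobis space for class *i* holds the class feature means μ and
standard deviations σ, the strictly lower-triangular Gram-Schmidt
coefficients t_lq fitted on the standardized members, and the standard
deviation ζ_q of each orthogonal component. Distances are computed in the
orthogonal basis,

    MD_r = (1/d) · Σ_q  u_rq² / ζ_q²,

which for a full-rank class equals the classic scaled Mahalanobis form
(1/d)·zᵀR⁻¹z with R the sample correlation matrix of the members — but is
obtained without inverting R, which is the point: clinical feature sets are
often near-collinear and make R ill-conditioned.

Standard deviations use the n−1 denominator throughout, which makes the
correlation-matrix identity exact and gives the closed form
mean(member self-distances) = (n−1)/n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular

from .config import ModelConfig
from .errors import CollinearityError, ConstantFeatureError, MMTSError


@dataclass
class MahalanobisSpace:
    """Fitted reference space of one class.

    ``gs_coeffs`` is the strictly lower-triangular t_lq matrix; ``kept``
    flags the Gram-Schmidt components that survived fitting (all of them,
    unless the fit was run with ``on_deficient='drop'`` and the class could
    not support the feature subset at full rank).
    """

    class_id: str
    n: int
    mu: np.ndarray
    sigma: np.ndarray
    gs_coeffs: np.ndarray
    zeta: np.ndarray
    feature_names: list[str]
    kept: np.ndarray

    @property
    def d(self) -> int:
        return len(self.feature_names)

    @property
    def is_deficient(self) -> bool:
        return not bool(self.kept.all())

    def to_dict(self) -> dict:
        tri = [self.gs_coeffs[l, :l].tolist() for l in range(self.d)]
        return {
            "class_id": self.class_id,
            "n": self.n,
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "gs_coeffs": tri,
            "zeta": self.zeta.tolist(),
            "feature_names": list(self.feature_names),
            "kept": [bool(k) for k in self.kept],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "MahalanobisSpace":
        d = len(doc["feature_names"])
        T = np.zeros((d, d))
        for l, row in enumerate(doc["gs_coeffs"]):
            T[l, :l] = row
        return cls(
            class_id=doc["class_id"],
            n=int(doc["n"]),
            mu=np.asarray(doc["mu"], dtype=float),
            sigma=np.asarray(doc["sigma"], dtype=float),
            gs_coeffs=T,
            zeta=np.asarray(doc["zeta"], dtype=float),
            feature_names=list(doc["feature_names"]),
            kept=np.asarray(doc["kept"], dtype=bool),
        )


def fit_space(members: np.ndarray, feature_names: list[str], class_id: str = "",
              config: ModelConfig | None = None,
              on_deficient: str = "error") -> MahalanobisSpace:
    """Fit the Mahalanobis space of one class from its member rows.

    Standardizes the columns, then sequentially orthogonalizes them in the
    given feature order: U_l = A_l − Σ_{q<l} t_lq U_q with
    t_lq = (A_l·U_q)/(U_q·U_q).

    Parameters
    ----------
    members:
        n × d feature matrix of the class members, n ≥ 2.
    on_deficient:
        ``'error'`` (full-rank fitting): a component whose ζ_q falls at or
        below ``config.zeta_floor`` raises :class:`CollinearityError`.
        ``'drop'`` (subspace fitting, used for orthogonal-array screening
        runs and for classes too small to support every feature): the
        component is excluded from the space (``kept[q] = False``, its
        coefficients to later components zeroed) and distances are measured
        in the spanned subspace. Drop mode also removes components whose
        residual degrees of freedom fall below ``config.min_component_dof``,
        since their ζ_q estimates collapse toward zero.
    """
    config = config or ModelConfig()
    if on_deficient not in ("error", "drop"):
        raise ValueError("on_deficient must be 'error' or 'drop'")
    X = np.asarray(members, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise MMTSError(f"class '{class_id}' needs at least 2 members to fit a space")
    n, d = X.shape
    if d != len(feature_names):
        raise MMTSError("feature_names length does not match members columns")

    mu = X.mean(axis=0)
    sigma = X.std(axis=0, ddof=1)
    for j in range(d):
        if sigma[j] <= 0.0 or X[:, j].max() == X[:, j].min():
            raise ConstantFeatureError(feature_names[j], class_id or None)

    A = (X - mu) / sigma
    U = np.zeros((n, d))
    T = np.zeros((d, d))
    zeta = np.zeros(d)
    kept = np.ones(d, dtype=bool)
    for l in range(d):
        u = A[:, l].copy()
        for q in range(l):
            if not kept[q]:
                continue  # dropped component: coefficient stays 0
            t = float(A[:, l] @ U[:, q]) / float(U[:, q] @ U[:, q])
            T[l, q] = t
            u -= t * U[:, q]
        z = float(np.sqrt((u @ u) / (n - 1)))
        dof = n - 1 - int(kept[:l].sum())
        # tiny classes keep at least one component: the DOF requirement is
        # capped at what the sample can possibly provide
        dof_needed = min(config.min_component_dof, n - 1)
        if z <= config.zeta_floor:
            if on_deficient == "error":
                raise CollinearityError(l, feature_names[l], class_id or None)
            kept[l] = False
        elif on_deficient == "drop" and dof < dof_needed:
            kept[l] = False
        if not kept[l]:
            zeta[l] = config.zeta_floor
            U[:, l] = 0.0
        else:
            zeta[l] = z
            U[:, l] = u
    return MahalanobisSpace(class_id, n, mu, sigma, T, zeta, list(feature_names), kept)


def gs_transform(space: MahalanobisSpace, x: np.ndarray) -> np.ndarray:
    """Standardize ``x`` against the space and apply its Gram-Schmidt coefficients."""
    x = np.asarray(x, dtype=float)
    if x.shape != (space.d,):
        raise MMTSError(f"expected a vector of {space.d} features, got shape {x.shape}")
    z = (x - space.mu) / space.sigma
    u = np.empty_like(z)
    for l in range(space.d):
        u[l] = z[l] - space.gs_coeffs[l, :l] @ u[:l]
    return u


def mahalanobis_distance(space: MahalanobisSpace, x: np.ndarray) -> float:
    """Scaled Gram-Schmidt Mahalanobis distance from ``x`` to the space's class.

    The scale factor is the number of retained components — identical to the
    feature count d in the full-rank case, and the per-dimension mean of the
    spanned subspace otherwise, which keeps distances comparable across
    classes that retain different component counts.
    """
    u = gs_transform(space, x)
    k = space.kept
    return float(np.sum(u[k] ** 2 / space.zeta[k] ** 2) / int(k.sum()))


@dataclass
class DistanceMatrix:
    """Examples × classes matrix of Mahalanobis distances."""

    values: np.ndarray
    class_order: list[str]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise MMTSError("distances must be finite and nonnegative")


def distance_matrix(spaces: list[MahalanobisSpace], X: np.ndarray) -> DistanceMatrix:
    """Distances from every row of ``X`` to every space, vectorized.

    Solves the unit-lower-triangular system (I + T)u = z per space instead of
    looping :func:`gs_transform` row by row; both paths agree to rounding.
    """
    names = spaces[0].feature_names
    for s in spaces[1:]:
        if s.feature_names != names:
            raise MMTSError("all spaces must share one feature order")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(names):
        raise MMTSError("X feature count does not match the spaces")
    out = np.empty((X.shape[0], len(spaces)))
    for j, s in enumerate(spaces):
        Z = (X - s.mu) / s.sigma
        L = np.eye(s.d) + s.gs_coeffs
        U = solve_triangular(L, Z.T, lower=True, unit_diagonal=True).T
        k = s.kept
        out[:, j] = np.sum(U[:, k] ** 2 / s.zeta[k] ** 2, axis=1) / int(k.sum())
    return DistanceMatrix(out, [s.class_id for s in spaces])


def fit_class_spaces(cohort, config: ModelConfig | None = None,
                     on_deficient: str = "error") -> list[MahalanobisSpace]:
    """Fit one space per class present in the cohort, in class order."""
    spaces = []
    for c in cohort.classes_present():
        spaces.append(fit_space(cohort.members(c), cohort.feature_names, c,
                                config, on_deficient))
    return spaces
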