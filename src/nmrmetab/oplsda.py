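"""PLS-DA and O-PLS-DA by NIPALS with orthogonal signal correction.

Two-class discrimination is modelled as PLS1 regression of a 0/1 class dummy
on the unit-variance-scaled spectra.  For a single y column the NIPALS inner
loop collapses to a closed form: w = X'y / ||X'y||, t = Xw, c = y't/t't,
p = X't/t't.  O-PLS-DA first removes ``n_orth`` orthogonal components
(w_orth = p - (w'p)w, normalized) whose scores are orthogonal to y by
construction, then fits one predictive component on the filtered matrix —
with ``n_orth = 0`` it reduces exactly to one-component PLS-DA.

Sign convention: w has unit norm and the scores carry the magnitude; because
w is proportional to X'y, the predictive score is positively correlated with
the class dummy, so recoding the classes flips score signs only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import ScalingState

__all__ = [
    "ClassVector",
    "PlsModel",
    "OplsModel",
    "LoadingsProfile",
    "make_class_vector",
    "fit_pls_da",
    "fit_opls_da",
    "predict",
    "backscaled_loadings",
]


@dataclass
class ClassVector:
    """0/1 class dummy with the label attached to each code."""

    y: np.ndarray
    class_names: dict[int, str]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        vals = set(np.unique(self.y))
        if not vals <= {0.0, 1.0}:
            raise ValueError("class vector must be coded 0/1")
        if len(vals) < 2:
            raise ValueError("both classes must be present")


def make_class_vector(labels, class_a: str, class_b: str) -> tuple[np.ndarray, ClassVector]:
    """Build a mask over ``labels`` plus a ClassVector (class_a -> 1)."""
    labels = np.asarray(labels)
    mask = (labels == class_a) | (labels == class_b)
    if not (labels == class_a).any() or not (labels == class_b).any():
        raise ValueError(f"both classes required, got counts "
                         f"{int((labels == class_a).sum())} vs {int((labels == class_b).sum())}")
    y = (labels[mask] == class_a).astype(float)
    return mask, ClassVector(y, {0: class_b, 1: class_a})


def _as_y(y) -> np.ndarray:
    if isinstance(y, ClassVector):
        return y.y.copy()
    y = np.asarray(y, dtype=float).ravel()
    if np.unique(y).size < 2:
        raise ValueError("y must contain both classes")
    return y.copy()


@dataclass
class PlsModel:
    """Multi-component PLS1 model (weights/scores/loadings per component)."""

    W: np.ndarray  # (p, k) unit-norm weight vectors
    T: np.ndarray  # (n, k) scores
    P: np.ndarray  # (p, k) X loadings
    c: np.ndarray  # (k,) y loadings
    r2x_cum: np.ndarray
    r2y_cum: np.ndarray
    y_mean: float

    @property
    def n_components(self) -> int:
        return self.W.shape[1]

    @property
    def r2x(self) -> float:
        return float(self.r2x_cum[-1])

    @property
    def r2y(self) -> float:
        return float(self.r2y_cum[-1])


def _check_xy(X: np.ndarray, y: np.ndarray) -> None:
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if X.shape[0] != y.size:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.size} entries")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")


def fit_pls_da(X: np.ndarray, y, n_components: int = 1) -> PlsModel:
    """NIPALS PLS1 discriminant model on column-centred (scaled) X."""
    X = np.asarray(X, dtype=float)
    yv = _as_y(y)
    _check_xy(X, yv)
    rank_bound = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_components <= rank_bound:
        raise ValueError(f"n_components must be in [1, {rank_bound}]")
    y_mean = float(yv.mean())
    yc = yv - y_mean
    Xd = X - 0.0  # work on a copy; X is expected centred already
    Xd = Xd.copy()
    ssx0 = float(np.sum(X * X))
    ssy0 = float(np.sum(yc * yc))
    W = np.empty((X.shape[1], n_components))
    T = np.empty((X.shape[0], n_components))
    P = np.empty((X.shape[1], n_components))
    c = np.empty(n_components)
    r2x_cum = np.empty(n_components)
    r2y_cum = np.empty(n_components)
    ssx_expl = 0.0
    for k in range(n_components):
        xty = Xd.T @ yc
        nrm = float(np.linalg.norm(xty))
        if nrm <= 1e-12 * max(1.0, np.sqrt(ssx0 * ssy0)):
            raise ValueError(f"component {k + 1} exceeds the effective rank of X'y")
        w = xty / nrm
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 0:
            raise ValueError(f"degenerate score vector at component {k + 1}")
        ck = float(yc @ t) / tt
        p = (Xd.T @ t) / tt
        Xd -= np.outer(t, p)
        yc = yc - ck * t
        W[:, k], T[:, k], P[:, k], c[k] = w, t, p, ck
        ssx_expl += tt * float(p @ p)
        r2x_cum[k] = ssx_expl / ssx0 if ssx0 > 0 else 0.0
        r2y_cum[k] = 1.0 - float(yc @ yc) / ssy0
    return PlsModel(W, T, P, c, r2x_cum, r2y_cum, y_mean)


@dataclass
class OplsModel:
    """One predictive + ``n_orth`` orthogonal components.

    ``t`` is the predictive score (the Tcv axis when cross-validated),
    ``T_orth`` the orthogonal (signal-corrected, TYosc) scores.
    ``loading_r`` is the Pearson correlation between the predictive score
    and each column of the (scaled) training matrix.
    """

    w: np.ndarray
    p: np.ndarray
    t: np.ndarray
    c: float
    W_orth: np.ndarray  # (p, n_orth)
    P_orth: np.ndarray
    T_orth: np.ndarray  # (n, n_orth)
    n_orth: int
    r2x: float
    r2y: float
    loading_r: np.ndarray
    y_mean: float
    scaling_state: ScalingState | None = field(default=None, repr=False)


def _column_corr(t: np.ndarray, X: np.ndarray) -> np.ndarray:
    tc = t - t.mean()
    tn = float(np.linalg.norm(tc))
    Xc = X - X.mean(axis=0)
    norms = np.linalg.norm(Xc, axis=0)
    r = np.zeros(X.shape[1])
    ok = (norms > 0) & (tn > 0)
    r[ok] = (Xc[:, ok].T @ tc) / (norms[ok] * tn)
    return r


def fit_opls_da(
    X: np.ndarray,
    y,
    n_orth: int = 0,
    scaling_state: ScalingState | None = None,
) -> OplsModel:
    """Fit O-PLS-DA: ``n_orth`` orthogonal filter rounds + one predictive
    PLS component on the filtered matrix."""
    X = np.asarray(X, dtype=float)
    yv = _as_y(y)
    _check_xy(X, yv)
    if n_orth < 0:
        raise ValueError("n_orth must be >= 0")
    rank_bound = min(X.shape[0] - 1, X.shape[1])
    if n_orth + 1 > rank_bound:
        raise ValueError(f"n_orth + 1 exceeds the rank bound ({rank_bound})")
    y_mean = float(yv.mean())
    yc = yv - y_mean
    X0 = X
    Xd = X.copy()
    ssx0 = float(np.sum(X0 * X0))
    pdim = X.shape[1]
    W_orth = np.empty((pdim, n_orth))
    P_orth = np.empty((pdim, n_orth))
    T_orth = np.empty((X.shape[0], n_orth))
    ssx_orth = 0.0
    for k in range(n_orth):
        xty = Xd.T @ yc
        nrm = float(np.linalg.norm(xty))
        if nrm <= 0:
            raise ValueError(f"orthogonal round {k + 1}: X'y vanished")
        w = xty / nrm
        t = Xd @ w
        tt = float(t @ t)
        p = (Xd.T @ t) / tt
        w_o = p - float(w @ p) * w
        nrm_o = float(np.linalg.norm(w_o))
        if nrm_o <= 1e-12:
            raise ValueError(
                f"orthogonal round {k + 1}: no y-orthogonal variance left"
            )
        w_o /= nrm_o
        t_o = Xd @ w_o
        tto = float(t_o @ t_o)
        p_o = (Xd.T @ t_o) / tto
        Xd -= np.outer(t_o, p_o)
        W_orth[:, k], P_orth[:, k], T_orth[:, k] = w_o, p_o, t_o
        ssx_orth += tto * float(p_o @ p_o)
    core = fit_pls_da(Xd, yv, n_components=1)
    t = core.T[:, 0]
    tt = float(t @ t)
    r2x = (ssx_orth + tt * float(core.P[:, 0] @ core.P[:, 0])) / ssx0 if ssx0 > 0 else 0.0
    resid = yc - core.c[0] * t
    r2y = 1.0 - float(resid @ resid) / float(yc @ yc)
    return OplsModel(
        w=core.W[:, 0],
        p=core.P[:, 0],
        t=t,
        c=float(core.c[0]),
        W_orth=W_orth,
        P_orth=P_orth,
        T_orth=T_orth,
        n_orth=n_orth,
        r2x=r2x,
        r2y=r2y,
        loading_r=_column_corr(t, X0),
        y_mean=y_mean,
        scaling_state=scaling_state,
    )


def predict(model: OplsModel, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Filter ``X_new`` with the training orthogonal components, then score.

    ``X_new`` must be scaled with the *training* scaling state.  Returns
    ``(t_new, T_orth_new, y_hat)`` with ``y_hat = t_new * c + y_mean``.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.w.size:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.w.size}"
        )
    Xd = X_new.copy()
    T_orth_new = np.empty((X_new.shape[0], model.n_orth))
    for k in range(model.n_orth):
        t_o = Xd @ model.W_orth[:, k]
        Xd -= np.outer(t_o, model.P_orth[:, k])
        T_orth_new[:, k] = t_o
    t_new = Xd @ model.w
    y_hat = t_new * model.c + model.y_mean
    return t_new, T_orth_new, y_hat


@dataclass
class LoadingsProfile:
    """Back-scaled (covariance-scale) loadings coloured by |r|."""

    ppm: np.ndarray | None
    backscaled: np.ndarray
    r: np.ndarray
    abs_r: np.ndarray


def backscaled_loadings(
    model: OplsModel,
    scaling_state: ScalingState | None = None,
    ppm: np.ndarray | None = None,
) -> LoadingsProfile:
    """Multiply predictive loadings back by the per-column SDs.

    Recovers a spectrum-like profile (covariance scale) from a model fitted
    on unit-variance data; paired with ``loading_r`` it is the standard
    coloured loadings plot.  ``ppm``, if given, must already be restricted
    to the scaler's kept columns.
    """
    state = scaling_state or model.scaling_state
    if state is None:
        raise ValueError("a ScalingState is required to back-scale loadings")
    sds = state.kept_sds
    if sds.size != model.p.size:
        raise ValueError(
            f"scaling state keeps {sds.size} columns, model has {model.p.size}"
        )
    if ppm is not None:
        ppm = np.asarray(ppm, dtype=float)
        if ppm.size != model.p.size:
            raise ValueError("ppm length does not match the model's columns")
    r = model.loading_r
    return LoadingsProfile(ppm=ppm, backscaled=model.p * sds, r=r, abs_r=np.abs(r))
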