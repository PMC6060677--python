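"""Model validation: 7-fold cross-validated Q2 and permutation testing.

Q2Y is computed by stratified k-fold cross-validation with *no leakage*:
unit-variance scaling is refit inside every training split and applied to
the held-out fold before prediction.  Model-level validity is assessed by
permuting class labels and recomputing the full cross-validation each time;
per-variable loading significance compares each variable's |r| (correlation
with the predictive score) against its own label-permutation null.  All
p-values use the +1-corrected one-sided estimator
``p = (1 + #{null >= observed}) / (1 + n_perm)``, so p is never zero and a
model beating every null at 1000 permutations reports p = 1/1001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .oplsda import ClassVector, fit_opls_da, predict
from .preprocess import apply_scaler, fit_scaler

__all__ = [
    "CvResult",
    "PermutationResult",
    "LoadingSignificance",
    "cross_validate_q2",
    "permutation_test_model",
    "permutation_test_loadings",
]


@dataclass
class CvResult:
    q2y: float
    fold_assignments: np.ndarray
    press: float
    tss: float
    seed: int


@dataclass
class PermutationResult:
    observed: float
    null_values: np.ndarray
    p_value: float
    n_perm: int
    seed: int


@dataclass
class LoadingSignificance:
    observed_abs_r: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    alpha: float
    n_perm: int
    seed: int
    significant_fdr: np.ndarray | None = None


def _as_labels(y) -> np.ndarray:
    if isinstance(y, ClassVector):
        return y.y.astype(float)
    return np.asarray(y, dtype=float).ravel()


def _grouped_folds(y, groups, k_folds, rng) -> np.ndarray:
    """Stratified folds that keep whole groups (e.g. one subject's repeat
    samples) together; each group must be single-class."""
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    glabel = np.empty(uniq.size)
    for j, g in enumerate(uniq):
        labs = np.unique(y[groups == g])
        if labs.size > 1:
            raise ValueError(f"group {g!r} mixes classes; cannot stratify")
        glabel[j] = labs[0]
    skf = StratifiedKFold(
        n_splits=k_folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
    )
    folds = np.empty(len(y), dtype=int)
    for f, (_, test_g) in enumerate(skf.split(np.zeros(uniq.size), glabel)):
        for g in uniq[test_g]:
            folds[groups == g] = f
    return folds


def _make_folds(y, k_folds, seed, groups=None, max_retries: int = 20) -> np.ndarray:
    """Per-sample fold indices; redrawn (bounded) if a training split would
    lose a class entirely."""
    rng = np.random.default_rng(seed)
    classes = np.unique(y)
    for _ in range(max_retries):
        if groups is not None:
            folds = _grouped_folds(y, groups, k_folds, rng)
        else:
            skf = StratifiedKFold(
                n_splits=k_folds, shuffle=True,
                random_state=int(rng.integers(2**31 - 1)),
            )
            folds = np.empty(len(y), dtype=int)
            for f, (_, test) in enumerate(skf.split(np.zeros(len(y)), y)):
                folds[test] = f
        ok = all(
            np.isin(classes, y[folds != f]).all() for f in range(k_folds)
        )
        if ok:
            return folds
    raise ValueError("could not build folds keeping both classes in every training split")


def cross_validate_q2(
    X: np.ndarray,
    y,
    n_orth: int = 0,
    k_folds: int = 7,
    seed: int = 0,
    groups=None,
) -> CvResult:
    """Stratified k-fold cross-validated Q2Y for an O-PLS-DA model.

    ``X`` is the preprocessed but *unscaled* matrix; scaling is refit on
    each training split.  Q2Y = 1 - PRESS/TSS with TSS around the overall
    class mean.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    yv = _as_labels(y)
    if len(yv) < k_folds:
        raise ValueError(f"need at least k_folds={k_folds} samples")
    if min(np.bincount(yv.astype(int))) < 2:
        raise ValueError("each class needs at least 2 samples")
    folds = _make_folds(yv, k_folds, seed, groups=groups)
    y_hat = np.empty_like(yv)
    for f in range(k_folds):
        train = folds != f
        test = ~train
        state = fit_scaler(X[train])
        Xt = apply_scaler(X[train], state)
        model = fit_opls_da(Xt, yv[train], n_orth=n_orth)
        _, _, yh = predict(model, apply_scaler(X[test], state))
        y_hat[test] = yh
    press = float(np.sum((yv - y_hat) ** 2))
    tss = float(np.sum((yv - yv.mean()) ** 2))
    return CvResult(q2y=1.0 - press / tss, fold_assignments=folds, press=press, tss=tss, seed=seed)


def permutation_test_model(
    X: np.ndarray,
    y,
    n_orth: int = 0,
    n_perm: int = 1000,
    k_folds: int = 7,
    seed: int = 0,
    groups=None,
) -> PermutationResult:
    """Permutation test of model validity on the cross-validated Q2Y.

    Class labels are randomly permuted ``n_perm`` times and the *entire*
    procedure (fold construction, per-fold scaling, O-PLS fit, prediction)
    is recomputed each time.  The model is valid at level alpha when the
    observed Q2Y sits in the top alpha tail of the null.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    yv = _as_labels(y)
    ss = np.random.SeedSequence([int(seed), 0x5EED])
    child_seeds = ss.generate_state(n_perm + 1) % (2**31 - 1)
    observed = cross_validate_q2(
        X, yv, n_orth=n_orth, k_folds=k_folds, seed=int(child_seeds[0]), groups=groups
    ).q2y
    rng = np.random.default_rng(ss.spawn(1)[0])
    null = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = rng.permutation(yv)
        null[b] = cross_validate_q2(
            X, y_perm, n_orth=n_orth, k_folds=k_folds, seed=int(child_seeds[b + 1]),
        ).q2y
    p = (1.0 + float(np.sum(null >= observed))) / (1.0 + n_perm)
    return PermutationResult(observed=observed, null_values=null, p_value=p, n_perm=n_perm, seed=seed)


def permutation_test_loadings(
    X: np.ndarray,
    y,
    n_orth: int = 0,
    n_perm: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
    fdr: bool = False,
) -> LoadingSignificance:
    """Per-variable significance of loading correlations by permutation.

    The observed statistic per variable is |r|, the correlation between the
    predictive score and that column of the scaled matrix.  Null
    distributions come from refitting the model on label-permuted data
    (scaling does not depend on y, so it is fit once).  Variables with
    +1-corrected p < alpha are flagged; ``fdr=True`` additionally reports a
    Benjamini-Hochberg flag (off by default — the primary rule is the
    per-variable alpha).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    yv = _as_labels(y)
    state = fit_scaler(X)
    Xs = apply_scaler(X, state)
    observed = np.abs(fit_opls_da(Xs, yv, n_orth=n_orth).loading_r)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x10AD]))
    exceed = np.zeros(observed.size)
    for _ in range(n_perm):
        y_perm = rng.permutation(yv)
        null_r = np.abs(fit_opls_da(Xs, y_perm, n_orth=n_orth).loading_r)
        exceed += null_r >= observed
    p = (1.0 + exceed) / (1.0 + n_perm)
    sig = p < alpha
    sig_fdr = None
    if fdr:
        from statsmodels.stats.multitest import multipletests

        sig_fdr = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    return LoadingSignificance(
        observed_abs_r=observed,
        p_values=p,
        significant=sig,
        alpha=alpha,
        n_perm=n_perm,
        seed=seed,
        significant_fdr=sig_fdr,
    )
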