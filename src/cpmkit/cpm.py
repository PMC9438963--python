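"""Connectome-based predictive modelling (CPM) with leave-one-out CV.

The estimator, for a cohort of n subjects with E edges each:

1. **Edge selection** — for every edge, the partial Spearman correlation
   between edge value and behaviour, controlling for nuisance covariates
   (age, sex, education): variables are rank-transformed (average ranks for
   ties), the ranked edge and behaviour are residualized on the ranked
   covariates plus an intercept, and the Pearson correlation of the
   residuals is tested against a t distribution with n - C - 2 degrees of
   freedom.  Edges with correlation > 0 and p strictly below the positive
   threshold form the positive network; likewise (correlation < 0) for the
   negative network.  The two masks are disjoint by construction.

2. **Network strength** — per subject, the plain sum of raw edge values over
   a mask (no Fisher transform; raw correlations are the edge currency).

3. **Strength model** — one simple (covariate-free) OLS regression of
   behaviour on strength per network sign.

4. **LOOCV** — each subject is predicted from masks and models fitted on the
   other n - 1 subjects; accuracy is rho_true, the Spearman correlation
   between cross-validated predictions and observed behaviour, reported per
   network sign.

Degenerate cases are total: a constant edge is never selected (rho = 0,
p = 1); a fold whose training strengths are constant (e.g. an empty mask)
predicts the training-behaviour mean; a constant prediction vector gets
rho_true = 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special
from scipy.stats import rankdata

logger = logging.getLogger("cpmkit")

__all__ = [
    "CohortDataset",
    "SelectionMasks",
    "StrengthModel",
    "LoocvPrediction",
    "partial_spearman",
    "select_edges",
    "network_strength",
    "fit_strength_model",
    "loocv_predict",
    "spearman_rho",
    "LoocvEngine",
]


# ---------------------------------------------------------------------------
# datasets and result containers
# ---------------------------------------------------------------------------


@dataclass
class CohortDataset:
    """Aligned per-subject edge vectors, behaviour deltas and covariates."""

    subject_ids: list[str]
    edge_matrix: np.ndarray  # n x E
    behaviour: np.ndarray  # n
    covariates: np.ndarray | None = None  # n x C (C may be 0)

    def __post_init__(self) -> None:
        self.edge_matrix = np.asarray(self.edge_matrix, dtype=float)
        self.behaviour = np.asarray(self.behaviour, dtype=float)
        n = self.edge_matrix.shape[0]
        if self.covariates is None:
            self.covariates = np.empty((n, 0))
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.ndim == 1:
            self.covariates = self.covariates[:, None]
        if len(self.subject_ids) != n or self.behaviour.shape != (n,):
            raise ValueError("subject_ids, edge_matrix and behaviour sizes disagree")
        if self.covariates.shape[0] != n:
            raise ValueError("covariates row count disagrees with edge_matrix")
        if n < 4:
            raise ValueError("need at least 4 subjects")
        for name, arr in (
            ("edge_matrix", self.edge_matrix),
            ("behaviour", self.behaviour),
            ("covariates", self.covariates),
        ):
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} contains missing or non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.edge_matrix.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_matrix.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]


@dataclass
class SelectionMasks:
    """Disjoint positive/negative edge masks at given selection thresholds."""

    p_threshold_pos: float
    p_threshold_neg: float
    positive_mask: np.ndarray
    negative_mask: np.ndarray

    def __post_init__(self) -> None:
        self.positive_mask = np.asarray(self.positive_mask, dtype=bool)
        self.negative_mask = np.asarray(self.negative_mask, dtype=bool)
        if self.positive_mask.shape != self.negative_mask.shape:
            raise ValueError("mask lengths disagree")
        if (self.positive_mask & self.negative_mask).any():
            raise ValueError("an edge cannot be in both networks")

    @property
    def p_threshold(self) -> float:
        if self.p_threshold_pos != self.p_threshold_neg:
            raise ValueError("masks were built with two different thresholds")
        return self.p_threshold_pos

    @property
    def n_edges(self) -> int:
        return self.positive_mask.size


@dataclass
class StrengthModel:
    """Simple linear model behaviour ~ network strength for one sign."""

    slope: float
    intercept: float
    network_sign: str  # "positive" | "negative"
    degenerate: bool = False  # constant training strengths; predicts the mean

    def predict(self, strength) -> np.ndarray:
        return self.slope * np.asarray(strength, dtype=float) + self.intercept


@dataclass
class LoocvPrediction:
    """Cross-validated predictions and accuracy for both network signs."""

    observed: np.ndarray
    predicted_pos: np.ndarray
    predicted_neg: np.ndarray
    rho_pos: float
    rho_neg: float
    fold_masks: list[SelectionMasks] = field(default_factory=list)
    fold_models_pos: list[StrengthModel] = field(default_factory=list)
    fold_models_neg: list[StrengthModel] = field(default_factory=list)
    fold_rhos: np.ndarray | None = None  # n_folds x E selection correlations
    p_threshold_pos: float = np.nan
    p_threshold_neg: float = np.nan

    def rho_true(self, sign: str) -> float:
        return {"positive": self.rho_pos, "negative": self.rho_neg}[sign]

    def predicted(self, sign: str) -> np.ndarray:
        return {"positive": self.predicted_pos, "negative": self.predicted_neg}[sign]


# ---------------------------------------------------------------------------
# rank / partial-correlation primitives
# ---------------------------------------------------------------------------


def _covariate_basis(covariates: np.ndarray) -> np.ndarray:
    """Orthonormal basis of span{intercept, ranked covariates}."""
    n = covariates.shape[0]
    cols = [np.ones((n, 1))]
    if covariates.shape[1]:
        cols.append(rankdata(covariates, axis=0))
    design = np.hstack(cols)
    q, r = np.linalg.qr(design)
    keep = np.abs(np.diag(r)) > 1e-12 * max(1.0, np.abs(r[0, 0]))
    return q[:, keep]


def _rho_pvalues(rho: np.ndarray, df: int) -> np.ndarray:
    """Two-sided t-distribution p-values for (partial) correlations."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(rho) * np.sqrt(df / np.maximum(1.0 - rho * rho, 0.0))
    p = np.where(np.isinf(t), 0.0, 2.0 * special.stdtr(df, -np.where(np.isinf(t), 0.0, t)))
    return np.minimum(p, 1.0)


def _edge_stats(
    edges: np.ndarray, y: np.ndarray, q_basis: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Partial Spearman rho of each edge column with y given the basis.

    ``edges`` must already be rank-transformed and residualized elsewhere or
    raw; this helper ranks both sides itself.  Returns (rho, residual norms
    of y) so callers can detect a degenerate behaviour vector.
    """
    ranked = rankdata(edges, axis=0)
    xc = ranked - q_basis @ (q_basis.T @ ranked)
    xn = np.sqrt((xc * xc).sum(axis=0))
    ry = rankdata(y)
    yc = ry - q_basis @ (q_basis.T @ ry)
    yn = float(np.sqrt(yc @ yc))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (xc.T @ yc) / (xn * yn)
    rho[~np.isfinite(rho)] = 0.0
    return np.clip(rho, -1.0, 1.0), xn if yn > 0 else np.zeros_like(xn)


def partial_spearman(x, y, covariates=None) -> tuple[float, float]:
    """Partial Spearman correlation of x and y controlling for covariates.

    Rank-transforms x, y and each covariate (average ranks for ties), then
    correlates the residuals of the ranked x and y after linear regression on
    the ranked covariates (plus intercept).  The two-sided p-value uses a t
    distribution with ``n - C - 2`` degrees of freedom.  With ``C = 0`` this
    is the plain Spearman rank correlation.

    A constant x or y has no defined rank correlation: returns ``(0.0, 1.0)``
    with a warning, so such a variable is never selected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        covariates = np.empty((x.size, 0))
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    n, c = x.size, covariates.shape[1]
    if not (np.isfinite(x).all() and np.isfinite(y).all() and np.isfinite(covariates).all()):
        raise ValueError("inputs must be finite")
    if n < c + 3:
        raise ValueError(f"need at least C + 3 = {c + 3} observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: rank correlation undefined, returning rho=0, p=1")
        return 0.0, 1.0
    q = _covariate_basis(covariates)
    rho, _ = _edge_stats(x[:, None], y, q)
    df = n - c - 2
    p = _rho_pvalues(rho, df)
    return float(rho[0]), float(p[0])


def spearman_rho(a, b) -> float:
    """Spearman correlation with the package's degenerate-input convention.

    Constant inputs (e.g. every LOOCV fold fell back to the training mean)
    yield 0.0 rather than NaN, so permutation counting stays total.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    ra, rb = rankdata(a), rankdata(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    return float((ra @ rb) / np.sqrt((ra @ ra) * (rb @ rb)))


def _col_spearman(pred: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman of each column of ``pred`` with ``y``; constant columns -> 0."""
    r = rankdata(pred, axis=0)
    rc = r - r.mean(axis=0)
    ry = rankdata(y)
    ry = ry - ry.mean()
    denom = np.sqrt((rc * rc).sum(axis=0) * (ry @ ry))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rc.T @ ry) / denom
    rho[~np.isfinite(rho)] = 0.0
    return rho


# ---------------------------------------------------------------------------
# public single-shot operations
# ---------------------------------------------------------------------------


def select_edges(data: CohortDataset, p_threshold: float) -> SelectionMasks:
    """Select positively / negatively behaviour-correlated edges at p < threshold."""
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must be in (0, 1)")
    q = _covariate_basis(data.covariates)
    rho, _ = _edge_stats(data.edge_matrix, data.behaviour, q)
    df = data.n_subjects - data.n_covariates - 2
    if df < 1:
        raise ValueError("too few subjects for the number of covariates")
    p = _rho_pvalues(rho, df)
    return SelectionMasks(
        p_threshold_pos=p_threshold,
        p_threshold_neg=p_threshold,
        positive_mask=(rho > 0) & (p < p_threshold),
        negative_mask=(rho < 0) & (p < p_threshold),
    )


def network_strength(edge_values, mask) -> float:
    """Sum of a subject's edge values over a boolean mask (0 if empty)."""
    edge_values = np.asarray(edge_values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if edge_values.shape != mask.shape:
        raise ValueError("edge values and mask lengths disagree")
    return float(edge_values[mask].sum())


def fit_strength_model(strengths, behaviour, sign: str = "positive") -> StrengthModel:
    """OLS of behaviour on network strength (slope, intercept).

    Constant strengths give a degenerate model that predicts the training
    mean (slope 0); this is logged, not an error, because empty masks are a
    legitimate outcome of stringent selection thresholds in small samples.
    """
    s = np.asarray(strengths, dtype=float)
    y = np.asarray(behaviour, dtype=float)
    if s.size != y.size:
        raise ValueError("strengths and behaviour lengths disagree")
    if s.size < 3:
        raise ValueError("need at least 3 training subjects")
    if np.ptp(s) == 0:
        logger.warning("constant network strengths: falling back to mean prediction")
        return StrengthModel(0.0, float(y.mean()), sign, degenerate=True)
    sbar, ybar = s.mean(), y.mean()
    slope = float(((s - sbar) @ (y - ybar)) / ((s - sbar) @ (s - sbar)))
    return StrengthModel(slope, float(ybar - slope * sbar), sign)


# ---------------------------------------------------------------------------
# LOOCV engine
# ---------------------------------------------------------------------------


class _Fold:
    __slots__ = ("test_index", "train_idx", "q", "xc", "xn", "train_raw", "test_raw", "df")


class LoocvEngine:
    """Precomputed per-fold state for repeated LOOCV runs on one cohort.

    Everything that does not depend on the behaviour vector — edge ranks
    within each training set, the covariate projection basis, residualized
    ranked edges and their norms — is computed once, so threshold sweeps and
    permutation tests (which only change y) are cheap.
    """

    def __init__(self, data: CohortDataset):
        self.data = data
        n = data.n_subjects
        c = data.n_covariates
        if n - 1 < c + 3:
            raise ValueError(
                f"LOOCV training sets of size {n - 1} are too small for "
                f"{c} covariates (need C + 3)"
            )
        self.folds: list[_Fold] = []
        for i in range(n):
            f = _Fold()
            f.test_index = i
            f.train_idx = np.flatnonzero(np.arange(n) != i)
            f.q = _covariate_basis(data.covariates[f.train_idx])
            f.train_raw = data.edge_matrix[f.train_idx]
            f.test_raw = data.edge_matrix[i]
            ranked = rankdata(f.train_raw, axis=0)
            f.xc = ranked - f.q @ (f.q.T @ ranked)
            f.xn = np.sqrt((f.xc * f.xc).sum(axis=0))
            f.df = (n - 1) - c - 2
            self.folds.append(f)

    # -- per-fold selection statistics ------------------------------------

    def fold_stats(self, fold: _Fold, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(rho, p) of every edge vs y within one training fold."""
        ry = rankdata(y[fold.train_idx])
        yc = ry - fold.q @ (fold.q.T @ ry)
        yn = float(np.sqrt(yc @ yc))
        if yn == 0.0:
            rho = np.zeros(fold.xc.shape[1])
            return rho, np.ones_like(rho)
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = (fold.xc.T @ yc) / (fold.xn * yn)
        rho[~np.isfinite(rho)] = 0.0
        rho = np.clip(rho, -1.0, 1.0)
        return rho, _rho_pvalues(rho, fold.df)

    # -- single-threshold detailed LOOCV -----------------------------------

    def loocv(
        self, y: np.ndarray, p_thr_pos: float, p_thr_neg: float, detailed: bool = False
    ) -> LoocvPrediction:
        n = self.data.n_subjects
        pred_pos = np.empty(n)
        pred_neg = np.empty(n)
        masks: list[SelectionMasks] = []
        models_pos: list[StrengthModel] = []
        models_neg: list[StrengthModel] = []
        rhos = np.empty((n, self.data.n_edges)) if detailed else None
        for k, f in enumerate(self.folds):
            rho, p = self.fold_stats(f, y)
            if detailed:
                rhos[k] = rho
            y_train = y[f.train_idx]
            pos = (rho > 0) & (p < p_thr_pos)
            neg = (rho < 0) & (p < p_thr_neg)
            for sign, mask, out, store in (
                ("positive", pos, pred_pos, models_pos),
                ("negative", neg, pred_neg, models_neg),
            ):
                s_train = f.train_raw[:, mask].sum(axis=1)
                s_test = float(f.test_raw[mask].sum())
                if np.ptp(s_train) == 0:
                    # WARN once per user-facing fit; DEBUG inside permutation loops
                    logger.log(
                        logging.WARNING if detailed else logging.DEBUG,
                        "fold %d (%s network): empty/constant strengths, "
                        "predicting the training mean", f.test_index, sign,
                    )
                    model = StrengthModel(0.0, float(y_train.mean()), sign, degenerate=True)
                else:
                    sbar, ybar = s_train.mean(), y_train.mean()
                    slope = float(
                        ((s_train - sbar) @ (y_train - ybar))
                        / ((s_train - sbar) @ (s_train - sbar))
                    )
                    model = StrengthModel(slope, float(ybar - slope * sbar), sign)
                out[f.test_index] = model.predict(s_test)
                if detailed:
                    store.append(model)
            if detailed:
                masks.append(
                    SelectionMasks(
                        p_threshold_pos=p_thr_pos,
                        p_threshold_neg=p_thr_neg,
                        positive_mask=pos,
                        negative_mask=neg,
                    )
                )
        return LoocvPrediction(
            observed=np.asarray(y, dtype=float).copy(),
            predicted_pos=pred_pos,
            predicted_neg=pred_neg,
            rho_pos=spearman_rho(pred_pos, y),
            rho_neg=spearman_rho(pred_neg, y),
            fold_masks=masks,
            fold_models_pos=models_pos,
            fold_models_neg=models_neg,
            fold_rhos=rhos,
            p_threshold_pos=p_thr_pos,
            p_threshold_neg=p_thr_neg,
        )

    # -- vectorized threshold sweep ----------------------------------------

    def sweep(
        self, y: np.ndarray, thresholds_pos: np.ndarray, thresholds_neg: np.ndarray
    ) -> dict:
        """LOOCV predictions and rho_true at every threshold in one pass.

        Per fold the edges of each sign are sorted by selection p-value; the
        cumulative sums of raw edge values then give every threshold's
        network strengths at once (selection is strict: p < threshold).
        """
        n = self.data.n_subjects
        y = np.asarray(y, dtype=float)
        tp = np.asarray(thresholds_pos, dtype=float)
        tn = np.asarray(thresholds_neg, dtype=float)
        pred_pos = np.empty((n, tp.size))
        pred_neg = np.empty((n, tn.size))
        for f in self.folds:
            rho, p = self.fold_stats(f, y)
            y_train = y[f.train_idx]
            ybar = y_train.mean()
            yc = y_train - ybar
            for sel, thresholds, out in (
                (rho > 0, tp, pred_pos),
                (rho < 0, tn, pred_neg),
            ):
                idx = np.flatnonzero(sel)
                order = idx[np.argsort(p[idx], kind="stable")]
                p_sorted = p[order]
                cum_tr = np.zeros((f.train_raw.shape[0], order.size + 1))
                np.cumsum(f.train_raw[:, order], axis=1, out=cum_tr[:, 1:])
                cum_te = np.concatenate([[0.0], np.cumsum(f.test_raw[order])])
                counts = np.searchsorted(p_sorted, thresholds, side="left")
                s_tr = cum_tr[:, counts]  # n_train x T
                s_te = cum_te[counts]
                sbar = s_tr.mean(axis=0)
                sc = s_tr - sbar
                var = (sc * sc).sum(axis=0)
                degen = np.ptp(s_tr, axis=0) == 0
                with np.errstate(divide="ignore", invalid="ignore"):
                    slope = np.where(degen, 0.0, (sc.T @ yc) / np.where(degen, 1.0, var))
                intercept = ybar - slope * sbar
                out[f.test_index] = slope * s_te + intercept
        return {
            "pos_curve": _col_spearman(pred_pos, y),
            "neg_curve": _col_spearman(pred_neg, y),
            "pred_pos": pred_pos,
            "pred_neg": pred_neg,
        }


def loocv_predict(
    data: CohortDataset, p_thr_pos: float, p_thr_neg: float
) -> LoocvPrediction:
    """Leave-one-out cross-validated CPM prediction at fixed thresholds.

    For each left-out subject, edges are selected and the two strength models
    are fitted on the remaining subjects only; the left-out subject's
    strengths are computed with the training masks and fed through the
    training models.  Returns fold-level masks, models and selection
    correlations along with predictions and rho_true per network sign.
    """
    for thr in (p_thr_pos, p_thr_neg):
        if not 0.0 < thr < 1.0:
            raise ValueError("thresholds must be in (0, 1)")
    return LoocvEngine(data).loocv(data.behaviour, p_thr_pos, p_thr_neg, detailed=True)
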