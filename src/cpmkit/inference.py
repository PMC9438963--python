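"""Threshold tuning, permutation significance and FDR correction.

The selection p-threshold is a free parameter of CPM.  Following common
practice it is tuned by sweeping a fine grid (default 0.0001 to 0.05 in
steps of 0.0001, 500 values) and keeping, independently per network sign,
the threshold whose LOOCV rho_true is largest (ties break to the smallest
threshold).  Because the two networks never interact within a run, a single
sweep yields both curves.

Significance of rho_true is assessed by permutation: the behaviour vector is
reshuffled (covariates stay attached to their subjects' connectomes), the
whole LOOCV is re-run, and

    p_permu = (#{rho_new >= rho_true} + 1) / (n_permutations + 1)

so 5000 permutations give the familiar denominator of 5001 and a smallest
attainable p of 1/5001.

``reoptimize`` controls whether the threshold search is considered part of
the procedure being permuted.  With ``reoptimize=True`` and no explicit
thresholds, both the observed statistic and every permutation statistic are
the grid-maximized rho_true — an exchangeable, exactly calibrated test.
With ``reoptimize=False`` the permutations are run at the supplied (fixed)
thresholds; if those thresholds were themselves tuned on the observed data
the test is optimistic, a bias this module deliberately makes measurable
(see the calibration tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .cpm import CohortDataset, LoocvEngine

__all__ = [
    "ThresholdGrid",
    "ThresholdSearchResult",
    "PermutationResult",
    "ModelSummary",
    "optimize_thresholds",
    "permutation_test",
    "permutation_pvalue",
    "fdr_correct",
]

_SIGNS = ("positive", "negative")


@dataclass
class ThresholdGrid:
    """Ascending inclusive grid of selection p-thresholds.

    Values are generated from integer multiples of the step to avoid
    floating-point accumulation; the default grid has 500 values.
    """

    start: float = 0.0001
    stop: float = 0.05
    step: float = 0.0001

    def __post_init__(self) -> None:
        if not 0 < self.start <= self.stop < 1 or self.step <= 0:
            raise ValueError("need 0 < start <= stop < 1 and step > 0")

    @property
    def values(self) -> np.ndarray:
        k0 = int(round(self.start / self.step))
        k1 = int(round(self.stop / self.step))
        return np.arange(k0, k1 + 1) * self.step

    @classmethod
    def parse(cls, spec: str) -> "ThresholdGrid":
        """Parse ``"start:stop:step"`` (e.g. ``"0.0001:0.05:0.0001"``)."""
        start, stop, step = (float(tok) for tok in spec.split(":"))
        return cls(start=start, stop=stop, step=step)

    def __len__(self) -> int:
        return self.values.size


@dataclass
class ThresholdSearchResult:
    thresholds: np.ndarray
    pos_curve: np.ndarray  # rho_true per threshold, positive network
    neg_curve: np.ndarray
    chosen_p_pos: float
    chosen_p_neg: float

    def curve(self, sign: str) -> np.ndarray:
        return {"positive": self.pos_curve, "negative": self.neg_curve}[sign]

    def chosen(self, sign: str) -> float:
        return {"positive": self.chosen_p_pos, "negative": self.chosen_p_neg}[sign]


@dataclass
class PermutationResult:
    network_sign: str
    n_permutations: int
    rho_true: float
    rho_null: np.ndarray
    p_permu: float
    seed: int
    p_threshold: float | None = None  # None when the threshold was re-optimized
    reoptimize: bool = False


@dataclass
class ModelSummary:
    label: str  # e.g. "dT1_positive"
    rho_true: float
    p_permu: float
    p_corr: float = np.nan
    extras: dict = field(default_factory=dict)


def optimize_thresholds(
    data: CohortDataset, grid: ThresholdGrid | None = None, engine: LoocvEngine | None = None
) -> ThresholdSearchResult:
    """Sweep the threshold grid and return per-network rho_true curves.

    The chosen threshold per network maximizes its curve; exact ties break to
    the smallest threshold.  Raises if every threshold is degenerate
    (constant predictions) for both networks.
    """
    grid = grid or ThresholdGrid()
    engine = engine or LoocvEngine(data)
    t = grid.values
    res = engine.sweep(data.behaviour, t, t)
    pos_dead = (np.ptp(res["pred_pos"], axis=0) == 0).all()
    neg_dead = (np.ptp(res["pred_neg"], axis=0) == 0).all()
    if pos_dead and neg_dead:
        raise ValueError(
            "every fold was degenerate at every threshold; no model can be tuned"
        )
    return ThresholdSearchResult(
        thresholds=t,
        pos_curve=res["pos_curve"],
        neg_curve=res["neg_curve"],
        chosen_p_pos=float(t[int(np.argmax(res["pos_curve"]))]),
        chosen_p_neg=float(t[int(np.argmax(res["neg_curve"]))]),
    )


def permutation_pvalue(rho_true: float, rho_null) -> float:
    """(#{rho_null >= rho_true} + 1) / (N + 1)."""
    rho_null = np.asarray(rho_null, dtype=float)
    return float((int((rho_null >= rho_true).sum()) + 1) / (rho_null.size + 1))


def permutation_test(
    data: CohortDataset,
    n_permutations: int = 5000,
    seed: int = 0,
    p_thr_pos: float | None = None,
    p_thr_neg: float | None = None,
    grid: ThresholdGrid | None = None,
    reoptimize: bool = False,
) -> dict[str, PermutationResult]:
    """Permutation significance of rho_true for both networks.

    Parameters
    ----------
    p_thr_pos, p_thr_neg
        Fixed selection thresholds.  Required when ``reoptimize=False``.
        When ``reoptimize=True`` they are optional: if omitted, the observed
        statistic is itself obtained by grid optimization (the exchangeable,
        exactly calibrated form); if given, the observed statistic is
        computed at these thresholds while permutations still re-optimize
        (a deliberately conservative mixture).
    grid
        Threshold grid for re-optimization (default: the standard 500-point
        grid).  Ignored when ``reoptimize=False``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    engine = LoocvEngine(data)
    y = data.behaviour
    rng = np.random.default_rng(seed)

    if reoptimize:
        grid = grid or ThresholdGrid()
        t = grid.values
        if p_thr_pos is None and p_thr_neg is None:
            obs = engine.sweep(y, t, t)
            rho_true = {
                "positive": float(obs["pos_curve"].max()),
                "negative": float(obs["neg_curve"].max()),
            }
            thr_out = {s: None for s in _SIGNS}
        elif p_thr_pos is not None and p_thr_neg is not None:
            obs = engine.loocv(y, p_thr_pos, p_thr_neg)
            rho_true = {"positive": obs.rho_pos, "negative": obs.rho_neg}
            thr_out = {"positive": p_thr_pos, "negative": p_thr_neg}
        else:
            raise ValueError("give both thresholds or neither")
        null = {s: np.empty(n_permutations) for s in _SIGNS}
        for b in range(n_permutations):
            yb = y[rng.permutation(y.size)]
            res = engine.sweep(yb, t, t)
            null["positive"][b] = res["pos_curve"].max()
            null["negative"][b] = res["neg_curve"].max()
    else:
        if p_thr_pos is None or p_thr_neg is None:
            raise ValueError("fixed thresholds are required when reoptimize=False")
        obs = engine.loocv(y, p_thr_pos, p_thr_neg)
        rho_true = {"positive": obs.rho_pos, "negative": obs.rho_neg}
        thr_out = {"positive": p_thr_pos, "negative": p_thr_neg}
        tp = np.asarray([p_thr_pos])
        tn = np.asarray([p_thr_neg])
        null = {s: np.empty(n_permutations) for s in _SIGNS}
        for b in range(n_permutations):
            yb = y[rng.permutation(y.size)]
            res = engine.sweep(yb, tp, tn)
            null["positive"][b] = res["pos_curve"][0]
            null["negative"][b] = res["neg_curve"][0]

    return {
        sign: PermutationResult(
            network_sign=sign,
            n_permutations=n_permutations,
            rho_true=rho_true[sign],
            rho_null=null[sign],
            p_permu=permutation_pvalue(rho_true[sign], null[sign]),
            seed=seed,
            p_threshold=thr_out[sign],
            reoptimize=reoptimize,
        )
        for sign in _SIGNS
    }


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
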