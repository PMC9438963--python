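"""End-to-end study orchestration.

Runs the full analysis the way the original study was run: compute
post-minus-pre behaviour deltas per contrast (dT1 = 1-month minus baseline,
dT2 = 6-month minus baseline) with listwise exclusion of subjects missing
either score, assemble per-contrast cohorts, tune the selection thresholds
on a grid, fit the LOOCV models, test significance by permutation, correct
the whole family of (contrast x network) p-values with Benjamini-Hochberg,
and write a results bundle:

* ``summary.csv`` — one row per contrast x network sign
* ``predictions_<contrast>.csv`` — observed and predicted scores
* ``consensus_<contrast>_<sign>.csv`` — labelled consensus edges
* ``tuning_<contrast>.json`` — full threshold curves and chosen values
* ``provenance.json`` — config echo, seed, software version

Every file is written via a temporary name and an atomic rename, so an
interrupted run never leaves truncated outputs, and the bundle contains no
timestamps: identical inputs, config and seed reproduce it byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anatomy import consensus_report, generic_node_table, load_node_table
from .cpm import CohortDataset, loocv_predict
from .inference import (
    ModelSummary,
    ThresholdGrid,
    fdr_correct,
    optimize_thresholds,
    permutation_test,
)

logger = logging.getLogger("cpmkit")

__all__ = ["StudyConfig", "StudyResult", "compute_deltas", "run_study"]

COVARIATE_COLUMNS = ["age", "sex", "education"]
_CONTRAST_SCORES = {"dT1": ("ps_t0", "ps_t1"), "dT2": ("ps_t0", "ps_t2")}


@dataclass
class StudyConfig:
    """Serializable description of one full analysis run."""

    edges_csv: str
    pheno_csv: str
    out_dir: str
    covariates: list[str] = field(default_factory=lambda: list(COVARIATE_COLUMNS))
    contrasts: list[str] = field(default_factory=lambda: ["dT1", "dT2"])
    grid: str = "0.0001:0.05:0.0001"
    n_permutations: int = 5000
    seed: int = 0
    reoptimize: bool = False
    node_table: str | None = None  # None -> packaged AAL-116

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class StudyResult:
    summary: pd.DataFrame
    predictions: dict[str, pd.DataFrame]
    consensus: dict[tuple[str, str], pd.DataFrame]
    tuning: dict[str, dict]


def compute_deltas(table: pd.DataFrame, contrasts=("dT1", "dT2")) -> dict[str, pd.DataFrame]:
    """Per-contrast behaviour-change cohorts with listwise exclusion.

    ``table`` needs columns subject_id, ps_t0, ps_t1 (and ps_t2 for dT2) plus
    any covariates; a contrast keeps only subjects with both of its scores
    present and errors if fewer than 4 remain.
    """
    out: dict[str, pd.DataFrame] = {}
    for contrast in contrasts:
        if contrast not in _CONTRAST_SCORES:
            raise ValueError(f"unknown contrast {contrast!r}")
        base, post = _CONTRAST_SCORES[contrast]
        for col in (base, post):
            if col not in table.columns:
                raise ValueError(f"behaviour table lacks column {col!r}")
        keep = table[base].notna() & table[post].notna()
        sub = table.loc[keep].copy()
        if len(sub) < 4:
            raise ValueError(
                f"contrast {contrast}: only {len(sub)} complete subjects (< 4)"
            )
        sub["delta"] = sub[post] - sub[base]
        out[contrast] = sub.reset_index(drop=True)
    return out


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(type(o))


def run_study(config: StudyConfig) -> StudyResult:
    """Execute the configured analysis and write the results bundle."""
    edges = pd.read_csv(config.edges_csv, index_col="subject_id")
    pheno = pd.read_csv(config.pheno_csv)
    if "subject_id" not in pheno.columns:
        raise ValueError("behaviour table needs a subject_id column")

    missing_edges = sorted(set(pheno["subject_id"]) - set(edges.index))
    missing_pheno = sorted(set(edges.index) - set(pheno["subject_id"]))
    if missing_edges or missing_pheno:
        raise ValueError(
            "subject-ID mismatch between files: "
            f"missing from edges {missing_edges}; missing from pheno {missing_pheno}"
        )

    grid = ThresholdGrid.parse(config.grid)
    n_nodes = int(round((1 + np.sqrt(1 + 8 * edges.shape[1])) / 2))
    if n_nodes * (n_nodes - 1) // 2 != edges.shape[1]:
        raise ValueError(f"{edges.shape[1]} edge columns is not a triangular number")
    if config.node_table is not None or n_nodes == 116:
        nodes = load_node_table(config.node_table)
        if len(nodes) != n_nodes:
            raise ValueError(
                f"node table has {len(nodes)} rows but edges imply {n_nodes} nodes"
            )
    else:
        nodes = generic_node_table(n_nodes)
    deltas = compute_deltas(pheno, contrasts=config.contrasts)

    summaries: list[ModelSummary] = []
    predictions: dict[str, pd.DataFrame] = {}
    consensus: dict[tuple[str, str], pd.DataFrame] = {}
    tuning: dict[str, dict] = {}

    for ci, contrast in enumerate(config.contrasts):
        sub = deltas[contrast]
        data = CohortDataset(
            subject_ids=list(sub["subject_id"]),
            edge_matrix=edges.loc[sub["subject_id"]].to_numpy(dtype=float),
            behaviour=sub["delta"].to_numpy(dtype=float),
            covariates=sub[config.covariates].to_numpy(dtype=float)
            if config.covariates
            else None,
        )
        logger.info("contrast %s: n=%d subjects, E=%d edges",
                    contrast, data.n_subjects, data.n_edges)
        search = optimize_thresholds(data, grid)
        fit = loocv_predict(data, search.chosen_p_pos, search.chosen_p_neg)
        perm_seed = int((config.seed + 1000003 * (ci + 1)) % (2**31 - 1))
        if config.reoptimize:
            perms = permutation_test(
                data, n_permutations=config.n_permutations, seed=perm_seed,
                grid=grid, reoptimize=True,
            )
        else:
            perms = permutation_test(
                data, n_permutations=config.n_permutations, seed=perm_seed,
                p_thr_pos=search.chosen_p_pos, p_thr_neg=search.chosen_p_neg,
                reoptimize=False,
            )

        for sign in ("positive", "negative"):
            summaries.append(
                ModelSummary(
                    label=f"{contrast}_{sign}",
                    rho_true=perms[sign].rho_true,
                    p_permu=perms[sign].p_permu,
                    extras={
                        "contrast": contrast,
                        "network": sign,
                        "n_subjects": data.n_subjects,
                        "p_threshold": search.chosen(sign),
                        "rho_loocv": fit.rho_true(sign),
                    },
                )
            )

        predictions[contrast] = pd.DataFrame(
            {
                "subject_id": data.subject_ids,
                "observed": data.behaviour,
                "predicted_positive": fit.predicted_pos,
                "predicted_negative": fit.predicted_neg,
            }
        )
        report = consensus_report(fit, nodes)
        for sign in ("positive", "negative"):
            consensus[(contrast, sign)] = report[sign]
        tuning[contrast] = {
            "thresholds": search.thresholds,
            "pos_curve": search.pos_curve,
            "neg_curve": search.neg_curve,
            "chosen_p_pos": search.chosen_p_pos,
            "chosen_p_neg": search.chosen_p_neg,
        }

    p_corr = fdr_correct([s.p_permu for s in summaries])
    for s, pc in zip(summaries, p_corr):
        s.p_corr = float(pc)

    summary = pd.DataFrame(
        {
            "contrast": [s.extras["contrast"] for s in summaries],
            "network": [s.extras["network"] for s in summaries],
            "n_subjects": [s.extras["n_subjects"] for s in summaries],
            "p_threshold": [s.extras["p_threshold"] for s in summaries],
            "rho_true": [s.rho_true for s in summaries],
            "p_permu": [s.p_permu for s in summaries],
            "p_corr": [s.p_corr for s in summaries],
        }
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _atomic_write(out / "summary.csv", summary.to_csv(index=False))
    for contrast, pred in predictions.items():
        _atomic_write(out / f"predictions_{contrast}.csv", pred.to_csv(index=False))
    for (contrast, sign), table in consensus.items():
        _atomic_write(out / f"consensus_{contrast}_{sign}.csv", table.to_csv(index=False))
    for contrast, tune in tuning.items():
        _atomic_write(
            out / f"tuning_{contrast}.json",
            json.dumps(tune, default=_json_default, sort_keys=True, indent=1),
        )
    provenance = {
        "config": config.to_dict(),
        "software": {"package": "cpmkit", "version": __version__},
        "n_per_contrast": {c: int(len(deltas[c])) for c in config.contrasts},
        "permutation_scope": (
            "threshold search re-run inside each permutation"
            if config.reoptimize
            else "permutations at the observed-data thresholds; note that "
            "thresholds tuned on the observed data make this optimistic"
        ),
    }
    _atomic_write(
        out / "provenance.json",
        json.dumps(provenance, default=_json_default, sort_keys=True, indent=1),
    )
    return StudyResult(
        summary=summary, predictions=predictions, consensus=consensus, tuning=tuning
    )
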