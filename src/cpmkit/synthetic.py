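"""Synthetic cohorts with planted brain-behaviour signal.

Real cohorts for this kind of study are small (around 9-20 subjects) and
private, so every stage of the pipeline is exercised against generated data
with known ground truth.  A cohort consists of

* an ``n_subjects x E`` matrix of correlation-valued edges (E = n*(n-1)/2
  for an n-node parcellation; 6670 edges for AAL-116),
* a continuous behaviour change score (a post-minus-pre delta, may be
  negative),
* three nuisance covariates (age in years, sex coded 0/1, education years).

Edges are generated directly in edge space rather than via a latent time
series: background edges are i.i.d. tanh-transformed Gaussians (bounded in
(-1, 1)), and a chosen subset of *signal* edges additionally shares a
subject-level latent factor, so that the planted edges covary like a small
network.  The behaviour score is a linear function of the *stored* signal
edge values plus covariate effects plus Gaussian noise, which makes exact
recovery oracles possible (at ``noise_sd=0`` an OLS regression of behaviour
on the true signal edges returns the planted coefficients to numerical
precision).

:func:`generate_timeseries` exists separately for end-to-end tests of
connectivity construction: it draws multivariate-Gaussian BOLD-like series
whose population correlation equals a requested target matrix (the default
scan length of 155 volumes mirrors a 160-volume acquisition with the first
five discarded).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .connectome import n_edges, edge_ids

DEFAULT_EDGE_MEAN = 0.15  # pre-tanh mean, typical resting-state edge level
DEFAULT_EDGE_SD = 0.30  # pre-tanh spread
DEFAULT_LATENT_SHARE = 0.5  # variance share of the common factor in signal edges
SEX_FEMALE_PROB = 9.0 / 12.0  # cohort sex ratio being emulated

__all__ = [
    "SyntheticTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_null_cohort",
    "regenerate_cohort",
    "calibrate_noise_sd",
    "generate_timeseries",
    "generate_motion_trace",
    "write_cohort",
    "read_cohort",
]


@dataclass
class SyntheticTruth:
    """Everything needed to reproduce a cohort and score recovery against it."""

    n_subjects: int
    n_nodes: int
    signal_edges: list[int]
    edge_effects: list[float]
    covariate_effects: list[float]
    noise_sd: float
    effect_scale: float
    latent_share: float
    edge_mean: float
    edge_sd: float
    seed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        return cls(**json.loads(text))


@dataclass
class SyntheticCohort:
    subject_ids: list[str]
    edge_matrix: np.ndarray  # n_subjects x E, values in (-1, 1)
    behaviour: np.ndarray  # n_subjects
    covariates: pd.DataFrame  # columns: age, sex, education
    truth: SyntheticTruth

    @property
    def n_subjects(self) -> int:
        return self.edge_matrix.shape[0]

    def to_dataset(self):
        """Package as a :class:`cpmkit.cpm.CohortDataset` for modelling."""
        from .cpm import CohortDataset

        return CohortDataset(
            subject_ids=list(self.subject_ids),
            edge_matrix=self.edge_matrix,
            behaviour=self.behaviour,
            covariates=self.covariates.to_numpy(dtype=float),
        )


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    age = rng.uniform(23.0, 50.0, size=n)
    sex = rng.binomial(1, SEX_FEMALE_PROB, size=n).astype(float)
    education = rng.integers(9, 20, size=n).astype(float)
    return pd.DataFrame({"age": age, "sex": sex, "education": education})


def generate_cohort(
    n_subjects: int,
    n_nodes: int,
    n_signal_edges: int,
    effect_scale: float,
    noise_sd: float,
    seed: int,
    covariate_effects=(0.0, 0.0, 0.0),
    latent_share: float = DEFAULT_LATENT_SHARE,
    edge_mean: float = DEFAULT_EDGE_MEAN,
    edge_sd: float = DEFAULT_EDGE_SD,
) -> SyntheticCohort:
    """Generate a cohort with ``n_signal_edges`` planted behaviour-coupled edges.

    The signal edges receive equal positive coefficients ``effect_scale`` and
    share a subject-level latent factor (``latent_share`` of their pre-bound
    variance), so they behave like a coherent network rather than independent
    features.  Behaviour is linear in the stored (bounded) edge values::

        behaviour = edges[:, signal] @ effects + covariates @ covariate_effects
                    + N(0, noise_sd)

    All randomness flows through one ``numpy.random.default_rng(seed)``;
    identical arguments give a bit-identical cohort.
    """
    E = n_edges(n_nodes)
    if n_subjects < 4:
        raise ValueError("n_subjects must be >= 4 (LOOCV is undefined below this)")
    if not 0 <= n_signal_edges <= E:
        raise ValueError(f"n_signal_edges must be in [0, {E}]")
    if not np.isfinite(effect_scale):
        raise ValueError("effect_scale must be finite")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0.0 <= latent_share <= 1.0:
        raise ValueError("latent_share must be in [0, 1]")
    covariate_effects = np.asarray(covariate_effects, dtype=float)
    if covariate_effects.shape != (3,):
        raise ValueError("covariate_effects must have length 3 (age, sex, education)")

    rng = np.random.default_rng(seed)
    signal = np.sort(rng.choice(E, size=n_signal_edges, replace=False))

    z = rng.standard_normal((n_subjects, E))
    if n_signal_edges:
        latent = rng.standard_normal(n_subjects)
        z[:, signal] = (
            np.sqrt(latent_share) * latent[:, None]
            + np.sqrt(1.0 - latent_share) * z[:, signal]
        )
    edge_matrix = np.tanh(edge_mean + edge_sd * z)

    covariates = _draw_covariates(rng, n_subjects)
    effects = np.full(n_signal_edges, float(effect_scale))
    behaviour = (
        edge_matrix[:, signal] @ effects
        + covariates.to_numpy(dtype=float) @ covariate_effects
        + rng.normal(0.0, noise_sd, size=n_subjects)
    )

    truth = SyntheticTruth(
        n_subjects=n_subjects,
        n_nodes=n_nodes,
        signal_edges=[int(k) for k in signal],
        edge_effects=[float(a) for a in effects],
        covariate_effects=[float(c) for c in covariate_effects],
        noise_sd=float(noise_sd),
        effect_scale=float(effect_scale),
        latent_share=float(latent_share),
        edge_mean=float(edge_mean),
        edge_sd=float(edge_sd),
        seed=int(seed),
    )
    ids = [f"S{k + 1:03d}" for k in range(n_subjects)]
    return SyntheticCohort(
        subject_ids=ids,
        edge_matrix=edge_matrix,
        behaviour=behaviour,
        covariates=covariates,
        truth=truth,
    )


def generate_null_cohort(
    n_subjects: int, n_nodes: int, seed: int, noise_sd: float = 1.0
) -> SyntheticCohort:
    """Cohort with no planted signal: behaviour is pure noise."""
    return generate_cohort(
        n_subjects=n_subjects,
        n_nodes=n_nodes,
        n_signal_edges=0,
        effect_scale=0.0,
        noise_sd=noise_sd,
        seed=seed,
        covariate_effects=(0.0, 0.0, 0.0),
    )


def regenerate_cohort(truth: SyntheticTruth) -> SyntheticCohort:
    """Rebuild the exact cohort a :class:`SyntheticTruth` came from."""
    cohort = generate_cohort(
        n_subjects=truth.n_subjects,
        n_nodes=truth.n_nodes,
        n_signal_edges=len(truth.signal_edges),
        effect_scale=truth.effect_scale,
        noise_sd=truth.noise_sd,
        seed=truth.seed,
        covariate_effects=truth.covariate_effects,
        latent_share=truth.latent_share,
        edge_mean=truth.edge_mean,
        edge_sd=truth.edge_sd,
    )
    return cohort


def calibrate_noise_sd(
    n_signal_edges: int,
    effect_scale: float,
    target_r2: float,
    latent_share: float = DEFAULT_LATENT_SHARE,
    edge_mean: float = DEFAULT_EDGE_MEAN,
    edge_sd: float = DEFAULT_EDGE_SD,
    n_sample: int = 20000,
    seed: int = 0,
) -> float:
    """Noise level giving a requested population R^2 for the planted signal.

    R^2 is defined as var(signal combination) / (var(signal) + noise^2),
    covariate effects aside.  The signal variance under the tanh bound has no
    closed form, so it is estimated from a large Monte-Carlo sample (the
    estimate is deterministic given ``seed``).
    """
    if not 0.0 < target_r2 < 1.0:
        raise ValueError("target_r2 must be in (0, 1)")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_sample, n_signal_edges))
    latent = rng.standard_normal(n_sample)
    z = np.sqrt(latent_share) * latent[:, None] + np.sqrt(1.0 - latent_share) * z
    x = np.tanh(edge_mean + edge_sd * z)
    combo = x @ np.full(n_signal_edges, float(effect_scale))
    v = float(combo.var())
    return float(np.sqrt(v * (1.0 - target_r2) / target_r2))


def generate_timeseries(
    n_volumes: int,
    n_nodes: int,
    target_connectivity=None,
    seed: int = 0,
) -> np.ndarray:
    """Gaussian parcel time series with a given population correlation.

    ``target_connectivity`` may be a :class:`~cpmkit.connectome.ConnectivityMatrix`
    or a plain square array; ``None`` means independent nodes (identity
    target).  A target that is not positive semi-definite is projected to the
    nearest correlation-compatible PSD matrix (eigenvalue clipping followed by
    re-standardisation); a warning records that this was done.
    """
    if target_connectivity is None:
        target = np.eye(n_nodes)
    else:
        target = np.asarray(getattr(target_connectivity, "values", target_connectivity), float)
        if target.shape != (n_nodes, n_nodes):
            raise ValueError("target connectivity shape does not match n_nodes")
    if n_volumes < n_nodes + 1:
        warnings.warn(
            "n_volumes < n_nodes + 1: the sample correlation matrix will be "
            "rank-deficient",
            stacklevel=2,
        )
    w, v = np.linalg.eigh((target + target.T) / 2.0)
    if w.min() < -1e-10:
        warnings.warn(
            "target connectivity is not positive semi-definite; projected to "
            "the nearest PSD correlation matrix",
            stacklevel=2,
        )
        w = np.clip(w, 0.0, None)
        target = (v * w) @ v.T
        d = np.sqrt(np.diag(target))
        target = target / np.outer(d, d)
        np.fill_diagonal(target, 1.0)
        w, v = np.linalg.eigh(target)
    rng = np.random.default_rng(seed)
    # explicit eigen factorization keeps draws reproducible and PSD-safe
    root = v * np.sqrt(np.clip(w, 0.0, None))
    ts = rng.standard_normal((n_volumes, n_nodes)) @ root.T
    return ts


def generate_motion_trace(
    n_volumes: int, spike_fraction: float, seed: int = 0
) -> np.ndarray:
    """Volumes x 6 rigid-body motion trace (mm, mm, mm, rad, rad, rad).

    A smooth bounded random walk keeps baseline FD well below the 0.5 mm
    spike threshold; sustained 0.8 mm translation steps are injected at
    approximately ``spike_fraction`` of the volumes (alternating sign so the
    absolute position stays small).
    """
    if not 0.0 <= spike_fraction <= 1.0:
        raise ValueError("spike_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    steps = np.empty((n_volumes - 1, 6))
    steps[:, 0:3] = rng.uniform(-0.02, 0.02, size=(n_volumes - 1, 3))
    steps[:, 3:6] = rng.uniform(-1e-4, 1e-4, size=(n_volumes - 1, 3))
    n_spikes = int(round(spike_fraction * (n_volumes - 1)))
    if n_spikes:
        where = rng.choice(n_volumes - 1, size=n_spikes, replace=False)
        signs = np.where(np.arange(n_spikes) % 2 == 0, 1.0, -1.0)
        steps[np.sort(where), 0] += 0.8 * signs
    motion = np.vstack([np.zeros(6), np.cumsum(steps, axis=0)])
    return motion


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write edges CSV, behaviour+covariates CSV and truth JSON to a directory."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    edges = pd.DataFrame(
        cohort.edge_matrix,
        index=pd.Index(cohort.subject_ids, name="subject_id"),
        columns=edge_ids(cohort.truth.n_nodes),
    )
    edges.to_csv(out / "edges.csv")
    pheno = pd.DataFrame(
        {
            "subject_id": cohort.subject_ids,
            "delta_ps": cohort.behaviour,
            "age": cohort.covariates["age"].to_numpy(),
            "sex": cohort.covariates["sex"].to_numpy(),
            "education": cohort.covariates["education"].to_numpy(),
        }
    )
    pheno.to_csv(out / "pheno.csv", index=False)
    (out / "truth.json").write_text(cohort.truth.to_json())


def read_cohort(indir) -> SyntheticCohort:
    """Inverse of :func:`write_cohort`."""
    from pathlib import Path

    ind = Path(indir)
    edges = pd.read_csv(ind / "edges.csv", index_col="subject_id")
    pheno = pd.read_csv(ind / "pheno.csv")
    truth = SyntheticTruth.from_json((ind / "truth.json").read_text())
    return SyntheticCohort(
        subject_ids=list(edges.index),
        edge_matrix=edges.to_numpy(dtype=float),
        behaviour=pheno["delta_ps"].to_numpy(dtype=float),
        covariates=pheno[["age", "sex", "education"]].copy(),
        truth=truth,
    )
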