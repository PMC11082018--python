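"""Synthetic questionnaire cohorts with known conditional-dependence truth.

The real study data (256 glioma patients, 420 assessments of 21 subscale
scores) cannot be shared, so every downstream stage is exercised on
synthetic cohorts drawn from a known sparse Gaussian graphical model:
latent scores are multivariate normal with a correlation-scaled precision
matrix whose off-diagonal support is a random graph, and observed subscale
scores are the latent values discretized to each instrument's bounded
Likert-like grid by equal-probability quantile cuts of the standard normal.

Repeated assessments of one patient are sampled independently given the
patient's generating network; the estimators treat assessments
cross-sectionally, so no within-patient correlation model is imposed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ggm import precision_to_partial
from .instruments import (
    META_COLUMNS,
    NODE_LABELS_21,
    SCORE_SCALES,
    TUMOR_GRADES,
)

#: Cohort composition defaults emulating the study conditions: 256 patients,
#: ~420 assessments (mean 1.64 per patient), grades II/III/IV at 47/25/28%,
#: about 40% of assessments preoperative, progression rare.
ASSESSMENT_COUNT_PROBS: dict[int, float] = {1: 0.50, 2: 0.36, 3: 0.14}
GRADE_PROBS: tuple[float, ...] = (0.47, 0.25, 0.28)
FIRST_PREOP_PROB = 0.65
POSTOP_STATUS_PROBS: dict[str, float] = {
    "active_treatment": 0.42, "stable": 0.48, "progression": 0.10,
}


@dataclass
class GroundTruthNetwork:
    """Data-generating precision matrix and its implied partial correlations."""

    labels: list[str]
    precision: np.ndarray
    partials: np.ndarray
    seed: int

    def covariance(self) -> np.ndarray:
        cov = np.linalg.inv(self.precision)
        return 0.5 * (cov + cov.T)

    def edge_count(self, tol: float = 1e-12) -> int:
        iu = np.triu_indices(len(self.labels), k=1)
        return int((np.abs(self.partials[iu]) > tol).sum())

    def global_strength(self) -> float:
        iu = np.triu_indices(len(self.labels), k=1)
        return float(np.abs(self.partials[iu]).sum())

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "labels": list(self.labels),
                    "precision": self.precision.tolist(),
                    "partials": self.partials.tolist(),
                    "seed": int(self.seed),
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "GroundTruthNetwork":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            labels=list(d["labels"]),
            precision=np.asarray(d["precision"], dtype=float),
            partials=np.asarray(d["partials"], dtype=float),
            seed=int(d["seed"]),
        )


@dataclass(frozen=True)
class SimConfig:
    """Cohort-generator settings; defaults emulate the study conditions."""

    n_patients: int = 256
    assessment_probs: dict[int, float] = field(
        default_factory=lambda: dict(ASSESSMENT_COUNT_PROBS)
    )
    p_nodes: int = 21
    edge_density: float = 0.30
    weight_range: tuple[float, float] = (0.05, 0.35)
    signs: str = "random"
    likert: bool = True
    missing_rate: float = 0.0
    subgroup_effect: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.edge_density <= 1.0:
            raise ValueError("edge_density must be in [0, 1]")
        lo, hi = self.weight_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("weight_range must satisfy 0 <= low <= high < 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if abs(sum(self.assessment_probs.values()) - 1.0) > 1e-9:
            raise ValueError("assessment_probs must sum to 1")


def _support_and_weights(p: int, edge_density: float,
                         weight_range: tuple[float, float], signs: str,
                         rng: np.random.Generator) -> np.ndarray:
    """Upper-triangle draw of the signed target partial correlations.

    Kept as a separate step so tests can re-simulate the support draw
    independently of the positive-definiteness construction.
    """
    iu = np.triu_indices(p, k=1)
    m = iu[0].size
    present = rng.random(m) < edge_density
    mags = rng.uniform(weight_range[0], weight_range[1], size=m)
    if signs == "positive":
        sgn = np.ones(m)
    else:
        sgn = rng.choice([-1.0, 1.0], size=m)
    w = np.zeros((p, p))
    w[iu] = present * mags * sgn
    return w + w.T


def generate_ggm(p: int, edge_density: float,
                 weight_range: tuple[float, float], seed: int,
                 signs: str = "random",
                 labels: list[str] | None = None) -> GroundTruthNetwork:
    """Generate a random sparse GGM with partials of known support.

    The precision matrix starts as I with off-diagonals -w_ij (so the
    implied partials equal the drawn weights when the matrix is already
    positive definite); if needed, |min eigenvalue| + 0.1 is added to the
    diagonal and the matrix is rescaled to a correlation-implied precision,
    which preserves the support and the relative weights.
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    if not 0.0 <= edge_density <= 1.0:
        raise ValueError("edge_density must be in [0, 1]")
    lo, hi = weight_range
    if lo > hi:
        raise ValueError("empty weight_range")
    rng = np.random.default_rng(seed)
    w = _support_and_weights(p, edge_density, weight_range, signs, rng)
    return _ggm_from_partials(w, seed, labels)


def _ggm_from_partials(w: np.ndarray, seed: int,
                       labels: list[str] | None = None) -> GroundTruthNetwork:
    p = w.shape[0]
    theta = np.eye(p) - w
    eig_min = float(np.linalg.eigvalsh(theta)[0])
    if eig_min < 0.05:
        theta = theta + (abs(eig_min) + 0.1) * np.eye(p)
    # rescale so the implied covariance is a correlation matrix; partial
    # correlations are invariant to this diagonal scaling
    cov = np.linalg.inv(theta)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    precision = np.linalg.inv(corr)
    precision = 0.5 * (precision + precision.T)
    if labels is None:
        labels = (list(NODE_LABELS_21) if p == 21
                  else [f"V{i + 1}" for i in range(p)])
    return GroundTruthNetwork(
        labels=list(labels), precision=precision,
        partials=precision_to_partial(precision), seed=int(seed),
    )


def scale_edges(truth: GroundTruthNetwork, factor: float) -> GroundTruthNetwork:
    """Ground truth with every partial correlation multiplied by `factor`.

    Used to build subgroup alternatives with a known global-strength ratio
    (exact as long as the scaled matrix needs no positive-definiteness
    repair).
    """
    return _ggm_from_partials(truth.partials * factor, truth.seed,
                              labels=list(truth.labels))


def _likert_spec_for(labels: list[str]) -> dict[str, tuple[float, float, int]]:
    return {
        lab: SCORE_SCALES.get(lab, (0.0, 100.0, 21)) for lab in labels
    }


def discretize_column(z: np.ndarray, lo: float, hi: float,
                      levels: int) -> np.ndarray:
    """Map standard-normal latents onto an equally spaced bounded score grid
    via equal-probability quantile cuts."""
    if levels < 2:
        raise ValueError("need >= 2 levels")
    cuts = stats.norm.ppf(np.arange(1, levels) / levels)
    idx = np.searchsorted(cuts, z, side="right")
    return lo + idx * (hi - lo) / (levels - 1)


def sample_observations(truth: GroundTruthNetwork, n: int,
                        likert: bool | dict = False,
                        seed: int = 0) -> pd.DataFrame:
    """Draw n assessments from the truth's latent Gaussian.

    likert=False returns the continuous latents; likert=True uses the
    instrument score grids for the canonical labels (0-100/21-level for
    unknown labels); a dict maps label -> (low, high, levels).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cov = truth.covariance()
    eig_min = float(np.linalg.eigvalsh(cov)[0])
    if eig_min <= 0:
        raise ValueError("truth precision is not positive definite")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(cov)
    Z = rng.standard_normal((n, cov.shape[0])) @ L.T
    if likert is False:
        return pd.DataFrame(Z, columns=truth.labels)
    spec = _likert_spec_for(truth.labels) if likert is True else dict(likert)
    X = np.empty_like(Z)
    for j, lab in enumerate(truth.labels):
        lo, hi, levels = spec[lab]
        X[:, j] = discretize_column(Z[:, j], lo, hi, levels)
    return pd.DataFrame(X, columns=truth.labels)


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Generate a long-format assessment table emulating the study cohort.

    Each patient has 1-3 assessments; the first is preoperative with
    probability ~0.65, later ones are postoperative (active treatment,
    stable, or rarely progression). Tumor grade is a patient-level label.
    If subgroup_effect != 1, postoperative (active_treatment/stable)
    assessments are drawn from a network with all edge weights multiplied
    by the effect, enabling power and type-I studies of the global-strength
    comparison.
    """
    ss = np.random.SeedSequence(config.seed)
    child = ss.spawn(2)
    truth = generate_ggm(config.p_nodes, config.edge_density,
                         config.weight_range, seed=config.seed,
                         signs=config.signs)
    alt = (scale_edges(truth, config.subgroup_effect)
           if config.subgroup_effect != 1.0 else truth)
    rng = np.random.default_rng(child[0])

    counts = sorted(config.assessment_probs)
    probs = [config.assessment_probs[k] for k in counts]
    post_statuses = list(POSTOP_STATUS_PROBS)
    post_probs = list(POSTOP_STATUS_PROBS.values())

    rows: list[dict] = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        grade = rng.choice(TUMOR_GRADES, p=GRADE_PROBS)
        n_assess = int(rng.choice(counts, p=probs))
        for t in range(n_assess):
            if t == 0 and rng.random() < FIRST_PREOP_PROB:
                status = "preoperative"
            else:
                status = str(rng.choice(post_statuses, p=post_probs))
            rows.append({
                "patient_id": pid,
                "assessment_id": f"{pid}-A{t + 1}",
                "timepoint": t + 1,
                "disease_status": status,
                "tumor_grade": str(grade),
            })
    meta = pd.DataFrame(rows, columns=list(META_COLUMNS))

    # latent scores: base network everywhere, effect network for the
    # postoperative (non-progression) assessments
    n_total = len(meta)
    sample_rng = np.random.default_rng(child[1])
    Lb = np.linalg.cholesky(truth.covariance())
    La = np.linalg.cholesky(alt.covariance())
    raw = sample_rng.standard_normal((n_total, config.p_nodes))
    is_alt = meta["disease_status"].isin(["active_treatment", "stable"]).to_numpy()
    Z = np.where(is_alt[:, None], raw @ La.T, raw @ Lb.T)

    spec = _likert_spec_for(truth.labels)
    X = np.empty_like(Z)
    for j, lab in enumerate(truth.labels):
        if config.likert:
            lo, hi, levels = spec[lab]
            X[:, j] = discretize_column(Z[:, j], lo, hi, levels)
        else:
            X[:, j] = Z[:, j]
    if config.missing_rate > 0:
        mask = sample_rng.random(X.shape) < config.missing_rate
        X[mask] = np.nan

    scores = pd.DataFrame(X, columns=truth.labels)
    return pd.concat([meta, scores], axis=1)


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
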