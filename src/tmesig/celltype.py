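"""Cell-type signature pipeline.

Stability selection for compartment-specific cell-type signatures: repeated
ten-fold splits of the training cohort, one sign-constrained LASSO-Cox model
per split at the split's cross-validated penalty, retention of cell types
selected in at least t of the M models (t chosen as the largest threshold
keeping at least ``min_features`` types), a final sign-constrained
unpenalized Cox refit, frozen median/upper-tertile cutpoints, and
evaluation by dichotomized hazard ratios with two-sided (discovery) or
one-sided (validation) log-rank tests.

Resistance signatures constrain coefficients to be non-negative (HR > 1 per
feature); response signatures to be non-positive.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .survival import (CoxFit, LassoConfig, SurvivalData, cv_lambda,
                       fit_constrained_lasso_cox, fit_cox, hazard_ratio,
                       km_estimate, logrank_test)
from .synthetic import FeatureMatrix

__all__ = [
    "CelltypePipelineConfig",
    "SelectionTally",
    "SignatureModel",
    "EvaluationResult",
    "direction_sign",
    "run_split_models",
    "select_features",
    "finalize_signature",
    "score_patients",
    "evaluate_signature",
    "univariable_cell_scan",
    "train_celltype_signature",
]

Direction = Literal["resistance", "response"]


def direction_sign(direction: Direction) -> str:
    if direction == "resistance":
        return "nonnegative"
    if direction == "response":
        return "nonpositive"
    raise ValueError(f"unknown direction: {direction}")


@dataclass
class CelltypePipelineConfig:
    n_models: int = 100  # M: 100 for tumor, 50 for stroma
    direction: Direction = "resistance"
    min_features: int = 3
    n_folds: int = 10
    cutpoint_rule: Literal["median", "upper_tertile"] = "median"
    seed: int = 0

    def __post_init__(self):
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.min_features < 1:
            raise ValueError("min_features must be >= 1")


@dataclass
class SelectionTally:
    counts: Dict[str, int]
    n_models: int

    def __post_init__(self):
        for f, c in self.counts.items():
            if not 0 <= c <= self.n_models:
                raise ValueError(f"count for {f} outside [0, M]")

    @property
    def all_zero(self) -> bool:
        return all(c == 0 for c in self.counts.values())


@dataclass
class SignatureModel:
    """A trained linear risk signature with a frozen cutpoint.

    score_i = sum_j beta_j * M_ij over the model's features; patients with
    score strictly above ``cutpoint_value`` form the high group (ties go to
    the low group).
    """

    features: List[str]
    coefficients: Dict[str, float]
    direction: Direction
    cutpoint_rule: str
    cutpoint_value: float
    compartment: str = "tumor"
    kind: str = "celltype"
    training_provenance: Dict = field(default_factory=dict)
    converged: bool = True

    def __post_init__(self):
        sgn = direction_sign(self.direction)
        for f, b in self.coefficients.items():
            if sgn == "nonnegative" and b < 0:
                raise ValueError(f"coefficient for {f} violates resistance sign")
            if sgn == "nonpositive" and b > 0:
                raise ValueError(f"coefficient for {f} violates response sign")

    def to_json(self) -> str:
        payload = {
            "features": self.features,
            "coefficients": self.coefficients,
            "direction": self.direction,
            "cutpoint_rule": self.cutpoint_rule,
            "cutpoint_value": self.cutpoint_value,
            "compartment": self.compartment,
            "kind": self.kind,
            "training_provenance": self.training_provenance,
            "converged": self.converged,
        }
        return json.dumps(payload, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SignatureModel":
        d = json.loads(text)
        return cls(features=d["features"], coefficients=d["coefficients"],
                   direction=d["direction"], cutpoint_rule=d["cutpoint_rule"],
                   cutpoint_value=d["cutpoint_value"],
                   compartment=d.get("compartment", "tumor"),
                   kind=d.get("kind", "celltype"),
                   training_provenance=d.get("training_provenance", {}),
                   converged=d.get("converged", True))


def _config_hash(cfg) -> str:
    blob = json.dumps({k: (v if np.isscalar(v) or isinstance(v, (str, list))
                           else str(v))
                       for k, v in vars(cfg).items()}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# stability selection
# ---------------------------------------------------------------------------


def run_split_models(matrix: FeatureMatrix, surv: SurvivalData,
                     config: CelltypePipelineConfig
                     ) -> Tuple[SelectionTally, List[Dict[str, float]]]:
    """M repeated fits: each split draws fresh ten folds, selects lambda by
    cross-validated deviance, then fits one sign-constrained LASSO-Cox model
    on the pooled training cohort at that lambda.

    Returns the per-feature nonzero tally and the M coefficient sets.
    """
    feats = matrix.feature_names
    if list(matrix.data.index) != list(surv.patient_id):
        raise ValueError("feature matrix and survival data are not aligned")
    if len(feats) < config.min_features:
        raise ValueError("fewer features than min_features")
    if surv.n_events < config.n_folds:
        raise ValueError("events fewer than n_folds")
    sgn = direction_sign(config.direction)
    counts = {f: 0 for f in feats}
    coef_sets: List[Dict[str, float]] = []
    X = matrix.data
    for m in range(config.n_models):
        lcfg = LassoConfig(sign=sgn, n_folds=config.n_folds,
                           seed=int(np.random.SeedSequence(
                               [config.seed, 11, m]).generate_state(1)[0] % (2**31)))
        cv = cv_lambda(X, surv, lcfg)
        fit = fit_constrained_lasso_cox(X, surv, cv.lambda_min, lcfg)
        coefs = {f: float(b) for f, b in fit.coefficients.items()}
        coef_sets.append(coefs)
        for f, b in coefs.items():
            if b != 0.0:
                counts[f] += 1
    tally = SelectionTally(counts, config.n_models)
    if tally.all_zero:
        warnings.warn("every split produced an empty model", stacklevel=2)
    return tally, coef_sets


def select_features(tally: SelectionTally, min_features: int = 3
                    ) -> Tuple[List[str], int]:
    """Consistency-threshold retention: t is the largest count such that at
    least ``min_features`` features reach it; returns (features, t).

    If fewer than ``min_features`` features were ever selected, returns all
    ever-selected features with a warning (degenerate path).
    """
    if not tally.counts:
        raise ValueError("empty tally")
    items = sorted(tally.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    counts_desc = [c for _, c in items]
    ever = [f for f, c in items if c > 0]
    if len(ever) < min_features:
        warnings.warn(
            f"only {len(ever)} features ever selected; returning all of them",
            stacklevel=2)
        t = min((c for c in counts_desc if c > 0), default=0)
        return ever, t
    t = counts_desc[min_features - 1]
    retained = [f for f, c in items if c >= t]
    return retained, t


def _cutpoint(scores: np.ndarray, rule: str) -> float:
    if rule == "median":
        return float(np.median(scores))
    if rule == "upper_tertile":
        return float(np.percentile(scores, 100 * 2 / 3, method="linear"))
    raise ValueError(f"unknown cutpoint rule: {rule}")


def finalize_signature(matrix: FeatureMatrix, surv: SurvivalData,
                       retained: Sequence[str], direction: Direction,
                       cutpoint_rule: str = "median",
                       provenance: Optional[Dict] = None) -> SignatureModel:
    """Final sign-constrained unpenalized Cox refit on the retained features;
    the cutpoint is computed on training scores and frozen into the model."""
    if not retained:
        raise ValueError("retained feature set is empty")
    missing = [f for f in retained if f not in matrix.data.columns]
    if missing:
        raise KeyError(f"features missing from matrix: {missing}")
    sgn = direction_sign(direction)
    X = matrix.data[list(retained)]
    fit = fit_cox(X, surv, sign=sgn)
    coefs = {f: float(b) for f, b in fit.coefficients.items()}
    # numerical guard: clamp sign violations from solver tolerance to zero
    for f in coefs:
        if sgn == "nonnegative" and coefs[f] < 0:
            coefs[f] = 0.0
        if sgn == "nonpositive" and coefs[f] > 0:
            coefs[f] = 0.0
    scores = X.to_numpy() @ np.array([coefs[f] for f in retained])
    model = SignatureModel(
        features=list(retained), coefficients=coefs, direction=direction,
        cutpoint_rule=cutpoint_rule,
        cutpoint_value=_cutpoint(scores, cutpoint_rule),
        compartment=matrix.compartment, kind="celltype",
        training_provenance=provenance or {}, converged=fit.converged)
    if not fit.converged:
        warnings.warn("final Cox refit did not converge", stacklevel=2)
    return model


def score_patients(model: SignatureModel, matrix: FeatureMatrix) -> pd.Series:
    """Linear signature scores S_i = sum_j beta_j M_ij."""
    missing = [f for f in model.features if f not in matrix.data.columns]
    if missing:
        raise KeyError(f"model features missing from matrix: {missing}")
    beta = np.array([model.coefficients[f] for f in model.features])
    s = matrix.data[model.features].to_numpy() @ beta
    return pd.Series(s, index=matrix.data.index, name="score")


@dataclass
class EvaluationResult:
    hr: float
    ci: Tuple[float, float]
    p: float
    statistic: float
    sided: str
    km: Dict[object, pd.DataFrame]
    n_high: int
    n_low: int
    evaluable: bool = True


def evaluate_signature(scores: pd.Series, surv: SurvivalData,
                       model: SignatureModel,
                       sided: Literal["two", "one"] = "two") -> EvaluationResult:
    """Dichotomize at the model's frozen cutpoint and test.

    Discovery cohorts use the two-sided log-rank test; validation cohorts a
    one-sided test in the direction established in training (high resistance
    scores at higher risk; high response scores at lower risk).
    """
    s = np.asarray(scores, dtype=float)
    high = s > model.cutpoint_value  # ties assigned to the low group
    n_high, n_low = int(high.sum()), int((~high).sum())
    if n_high == 0 or n_low == 0:
        return EvaluationResult(float("nan"), (float("nan"), float("nan")),
                                float("nan"), float("nan"), sided, {},
                                n_high, n_low, evaluable=False)
    group = np.where(high, "high", "low")
    if sided == "one":
        direction = "high" if model.direction == "resistance" else "low"
        stat, p = logrank_test(surv, group, sided="one", direction=direction)
    else:
        stat, p = logrank_test(surv, group, sided="two")
    hr, ci, _, stable = hazard_ratio(surv, high.astype(int))
    km = km_estimate(surv, group)
    return EvaluationResult(hr, ci, p, stat, sided, km, n_high, n_low, True)


def univariable_cell_scan(matrix: FeatureMatrix, surv: SurvivalData,
                          cutrule: str = "median") -> pd.DataFrame:
    """Per-cell-type univariable analysis: median-dichotomized Cox HR with
    95% CI, two-sided log-rank p, and BH-adjusted p across the compartment's
    features.  Constant features yield NA rows excluded from the BH family.
    """
    rows = []
    for f in matrix.feature_names:
        x = matrix.data[f].to_numpy(dtype=float)
        cut = _cutpoint(x, cutrule)
        high = x > cut
        if high.all() or (~high).all():
            rows.append((f, np.nan, np.nan, np.nan, np.nan))
            continue
        hr, ci, _, stable = hazard_ratio(surv, high.astype(int))
        _, p = logrank_test(surv, np.where(high, "high", "low"), sided="two")
        rows.append((f, hr, ci[0], ci[1], p))
    out = pd.DataFrame(rows, columns=["feature", "hr", "ci_low", "ci_high", "p"])
    mask = out["p"].notna()
    adj = np.full(len(out), np.nan)
    if mask.any():
        adj[mask.to_numpy()] = multipletests(out.loc[mask, "p"],
                                             method="fdr_bh")[1]
    out["p_adj"] = adj
    return out


def train_celltype_signature(matrix: FeatureMatrix, surv: SurvivalData,
                             config: CelltypePipelineConfig) -> SignatureModel:
    """End-to-end: repeated splits -> tally -> threshold retention -> final
    sign-constrained refit with a frozen cutpoint."""
    tally, coef_sets = run_split_models(matrix, surv, config)
    retained, t = select_features(tally, config.min_features)
    if not retained:
        raise ValueError("no features were ever selected")
    provenance = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_models": config.n_models,
        "threshold_t": t,
        "tally": tally.counts,
    }
    return finalize_signature(matrix, surv, retained, config.direction,
                              config.cutpoint_rule, provenance)
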