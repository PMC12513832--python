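"""Cell-to-gene signature pipeline.

Derives gene-level signatures from the cell types retained in a cell-type
signature: candidate genes are restricted to those cell types' marker sets,
then a stability ensemble runs 50 train/test splits (80/20).  Within each
split, differentially expressed genes (negative binomial exact test,
P < 0.05, on the training half only) feed 100 differently-seeded
cross-validated sign-constrained LASSO-Cox fits; the union of genes those
fits select defines the split's signature, refit unpenalized on the
training half and scored on the held-out fifth for a hazard ratio.  Genes
with nonzero coefficients in at least 5% of HR-gated splits (HR > 1.5 for
resistance, HR < 0.7 for response) are kept, capped at ten, and refit on
the full discovery cohort with an upper-tertile frozen cutpoint.

Also houses the NNLS deconvolution consistency check B x F_i ~ M_i against
a reference signature matrix, and multivariable Cox adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .celltype import (Direction, EvaluationResult, SignatureModel,
                       direction_sign, evaluate_signature, finalize_signature,
                       score_patients)
from .survival import (LassoConfig, SurvivalData, cv_lambda,
                       fit_constrained_lasso_cox, fit_cox, hazard_ratio)
from .synthetic import FeatureMatrix

__all__ = [
    "GeneSetLibrary",
    "GenePipelineConfig",
    "SplitRecord",
    "restrict_genes",
    "normalize_counts",
    "binary_outcome_at",
    "estimate_common_dispersion",
    "nb_exact_test",
    "run_gene_splits",
    "retain_genes",
    "finalize_gene_signature",
    "validate_gene_signature",
    "multivariable_adjustment",
    "nnls_deconvolve",
]


@dataclass
class GeneSetLibrary:
    """Cell type -> marker gene symbols, e.g. an LM22- or atlas-derived map."""

    sets: Dict[str, List[str]]
    provenance: str = "synthetic"

    def __post_init__(self):
        for ct, genes in self.sets.items():
            if not genes:
                raise ValueError(f"empty gene list for {ct}")
            if len(set(genes)) != len(genes):
                raise ValueError(f"duplicate symbols in gene list for {ct}")

    def genes_for(self, cell_types: Sequence[str]) -> List[str]:
        missing = [ct for ct in cell_types if ct not in self.sets]
        if missing:
            raise KeyError(f"cell types missing from library: {missing}")
        out: set = set()
        for ct in cell_types:
            out.update(self.sets[ct])
        return sorted(out)


@dataclass
class GenePipelineConfig:
    n_splits: int = 50
    train_frac: float = 0.8
    n_seeds_per_split: int = 100
    de_alpha: float = 0.05
    retain_frac: float = 0.05
    hr_gate_resistance: float = 1.5  # per-split test HR must exceed this
    hr_gate_response: float = 0.7   # or fall below this, for response
    max_genes: int = 10
    direction: Direction = "resistance"
    n_folds: int = 10
    de_horizon_months: float = 24.0
    cutpoint_rule: str = "upper_tertile"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must lie in (0, 1)")
        if not 0 < self.retain_frac <= 1:
            raise ValueError("retain_frac must lie in (0, 1]")
        if self.max_genes < 1:
            raise ValueError("max_genes must be >= 1")


@dataclass
class SplitRecord:
    index: int
    train_ids: List[str]
    test_ids: List[str]
    de_genes: List[str]
    union_genes: List[str]
    coefficients: Dict[str, float]
    test_hr: float

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


# ---------------------------------------------------------------------------
# candidate restriction and normalization
# ---------------------------------------------------------------------------


def restrict_genes(expr: FeatureMatrix, library: GeneSetLibrary,
                   signature_cell_types: Sequence[str]) -> FeatureMatrix:
    """Restrict the expression matrix to the union of the signature cell
    types' marker genes, in sorted order."""
    wanted = library.genes_for(signature_cell_types)
    measured = set(expr.data.columns)
    for ct in signature_cell_types:
        if not measured.intersection(library.sets[ct]):
            raise KeyError(
                f"no genes of cell type {ct!r} measured; missing: "
                f"{sorted(library.sets[ct])[:10]}...")
    cols = [g for g in wanted if g in measured]
    if not cols:
        raise KeyError("no overlap between library and measured genes")
    return FeatureMatrix(expr.data[cols].copy(), compartment=expr.compartment,
                         kind=expr.kind)


def normalize_counts(expr: FeatureMatrix, scale: float = 1e4) -> FeatureMatrix:
    """Library-size normalization to log1p counts-per-``scale``; this is the
    representation gene models are fit and scored on, so frozen cutpoints
    transfer across cohorts with different sequencing depth."""
    counts = expr.data.to_numpy(dtype=float)
    lib = counts.sum(axis=1)
    lib = np.where(lib == 0, 1.0, lib)
    norm = np.log1p(counts / lib[:, None] * scale)
    return FeatureMatrix(pd.DataFrame(norm, index=expr.data.index,
                                      columns=expr.data.columns),
                         compartment=expr.compartment, kind="normalized")


def binary_outcome_at(surv: SurvivalData, horizon_months: float) -> pd.Series:
    """Progression status at a horizon: 1 = progressed/died by the horizon,
    0 = event-free at the horizon, NA = censored before the horizon."""
    status = np.full(len(surv), np.nan)
    status[(surv.event == 1) & (surv.time <= horizon_months)] = 1.0
    status[surv.time >= horizon_months] = np.where(
        (surv.event[surv.time >= horizon_months] == 1)
        & (surv.time[surv.time >= horizon_months] <= horizon_months), 1.0, 0.0)
    return pd.Series(status, index=surv.patient_id, name="progressed")


# ---------------------------------------------------------------------------
# negative binomial exact test
# ---------------------------------------------------------------------------


def _equalize_library(counts: np.ndarray) -> np.ndarray:
    """Scale each sample's counts to the geometric-mean library size and
    round — the pseudo-count equalization the exact test conditions on."""
    lib = counts.sum(axis=1).astype(float)
    lib = np.where(lib == 0, 1.0, lib)
    target = np.exp(np.mean(np.log(lib)))
    return np.rint(counts * (target / lib)[:, None]).astype(np.int64)


def _cond_loglik_dispersion(counts: np.ndarray, phi: float) -> float:
    """Conditional log likelihood of within-group counts given their sum for
    iid NB with dispersion phi (negative hypergeometric)."""
    m, _ = counts.shape
    r = 1.0 / phi
    t = counts.sum(axis=0)
    ll = (special.gammaln(counts + r).sum(axis=0)
          - m * special.gammaln(r)
          - special.gammaln(t + m * r)
          + special.gammaln(m * r))
    return float(ll.sum())


def estimate_common_dispersion(counts_a: np.ndarray, counts_b: np.ndarray
                               ) -> float:
    """Common NB dispersion by conditional maximum likelihood on
    library-equalized counts, pooled over genes and both groups."""
    a = _equalize_library(np.vstack([counts_a, counts_b]))
    na = counts_a.shape[0]
    ga, gb = a[:na], a[na:]

    def neg(delta):
        phi = delta / (1.0 - delta)
        out = 0.0
        if ga.shape[0] > 1:
            out += _cond_loglik_dispersion(ga, phi)
        if gb.shape[0] > 1:
            out += _cond_loglik_dispersion(gb, phi)
        return -out

    res = optimize.minimize_scalar(neg, bounds=(1e-6, 0.999),
                                   method="bounded",
                                   options={"xatol": 1e-6})
    delta = float(res.x)
    return delta / (1.0 - delta)


def _exact_nb_pvalue(sum_a: int, sum_b: int, n_a: int, n_b: int,
                     phi: float) -> float:
    """Two-sided exact p for group-A sum given the total, under iid NB with
    common per-sample mean and dispersion phi.  Sums outcomes whose
    conditional probability does not exceed that of the observed one.

    In the dispersion -> 0 limit this is the conditional binomial test.
    """
    t = int(sum_a + sum_b)
    if t == 0:
        return 1.0
    if phi < 1e-8:  # Poisson limit: S_A | total ~ Binomial(t, n_a/(n_a+n_b))
        pr = stats.binom.logpmf(np.arange(t + 1), t, n_a / (n_a + n_b))
    else:
        mu = t / (n_a + n_b)
        ra, rb = n_a / phi, n_b / phi
        a = np.arange(t + 1)
        # log P(S_A=a) + log P(S_B=t-a); the normalizing constant cancels
        pr = (stats.nbinom.logpmf(a, ra, ra / (ra + n_a * mu))
              + stats.nbinom.logpmf(t - a, rb, rb / (rb + n_b * mu)))
    pr = pr - special.logsumexp(pr)
    obs = pr[int(sum_a)]
    keep = pr <= obs + 1e-12
    p = float(np.exp(special.logsumexp(pr[keep])))
    return 1.0 if p >= 1.0 - 1e-12 else p


def nb_exact_test(counts_a, counts_b,
                  dispersion_estimate: Optional[float] = None) -> pd.Series:
    """Per-gene exact two-sided NB test between two groups of samples.

    Arguments are samples x genes count frames (or arrays) with aligned
    genes.  Library sizes are equalized by scaling to the geometric mean
    before conditioning on the per-gene total; a common dispersion is
    estimated by conditional likelihood when not provided.  Genes with zero
    total count get p = 1.
    """
    names = (list(counts_a.columns) if isinstance(counts_a, pd.DataFrame)
             else [f"g{j}" for j in range(np.asarray(counts_a).shape[1])])
    ca = np.asarray(counts_a, dtype=np.int64)
    cb = np.asarray(counts_b, dtype=np.int64)
    if ca.ndim != 2 or cb.ndim != 2 or ca.shape[1] != cb.shape[1]:
        raise ValueError("count matrices must be 2-D with aligned genes")
    if ca.shape[0] < 1 or cb.shape[0] < 1:
        raise ValueError("each group needs at least one sample")
    if np.any(ca < 0) or np.any(cb < 0):
        raise ValueError("counts must be non-negative integers")
    if dispersion_estimate is None:
        dispersion_estimate = estimate_common_dispersion(ca, cb)
    eq = _equalize_library(np.vstack([ca, cb]))
    ea, eb = eq[:ca.shape[0]], eq[ca.shape[0]:]
    sa, sb = ea.sum(axis=0), eb.sum(axis=0)
    pvals = np.array([
        _exact_nb_pvalue(int(sa[j]), int(sb[j]), ca.shape[0], cb.shape[0],
                         dispersion_estimate)
        for j in range(ca.shape[1])
    ])
    return pd.Series(pvals, index=names, name="p")


# ---------------------------------------------------------------------------
# split ensemble
# ---------------------------------------------------------------------------


def _split_train_test(ids: np.ndarray, event: np.ndarray, train_frac: float,
                      rng: np.random.Generator):
    """80/20 split stratified by event status."""
    tr_idx: List[int] = []
    te_idx: List[int] = []
    for val in (1, 0):
        idx = rng.permutation(np.flatnonzero(event == val))
        n_tr = int(round(train_frac * idx.size))
        tr_idx.extend(idx[:n_tr])
        te_idx.extend(idx[n_tr:])
    return np.array(sorted(tr_idx)), np.array(sorted(te_idx))


def run_gene_splits(expr: FeatureMatrix, surv: SurvivalData,
                    config: GenePipelineConfig,
                    de_grouping: Optional[pd.Series] = None
                    ) -> List[SplitRecord]:
    """The per-split ensemble.  ``expr`` holds raw candidate-gene counts
    (after `restrict_genes`); DE filtering, penalty selection and model
    fitting all see the split's training half only.

    ``de_grouping`` is the binary progression status used for the DE filter
    (default: progression by ``config.de_horizon_months``).
    """
    if list(expr.data.index) != list(surv.patient_id):
        raise ValueError("expression matrix and survival data are not aligned")
    if de_grouping is None:
        de_grouping = binary_outcome_at(surv, config.de_horizon_months)
    de_grouping = de_grouping.reindex(expr.data.index)
    ids = np.asarray(expr.data.index)
    norm = normalize_counts(expr)
    records: List[SplitRecord] = []
    for s in range(config.n_splits):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 21, s]))
        tr, te = _split_train_test(ids, surv.event, config.train_frac, rng)
        records.append(_run_one_split(expr, norm, surv, de_grouping, tr, te,
                                      config, s))
    return records


def _run_one_split(expr: FeatureMatrix, norm: FeatureMatrix,
                   surv: SurvivalData, de_grouping: pd.Series,
                   tr: np.ndarray, te: np.ndarray,
                   config: GenePipelineConfig, s: int) -> SplitRecord:
    """DE filter, seeded LASSO ensemble and per-split signature for a fixed
    train/test partition.  Only the training half's rows are ever touched
    before the final held-out HR."""
    ids = np.asarray(expr.data.index)
    sgn = direction_sign(config.direction)
    surv_tr, surv_te = surv.subset(tr), surv.subset(te)
    if surv_tr.n_events < config.n_folds:
        raise ValueError(f"split {s}: training events fewer than folds")
    grp = de_grouping.iloc[tr]
    known = grp.notna().to_numpy()
    prog = (grp == 1).to_numpy() & known
    nonprog = (grp == 0).to_numpy() & known
    counts_tr = expr.data.iloc[tr].to_numpy(dtype=np.int64)
    if prog.sum() >= 1 and nonprog.sum() >= 1:
        pv = nb_exact_test(
            pd.DataFrame(counts_tr[prog], columns=expr.data.columns),
            pd.DataFrame(counts_tr[nonprog], columns=expr.data.columns))
        de_genes = sorted(pv.index[pv < config.de_alpha])
    else:
        de_genes = []
    if not de_genes:
        return SplitRecord(s, list(ids[tr]), list(ids[te]), [], [], {},
                           float("nan"))
    X_tr = norm.data.iloc[tr][de_genes]
    union: set = set()
    for m in range(config.n_seeds_per_split):
        lcfg = LassoConfig(sign=sgn, n_folds=config.n_folds,
                           seed=int(np.random.SeedSequence(
                               [config.seed, 22, s, m]
                           ).generate_state(1)[0] % (2**31)))
        cv = cv_lambda(X_tr, surv_tr, lcfg)
        fit = fit_constrained_lasso_cox(X_tr, surv_tr, cv.lambda_min, lcfg)
        union.update(g for g, b in fit.coefficients.items() if b != 0.0)
    union_genes = sorted(union)
    if not union_genes:
        return SplitRecord(s, list(ids[tr]), list(ids[te]), de_genes, [], {},
                           float("nan"))
    # per-split signature: sign-constrained unpenalized refit on training
    fit = fit_cox(norm.data.iloc[tr][union_genes], surv_tr, sign=sgn)
    coefs = {g: float(b) for g, b in fit.coefficients.items()}
    beta = np.array([coefs[g] for g in union_genes])
    s_te = norm.data.iloc[te][union_genes].to_numpy() @ beta
    # test-split HR, median-dichotomized
    high = s_te > np.median(s_te)
    if high.any() and (~high).any():
        hr, _, _, stable = hazard_ratio(surv_te, high.astype(int))
        if not stable:
            hr = float("nan")
    else:
        hr = float("nan")
    return SplitRecord(s, list(ids[tr]), list(ids[te]), de_genes,
                       union_genes, coefs, hr)


def retain_genes(records: Sequence[SplitRecord], config: GenePipelineConfig
                 ) -> Tuple[List[str], pd.DataFrame]:
    """HR-gated stability retention.

    Splits pass the gate when their held-out HR exceeds 1.5 (resistance) or
    falls below 0.7 (response).  A gene's support is the fraction of gated
    splits where it carried a nonzero coefficient; genes with support >=
    ``retain_frac`` are kept, capped at ``max_genes`` by support (ties by
    mean |coefficient|, then name).
    """
    finite = [r for r in records if np.isfinite(r.test_hr)]
    if not finite:
        raise ValueError("no split produced a finite test HR")
    if config.direction == "resistance":
        gated = [r for r in finite if r.test_hr > config.hr_gate_resistance]
    else:
        gated = [r for r in finite if r.test_hr < config.hr_gate_response]
    if not gated:
        raise ValueError("no split passed HR gate")
    support: Dict[str, int] = {}
    coef_mag: Dict[str, List[float]] = {}
    for r in gated:
        for g, b in r.coefficients.items():
            if b != 0.0:
                support[g] = support.get(g, 0) + 1
                coef_mag.setdefault(g, []).append(abs(b))
    n_gated = len(gated)
    tbl = pd.DataFrame({
        "gene": list(support.keys()),
        "support": [support[g] / n_gated for g in support],
        "mean_abs_coef": [float(np.mean(coef_mag[g])) for g in support],
    }).sort_values(["support", "mean_abs_coef", "gene"],
                   ascending=[False, False, True]).reset_index(drop=True)
    kept = tbl[tbl["support"] >= config.retain_frac]
    genes = list(kept["gene"].iloc[:config.max_genes])
    return genes, tbl


def finalize_gene_signature(expr: FeatureMatrix, surv: SurvivalData,
                            retained: Sequence[str], direction: Direction,
                            cutpoint_rule: str = "upper_tertile",
                            provenance: Optional[Dict] = None) -> SignatureModel:
    """Sign-constrained unpenalized Cox on the full discovery cohort,
    restricted to the retained genes; upper-tertile (PFS) or median (OS)
    cutpoint frozen from training scores."""
    norm = normalize_counts(expr) if expr.kind == "counts" else expr
    model = finalize_signature(norm, surv, retained, direction,
                               cutpoint_rule, provenance)
    model.kind = "gene"
    return model


def validate_gene_signature(model: SignatureModel, expr_val: FeatureMatrix,
                            surv_val: SurvivalData,
                            sided: Literal["one", "two"] = "one"
                            ) -> EvaluationResult:
    """Frozen-cutpoint external validation.

    Genes are matched by symbol.  More than 20% of model genes missing is a
    hard error; up to 20% proceeds on the intersection with a warning and no
    imputation.
    """
    norm = normalize_counts(expr_val) if expr_val.kind == "counts" else expr_val
    missing = [g for g in model.features if g not in norm.data.columns]
    if len(missing) > 0.2 * len(model.features):
        raise KeyError(f"{len(missing)}/{len(model.features)} model genes "
                       f"missing from validation matrix: {missing}")
    use_model = model
    if missing:
        warnings.warn(
            f"validating without {len(missing)} missing genes "
            f"(no imputation): {missing}", stacklevel=2)
        feats = [g for g in model.features if g not in missing]
        use_model = SignatureModel(
            features=feats,
            coefficients={g: model.coefficients[g] for g in feats},
            direction=model.direction, cutpoint_rule=model.cutpoint_rule,
            cutpoint_value=model.cutpoint_value,
            compartment=model.compartment, kind=model.kind,
            training_provenance=model.training_provenance)
    scores = score_patients(use_model, norm)
    return evaluate_signature(scores, surv_val, use_model, sided=sided)


# ---------------------------------------------------------------------------
# multivariable adjustment & deconvolution
# ---------------------------------------------------------------------------


def multivariable_adjustment(scores_binary, covariates: pd.DataFrame,
                             surv: SurvivalData) -> pd.DataFrame:
    """Multivariable Cox of the binarized signature plus clinical covariates
    (categoricals reference-coded).  Collinear or constant terms are dropped
    with a warning — sparse covariate subgroups make them unidentifiable.

    Returns a table with HR, 95% CI and Wald p per term.
    """
    X = pd.DataFrame({"signature_high": np.asarray(scores_binary, dtype=float)},
                     index=covariates.index if len(covariates) else None)
    if len(covariates):
        enc = pd.get_dummies(covariates, drop_first=True, dtype=float)
        X = pd.concat([X.reset_index(drop=True),
                       enc.reset_index(drop=True)], axis=1)
    # drop constant columns
    keep = [c for c in X.columns if X[c].nunique() > 1]
    dropped = [c for c in X.columns if c not in keep]
    X = X[keep]
    # drop collinear columns greedily by QR rank
    cols: List[str] = []
    for c in X.columns:
        cand = X[cols + [c]].to_numpy()
        if np.linalg.matrix_rank(cand - cand.mean(axis=0)) == len(cols) + 1:
            cols.append(c)
        else:
            dropped.append(c)
    if dropped:
        warnings.warn(f"dropped unidentifiable terms: {dropped}", stacklevel=2)
    X = X[cols]
    fit = fit_cox(X, surv)
    rows = []
    for term in X.columns:
        b = fit.coefficients[term]
        se = fit.se[term]
        rows.append((term, float(np.exp(b)), float(np.exp(b - 1.96 * se)),
                     float(np.exp(b + 1.96 * se)),
                     float(2 * stats.norm.sf(abs(b) / se)) if se > 0 else np.nan))
    return pd.DataFrame(rows, columns=["term", "hr", "ci_low", "ci_high", "p"])


def nnls_deconvolve(B: pd.DataFrame, M_i) -> Tuple[pd.Series, float]:
    """Non-negative least squares deconvolution B x F_i ~ M_i.

    ``B`` is a genes x cell-types reference signature matrix; ``M_i`` a
    per-patient expression vector indexed by gene.  Fractions are
    renormalized to sum to 1; the residual norm of the unnormalized solution
    is returned alongside.
    """
    if isinstance(M_i, pd.Series):
        shared = [g for g in B.index if g in M_i.index]
        if not shared:
            raise ValueError("no shared genes between signature matrix and sample")
        A = B.loc[shared].to_numpy(dtype=float)
        y = M_i.loc[shared].to_numpy(dtype=float)
    else:
        y = np.asarray(M_i, dtype=float)
        if y.shape[0] != B.shape[0]:
            raise ValueError("expression vector does not match signature rows")
        A = B.to_numpy(dtype=float)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        warnings.warn("signature matrix is rank-deficient on shared genes",
                      stacklevel=2)
    f, resid = optimize.nnls(A, y)
    total = f.sum()
    frac = f / total if total > 0 else f
    return pd.Series(frac, index=B.columns, name="fraction"), float(resid)
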