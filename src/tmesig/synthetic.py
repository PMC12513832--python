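"""Synthetic cohort generator.

Emulates the statistical structure of a spatial multi-omics immunotherapy
cohort: Dirichlet-distributed per-compartment cell-type fractions over 14
phenotypes, negative-binomial gene-expression counts with cell-type-specific
programs, exponential proportional-hazards survival driven by planted
resistance/response signatures with independent and administrative
censoring, and spatial point patterns with planted niches.

Planted signature coefficients are log hazard ratios *per standard
deviation* of the feature (fractions live on the simplex and have small raw
scale); `planted_scores` standardizes columns before applying them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .survival import SurvivalData

__all__ = [
    "DEFAULT_CELL_TYPES",
    "CohortSpec",
    "ExpressionSpec",
    "SpatialSpec",
    "FeatureMatrix",
    "SpatialCellTable",
    "simulate_cell_fractions",
    "planted_scores",
    "simulate_survival",
    "make_gene_library",
    "simulate_expression",
    "simulate_spatial_cells",
]

#: The 14 merged phenotypes used throughout: epithelial tumor states,
#: myeloid and lymphoid subsets, vasculature and stroma.
DEFAULT_CELL_TYPES: Tuple[str, ...] = (
    "tumor",
    "proliferating_tumor",
    "pdl1_tumor",
    "granulocyte",
    "vessel",
    "m1_macrophage",
    "m2_macrophage",
    "cd4_t",
    "cd8_t",
    "treg",
    "b_cell",
    "dendritic",
    "stromal",
    "unidentified",
)

COMPARTMENTS = ("tumor", "stroma")


@dataclass
class FeatureMatrix:
    """Patients x features matrix (cell fractions, counts or normalized
    expression) for one tissue compartment."""

    data: pd.DataFrame
    compartment: str = "tumor"
    kind: str = "fractions"

    def __post_init__(self):
        if self.data.index.has_duplicates:
            raise ValueError("patient ids must be unique")
        if self.data.isna().any().any():
            raise ValueError("feature matrix contains NaN")
        if self.kind == "fractions":
            sums = self.data.to_numpy().sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("fraction rows must sum to 1")

    @property
    def patient_ids(self) -> List[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> List[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def __repr__(self):
        return (f"FeatureMatrix({self.data.shape[0]} patients x "
                f"{self.data.shape[1]} features, {self.compartment}, {self.kind})")


@dataclass
class CohortSpec:
    """Study-level design of a synthetic cohort."""

    n_patients: int = 100
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES
    compartments: Sequence[str] = COMPARTMENTS
    planted_resistance: Mapping[str, float] = field(default_factory=dict)
    planted_response: Mapping[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.04  # events per month
    censor_rate: float = 0.01  # per-month censoring hazard
    horizon_months: float = 60.0
    dirichlet_concentration: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("n_patients must be at least 2")
        if self.horizon_months <= 0:
            raise ValueError("horizon_months must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be non-negative")
        if np.any(np.asarray(self.dirichlet_concentration) <= 0):
            raise ValueError("Dirichlet concentration must be positive")
        for name, c in self.planted_resistance.items():
            if c < 0:
                raise ValueError(f"resistance coefficient for {name} must be >= 0")
        for name, c in self.planted_response.items():
            if c > 0:
                raise ValueError(f"response coefficient for {name} must be <= 0")

    @property
    def patient_ids(self) -> List[str]:
        return [f"P{i:04d}" for i in range(self.n_patients)]


@dataclass
class ExpressionSpec:
    """Design of a synthetic compartment count matrix."""

    gene_set_library: Mapping[str, Sequence[str]] = field(default_factory=dict)
    genes_per_type: int = 40
    nb_mean_baseline: float = 8.0
    nb_dispersion: float = 0.2
    effect_log_fc: float = 3.0  # cell-type loading applied to fractions
    library_size_cv: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.nb_mean_baseline <= 0:
            raise ValueError("nb_mean_baseline must be positive")
        if self.library_size_cv < 0:
            raise ValueError("library_size_cv must be non-negative")
        seen: Dict[str, str] = {}
        for ct, genes in self.gene_set_library.items():
            for g in genes:
                if g in seen and seen[g] != ct:
                    warnings.warn(
                        f"gene {g} occurs in sets {seen[g]} and {ct}",
                        stacklevel=2)
                seen[g] = ct


@dataclass
class SpatialSpec:
    """Design of a synthetic spatial field: uniform background with planted
    circular niches.  Overlapping niches are resolved by declaration order."""

    field_size_um: Tuple[float, float] = (1000.0, 1000.0)
    n_cells: int = 5000
    # (center_xy, radius_um, {cell_type: probability})
    niche_definitions: Sequence[Tuple[Tuple[float, float], float,
                                      Mapping[str, float]]] = ()
    background_mixture: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        w, h = self.field_size_um
        if w <= 0 or h <= 0:
            raise ValueError("field size must be positive")
        mixes = [self.background_mixture] + [m for _, _, m in
                                             self.niche_definitions]
        for m in mixes:
            if not m:
                raise ValueError("mixtures must be nonempty")
            total = sum(m.values())
            if not np.isclose(total, 1.0, atol=1e-9):
                raise ValueError(f"mixture probabilities sum to {total}, not 1")
            if any(v < 0 for v in m.values()):
                raise ValueError("mixture probabilities must be non-negative")
        for (cx, cy), r, _ in self.niche_definitions:
            if r <= 0:
                raise ValueError("niche radii must be positive")
            if not (0 <= cx <= w and 0 <= cy <= h):
                raise ValueError("niche centers must lie within the field")


@dataclass
class SpatialCellTable:
    """Cells with physical coordinates (µm) and phenotype labels."""

    data: pd.DataFrame  # cell_id, x_um, y_um, cell_type, patient_id, region_id

    REQUIRED = ("cell_id", "x_um", "y_um", "cell_type")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        if "region_id" not in self.data.columns:
            self.data = self.data.assign(region_id="R0")
        if "patient_id" not in self.data.columns:
            self.data = self.data.assign(patient_id="P0")
        xy = self.data[["x_um", "y_um"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise ValueError("coordinates must be finite")

    def __len__(self):
        return len(self.data)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _rng(seed, *keys) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


def simulate_cell_fractions(spec: CohortSpec) -> Dict[str, FeatureMatrix]:
    """Per-compartment Dirichlet cell-fraction matrices.

    Each patient row is a probability vector over the cell types; matrices
    are bitwise reproducible under a fixed seed.
    """
    conc = np.broadcast_to(np.asarray(spec.dirichlet_concentration, dtype=float),
                           (len(spec.cell_types),))
    out: Dict[str, FeatureMatrix] = {}
    for ci, comp in enumerate(spec.compartments):
        rng = _rng(spec.seed, 1, ci)
        frac = rng.dirichlet(conc, size=spec.n_patients)
        df = pd.DataFrame(frac, index=spec.patient_ids,
                          columns=list(spec.cell_types))
        out[comp] = FeatureMatrix(df, compartment=comp, kind="fractions")
    return out


def planted_scores(fractions: FeatureMatrix, spec: CohortSpec) -> np.ndarray:
    """Linear predictor from the planted signatures applied to z-scored
    feature columns (coefficients are log HRs per feature SD)."""
    score = np.zeros(len(fractions.data))
    coefs = dict(spec.planted_resistance)
    for k, v in spec.planted_response.items():
        coefs[k] = coefs.get(k, 0.0) + v
    for name, c in coefs.items():
        if name not in fractions.data.columns:
            raise KeyError(f"planted feature {name!r} not in matrix")
        col = fractions.data[name].to_numpy(dtype=float)
        sd = col.std()
        if sd > 0:
            score += c * (col - col.mean()) / sd
    return score


def simulate_survival(scores, spec: CohortSpec) -> SurvivalData:
    """Exponential proportional-hazards event times.

    time ~ Exponential(baseline_hazard * exp(score)), censored independently
    at Exponential(censor_rate) and administratively at horizon_months.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if scores.shape[0] != spec.n_patients:
        raise ValueError("scores must align with spec.n_patients")
    rng = _rng(spec.seed, 2)
    haz = spec.baseline_hazard * np.exp(scores)
    t_event = rng.exponential(1.0 / haz)
    if spec.censor_rate > 0:
        t_cens = rng.exponential(1.0 / spec.censor_rate, size=spec.n_patients)
    else:
        t_cens = np.full(spec.n_patients, np.inf)
    t_cens = np.minimum(t_cens, spec.horizon_months)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-6)  # guard strictly positive times
    return SurvivalData(time, event, np.asarray(spec.patient_ids))


def make_gene_library(cell_types: Sequence[str] = DEFAULT_CELL_TYPES,
                      genes_per_type: int = 40,
                      prefix: str = "G") -> Dict[str, List[str]]:
    """Synthetic marker gene library: disjoint symbol lists per cell type."""
    lib: Dict[str, List[str]] = {}
    for i, ct in enumerate(cell_types):
        lib[ct] = [f"{prefix}_{ct}_{j:03d}" for j in range(genes_per_type)]
    return lib


def simulate_expression(fractions: FeatureMatrix, spec: ExpressionSpec,
                        planted_genes: Optional[Mapping[str, float]] = None,
                        group=None) -> FeatureMatrix:
    """Negative-binomial compartment count matrix (patients x genes).

    log mean = log(baseline) + loading * fraction(cell type of the gene)
             + planted log-fc * group + log library size,
    counts ~ NB(mean, dispersion) with Var = mu + dispersion * mu^2.
    """
    planted_genes = dict(planted_genes or {})
    n = len(fractions.data)
    genes: List[str] = []
    gene_ct: List[str] = []
    for ct, gl in spec.gene_set_library.items():
        genes.extend(gl)
        gene_ct.extend([ct] * len(gl))
    if not genes:
        raise ValueError("gene_set_library is empty")
    unknown = [g for g in planted_genes if g not in genes]
    if unknown:
        raise KeyError(f"planted genes not in library: {unknown}")
    if group is None:
        group = np.zeros(n)
    group = np.asarray(group, dtype=float)
    rng = _rng(spec.seed, 3)
    lib_sigma = np.sqrt(np.log1p(spec.library_size_cv ** 2))
    libsize = rng.lognormal(-0.5 * lib_sigma ** 2, lib_sigma, size=n)
    logmu = np.full((n, len(genes)), np.log(spec.nb_mean_baseline))
    for j, (g, ct) in enumerate(zip(genes, gene_ct)):
        if ct in fractions.data.columns:
            logmu[:, j] += spec.effect_log_fc * fractions.data[ct].to_numpy()
        if g in planted_genes:
            logmu[:, j] += planted_genes[g] * group
    logmu += np.log(libsize)[:, None]
    mu = np.exp(logmu)
    r = 1.0 / spec.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    df = pd.DataFrame(counts, index=fractions.data.index, columns=genes)
    return FeatureMatrix(df, compartment=fractions.compartment, kind="counts")


def simulate_spatial_cells(spec: SpatialSpec, patient_id: str = "P0",
                           region_id: str = "R0") -> SpatialCellTable:
    """Uniform point pattern over the field; cells inside a niche disk draw
    their phenotype from the niche mixture (first-listed niche wins on
    overlap), others from the background mixture."""
    rng = _rng(spec.seed, 4)
    w, h = spec.field_size_um
    xy = rng.uniform((0, 0), (w, h), size=(spec.n_cells, 2))
    assignment = np.full(spec.n_cells, -1, dtype=int)
    for k, ((cx, cy), r, _) in enumerate(spec.niche_definitions):
        inside = ((xy[:, 0] - cx) ** 2 + (xy[:, 1] - cy) ** 2) <= r ** 2
        assignment[(assignment == -1) & inside] = k
    labels = np.empty(spec.n_cells, dtype=object)
    mixes = [spec.background_mixture] + [m for _, _, m in spec.niche_definitions]
    for k in range(-1, len(spec.niche_definitions)):
        m = assignment == k
        if not m.any():
            continue
        mix = mixes[k + 1]
        types = list(mix.keys())
        probs = np.array([mix[t] for t in types], dtype=float)
        probs = probs / probs.sum()
        labels[m] = rng.choice(types, size=int(m.sum()), p=probs)
    df = pd.DataFrame({
        "cell_id": [f"C{i:06d}" for i in range(spec.n_cells)],
        "x_um": xy[:, 0],
        "y_um": xy[:, 1],
        "cell_type": labels,
        "patient_id": patient_id,
        "region_id": region_id,
        "niche_id": assignment,
    })
    return SpatialCellTable(df)
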