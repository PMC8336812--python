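"""Declarative model specification and predictor assembly.

A location-scale Gaussian model for the height-for-age z-score:

    z_i ~ N(mu_i, sigma_i^2),   mu = eta_mu,   sigma = exp(eta_sigma),

where each predictor ``eta`` is a structured additive sum of an intercept,
effect-coded categorical covariates (gender, place of living, survey wave),
one-dimensional P-splines, two tensor-product surfaces and a spatial MRF
field per survey wave.  ``make_model_grid`` builds the six model variants
compared in the analysis; ``assemble`` turns a spec plus data into
design/penalty blocks ready for the MCMC engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from distreg.bases import (
    DistrictGraph,
    PenaltyMatrix,
    SplineBasisDef,
    apply_sum_to_zero_constraint,
    build_bspline_basis,
    build_difference_penalty,
    build_mrf_penalty,
    build_tensor_basis,
    effect_code,
    spline_def_for,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TermSpec",
    "ModelSpec",
    "SmoothBlock",
    "AssembledModel",
    "make_model_grid",
    "assemble",
    "predict",
    "CATEGORICAL_COVARIATES",
]

#: categorical covariates entering x'beta (effect coded)
CATEGORICAL_COVARIATES = ("gender", "urban", "wave")

#: covariate transformed at assembly, as named in the predictor
LOG1P_COVARIATE = "population_density"


@dataclass(frozen=True)
class TermSpec:
    """One additive term of a predictor.

    kind is one of ``spline1d``, ``tensor2d`` or ``mrf``; ``covariates``
    holds 1 label (spline1d), 2 labels (tensor2d) or the district label
    (mrf, which is additionally stratified by survey wave).
    """

    name: str
    kind: str
    covariates: tuple
    in_mu: bool = True
    in_sigma: bool = False
    n_intervals: int = 20
    penalty_order: int = 2
    degree: int = 3

    def __post_init__(self) -> None:
        if self.kind not in {"spline1d", "tensor2d", "mrf"}:
            raise ValueError(f"unknown term kind {self.kind!r}")
        if self.kind == "tensor2d" and len(self.covariates) != 2:
            raise ValueError("tensor2d terms need exactly 2 covariates")
        if self.kind == "spline1d" and len(self.covariates) != 1:
            raise ValueError("spline1d terms need exactly 1 covariate")
        if not (self.in_mu or self.in_sigma):
            raise ValueError("term must enter at least one predictor")


@dataclass(frozen=True)
class ModelSpec:
    """A full two-predictor model: term list plus the categorical block."""

    model_id: int
    terms: tuple
    response: str = "haz"
    sigma_modelled: bool = False

    def mu_terms(self) -> list:
        return [t for t in self.terms if t.in_mu]

    def sigma_terms(self) -> list:
        return [t for t in self.terms if t.in_sigma] if self.sigma_modelled else []


def _smooth_terms(
    include: set,
    sigma_smooths: set,
    n_intervals: int = 20,
    tensor_intervals: int = 8,
) -> list:
    """Construct the named f1..f11 term library, filtered to ``include``;
    ``sigma_smooths`` says which of those also enter the sigma predictor."""
    lib = {
        "f1": TermSpec("f1", "spline1d", ("asset_index_dev",), n_intervals=n_intervals),
        "f2": TermSpec(
            "f2", "tensor2d", ("birth_order", "mother_age_at_birth"),
            n_intervals=tensor_intervals,
        ),
        "f3": TermSpec(
            "f3", "tensor2d", ("age_months", "breastfeeding_months"),
            n_intervals=tensor_intervals,
        ),
        "f4": TermSpec("f4", "spline1d", ("mother_education_years",), n_intervals=n_intervals),
        "f5": TermSpec("f5", "spline1d", ("household_size",), n_intervals=n_intervals),
        "f6": TermSpec("f6", "spline1d", ("mother_bmi",), n_intervals=n_intervals),
        "f7": TermSpec("f7", "spline1d", ("vaccinations",), n_intervals=n_intervals),
        "f8": TermSpec("f8", "spline1d", ("drought_index",), n_intervals=n_intervals),
        "f9": TermSpec("f9", "spline1d", ("malaria_incidence",), n_intervals=n_intervals),
        "f10": TermSpec("f10", "spline1d", ("population_density",), n_intervals=n_intervals),
        "f11": TermSpec("f11", "mrf", ("district_id",)),
    }
    out = []
    for name in [f"f{i}" for i in range(1, 12)]:
        if name in include:
            t = lib[name]
            out.append(replace(t, in_sigma=name in sigma_smooths))
    return out


# interaction surfaces are kept out of the sigma predictor throughout
# (they mix badly there); spatial + all 1-D smooths may enter it
_SIGMA_ELIGIBLE = {"f1", "f4", "f5", "f6", "f7", "f8", "f9", "f10", "f11"}
_ALL = {f"f{i}" for i in range(1, 12)}
_SOCIOECONOMIC = {"f1", "f2", "f3", "f4", "f5", "f6", "f7", "f11"}
_REMOTE_SENSED = {"f8", "f9", "f10", "f11"}


def make_model_grid(n_intervals: int = 20, tensor_intervals: int = 8) -> list:
    """The six-model comparison grid.

    * Model 1: full mean predictor, constant sigma.
    * Model 2: socio-economic smooths only (plus spatial), both predictors.
    * Model 3: remote-sensed smooths only (plus spatial), both predictors.
    * Model 4: linear/categorical terms only, both predictors.
    * Model 5: full model — all smooths in the mean predictor, all
      sigma-eligible smooths in the scale predictor.
    * Model 6: Model 5 without the population-density term.

    Basis sizes are parameterised so reduced-scale runs reuse the grid.
    """
    kw = dict(n_intervals=n_intervals, tensor_intervals=tensor_intervals)
    grid = [
        ModelSpec(1, tuple(_smooth_terms(_ALL, set(), **kw)), sigma_modelled=False),
        ModelSpec(
            2,
            tuple(_smooth_terms(_SOCIOECONOMIC, _SIGMA_ELIGIBLE & _SOCIOECONOMIC, **kw)),
            sigma_modelled=True,
        ),
        ModelSpec(
            3,
            tuple(_smooth_terms(_REMOTE_SENSED, _SIGMA_ELIGIBLE & _REMOTE_SENSED, **kw)),
            sigma_modelled=True,
        ),
        ModelSpec(4, (), sigma_modelled=True),
        ModelSpec(5, tuple(_smooth_terms(_ALL, _SIGMA_ELIGIBLE, **kw)), sigma_modelled=True),
        ModelSpec(
            6,
            tuple(_smooth_terms(_ALL - {"f10"}, _SIGMA_ELIGIBLE - {"f10"}, **kw)),
            sigma_modelled=True,
        ),
    ]
    return grid


@dataclass
class SmoothBlock:
    """One penalised (or fixed-effect) block of a predictor.

    Holds the constrained design, the constrained penalty, the
    back-transform to the original basis, and metadata used for effect
    extraction (evaluation grids, district/wave labelling).
    """

    name: str
    design: np.ndarray
    penalty: PenaltyMatrix | None  # None => fixed effects, diffuse prior
    transform: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_coef(self) -> int:
        return self.design.shape[1]

    @property
    def penalized(self) -> bool:
        return self.penalty is not None


@dataclass
class AssembledModel:
    """Response plus per-predictor block lists, ready for sampling."""

    y: np.ndarray
    mu_blocks: list
    sigma_blocks: list
    spec: ModelSpec
    data: pd.DataFrame
    graph: DistrictGraph | None = None

    @property
    def n_obs(self) -> int:
        return self.y.size


def _constraint_null_basis(C: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the null space of constraint matrix C (k x p)."""
    from scipy.linalg import null_space

    Z = null_space(C)
    return Z


def _apply_constraints(
    design: np.ndarray, penalty: PenaltyMatrix, C: np.ndarray
) -> tuple[np.ndarray, PenaltyMatrix, np.ndarray]:
    Z = _constraint_null_basis(C)
    Kc = Z.T @ penalty.matrix @ Z
    Kc = 0.5 * (Kc + Kc.T)
    eig = np.linalg.eigvalsh(Kc)
    scale = max(float(np.max(np.abs(eig))), 1.0)
    new_def = int(np.sum(eig < 1e-9 * scale))
    return design @ Z, PenaltyMatrix(matrix=Kc, rank_deficiency=new_def), Z


def _build_term_block(
    term: TermSpec, data: pd.DataFrame, graph: DistrictGraph | None
) -> SmoothBlock:
    if term.kind == "spline1d":
        cov = term.covariates[0]
        x = data[cov].to_numpy(dtype=float)
        if cov == LOG1P_COVARIATE:
            x = np.log1p(x)
        bd = spline_def_for(
            x, cov, degree=term.degree,
            n_intervals=term.n_intervals, penalty_order=term.penalty_order,
        )
        B = build_bspline_basis(x, bd)
        K = build_difference_penalty(bd.n_basis, bd.penalty_order)
        Bc, Kc, Z = apply_sum_to_zero_constraint(B, K)
        grid = np.linspace(bd.boundary[0], bd.boundary[1], 100)
        return SmoothBlock(
            name=term.name, design=Bc, penalty=Kc, transform=Z,
            meta={"kind": "spline1d", "covariate": cov, "basis": bd, "grid": grid},
        )
    if term.kind == "tensor2d":
        c1, c2 = term.covariates
        x1 = data[c1].to_numpy(dtype=float)
        x2 = data[c2].to_numpy(dtype=float)
        d1 = spline_def_for(x1, c1, degree=term.degree,
                            n_intervals=term.n_intervals,
                            penalty_order=term.penalty_order)
        d2 = spline_def_for(x2, c2, degree=term.degree,
                            n_intervals=term.n_intervals,
                            penalty_order=term.penalty_order)
        B, K = build_tensor_basis(x1, x2, d1, d2)
        Bc, Kc, Z = apply_sum_to_zero_constraint(B, K)
        return SmoothBlock(
            name=term.name, design=Bc, penalty=Kc, transform=Z,
            meta={"kind": "tensor2d", "covariates": (c1, c2),
                  "bases": (d1, d2)},
        )
    if term.kind == "mrf":
        if graph is None:
            raise ValueError("mrf term requires a district graph")
        cov = term.covariates[0]
        waves = sorted(data["wave"].unique().tolist())
        S = graph.n_nodes
        n = len(data)
        didx = data[cov].map(graph.index).to_numpy()
        design = np.zeros((n, S * len(waves)))
        for w, wave in enumerate(waves):
            rows = np.where((data["wave"] == wave).to_numpy())[0]
            design[rows, w * S + didx[rows]] = 1.0
        Kmrf = build_mrf_penalty(graph)
        K = PenaltyMatrix(
            matrix=np.kron(np.eye(len(waves)), Kmrf.matrix),
            rank_deficiency=len(waves) * Kmrf.rank_deficiency,
        )
        # identifiability: district effects sum to zero per wave
        C = np.kron(np.eye(len(waves)), np.ones((1, S)))
        Bc, Kc, Z = _apply_constraints(design, K, C)
        return SmoothBlock(
            name=term.name, design=Bc, penalty=Kc, transform=Z,
            meta={"kind": "mrf", "districts": list(graph.nodes), "waves": waves},
        )
    raise ValueError(term.kind)


def _fixed_block(data: pd.DataFrame, which: str) -> SmoothBlock:
    """Intercept plus effect-coded categorical covariates (diffuse prior)."""
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for cov in CATEGORICAL_COVARIATES:
        vals = data[cov]
        if vals.nunique() < 2:
            logger.info("categorical %s has one level; skipped from x'beta", cov)
            continue
        X, levels = effect_code(vals.to_numpy())
        cols.append(X)
        names.extend(f"{cov}[{lv}]" for lv in levels)
    design = np.column_stack(cols)
    return SmoothBlock(
        name=f"linear_{which}", design=design, penalty=None,
        meta={"kind": "linear", "colnames": names},
    )


def required_columns(spec: ModelSpec) -> list:
    cols = {spec.response, *CATEGORICAL_COVARIATES, }
    for t in spec.terms:
        cols.update(t.covariates)
    return sorted(cols)


def assemble(
    spec: ModelSpec, data: pd.DataFrame, graph: DistrictGraph | None = None
) -> AssembledModel:
    """Build design/penalty blocks for both predictors from a survey table.

    Rows with any missing value in a used column are dropped
    (complete-case); districts in the data must all appear in the graph.
    """
    cols = required_columns(spec)
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise ValueError(f"columns absent from data: {missing_cols}")
    use = data[cols + [c for c in ("psu_id",) if c in data.columns]].copy()
    n0 = len(use)
    complete = use[cols].notna().all(axis=1)
    use = data.loc[complete].reset_index(drop=True)
    if len(use) < n0:
        logger.info("complete-case filter dropped %d of %d rows", n0 - len(use), n0)
    if len(use) == 0:
        raise ValueError("no complete-case rows remain")
    for c in cols:
        if use[c].isna().all():
            raise ValueError(f"covariate {c!r} entirely missing")

    uses_mrf = any(t.kind == "mrf" for t in spec.terms)
    if uses_mrf:
        if graph is None:
            raise ValueError("model contains a spatial term but no graph given")
        unknown = sorted(set(use["district_id"]) - set(graph.nodes))
        if unknown:
            raise ValueError(f"districts absent from graph: {unknown}")

    y = use[spec.response].to_numpy(dtype=float)

    mu_blocks = [_fixed_block(use, "mu")]
    for t in spec.mu_terms():
        mu_blocks.append(_build_term_block(t, use, graph))

    if spec.sigma_modelled:
        sigma_blocks = [_fixed_block(use, "sigma")]
        for t in spec.sigma_terms():
            sigma_blocks.append(_build_term_block(t, use, graph))
    else:
        sigma_blocks = [
            SmoothBlock(
                name="linear_sigma", design=np.ones((len(use), 1)),
                penalty=None, meta={"kind": "linear", "colnames": ["intercept"]},
            )
        ]
    return AssembledModel(
        y=y, mu_blocks=mu_blocks, sigma_blocks=sigma_blocks,
        spec=spec, data=use, graph=graph,
    )


def predict(model: AssembledModel, coefficients: dict) -> tuple[np.ndarray, np.ndarray]:
    """Fitted (mu, sigma) for a coefficient dict keyed ``(side, block name)``.

    mu = eta_mu (identity link); sigma = exp(eta_sigma), strictly positive.
    """
    eta_mu = np.zeros(model.n_obs)
    eta_sigma = np.zeros(model.n_obs)
    for side, blocks, eta in (
        ("mu", model.mu_blocks, eta_mu),
        ("sigma", model.sigma_blocks, eta_sigma),
    ):
        for blk in blocks:
            beta = np.asarray(coefficients[(side, blk.name)], dtype=float)
            if beta.shape != (blk.n_coef,):
                raise ValueError(
                    f"coefficient shape {beta.shape} != ({blk.n_coef},) "
                    f"for block {side}/{blk.name}"
                )
            eta += blk.design @ beta
    return eta_mu, np.exp(eta_sigma)
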