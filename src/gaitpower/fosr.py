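"""Penalized function-on-scalar regression (FoSR) for gait-cycle waveforms.

Fits, per joint, the functional additive model

    y_ij(t) = beta_0(t) + sex_ij * beta_sex + f_age(age_ij, t)
              + f_speed(speed_ij, t) + f_strlen(l_ij, t) + f_ht(h_ij, t)
              + f_age,speed(age_ij, speed_ij, t) + b_j(t) + eps_ij(t)

where t runs over the discrete cycle grid, the f(.,t) are tensor-product
smooths (cubic B-splines with 2nd-order difference penalties, anisotropic in
the covariate and cycle directions), b_j(t) are study-intercept curves with a
shared ridge penalty (the penalized-regression form of functional random
intercepts), and eps is iid Gaussian.  Identifiability: every covariate
margin carries a sum-to-zero constraint over the observed covariate values,
including both margins of the trivariate age x speed x cycle smooth.

Estimation is penalized least squares; smoothing parameters are selected by
exact profiled Gaussian REML (quasi-Newton on log-lambda with analytic
gradients) or by a GCV coordinate grid search.  The normal equations are
assembled in product form — for curves sharing one cycle grid, each design
block between terms m and n is kron(Z_m' Z_n, B_m' B_n) — so the stacked
(n_curves * n_points) x p design matrix is never materialised.

Pointwise confidence bands use the Bayesian posterior covariance
sigma^2 (X'X + S_lambda)^{-1} of the stacked coefficient vector.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.interpolate import BSpline
from scipy.optimize import minimize
from scipy.stats import t as student_t

from .preprocess import PowerWaveform

DEFAULT_COVARIATES = ("age", "speed", "stride_length", "height")


class FoSRError(RuntimeError):
    """Raised for singular designs or failed factorizations."""


class ConvergenceWarning(UserWarning):
    """Smoothing-parameter optimization did not formally converge."""


class ExtrapolationWarning(UserWarning):
    """Prediction requested outside the training covariate range."""


# ---------------------------------------------------------------------------
# bases and penalties
# ---------------------------------------------------------------------------


def bspline_knots(lo: float, hi: float, k_basis: int, degree: int = 3) -> np.ndarray:
    """Clamped knot vector giving exactly ``k_basis`` B-spline functions."""
    if k_basis < degree + 1:
        raise ValueError(f"need at least {degree + 1} basis functions, got {k_basis}")
    interior = np.linspace(lo, hi, k_basis - degree + 1)
    return np.r_[[lo] * degree, interior, [hi] * degree]


def bspline_design(x: np.ndarray, knots: np.ndarray, degree: int = 3) -> np.ndarray:
    lo, hi = knots[degree], knots[-degree - 1]
    xc = np.clip(np.asarray(x, dtype=float), lo, hi)
    return BSpline.design_matrix(xc, knots, degree).toarray()


def difference_penalty(k: int, order: int = 2) -> np.ndarray:
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


def sum_to_zero_transform(basis_rows: np.ndarray) -> np.ndarray:
    """Null-space transform Z with (column means of B) @ Z = 0.

    Applying Z to the basis drops one dimension and makes the smooth average
    to zero over the observed covariate values.
    """
    c = basis_rows.mean(axis=0)
    return sla.null_space(c[None, :])


def _row_kron(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Kronecker product of (n, p) and (n, q) -> (n, p*q)."""
    return np.einsum("ip,iq->ipq", a, b).reshape(a.shape[0], -1)


def _sex_numeric(values) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind in "OUS":
        lowered = np.char.lower(arr.astype(str))
        bad = set(np.unique(lowered)) - {"male", "female"}
        if bad:
            raise ValueError(f"sex must be 'male' or 'female', got {sorted(bad)}")
        return (lowered == "male").astype(float)
    return arr.astype(float)


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Bases, penalties and smoothing-selection settings for one joint.

    Defaults: cubic B-splines with 2nd-order difference penalties; cycle-time
    basis dimension 20 for the full cycle (12 for the ankle subset), covariate
    marginal dimension 8, trivariate term (6, 5, 8), REML selection.
    """

    joint: str
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    k_time: int = 20
    k_cov: int = 8
    k_age: int = 6
    k_speed: int = 5
    k_time3: int = 8
    penalty_order: int = 2
    selection: str = "REML"
    fixed_lambda: Mapping[str, float] | None = None
    maxiter: int = 200
    tol: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("k_time", "k_cov", "k_age", "k_speed", "k_time3"):
            if getattr(self, name) < 4:
                raise ValueError(f"{name} must be >= 4, got {getattr(self, name)}")
        if self.selection not in ("REML", "GCV-grid"):
            raise ValueError(f"selection must be 'REML' or 'GCV-grid', got {self.selection!r}")
        object.__setattr__(self, "covariates", tuple(self.covariates))
        _check_collinear(self.covariates)

    @classmethod
    def for_joint(cls, joint: str, size: str = "default", **overrides) -> "ModelSpec":
        """Convenience constructor.

        ``size='default'`` gives the full-resolution bases; ``size='compact'``
        gives the smaller bases used for replicated simulation studies.
        """
        if size == "default":
            params = dict(k_time=12 if joint == "ankle" else 20)
        elif size == "compact":
            params = dict(k_time=16, k_cov=6, k_age=5, k_speed=4, k_time3=8)
        else:
            raise ValueError(f"unknown size {size!r}")
        params.update(overrides)
        return cls(joint=joint, **params)


def _check_collinear(covariates: Sequence[str]) -> None:
    if (
        "stride_frequency" in covariates
        and "speed" in covariates
        and "stride_length" in covariates
    ):
        raise ValueError(
            "stride_frequency cannot be included together with speed and "
            "stride_length: speed / stride_length determines stride frequency, "
            "so the covariate set would be perfectly collinear"
        )


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


@dataclass
class TermInfo:
    """One additive term: rows factorize as kron(z_i, B) over the cycle grid."""

    name: str
    kind: str  # intercept | sex | smooth | tri | study
    Z: np.ndarray | None  # (n_curves, q) training covariate rows
    B: np.ndarray  # (T, K) cycle-time basis (ones column for sex)
    penalties: list[tuple[str, np.ndarray]]
    meta: dict = field(default_factory=dict)
    offset: int = 0

    @property
    def q(self) -> int:
        return self.Z.shape[1] if self.Z is not None else self.meta["q"]

    @property
    def K(self) -> int:
        return self.B.shape[1]

    @property
    def size(self) -> int:
        return self.q * self.K

    @property
    def slice(self) -> slice:
        return slice(self.offset, self.offset + self.size)


@dataclass
class FoSRDesign:
    spec: ModelSpec
    grid: np.ndarray
    Y: np.ndarray  # (n_curves, T)
    terms: list[TermInfo]
    participant_ids: list[str]
    covariates: pd.DataFrame  # training covariate table (row-aligned with Y)
    study_levels: list[str]
    cov_ranges: dict[str, tuple[float, float]]

    @property
    def n_curves(self) -> int:
        return self.Y.shape[0]

    @property
    def n_points(self) -> int:
        return self.Y.shape[1]

    @property
    def n_cols(self) -> int:
        return sum(t.size for t in self.terms)

    @property
    def n_obs(self) -> int:
        return self.Y.size

    def term(self, name: str) -> TermInfo:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(f"no term named {name!r}")

    # -- row construction for new covariates --------------------------------

    def term_rows(
        self, cov: pd.DataFrame, term: TermInfo, include_study: bool
    ) -> np.ndarray:
        n = len(cov)
        if term.kind == "intercept":
            return np.ones((n, 1))
        if term.kind == "sex":
            return _sex_numeric(cov["sex"].to_numpy())[:, None]
        if term.kind == "smooth":
            x = cov[term.meta["covariate"]].to_numpy(dtype=float)
            return bspline_design(x, term.meta["knots"]) @ term.meta["Zc"]
        if term.kind == "tri":
            za = bspline_design(cov["age"].to_numpy(dtype=float), term.meta["knots_age"])
            za = za @ term.meta["Zc_age"]
            zs = bspline_design(cov["speed"].to_numpy(dtype=float), term.meta["knots_speed"])
            zs = zs @ term.meta["Zc_speed"]
            return _row_kron(za, zs)
        if term.kind == "study":
            if not include_study:
                return np.zeros((n, term.q))
            levels = term.meta["levels"]
            idx = np.empty(n, dtype=int)
            for i, sid in enumerate(cov["study_id"].astype(str)):
                if sid not in levels:
                    raise ValueError(f"unknown study id {sid!r}; known: {levels}")
                idx[i] = levels.index(sid)
            Z = np.zeros((n, term.q))
            Z[np.arange(n), idx] = 1.0
            return Z
        raise ValueError(f"unknown term kind {term.kind!r}")

    def row_design(self, cov: pd.DataFrame, include_study: bool = False) -> np.ndarray:
        """Dense design rows for new records: (n_records * T, p), record-major."""
        n = len(cov)
        blocks = []
        for term in self.terms:
            Z = self.term_rows(cov, term, include_study)
            # kron(z_i, B) stacked over records: (n, T, q*K)
            blocks.append(
                np.einsum("iq,tk->itqk", Z, term.B).reshape(n, self.n_points, term.size)
            )
        return np.concatenate(blocks, axis=2).reshape(n * self.n_points, self.n_cols)

    def check_extrapolation(self, cov: pd.DataFrame) -> np.ndarray:
        """Flag records outside the training covariate range (warn, not error)."""
        flags = np.zeros(len(cov), dtype=bool)
        for name, (lo, hi) in self.cov_ranges.items():
            if name not in cov.columns:
                continue
            x = cov[name].to_numpy(dtype=float)
            flags |= (x < lo) | (x > hi)
        if flags.any():
            warnings.warn(
                f"{int(flags.sum())} prediction record(s) lie outside the training "
                "covariate range; predictions there are extrapolations",
                ExtrapolationWarning,
                stacklevel=3,
            )
        return flags


def build_design(
    waveforms: Iterable[PowerWaveform],
    covariates: pd.DataFrame,
    spec: ModelSpec,
) -> FoSRDesign:
    """Assemble the penalized design for one joint.

    ``waveforms`` may contain several joints; only ``spec.joint`` is used.
    Every waveform must have exactly one covariate record (matched on
    ``participant_id``) with no missing values, and all waveforms must share
    one cycle grid.
    """
    _check_collinear(spec.covariates)
    waves = [w for w in waveforms if w.joint == spec.joint]
    if not waves:
        raise ValueError(f"no waveforms for joint {spec.joint!r}")
    grid = waves[0].grid
    for w in waves:
        if w.grid.shape != grid.shape or not np.array_equal(w.grid, grid):
            raise ValueError("all waveforms must share one cycle grid")
    if np.unique(grid).size < spec.k_time:
        raise ValueError(
            f"need at least k_time={spec.k_time} distinct cycle points, "
            f"got {np.unique(grid).size}"
        )

    cov = covariates.copy()
    if "participant_id" in cov.columns:
        cov = cov.set_index(cov["participant_id"].astype(str), drop=False)
    if cov.index.has_duplicates:
        raise ValueError("covariate table has duplicated participant ids")
    needed = set(spec.covariates) | {"sex", "study_id"}
    missing_cols = needed - set(cov.columns)
    if missing_cols:
        raise ValueError(f"covariate table is missing columns: {sorted(missing_cols)}")

    pids = [w.participant_id for w in waves]
    unknown = sorted(set(pids) - set(cov.index))
    if unknown:
        raise ValueError(f"waveforms without covariate records: {unknown[:5]}")
    cov = cov.loc[pids].reset_index(drop=True)
    if cov[sorted(needed)].isna().any().any():
        bad = sorted(c for c in needed if cov[c].isna().any())
        raise ValueError(f"missing covariate values in columns: {bad}")

    Y = np.vstack([w.values for w in waves])
    T = grid.size
    lo_t, hi_t = float(grid[0]), float(grid[-1])
    B_t = bspline_design(grid, bspline_knots(lo_t, hi_t, spec.k_time))
    S_t = difference_penalty(spec.k_time, spec.penalty_order)

    terms: list[TermInfo] = [
        TermInfo("intercept", "intercept", np.ones((len(waves), 1)), B_t,
                 [("intercept.t", S_t.copy())]),
        TermInfo("sex", "sex", _sex_numeric(cov["sex"].to_numpy())[:, None],
                 np.ones((T, 1)), []),
    ]

    cov_ranges: dict[str, tuple[float, float]] = {}
    for name in spec.covariates:
        x = cov[name].to_numpy(dtype=float)
        lo, hi = float(x.min()), float(x.max())
        if lo == hi:
            raise ValueError(f"covariate {name!r} is constant; design would be rank-deficient")
        cov_ranges[name] = (lo, hi)
        knots = bspline_knots(lo, hi, spec.k_cov)
        Braw = bspline_design(x, knots)
        Zc = sum_to_zero_transform(Braw)
        Zrows = Braw @ Zc
        q = Zrows.shape[1]
        S_x = Zc.T @ difference_penalty(spec.k_cov, spec.penalty_order) @ Zc
        terms.append(
            TermInfo(
                name=name,
                kind="smooth",
                Z=Zrows,
                B=B_t,
                penalties=[
                    (f"{name}.x", np.kron(S_x, np.eye(spec.k_time))),
                    (f"{name}.t", np.kron(np.eye(q), S_t)),
                ],
                meta={"covariate": name, "knots": knots, "Zc": Zc},
            )
        )

    if {"age", "speed"} <= set(spec.covariates):
        B_t3 = bspline_design(grid, bspline_knots(lo_t, hi_t, spec.k_time3))
        S_t3 = difference_penalty(spec.k_time3, spec.penalty_order)
        age = cov["age"].to_numpy(dtype=float)
        speed = cov["speed"].to_numpy(dtype=float)
        knots_a = bspline_knots(age.min(), age.max(), spec.k_age)
        knots_s = bspline_knots(speed.min(), speed.max(), spec.k_speed)
        Ba, Bs = bspline_design(age, knots_a), bspline_design(speed, knots_s)
        Za, Zs = sum_to_zero_transform(Ba), sum_to_zero_transform(Bs)
        Sa = Za.T @ difference_penalty(spec.k_age, spec.penalty_order) @ Za
        Ss = Zs.T @ difference_penalty(spec.k_speed, spec.penalty_order) @ Zs
        qa, qs = Za.shape[1], Zs.shape[1]
        terms.append(
            TermInfo(
                name="age_speed",
                kind="tri",
                Z=_row_kron(Ba @ Za, Bs @ Zs),
                B=B_t3,
                penalties=[
                    ("age_speed.age", np.kron(Sa, np.eye(qs * spec.k_time3))),
                    ("age_speed.speed", np.kron(np.eye(qa), np.kron(Ss, np.eye(spec.k_time3)))),
                    ("age_speed.t", np.kron(np.eye(qa * qs), S_t3)),
                ],
                meta={"knots_age": knots_a, "Zc_age": Za, "knots_speed": knots_s, "Zc_speed": Zs},
            )
        )

    study_levels = sorted(cov["study_id"].astype(str).unique())
    Z_study = np.zeros((len(waves), len(study_levels)))
    for i, sid in enumerate(cov["study_id"].astype(str)):
        Z_study[i, study_levels.index(sid)] = 1.0
    terms.append(
        TermInfo(
            name="study",
            kind="study",
            Z=Z_study,
            B=B_t,
            penalties=[("study.ridge", np.eye(len(study_levels) * spec.k_time))],
            meta={"levels": study_levels},
        )
    )

    offset = 0
    for t in terms:
        t.offset = offset
        offset += t.size

    return FoSRDesign(
        spec=spec,
        grid=grid.copy(),
        Y=Y,
        terms=terms,
        participant_ids=pids,
        covariates=cov,
        study_levels=study_levels,
        cov_ranges=cov_ranges,
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _assemble_normal_equations(design: FoSRDesign):
    """X'X, X'y and y'y in product form without materialising X."""
    terms = design.terms
    p = design.n_cols
    XtX = np.zeros((p, p))
    Xty = np.zeros(p)
    Y = design.Y
    for m, tm in enumerate(terms):
        A = tm.B.T @ Y.T  # (K_m, n)
        Xty[tm.slice] = (A @ tm.Z).T.ravel()
        for tn in terms[: m + 1]:
            block = np.kron(tm.Z.T @ tn.Z, tm.B.T @ tn.B)
            XtX[tm.slice, tn.slice] = block
            if tn is not tm:
                XtX[tn.slice, tm.slice] = block.T
    return XtX, Xty, float(np.sum(Y * Y))


@dataclass
class _PenaltyComponent:
    name: str
    term: TermInfo
    S: np.ndarray


class _REMLProblem:
    """Profiled Gaussian REML score and its analytic gradient in log-lambda."""

    def __init__(self, design: FoSRDesign):
        self.design = design
        self.XtX, self.Xty, self.yty = _assemble_normal_equations(design)
        self.p = design.n_cols
        self.nobs = design.n_obs
        self.components: list[_PenaltyComponent] = []
        for term in design.terms:
            for name, S in term.penalties:
                self.components.append(_PenaltyComponent(name, term, S))
        # per-term penalty structure: rank / null dimension of the summed
        # penalty (independent of positive lambdas)
        self.term_pen: dict[str, list[int]] = {}
        for i, c in enumerate(self.components):
            self.term_pen.setdefault(c.term.name, []).append(i)
        self.block_rank: dict[str, int] = {}
        self.block_logdet_const: dict[str, float] = {}
        null_total = 0
        for term in design.terms:
            idx = self.term_pen.get(term.name, [])
            if not idx:
                null_total += term.size
                continue
            S_sum = sum(self.components[i].S for i in idx)
            eigvals = sla.eigh(S_sum, eigvals_only=True)
            tol = eigvals.max() * term.size * np.finfo(float).eps * 10
            rank = int((eigvals > tol).sum())
            self.block_rank[term.name] = rank
            null_total += term.size - rank
            if len(idx) == 1:
                pos = np.sort(sla.eigh(self.components[idx[0]].S, eigvals_only=True))[-rank:]
                self.block_logdet_const[term.name] = float(np.log(pos).sum())
        self.null_dim = null_total
        self.r_floor = 1e-12 * (self.yty + 1.0)

    def initial_rho(self) -> np.ndarray:
        rho0 = np.empty(len(self.components))
        for k, c in enumerate(self.components):
            sl = c.term.slice
            tr_x = np.trace(self.XtX[sl, sl])
            tr_s = np.trace(c.S)
            rho0[k] = np.log(max(tr_x, 1e-8) / max(tr_s, 1e-8))
            if c.term.kind == "study":
                # ridge lambda ~ sigma^2 / tau^2; crude method-of-moments start
                # from the spread of per-study mean curves (the trace-ratio
                # start sits in the flat large-lambda basin of the REML score
                # and can trap the optimizer there)
                Y = self.design.Y
                Zs = c.term.Z
                counts = Zs.sum(axis=0)
                means = (Zs.T @ Y) / np.maximum(counts, 1)[:, None]
                dev = means - Y.mean(axis=0)
                tau2 = max(float(np.mean(dev**2)), 1e-6)
                sigma2 = max(float(np.var(Y - Y.mean(axis=0))), 1e-6) * 0.5
                rho0[k] = np.log(sigma2 / tau2)
        return rho0

    def _penalty_matrix(self, lam: np.ndarray) -> np.ndarray:
        S = np.zeros((self.p, self.p))
        for lk, c in zip(lam, self.components):
            sl = c.term.slice
            S[sl, sl] += lk * c.S
        return S

    def _factor(self, H: np.ndarray):
        jitter = 0.0
        scale = np.mean(np.diag(H)) or 1.0
        for attempt in range(4):
            try:
                return sla.cho_factor(H + jitter * np.eye(self.p), lower=True)
            except sla.LinAlgError:
                jitter = scale * 10.0 ** (-10 + 2 * attempt)
        raise FoSRError(
            "penalized normal equations are singular (rank-deficient design "
            "after constraints?)"
        )

    def solve(self, lam: np.ndarray):
        H = self.XtX + self._penalty_matrix(lam)
        cho = self._factor(H)
        beta = sla.cho_solve(cho, self.Xty)
        return cho, beta

    def score(self, rho: np.ndarray, with_grad: bool = True):
        lam = np.exp(np.clip(rho, -40, 40))
        cho, beta = self.solve(lam)
        r = max(self.yty - beta @ self.Xty, self.r_floor)
        logdet_H = 2.0 * np.sum(np.log(np.diag(cho[0])))
        n_eff = self.nobs - self.null_dim

        logdet_S = 0.0
        block_pinv: dict[str, np.ndarray] = {}
        for term_name, idx in self.term_pen.items():
            rank = self.block_rank[term_name]
            if len(idx) == 1:
                k = idx[0]
                logdet_S += rank * np.log(lam[k]) + self.block_logdet_const[term_name]
            else:
                S_blk = sum(lam[i] * self.components[i].S for i in idx)
                w, V = sla.eigh(S_blk)
                pos_w, pos_V = w[-rank:], V[:, -rank:]
                pos_w = np.maximum(pos_w, w[-1] * 1e-300 + 1e-300)
                logdet_S += float(np.log(pos_w).sum())
                if with_grad:
                    block_pinv[term_name] = (pos_V / pos_w) @ pos_V.T

        score = n_eff * np.log(r) + logdet_H - logdet_S
        if not with_grad:
            return score

        Hinv = sla.cho_solve(cho, np.eye(self.p))
        grad = np.empty(len(lam))
        for k, c in enumerate(self.components):
            sl = c.term.slice
            b = beta[sl]
            dr = lam[k] * (b @ c.S @ b)  # envelope theorem
            d_logdet_H = lam[k] * float(np.sum(Hinv[sl, sl] * c.S))
            idx = self.term_pen[c.term.name]
            if len(idx) == 1:
                d_logdet_S = float(self.block_rank[c.term.name])
            else:
                d_logdet_S = lam[k] * float(np.sum(block_pinv[c.term.name] * c.S))
            grad[k] = n_eff * dr / r + d_logdet_H - d_logdet_S
        return score, grad

    def gcv(self, rho: np.ndarray) -> float:
        lam = np.exp(np.clip(rho, -40, 40))
        cho, beta = self.solve(lam)
        rss = self.yty - 2 * beta @ self.Xty + beta @ self.XtX @ beta
        edf = float(np.trace(sla.cho_solve(cho, self.XtX)))
        return self.nobs * max(rss, self.r_floor) / (self.nobs - edf) ** 2


def _select_lambda(problem: _REMLProblem, spec: ModelSpec):
    names = [c.name for c in problem.components]
    if spec.fixed_lambda is not None:
        missing = set(names) - set(spec.fixed_lambda)
        if missing:
            raise ValueError(f"fixed_lambda is missing penalties: {sorted(missing)}")
        lam = np.array([float(spec.fixed_lambda[n]) for n in names])
        return lam, {"method": "fixed", "converged": True}

    rho0 = problem.initial_rho()
    if spec.selection == "REML":
        bounds = [(r - 25.0, r + 25.0) for r in rho0]

        def _optimize(start):
            return minimize(
                problem.score,
                start,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": spec.maxiter, "ftol": spec.tol * 1e-2, "gtol": 1e-4},
            )

        res = _optimize(rho0)
        rho, best, nit = res.x, res.fun, res.nit
        # coordinate-probe polish: the REML score is flat as any full-rank
        # penalty's lambda grows, which can strand a quasi-Newton run on a
        # shoulder far above the optimum; probe each coordinate and restart
        # from any strict improvement
        for _ in range(3):
            improved = False
            for k in range(len(rho)):
                for delta in (-8.0, -4.0, -2.0, 2.0, 4.0, 8.0):
                    trial = rho.copy()
                    trial[k] = np.clip(rho[k] + delta, *bounds[k])
                    val = problem.score(trial, with_grad=False)
                    if val < best - 1e-6 * (abs(best) + 1.0):
                        rho, best, improved = trial, val, True
            if not improved:
                break
            res = _optimize(rho)
            rho, best, nit = res.x, res.fun, nit + res.nit
        if not res.success:
            warnings.warn(
                "REML smoothing-parameter optimization did not formally converge: "
                f"{res.message} after {nit} iterations "
                f"(score {res.fun:.6g}, |grad| {np.abs(res.jac).max():.3g})",
                ConvergenceWarning,
                stacklevel=3,
            )
        return np.exp(np.clip(rho, -40, 40)), {
            "method": "REML",
            "converged": bool(res.success),
            "iterations": int(nit),
            "score": float(best),
        }

    # GCV grid: coordinate descent over per-penalty log-lambda grids
    rho = rho0.copy()
    best = problem.gcv(rho)
    for _ in range(3):
        improved = False
        for k in range(len(rho)):
            for delta in np.linspace(-8.0, 8.0, 9):
                trial = rho.copy()
                trial[k] = rho0[k] + delta
                val = problem.gcv(trial)
                if val < best - 1e-12:
                    best, rho, improved = val, trial, True
        if not improved:
            break
    return np.exp(rho), {"method": "GCV-grid", "converged": True, "score": float(best)}


@dataclass
class SexEffectTest:
    estimate: float
    se: float
    tstat: float
    pvalue: float
    df: float


@dataclass
class FittedFoSR:
    """A fitted function-on-scalar regression for one joint."""

    design: FoSRDesign
    beta: np.ndarray
    Vb: np.ndarray  # posterior covariance sigma^2 (X'X + S)^{-1}
    sigma2: float
    edf: float
    df_resid: float
    lambdas: dict[str, float]
    selection_info: dict
    _Vc: np.ndarray | None = None

    @property
    def spec(self) -> ModelSpec:
        return self.design.spec

    @property
    def joint(self) -> str:
        return self.design.spec.joint

    def coefficients(self, term_name: str) -> np.ndarray:
        """Coefficient block of one term, reshaped (q, K)."""
        term = self.design.term(term_name)
        return self.beta[term.slice].reshape(term.q, term.K)

    # -- prediction ----------------------------------------------------------

    def predict(
        self,
        covariates: pd.DataFrame,
        include_study: bool = False,
        with_se: bool = True,
    ) -> dict[str, np.ndarray]:
        """Predicted curves for new covariate records.

        Returns ``mean`` (n, T) and, with ``with_se``, pointwise ``se`` and
        95% bands ``lower``/``upper`` (estimate +/- 1.96 se), plus a boolean
        ``extrapolated`` flag per record.  ``include_study=False`` drops the
        study curves (population-level prediction).
        """
        cov = covariates.reset_index(drop=True)
        flags = self.design.check_extrapolation(cov)
        X = self.design.row_design(cov, include_study=include_study)
        n, T = len(cov), self.design.n_points
        mean = (X @ self.beta).reshape(n, T)
        out = {"mean": mean, "extrapolated": flags, "grid": self.design.grid.copy()}
        if with_se:
            se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, self.Vb, X), 0.0))
            se = se.reshape(n, T)
            out["se"] = se
            out["lower"] = mean - 1.96 * se
            out["upper"] = mean + 1.96 * se
        return out

    def fitted_values(self) -> np.ndarray:
        """In-sample fitted curves (n_curves, T), study terms included."""
        X = self.design.row_design(self.design.covariates, include_study=True)
        return (X @ self.beta).reshape(self.design.n_curves, self.design.n_points)

    def intercept_curve(self, with_se: bool = True):
        """beta_0(t) with pointwise SE from its posterior covariance block."""
        term = self.design.term("intercept")
        coef = self.beta[term.slice]
        mean = term.B @ coef
        if not with_se:
            return mean
        Vblock = self.Vb[term.slice, term.slice]
        se = np.sqrt(np.maximum(np.einsum("tj,jk,tk->t", term.B, Vblock, term.B), 0.0))
        return mean, se

    def evaluate_term(self, term_name: str, x: np.ndarray) -> np.ndarray:
        """Coefficient surface f_term(x, t) on outer(x, grid)."""
        term = self.design.term(term_name)
        if term.kind != "smooth":
            raise ValueError(f"evaluate_term expects a bivariate smooth, got {term.kind!r}")
        Zx = bspline_design(np.asarray(x, dtype=float), term.meta["knots"]) @ term.meta["Zc"]
        return Zx @ self.coefficients(term_name) @ term.B.T

    def study_curves(self) -> dict[str, np.ndarray]:
        """Estimated study-intercept curves b_j(t)."""
        coef = self.coefficients("study")
        term = self.design.term("study")
        return {
            level: term.B @ coef[j]
            for j, level in enumerate(term.meta["levels"])
        }

    # -- inference -----------------------------------------------------------

    def sex_effect_test(self) -> SexEffectTest:
        term = self.design.term("sex")
        i = term.offset
        est = float(self.beta[i])
        se = float(np.sqrt(self.Vb[i, i]))
        tstat = est / se
        pvalue = 2.0 * float(student_t.sf(abs(tstat), self.df_resid))
        return SexEffectTest(est, se, tstat, pvalue, self.df_resid)

    def smoothing_uncertainty_covariance(self) -> np.ndarray:
        """Posterior covariance corrected for smoothing-parameter uncertainty.

        V_c = V_b + J V_rho J' with J_k = d beta_hat / d rho_k =
        -lambda_k H^{-1} S_k beta_hat and V_rho the inverse curvature of the
        REML score in log-lambda.  Conditioning on the selected lambda
        understates the uncertainty of penalized components (and of scalar
        effects partially confounded with them, e.g. sex vs. the shrunken
        study curves); this is the standard first-order correction.
        """
        if self._Vc is not None:
            return self._Vc
        if self.selection_info.get("method") != "REML":
            self._Vc = self.Vb
            return self._Vc
        problem = _REMLProblem(self.design)
        lam = np.array([self.lambdas[c.name] for c in problem.components])
        rho = np.log(lam)
        m = len(rho)
        hess = np.zeros((m, m))
        h = 1e-3
        for k in range(m):
            e = np.zeros(m)
            e[k] = h
            _, gp = problem.score(rho + e)
            _, gm = problem.score(rho - e)
            hess[:, k] = (gp - gm) / (4 * h)  # Hessian of score/2
        hess = 0.5 * (hess + hess.T)
        w, V = sla.eigh(hess)
        w = np.maximum(w, 1e-2)  # floor flat directions (lambda -> inf shoulders)
        V_rho = (V / w) @ V.T
        cho, beta = problem.solve(lam)
        J = np.zeros((self.beta.size, m))
        for k, c in enumerate(problem.components):
            v = np.zeros(self.beta.size)
            sl = c.term.slice
            v[sl] = c.S @ beta[sl]
            J[:, k] = -lam[k] * sla.cho_solve(cho, v)
        Vc = self.Vb + J @ V_rho @ J.T
        self._Vc = 0.5 * (Vc + Vc.T)
        return self._Vc

    def posterior_draws(
        self, n_draws: int, seed: int, smoothing_uncertainty: bool = False
    ) -> np.ndarray:
        """Multivariate-normal coefficient draws N(beta, Vb), seeded.

        With ``smoothing_uncertainty=True`` the draws use the corrected
        covariance from :meth:`smoothing_uncertainty_covariance`.
        """
        if n_draws < 0:
            raise ValueError("n_draws must be >= 0")
        if n_draws == 0:
            return np.empty((0, self.beta.size))
        cov = self.smoothing_uncertainty_covariance() if smoothing_uncertainty else self.Vb
        rng = np.random.default_rng(seed)
        scale = float(np.mean(np.diag(cov))) or 1.0
        jitter = 0.0
        for attempt in range(5):
            try:
                L = sla.cholesky(cov + jitter * np.eye(self.beta.size), lower=True)
                break
            except sla.LinAlgError:
                jitter = scale * 10.0 ** (-12 + 2 * attempt)
        else:
            raise FoSRError("posterior covariance could not be factorized")
        return self.beta + rng.standard_normal((n_draws, self.beta.size)) @ L.T

    def export_term_surfaces(self, out_dir: str | Path, n_points: int = 50) -> dict[str, Path]:
        """Write each coefficient function as a CSV grid.

        The intercept curve goes out as (cycle_point, estimate, se); every
        bivariate smooth as a (n_points x T) grid with the covariate value in
        the first column and one column per cycle point.
        """
        out_dir = Path(out_dir)
        if not out_dir.is_dir():
            raise FileNotFoundError(f"output directory does not exist: {out_dir}")
        paths: dict[str, Path] = {}
        mean, se = self.intercept_curve()
        path = out_dir / "term_intercept.csv"
        pd.DataFrame(
            {"cycle_point": self.design.grid, "estimate_wkg": mean, "se_wkg": se}
        ).to_csv(path, index=False)
        paths["intercept"] = path
        for term in self.design.terms:
            if term.kind != "smooth":
                continue
            lo, hi = self.design.cov_ranges[term.meta["covariate"]]
            xgrid = np.linspace(lo, hi, n_points)
            surf = self.evaluate_term(term.name, xgrid)
            df = pd.DataFrame(
                surf, columns=[f"t{int(t)}" for t in self.design.grid]
            )
            df.insert(0, term.meta["covariate"], xgrid)
            path = out_dir / f"term_{term.name}.csv"
            df.to_csv(path, index=False)
            paths[term.name] = path
        return paths

    # -- serialization -------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Serialize to an .npz bundle (arrays + a JSON metadata entry)."""
        path = Path(path)
        arrays: dict[str, np.ndarray] = {
            "beta": self.beta,
            "Vb": self.Vb,
            "grid": self.design.grid,
            "Y": self.design.Y,
        }
        meta = {
            "spec": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self.design.spec).items()
                if k != "fixed_lambda"
            },
            "sigma2": self.sigma2,
            "edf": self.edf,
            "df_resid": self.df_resid,
            "lambdas": self.lambdas,
            "selection_info": self.selection_info,
            "participant_ids": self.design.participant_ids,
            "study_levels": self.design.study_levels,
            "cov_ranges": {k: list(v) for k, v in self.design.cov_ranges.items()},
            "terms": [],
        }
        for i, term in enumerate(self.design.terms):
            tmeta = {"name": term.name, "kind": term.kind, "offset": term.offset}
            arrays[f"term{i}_B"] = term.B
            arrays[f"term{i}_Z"] = term.Z
            for key, val in term.meta.items():
                if isinstance(val, np.ndarray):
                    arrays[f"term{i}_{key}"] = val
                    tmeta[f"array:{key}"] = True
                else:
                    tmeta[key] = val
            meta["terms"].append(tmeta)
        cov = self.design.covariates
        meta["covariate_columns"] = list(cov.columns)
        for c in cov.columns:
            arr = cov[c].to_numpy()
            if arr.dtype == object:
                arr = arr.astype(str)
            arrays[f"cov_{c}"] = arr
        arrays["meta_json"] = np.array(json.dumps(meta))
        np.savez_compressed(path, **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FittedFoSR":
        with np.load(Path(path), allow_pickle=False) as data:
            meta = json.loads(str(data["meta_json"]))
            spec_d = dict(meta["spec"])
            spec_d["covariates"] = tuple(spec_d["covariates"])
            spec = ModelSpec(**spec_d)
            terms = []
            for i, tmeta in enumerate(meta["terms"]):
                extra = {}
                for key, val in tmeta.items():
                    if key.startswith("array:"):
                        extra[key.removeprefix("array:")] = data[f"term{i}_{key.removeprefix('array:')}"]
                    elif key not in ("name", "kind", "offset"):
                        extra[key] = val
                term = TermInfo(
                    name=tmeta["name"],
                    kind=tmeta["kind"],
                    Z=data[f"term{i}_Z"],
                    B=data[f"term{i}_B"],
                    penalties=[],
                    meta=extra,
                    offset=tmeta["offset"],
                )
                terms.append(term)
            cov = pd.DataFrame(
                {c: data[f"cov_{c}"] for c in meta["covariate_columns"]}
            )
            design = FoSRDesign(
                spec=spec,
                grid=data["grid"],
                Y=data["Y"],
                terms=terms,
                participant_ids=list(meta["participant_ids"]),
                covariates=cov,
                study_levels=list(meta["study_levels"]),
                cov_ranges={k: tuple(v) for k, v in meta["cov_ranges"].items()},
            )
            return cls(
                design=design,
                beta=data["beta"],
                Vb=data["Vb"],
                sigma2=float(meta["sigma2"]),
                edf=float(meta["edf"]),
                df_resid=float(meta["df_resid"]),
                lambdas=dict(meta["lambdas"]),
                selection_info=dict(meta["selection_info"]),
            )


def fit(design: FoSRDesign) -> FittedFoSR:
    """Penalized least squares with REML/GCV smoothing selection.

    Solves (X'X + sum_k lambda_k S_k) beta = X'y at the selected lambda;
    sigma^2 is the unpenalized residual sum of squares over the residual
    degrees of freedom n - edf, with edf = tr[(X'X + S)^{-1} X'X].
    """
    problem = _REMLProblem(design)
    lam, info = _select_lambda(problem, design.spec)
    cho, beta = problem.solve(lam)
    rss = float(
        problem.yty - 2 * beta @ problem.Xty + beta @ problem.XtX @ beta
    )
    edf = float(np.trace(sla.cho_solve(cho, problem.XtX)))
    df_resid = problem.nobs - edf
    sigma2 = max(rss, 0.0) / df_resid
    Vb = sigma2 * sla.cho_solve(cho, np.eye(problem.p))
    Vb = 0.5 * (Vb + Vb.T)
    lambdas = {c.name: float(l) for c, l in zip(problem.components, lam)}
    return FittedFoSR(
        design=design,
        beta=beta,
        Vb=Vb,
        sigma2=float(sigma2),
        edf=edf,
        df_resid=float(df_resid),
        lambdas=lambdas,
        selection_info=info,
    )


def fit_model(
    waveforms: Iterable[PowerWaveform],
    covariates: pd.DataFrame,
    spec: ModelSpec,
) -> FittedFoSR:
    """Build the design and fit in one call."""
    return fit(build_design(waveforms, covariates, spec))
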