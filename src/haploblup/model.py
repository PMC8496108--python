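"""GREML variance components, BLUE of fixed effects, GBLUP and reliabilities.

Six prediction models are supported, differing in the genetic components
included (A = SNP additive, D = SNP dominance, H = haplotype additive):

    Model-1: A + D + H     Model-4: H
    Model-2: A + H         Model-5: A + D
    Model-3: D + H         Model-6: A

The phenotypic model for the training individuals is

    y = X b + sum_c u_c + e,     u_c ~ N(0, sigma2_c K_c),  e ~ N(0, sigma2_e I)

with K_c the component's genomic relationship matrix. Variance components
are estimated by REML with an EM warm start followed by average-information
(AI) steps; negative estimates are floored at a small fraction of the
phenotypic variance. Genetic values for all individuals (training and
masked) are predicted by the conditional-expectation (CE) form

    u_c(all) = sigma2_c K_c[all, train] P y

which avoids the effect-level mixed model equations; those serve only as a
small-instance oracle (see :mod:`haploblup.mme`). Reliabilities follow the
variance-ratio form var(g_hat)/var(g) with all cross-component terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .coding import GRMSet

__all__ = [
    "MODEL_COMPONENTS",
    "ModelSpec",
    "VarianceComponents",
    "HeritabilityEstimates",
    "ModelFit",
    "fit_model",
    "blue_fixed_effects",
]

MODEL_COMPONENTS: dict[int, tuple[str, ...]] = {
    1: ("add", "dom", "hap"),
    2: ("add", "hap"),
    3: ("dom", "hap"),
    4: ("hap",),
    5: ("add", "dom"),
    6: ("add",),
}


@dataclass(frozen=True)
class ModelSpec:
    model_id: int

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_COMPONENTS:
            raise ValueError(f"unknown model id {self.model_id}; use 1..6")

    @property
    def components(self) -> tuple[str, ...]:
        return MODEL_COMPONENTS[self.model_id]

    @property
    def uses_haplotypes(self) -> bool:
        return "hap" in self.components


@dataclass
class VarianceComponents:
    """REML estimates; ``genetic`` maps component name to sigma^2."""

    genetic: dict[str, float]
    residual: float

    @property
    def total(self) -> float:
        return sum(self.genetic.values()) + self.residual

    def lambda_(self, component: str) -> float:
        return self.residual / self.genetic[component]


@dataclass
class HeritabilityEstimates:
    """Per-component and total genomic heritabilities for one model fit."""

    model_id: int
    by_component: dict[str, float]

    @property
    def h2_total(self) -> float:
        """Total genomic heritability: the exact sum of the components."""
        return sum(self.by_component.values())

    def __getitem__(self, component: str) -> float:
        return self.by_component[component]


def _sym_pinv_logdet(m: np.ndarray, rtol: float = 1e-10):
    """Eigen-threshold pseudo-inverse and log-pseudo-determinant."""
    vals, vecs = np.linalg.eigh(m)
    thr = rtol * max(vals.max(), 0.0) if vals.size else 0.0
    keep = vals > thr
    inv_vals = np.where(keep, 1.0 / np.where(keep, vals, 1.0), 0.0)
    pinv = (vecs * inv_vals) @ vecs.T
    logdet = float(np.log(vals[keep]).sum())
    return pinv, logdet, int(keep.sum())


def _factor_v(v: np.ndarray):
    jitter = 0.0
    for _ in range(6):
        try:
            return cho_factor(
                v + jitter * np.eye(v.shape[0]), lower=True
            )
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-10 * np.trace(v) / v.shape[0])
    raise np.linalg.LinAlgError("V is singular beyond jitter tolerance")


class _RemlState:
    """V, P and the REML log-likelihood at one parameter value."""

    def __init__(self, y, x, ks, theta):
        self.theta = np.asarray(theta, dtype=float)
        n = y.size
        v = np.zeros((n, n))
        for t, k in zip(self.theta, ks):
            v += t * k
        cf = _factor_v(v)
        vinv = cho_solve(cf, np.eye(n))
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        vinv_x = vinv @ x
        xtvx = x.T @ vinv_x
        xtvx_pinv, logdet_x, rank_x = _sym_pinv_logdet(xtvx)
        p = vinv - vinv_x @ xtvx_pinv @ vinv_x.T
        p = (p + p.T) / 2.0
        py = p @ y
        self.V, self.Vinv, self.P, self.Py = v, vinv, p, py
        self.xtvx_pinv, self.vinv_x, self.rank_x = xtvx_pinv, vinv_x, rank_x
        self.loglik = -0.5 * (logdet_v + logdet_x + float(y @ py))


def _greml(
    y: np.ndarray,
    x: np.ndarray,
    ks: Sequence[np.ndarray],
    max_iter: int = 200,
    tol: float = 1e-6,
    n_em_steps: int = 3,
    algorithm: str = "em-ai",
    floor_frac: float = 1e-8,
    init: Optional[np.ndarray] = None,
):
    """REML for theta = (sigma2_c..., sigma2_e); ks must end with I.

    Returns (theta, loglik_trace, converged, final _RemlState).
    """
    if algorithm not in {"em", "ai", "em-ai"}:
        raise ValueError(f"unknown REML algorithm {algorithm!r}")
    n = y.size
    nk = len(ks)
    vy = float(np.var(y, ddof=1)) if n > 1 else float(y[0] ** 2) or 1.0
    if vy == 0.0:
        vy = 1.0
    floor = floor_frac * vy
    if init is None:
        theta = np.full(nk, 0.5 * vy / max(nk - 1, 1))
        theta[-1] = 0.5 * vy
    else:
        theta = np.asarray(init, dtype=float).copy()
    theta = np.maximum(theta, floor)
    state = _RemlState(y, x, ks, theta)
    trace = [state.loglik]
    converged = False
    for it in range(max_iter):
        tr_pk = np.array([float(np.sum(state.P * k)) for k in ks])
        kpy = [k @ state.Py for k in ks]
        ypkpy = np.array([float(state.Py @ v) for v in kpy])
        score = -0.5 * (tr_pk - ypkpy)
        use_em = algorithm == "em" or (
            algorithm == "em-ai" and it < n_em_steps
        )
        if use_em:
            new_theta = theta + theta**2 * (ypkpy - tr_pk) / n
            new_theta = np.maximum(new_theta, floor)
            new_state = _RemlState(y, x, ks, new_theta)
        else:
            pkpy = [state.P @ v for v in kpy]
            ai = 0.5 * np.array(
                [[float(kpy[i] @ pkpy[j]) for j in range(nk)] for i in range(nk)]
            )
            ai = (ai + ai.T) / 2.0
            try:
                delta = np.linalg.solve(
                    ai + 1e-12 * np.eye(nk) * max(ai.max(), 1.0), score
                )
            except np.linalg.LinAlgError:
                delta = score / np.maximum(np.diag(ai), 1e-12)
            step = 1.0
            new_state = None
            for _ in range(20):
                cand = np.maximum(theta + step * delta, floor)
                cand_state = _RemlState(y, x, ks, cand)
                if cand_state.loglik >= state.loglik - 1e-10:
                    new_theta, new_state = cand, cand_state
                    break
                step *= 0.5
            if new_state is None:  # AI failed; fall back to one EM step
                new_theta = np.maximum(
                    theta + theta**2 * (ypkpy - tr_pk) / n, floor
                )
                new_state = _RemlState(y, x, ks, new_theta)
        rel_change = np.max(np.abs(new_theta - theta)) / vy
        ll_change = new_state.loglik - state.loglik
        theta, state = new_theta, new_state
        trace.append(state.loglik)
        # parameter stability, or likelihood stalled past the warm start
        # (components pinned at the floor keep a nonzero score forever);
        # the stall threshold follows tol so tight fits are not cut short
        if rel_change < tol or (
            it >= n_em_steps
            and abs(ll_change)
            < max(0.01 * tol, 1e-16) * max(1.0, abs(state.loglik))
        ):
            converged = True
            break
    return theta, trace, converged, state


def blue_fixed_effects(
    y: np.ndarray, x: np.ndarray, v: np.ndarray
) -> np.ndarray:
    """Generalized least squares b = (X' V^-1 X)^- X' V^-1 y."""
    cf = _factor_v(v)
    vinv_x = cho_solve(cf, x)
    xtvx_pinv, _, _ = _sym_pinv_logdet(x.T @ vinv_x)
    return xtvx_pinv @ (vinv_x.T @ y)


@dataclass
class ModelFit:
    """A fitted SNP/haplotype mixed model on one training set."""

    spec: ModelSpec
    varcomp: VarianceComponents
    herit: HeritabilityEstimates
    beta: np.ndarray
    train_idx: np.ndarray
    y: np.ndarray                      # all individuals (NaN-free on train)
    X: np.ndarray                      # full design, all individuals
    grms: dict[str, np.ndarray] = field(repr=False)
    P: np.ndarray = field(repr=False)          # training-level projection
    Py: np.ndarray = field(repr=False)
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = True

    @property
    def n_individuals(self) -> int:
        return self.y.size

    def gblup(self) -> dict[str, np.ndarray]:
        """CE predictions of each component for ALL individuals, plus 'total'.

        u_c(all) = sigma2_c K_c[all, train] P y; 'total' is the exact sum of
        the included component predictions.
        """
        out: dict[str, np.ndarray] = {}
        total = np.zeros(self.n_individuals)
        for comp in self.spec.components:
            u = self.varcomp.genetic[comp] * (
                self.grms[comp][:, self.train_idx] @ self.Py
            )
            out[comp] = u
            total += u
        out["total"] = total
        return out

    def _g_total(self) -> np.ndarray:
        g = np.zeros((self.n_individuals, self.n_individuals))
        for comp in self.spec.components:
            g += self.varcomp.genetic[comp] * self.grms[comp]
        return g

    def reliability(self) -> np.ndarray:
        """Theoretical accuracy R_gi of the total genetic value, in [0, 1].

        R_gi^2 = [G Z' P Z G]_ii / [diag G]_ii with G the summed genetic
        covariance over included components (all cross terms included; terms
        for absent components are simply not present).
        """
        g = self._g_total()
        gz = g[:, self.train_idx]
        num = np.einsum("ij,jk,ik->i", gz, self.P, gz)
        den = np.diag(g)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        if np.any(r2 < -1e-10):
            raise FloatingPointError("negative squared reliability")
        r2 = np.clip(r2, 0.0, 1.0)
        return np.sqrt(r2)

    def fitted_fixed(self) -> np.ndarray:
        return self.X @ self.beta


def _resolve_grms(
    grms: Union[GRMSet, dict[str, np.ndarray]], components: tuple[str, ...]
) -> dict[str, np.ndarray]:
    table = grms.by_component() if isinstance(grms, GRMSet) else dict(grms)
    missing = [c for c in components if c not in table]
    if missing:
        raise ValueError(f"missing relationship matrices for {missing}")
    return {c: table[c] for c in components}


def fit_model(
    y: np.ndarray,
    X: np.ndarray,
    grms: Union[GRMSet, dict[str, np.ndarray]],
    model: Union[int, ModelSpec] = 1,
    train_idx: Optional[np.ndarray] = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    n_em_steps: int = 3,
    algorithm: str = "em-ai",
    floor_frac: float = 1e-8,
    init: Optional[np.ndarray] = None,
) -> ModelFit:
    """GREML + BLUE on the training subset; returns a :class:`ModelFit`.

    ``train_idx`` selects the individuals whose phenotypes enter the REML;
    all others are masked (their phenotypes are never touched) and receive
    predictions through :meth:`ModelFit.gblup`.
    """
    spec = model if isinstance(model, ModelSpec) else ModelSpec(model)
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        raise ValueError("X row count does not match y")
    n_all = y.size
    if train_idx is None:
        train_idx = np.arange(n_all)
    train_idx = np.asarray(train_idx, dtype=np.int64)
    if np.any(np.isnan(y[train_idx])):
        raise ValueError("missing phenotypes in the training set")
    comp_grms = _resolve_grms(grms, spec.components)
    for name, k in comp_grms.items():
        if k.shape != (n_all, n_all):
            raise ValueError(f"GRM {name!r} has wrong shape {k.shape}")
    ytr = y[train_idx]
    xtr = X[np.ix_(train_idx, np.arange(X.shape[1]))]
    ks = [k[np.ix_(train_idx, train_idx)] for k in comp_grms.values()]
    ks.append(np.eye(train_idx.size))
    theta, trace, converged, state = _greml(
        ytr,
        xtr,
        ks,
        max_iter=max_iter,
        tol=tol,
        n_em_steps=n_em_steps,
        algorithm=algorithm,
        floor_frac=floor_frac,
        init=init,
    )
    genetic = dict(zip(spec.components, theta[:-1]))
    varcomp = VarianceComponents(genetic=genetic, residual=float(theta[-1]))
    total = varcomp.total
    herit = HeritabilityEstimates(
        model_id=spec.model_id,
        by_component={c: float(v / total) for c, v in genetic.items()},
    )
    beta = state.xtvx_pinv @ (state.vinv_x.T @ ytr)
    return ModelFit(
        spec=spec,
        varcomp=varcomp,
        herit=herit,
        beta=beta,
        train_idx=train_idx,
        y=y,
        X=X,
        grms=comp_grms,
        P=state.P,
        Py=state.Py,
        loglik_trace=trace,
        converged=converged,
    )
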