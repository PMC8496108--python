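"""Explicit mixed-model-equation (MME) solver for small instances.

The production path predicts genetic values and effects through conditional
expectations at the individual level, which scales when effects vastly
outnumber individuals. This module builds Henderson's equations explicitly
for the equivalent model y = Xb + sum_c T_c u_c + e (T_c = W_c / sqrt(k_c),
var(u_c) = sigma2_c I) and solves them directly. It exists to certify the CE
path on instances small enough to afford the effect-level system, including
the per-effect variance decomposition

    sigma2_hat_c = u_c' u_c / [m_c - tr(C^cc) lambda_c],
    sigma2_hat_ci = u_ci^2 / [m_c - tr(C^cc) lambda_c],

where C^cc is the random-effect block of the inverse coefficient matrix and
lambda_c = sigma2_e / sigma2_c. The total is the sum of the per-effect terms
by construction, and at a REML stationary point it coincides with the GREML
estimate of sigma2_c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MMESolution", "solve_mme"]


@dataclass
class MMESolution:
    beta: np.ndarray
    effects: dict[str, np.ndarray]        # BLUP of u_c per component
    component_values: dict[str, np.ndarray]   # T_c u_c per training individual
    c_inv: np.ndarray                      # inverse coefficient matrix
    blocks: dict[str, slice]               # slice of each component in c_inv
    lambdas: dict[str, float]
    sigma2_e: float

    def tr_c_block(self, component: str) -> float:
        s = self.blocks[component]
        return float(np.trace(self.c_inv[s, s]))

    def effective_m(self, component: str) -> float:
        """m_c - tr(C^cc) lambda_c, the denominator of the variance split."""
        m = self.effects[component].size
        return m - self.tr_c_block(component) * self.lambdas[component]

    def per_effect_variance(self, component: str) -> np.ndarray:
        """Per-effect variance contributions; they sum to total_variance."""
        return self.effects[component] ** 2 / self.effective_m(component)

    def total_variance(self, component: str) -> float:
        u = self.effects[component]
        return float(u @ u) / self.effective_m(component)


def solve_mme(
    y: np.ndarray,
    x: np.ndarray,
    t_mats: dict[str, np.ndarray],
    sigma2: dict[str, float],
    sigma2_e: float,
) -> MMESolution:
    """Solve Henderson's equations for the given (fixed) variance values.

    ``t_mats`` maps component name to its n x m_c scaled design matrix on the
    training individuals; ``sigma2`` maps component name to its variance.
    """
    y = np.asarray(y, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    comps = list(t_mats)
    lambdas = {c: sigma2_e / sigma2[c] for c in comps}
    p = x.shape[1]
    sizes = [t_mats[c].shape[1] for c in comps]
    dim = p + sum(sizes)
    c_mat = np.zeros((dim, dim))
    rhs = np.zeros(dim)
    c_mat[:p, :p] = x.T @ x
    rhs[:p] = x.T @ y
    blocks: dict[str, slice] = {}
    off = p
    for c, m in zip(comps, sizes):
        blocks[c] = slice(off, off + m)
        off += m
    for c in comps:
        s = blocks[c]
        t = t_mats[c]
        c_mat[:p, s] = x.T @ t
        c_mat[s, :p] = t.T @ x
        c_mat[s, s] = t.T @ t + lambdas[c] * np.eye(t.shape[1])
        rhs[s] = t.T @ y
        for c2 in comps:
            if c2 == c:
                continue
            c_mat[s, blocks[c2]] = t.T @ t_mats[c2]
    try:
        c_inv = np.linalg.inv(c_mat)
        sol = np.linalg.solve(c_mat, rhs)
    except np.linalg.LinAlgError:
        c_inv = np.linalg.pinv(c_mat)
        sol = c_inv @ rhs
    effects = {c: sol[blocks[c]] for c in comps}
    values = {c: t_mats[c] @ effects[c] for c in comps}
    return MMESolution(
        beta=sol[:p],
        effects=effects,
        component_values=values,
        c_inv=c_inv,
        blocks=blocks,
        lambdas=lambdas,
        sigma2_e=sigma2_e,
    )


def mme_reliability(
    solution: MMESolution,
    t_all: dict[str, np.ndarray],
    sigma2: dict[str, float],
) -> np.ndarray:
    """Reliability-based accuracy from the MME inverse, for all individuals.

    R_i = sqrt(1 - PEV_ii / var(g_i)) with PEV from M C^- M' sigma2_e, where
    M stacks zeros for the fixed part and T_c (built on all individuals) for
    each random component.
    """
    comps = list(solution.effects)
    n = next(iter(t_all.values())).shape[0]
    p = solution.beta.size
    m_mat = np.zeros((n, p + sum(t_all[c].shape[1] for c in comps)))
    for c in comps:
        m_mat[:, solution.blocks[c]] = t_all[c]
    pev = np.einsum(
        "ij,jk,ik->i", m_mat, solution.c_inv, m_mat
    ) * solution.sigma2_e
    var_g = np.zeros(n)
    for c in comps:
        var_g += sigma2[c] * np.einsum("ij,ij->i", t_all[c], t_all[c])
    r2 = np.clip(1.0 - pev / var_g, 0.0, 1.0)
    return np.sqrt(r2)
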