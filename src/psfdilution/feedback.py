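"""General host-soil-microbiome feedback model over multispecies communities.

Plant frequencies P_i on the simplex follow replicator dynamics

    dP_i/dt = P_i (w_i - sum_j w_j P_j),   w = A P,

where the interaction matrix entry sigma_ij is the fitness of species i in a
soil environment dominated by species j.  The matrix is parameterized from
the dissimilarity-based pairwise PSF predictor: conspecific fitness w_mono
is half the predicted feedback at complete dissimilarity (conspecific
effects assumed equal across species), and off-diagonals are chosen so the
pairwise feedback recovered from sigma (sigma_ii + sigma_jj - sigma_ij -
sigma_ji) equals the predicted PSF of that pair exactly.

For every community assembled from the pool the interior equilibrium is
obtained by Cramer's rule (P_i = det A_i / sum_j det A_j, column i replaced
by ones), screened for feasibility (all frequencies strictly inside (0,1)),
local stability (dominant eigenvalue of the simplex-reduced Jacobian), and
negative community-level feedback (dominant eigenvalue of the symmetrized
sigma on the zero-sum tangent space).  Passing communities report a model
complementarity CE = N x (w_hat - w_mono), the plot-level predicted PSF at
the equilibrium frequencies and the corresponding pathogen dilution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import helmert

from .microbiome import DissimilarityMatrix
from .predictor import PsfPredictor, pathogen_dilution, predict_pairwise_psf

FEASIBILITY_EPS = 1e-9
STABILITY_EPS = -1e-9


@dataclass
class InteractionMatrix:
    species: tuple[str, ...]
    sigma: np.ndarray
    w_mono: float

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = len(self.species)
        if self.sigma.shape != (n, n):
            raise ValueError("sigma must be square and match the species list")
        if not np.all(np.isfinite(self.sigma)):
            raise ValueError("sigma must be finite")
        if not np.allclose(np.diag(self.sigma), self.w_mono, atol=1e-9):
            raise ValueError("diagonal must equal the common conspecific fitness")


@dataclass
class EquilibriumResult:
    P_hat: np.ndarray
    w_hat: float
    feasible: bool
    degenerate: bool = False
    dominant_eig: float = np.nan
    stable: bool = False
    community_feedback: float = np.nan
    CE_model: float = np.nan


def conspecific_sigma(predictor: PsfPredictor) -> float:
    """Common conspecific fitness w_mono.

    Pairwise feedback between two species with completely dissimilar
    microbiomes is the sum of their (equal) conspecific effects, so w_mono is
    half the predicted PSF at dissimilarity 1; the heterospecific baseline
    for a fully dissimilar pair is set to zero (any common offset is
    dynamics-irrelevant by shift invariance).
    """
    psf_full = predictor.predict({g: 1.0 for g in predictor.coefficients})
    return psf_full / 2.0


def build_interaction_matrix(
    predictor: PsfPredictor,
    dissims: Mapping[str, DissimilarityMatrix],
    subset: Sequence[str] | None = None,
) -> InteractionMatrix:
    """Symmetric sigma with sigma_ij = w_mono - PSF_ij / 2.

    Construction identity: sigma_ii + sigma_jj - sigma_ij - sigma_ji equals
    the predicted pairwise PSF exactly.
    """
    psf = predict_pairwise_psf(predictor, dissims)
    species = tuple(subset) if subset is not None else tuple(psf.index)
    missing = [s for s in species if s not in psf.index]
    if missing:
        raise KeyError(f"species missing from dissimilarities: {missing}")
    w_mono = conspecific_sigma(predictor)
    psi = psf.loc[list(species), list(species)].to_numpy(dtype=float)
    sigma = w_mono - psi / 2.0
    np.fill_diagonal(sigma, w_mono)
    return InteractionMatrix(species=species, sigma=sigma, w_mono=w_mono)


def pairwise_feedback(sigma: np.ndarray, i: int = 0, j: int = 1) -> float:
    """Two-species feedback I_s recovered from an interaction matrix."""
    return float(sigma[i, i] + sigma[j, j] - sigma[i, j] - sigma[j, i])


def cramer_equilibrium(sigma: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Interior equilibrium by Cramer's rule.

    Replaces each column i of sigma with ones and forms P_i = det A_i /
    sum_j det A_j; the equilibrium fitness is det A / sum_j det A_j.
    Returns (P_hat, w_hat, degenerate).
    """
    n = sigma.shape[0]
    dets = np.empty(n)
    for i in range(n):
        Ai = sigma.copy()
        Ai[:, i] = 1.0
        dets[i] = np.linalg.det(Ai)
    total = dets.sum()
    if abs(total) < 1e-12 * max(1.0, np.abs(dets).max()):
        return np.full(n, np.nan), np.nan, True
    return dets / total, float(np.linalg.det(sigma) / total), False


def equilibrium(A: InteractionMatrix) -> EquilibriumResult:
    """Feasibility of the community coexistence equilibrium.

    The Cramer-rule frequencies are cross-checked against the direct linear
    solve of sigma x = 1 (P = x / sum x, w_hat = 1 / sum x); disagreement or
    a singular system flags the equilibrium degenerate (not feasible).
    """
    sigma = A.sigma
    if sigma.shape[0] < 2:
        raise ValueError("equilibrium requires N >= 2")
    P, w_hat, degenerate = cramer_equilibrium(sigma)
    if not degenerate:
        try:
            x = np.linalg.solve(sigma, np.ones(sigma.shape[0]))
            if abs(x.sum()) > 1e-12:
                P_direct = x / x.sum()
                if not np.allclose(P, P_direct, atol=1e-8):
                    degenerate = True
        except np.linalg.LinAlgError:
            # singular sigma but nonzero sum of cofactor determinants:
            # w_hat = 0 equilibria remain meaningful, keep the Cramer result
            pass
    feasible = (not degenerate) and bool(
        np.all(P > FEASIBILITY_EPS) and np.all(P < 1 - FEASIBILITY_EPS)
    )
    return EquilibriumResult(P_hat=P, w_hat=w_hat, feasible=feasible, degenerate=degenerate)


def replicator_jacobian(sigma: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the simplex-reduced replicator system.

    The last frequency is substituted as P_N = 1 - sum of the others; the
    returned matrix is (N-1) x (N-1).
    """
    n = sigma.shape[0]
    w = sigma @ P
    wbar = float(w @ P)
    c = w + sigma.T @ P  # d(wbar)/dP_k
    J_full = np.diag(w - wbar) + P[:, None] * (sigma - c[None, :])
    return J_full[: n - 1, : n - 1] - J_full[: n - 1, n - 1][:, None]


def stability(A: InteractionMatrix, P_hat: np.ndarray) -> tuple[float, bool]:
    """Dominant eigenvalue of the reduced Jacobian at the equilibrium."""
    P_hat = np.asarray(P_hat, dtype=float)
    if np.any(~np.isfinite(P_hat)) or abs(P_hat.sum() - 1) > 1e-6:
        raise ValueError("stability requires a feasible equilibrium on the simplex")
    J = replicator_jacobian(A.sigma, P_hat)
    dom = float(np.max(np.linalg.eigvals(J).real))
    return dom, dom < STABILITY_EPS


def tangent_basis(n: int) -> np.ndarray:
    """Orthonormal basis (n x (n-1)) of the zero-sum tangent space."""
    return helmert(n, full=False).T


def community_feedback(A: InteractionMatrix | np.ndarray) -> float:
    """Community-level feedback I_c.

    Dominant eigenvalue of the symmetrized interaction matrix restricted to
    the zero-sum tangent space of the simplex; negative I_c generalizes
    pairwise negative feedback (at N = 2 its sign equals the sign of I_s).
    """
    sigma = A.sigma if isinstance(A, InteractionMatrix) else np.asarray(A, dtype=float)
    n = sigma.shape[0]
    B = tangent_basis(n)
    sym = (sigma + sigma.T) / 2.0
    return float(np.max(np.linalg.eigvalsh(B.T @ sym @ B)))


def model_complementarity(result: EquilibriumResult, w_mono: float) -> float:
    """Model complementarity CE = N x (w_hat - w_mono)."""
    n = len(result.P_hat)
    return float(n * (result.w_hat - w_mono))


def analyze_community(A: InteractionMatrix) -> EquilibriumResult:
    """Equilibrium, stability, community feedback and CE for one community."""
    res = equilibrium(A)
    res.community_feedback = community_feedback(A)
    if res.feasible:
        res.dominant_eig, res.stable = stability(A, res.P_hat)
        res.CE_model = model_complementarity(res, A.w_mono)
    return res


def enumerate_communities(
    species: Sequence[str], min_size: int = 2
) -> Iterator[tuple[str, ...]]:
    """All subsets of size >= 2, sizes ascending, lexicographic by index."""
    species = list(species)
    if len(species) > 22:
        raise ValueError(
            "pool too large for exhaustive enumeration (max 22); sample subsets instead"
        )
    for size in range(min_size, len(species) + 1):
        yield from itertools.combinations(species, size)


def screen_pool(
    predictor: PsfPredictor,
    dissims: Mapping[str, DissimilarityMatrix],
    species: Sequence[str] | None = None,
    max_richness: int | None = None,
) -> pd.DataFrame:
    """Screen every community from the pool for coexistence and overyielding.

    Vectorized over all communities of each richness: batched linear solves
    give the equilibria, batched eigendecompositions the stability and
    community-feedback classifications.  A community *passes* when it is
    feasible, locally stable and exhibits negative community feedback; for
    every community the predicted plot PSF at the equilibrium frequencies
    and the matching pathogen dilution are reported.
    """
    psf = predict_pairwise_psf(predictor, dissims)
    pool = list(species) if species is not None else list(psf.index)
    if len(pool) > 22:
        raise ValueError("pool too large for exhaustive enumeration (max 22)")
    w_mono = conspecific_sigma(predictor)
    psi_full = psf.loc[pool, pool].to_numpy(dtype=float)
    np.fill_diagonal(psi_full, 0.0)
    sigma_full = w_mono - psi_full / 2.0
    np.fill_diagonal(sigma_full, w_mono)
    top = min(len(pool), max_richness or len(pool))
    frames = []
    for size in range(2, top + 1):
        idx = np.array(list(itertools.combinations(range(len(pool)), size)))
        m = len(idx)
        S = sigma_full[idx[:, :, None], idx[:, None, :]]
        psi = psi_full[idx[:, :, None], idx[:, None, :]]
        dets = np.linalg.det(S)
        x = np.full((m, size), np.nan)
        ok = np.abs(dets) > 1e-12
        if ok.any():
            x[ok] = np.linalg.solve(S[ok], np.ones(size))
        sum_x = x.sum(axis=1)
        degenerate = ~ok | ~np.isfinite(sum_x) | (np.abs(sum_x) < 1e-12)
        with np.errstate(invalid="ignore", divide="ignore"):
            P = x / sum_x[:, None]
            w_hat = 1.0 / sum_x
        feasible = (
            ~degenerate
            & np.all(P > FEASIBILITY_EPS, axis=1)
            & np.all(P < 1 - FEASIBILITY_EPS, axis=1)
        )
        # community feedback on the tangent space (sigma is symmetric here)
        B = tangent_basis(size)
        sym = (S + np.swapaxes(S, 1, 2)) / 2.0
        T = np.einsum("ji,mjk,kl->mil", B, sym, B, optimize=True)
        i_c = np.linalg.eigvalsh(T)[:, -1]
        dom = np.full(m, np.nan)
        if feasible.any():
            Sf, Pf = S[feasible], P[feasible]
            w = np.einsum("mij,mj->mi", Sf, Pf)
            wbar = np.einsum("mi,mi->m", w, Pf)
            c = w + np.einsum("mji,mj->mi", Sf, Pf)
            J = Pf[:, :, None] * (Sf - c[:, None, :])
            J[:, np.arange(size), np.arange(size)] += w - wbar[:, None]
            J_red = J[:, : size - 1, : size - 1] - J[:, : size - 1, size - 1][:, :, None]
            if size == 2:
                dom[feasible] = J_red[:, 0, 0]
            else:
                dom[feasible] = np.max(np.linalg.eigvals(J_red).real, axis=1)
        stable = feasible & (dom < STABILITY_EPS)
        ce = size * (w_hat - w_mono)
        plot_psf = 0.5 * np.einsum("mi,mij,mj->m", P, psi, P, optimize=True)
        dilution = -plot_psf * (1.0 - 1.0 / size)
        frames.append(
            pd.DataFrame(
                {
                    "community": ["|".join(pool[i] for i in row) for row in idx],
                    "richness": size,
                    "degenerate": degenerate,
                    "feasible": feasible,
                    "stable": stable,
                    "dominant_eig": dom,
                    "I_c": i_c,
                    "negative_feedback": i_c < 0,
                    "w_hat": w_hat,
                    "CE_model": ce,
                    "predicted_psf": plot_psf,
                    "dilution": dilution,
                    "passes": feasible & stable & (i_c < 0),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def screen_summary(screen: pd.DataFrame) -> pd.DataFrame:
    """Per-richness counts and CE summaries of the community screen."""
    rows = []
    for richness, grp in screen.groupby("richness", sort=True):
        passing = grp[grp["passes"]]
        rows.append(
            {
                "richness": int(richness),
                "n_communities": len(grp),
                "n_feasible": int(grp["feasible"].sum()),
                "n_stable": int(grp["stable"].sum()),
                "n_passing": len(passing),
                "median_CE_model": float(passing["CE_model"].median())
                if len(passing)
                else np.nan,
                "median_dilution": float(passing["dilution"].median())
                if len(passing)
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def integrate_dynamics(
    A: InteractionMatrix,
    P0: Sequence[float],
    t_max: float = 200.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
):
    """Integrate the replicator dynamics from a simplex start.

    Uses adaptive Runge-Kutta (RK45) on the reduced system (the last
    frequency substituted as one minus the rest), so the trajectory stays on
    the simplex by construction; total frequency is exact to ~1e-12.
    Returns (times, trajectory) with one row per time point.
    """
    P0 = np.asarray(P0, dtype=float)
    if abs(P0.sum() - 1.0) > 1e-9 or np.any(P0 < -1e-12):
        raise ValueError("initial frequencies must lie on the simplex")
    sigma = A.sigma
    n = sigma.shape[0]

    def rhs(_t, q):
        P = np.append(q, 1.0 - q.sum())
        w = sigma @ P
        return (P * (w - float(w @ P)))[: n - 1]

    sol = solve_ivp(rhs, (0.0, t_max), P0[: n - 1], method="RK45",
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    traj = np.column_stack([sol.y.T, 1.0 - sol.y.T.sum(axis=1)])
    return sol.t, traj
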