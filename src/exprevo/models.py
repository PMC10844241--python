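"""Per-gene evolutionary model selection: BM vs OU1 vs multi-optimum OU.

For each gene (and tissue), replicate-level traits on the log2(TPM+1) scale
are fitted under three Gaussian models on the species tree:

* BM    — neutral drift (root state, sigma2, sigma2_e);
* OU1   — stabilizing selection toward a single optimum;
* OUM   — stabilizing selection with optimum shifts on a subset of edges,
          interpreted as expression changes on those branches.

Shift configurations are enumerated exhaustively up to ``max_shifts`` (176
configurations on the six-taxon tree at the default of 3) and scored with a
phylogenetically informed BIC:

    pBIC = -2 logL + n_var ln N + 2 ln C(E, s) + sum_j max(ln I_jj, ln N)

where n_var counts the variance-type parameters (sigma2, sigma2_e and, for
OU, alpha), N is the number of observations, the combinatorial term over the
E candidate edges penalizes the size of the searched configuration space,
and I_jj is the observed Fisher information of the j-th mean parameter
(optimum) — the Laplace correction that the plain k ln N penalty lacks.
The information term matters: with replicated data the OU family has a
degenerate maximum at very large alpha where shifted species receive
near-free means estimated at replicate precision (information ~ 1/sigma2_e
per parameter, far exceeding N); penalizing each optimum by the log of its
actual information, floored at ln N, removes that overfitting channel while
never penalizing less than BIC.

Likelihoods are profiled: for fixed (alpha, lambda = sigma2_e / sigma2) the
optimum values and the overall scale have closed-form GLS solutions, so the
search is a dense grid over (alpha, lambda) followed by local refinement.
The design matrix of an OUM configuration is assembled from per-edge
"reversion band" weights, making the whole grid evaluation a handful of
batched linear-algebra calls shared across genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from exprevo.tree import Regime, SpeciesTree, regime_from_shifts

__all__ = [
    "ModelFit",
    "GeneFit",
    "enumerate_shift_configs",
    "fit_bm",
    "fit_ou",
    "select_model",
    "select_models",
    "classify_branches",
    "change_events",
]

LOG2PI = math.log(2.0 * math.pi)
DEGENERATE_VAR = 1e-12

ALPHA_MIN, ALPHA_MAX = 1e-6, 50.0  # 1/My; the surface is flat beyond these
LAMBDA_MIN, LAMBDA_MAX = 1e-8, 50.0

ALPHA_GRID = np.geomspace(5e-3, ALPHA_MAX, 22)
LAMBDA_GRID = np.concatenate([[1e-6], np.geomspace(1e-3, 30.0, 16)])


@dataclass
class ModelFit:
    """One fitted model for one gene."""

    model: str  # "BM" | "OU1" | "OUM"
    logL: float
    k: int
    pbic: float
    alpha: float  # 0 for BM
    sigma2: float
    sigma2_e: float
    theta: np.ndarray  # optima; for BM the single entry is the root state
    shift_edges: tuple[int, ...] = ()
    directions: dict[int, str] = field(default_factory=dict)

    @property
    def n_shifts(self) -> int:
        return len(self.shift_edges)


@dataclass
class GeneFit:
    gene: str
    tissue: str | None
    fits: dict[str, ModelFit]  # keys BM, OU1, OUM (best OUM)
    selected: str
    degenerate: bool = False

    @property
    def best(self) -> ModelFit:
        return self.fits[self.selected]

    def branch_classes(self, tree: SpeciesTree) -> dict[int, str]:
        """Edge -> neutral / constrained / divergent under the selected model."""
        if self.selected == "BM":
            return {e: "neutral" for e in tree.edges}
        classes = {e: "constrained" for e in tree.edges}
        for e in self.best.shift_edges:
            classes[e] = "divergent"
        return classes


def enumerate_shift_configs(tree: SpeciesTree, max_shifts: int = 3) -> list[Regime]:
    """All shift configurations with 0..max_shifts shift edges.

    Every non-root edge is a candidate; on the six-taxon rooted binary tree
    (10 edges) the default yields 1 + 10 + 45 + 120 = 176 regimes.
    """
    if max_shifts < 0:
        raise ValueError("max_shifts must be >= 0")
    edges = tree.edges
    if max_shifts > len(edges):
        import warnings

        warnings.warn("max_shifts exceeds edge count; capped")
        max_shifts = len(edges)
    configs = []
    for s in range(max_shifts + 1):
        for subset in combinations(edges, s):
            configs.append(regime_from_shifts(tree, subset))
    return configs


# --------------------------------------------------------------------------
# likelihood engine
# --------------------------------------------------------------------------


class _Engine:
    """Precomputed quantities for replicate-level GLS likelihoods."""

    def __init__(self, tree: SpeciesTree, species_of_sample: np.ndarray):
        self.tree = tree
        self.idx = np.asarray(species_of_sample, dtype=int)
        self.N = len(self.idx)
        self.T = tree.shared_time_matrix()
        self.D = tree.patristic_matrix()
        self.tip_depth = tree.tip_depths()
        self.edges = list(tree.edges)
        self.edge_pos = {e: t for t, e in enumerate(self.edges)}
        # per tip: list of (edge position, d_near, d_far) along the root path
        self.paths = []
        for i in range(tree.n_taxa):
            segs, d = [], 0.0
            for e in tree.root_path(i):
                segs.append((self.edge_pos[e], d, d + tree.lengths[e]))
                d += tree.lengths[e]
            self.paths.append(segs)

    # ---- covariance ----
    def _unit_cov(self, alpha: float | None, lam: float) -> np.ndarray:
        """Sample-level covariance / sigma2 at given alpha (None = BM)."""
        if alpha is None:
            K = self.T
        else:
            K = np.exp(-alpha * self.D) / (2.0 * alpha)
        V = K[np.ix_(self.idx, self.idx)].copy()
        V[np.diag_indices_from(V)] += lam
        return V

    def _bands(self, alpha: float) -> tuple[np.ndarray, np.ndarray]:
        """Root weight r (n_taxa,) and band matrix B (n_taxa x n_edges)."""
        n = self.tree.n_taxa
        r = np.exp(-alpha * self.tip_depth)
        B = np.zeros((n, len(self.edges)))
        for i in range(n):
            for t, d_near, d_far in self.paths[i]:
                B[i, t] = math.exp(-alpha * d_near) - math.exp(-alpha * d_far)
        return r, B

    def whiten(self, alpha: float | None, lam: float):
        V = self._unit_cov(alpha, lam)
        L = np.linalg.cholesky(V + 1e-10 * np.eye(self.N))
        logdet = 2.0 * np.log(np.diag(L)).sum()
        return L, logdet

    def design(self, alpha, lam, shift_edges=()):
        if alpha is None or not shift_edges:
            return np.ones((self.N, 1))
        regime = regime_from_shifts(self.tree, shift_edges)
        r, B = self._bands(alpha)
        Xt = np.zeros((self.tree.n_taxa, regime.n_optima))
        Xt[:, 0] = r
        for t, e in enumerate(self.edges):
            Xt[:, regime.optimum_index[e]] += B[:, t]
        return Xt[self.idx]

    def profile_loglik(self, y, alpha, lam, shift_edges=(), reml=False):
        """Profile logL over mean params and scale; returns fit pieces.

        alpha=None fits BM.  Returns (logL, sigma2_hat_unbiased, sigma2e,
        theta, info_diag) where info_diag holds the observed-information
        diagonals of the mean parameters (for the pBIC Laplace term).
        With ``reml=True`` the restricted likelihood is returned instead
        (used for unbiased variance estimation, never for model selection
        across different mean structures).
        """
        from scipy.linalg import solve_triangular

        L, logdet = self.whiten(alpha, lam)
        X = self.design(alpha, lam, shift_edges)
        wy = solve_triangular(L, y, lower=True)
        wX = solve_triangular(L, X, lower=True)
        beta, _, _, _ = np.linalg.lstsq(wX, wy, rcond=None)
        resid = wy - wX @ beta
        rss = float(resid @ resid)
        p = X.shape[1]
        sigma2_ml = max(rss / self.N, 1e-300)
        sigma2 = rss / max(self.N - p, 1)
        R = np.linalg.qr(wX, mode="r")
        info_diag = np.diag(R) ** 2 / sigma2_ml
        if reml:
            df = self.N - p
            with np.errstate(divide="ignore"):
                logdet_xx = float(np.log(np.abs(np.diag(R)) ** 2).sum())
            logL = -0.5 * (
                df * (LOG2PI + math.log(max(sigma2, 1e-300)) + 1.0)
                + logdet
                + logdet_xx
            )
        else:
            logL = -0.5 * (self.N * (LOG2PI + math.log(sigma2_ml) + 1.0) + logdet)
        return logL, sigma2, lam * sigma2, beta, info_diag


def _pbic(
    logL: float, n_var: int, N: int, n_edges: int, s: int, info_diag
) -> float:
    """Laplace-corrected phylogenetic BIC (see module docstring)."""
    with np.errstate(divide="ignore"):
        mean_pen = float(
            np.maximum(np.log(np.maximum(info_diag, 0.0)), math.log(N)).sum()
        )
    return (
        -2.0 * logL
        + n_var * math.log(N)
        + 2.0 * math.log(math.comb(n_edges, s))
        + mean_pen
    )


def _config_assignments(tree: SpeciesTree, configs: list[Regime]):
    """Group configs by shift count; build 11 x (s+1) assignment matrices.

    Design columns are linear combinations of [root weight | edge bands].
    """
    edges = list(tree.edges)
    pos = {e: t for t, e in enumerate(edges)}
    groups: dict[int, list[tuple[Regime, np.ndarray]]] = {}
    for regime in configs:
        s = len(regime.shift_edges)
        A = np.zeros((1 + len(edges), s + 1))
        A[0, 0] = 1.0
        for e in edges:
            A[1 + pos[e], regime.optimum_index[e]] = 1.0
        groups.setdefault(s, []).append((regime, A))
    return groups


def select_models(
    Y: pd.DataFrame,
    species_of_sample,
    tree: SpeciesTree,
    max_shifts: int = 3,
    tissue: str | None = None,
    refine: bool = True,
    on: str = "replicates",
    models: tuple[str, ...] = ("BM", "OU1", "OUM"),
) -> list[GeneFit]:
    """Fit BM, OU1 and all OUM shift configurations for every gene (row of Y).

    Y: genes x samples on the trait scale (log2(TPM+1) by default upstream).
    ``species_of_sample``: species name per sample column.

    ``on`` controls the selection likelihood.  The default
    ``"species_means"`` collapses replicates to one mean per species and
    models the six species values with the pure evolutionary kernel
    (V = sigma2 K), as the shift-search literature does; this keeps the
    shift search honestly calibrated, because a free within-species noise
    term at the species level lets every model collapse to white noise.
    ``"replicates"`` keeps all samples and adds the replicate-noise ratio
    lambda = sigma2_e/sigma2 as a free parameter (EvoGeneX-style full
    likelihood); use it for parameter estimation rather than shift counting.
    """
    from scipy.linalg import solve_triangular

    if on not in ("species_means", "replicates"):
        raise ValueError("on must be 'species_means' or 'replicates'")
    if on == "species_means":
        sample_sp = pd.Series(list(species_of_sample), index=Y.columns)
        Y = Y.T.groupby(sample_sp).mean().T
        species_of_sample = list(Y.columns)
        lambda_grid = np.array([0.0])
        free_lambda = False
    else:
        lambda_grid = LAMBDA_GRID
        free_lambda = True

    sp_idx = tree.tip_index(list(species_of_sample))
    eng = _Engine(tree, sp_idx)
    genes = list(Y.index)
    Ymat = np.ascontiguousarray(Y.to_numpy(dtype=float).T)  # samples x genes
    N, G = Ymat.shape
    n_edges = len(tree.edges)
    logN = math.log(N)

    degenerate = Ymat.var(axis=0) < DEGENERATE_VAR

    if not models or any(m not in ("BM", "OU1", "OUM") for m in models):
        raise ValueError("models must be a non-empty subset of BM/OU1/OUM")
    if "OUM" not in models:
        max_shifts = 0
    configs = enumerate_shift_configs(tree, max_shifts)
    groups = _config_assignments(tree, configs)  # includes the s=0 (OU1) config

    # flat config indexing, grouped by shift count
    flat_regimes: list[Regime] = []
    group_arrays = {}
    for s, items in sorted(groups.items()):
        regs, As = zip(*items)
        base = len(flat_regimes)
        flat_regimes.extend(regs)
        group_arrays[s] = (base, np.stack(As))  # (m, 1+n_edges, s+1)
    C = len(flat_regimes)

    # per (config, gene): best ML logL over the grid and the pBIC at that point
    ou_logL = np.full((C, G), -np.inf)
    ou_pbic = np.full((C, G), np.inf)
    ou_alpha = np.zeros((C, G))
    ou_lam = np.zeros((C, G))
    bm_logL = np.full(G, -np.inf)
    bm_pbic = np.full(G, np.inf)
    bm_lam = np.zeros(G)

    ones = np.ones((N, 1))

    def logl_from_rss(rss, logdet):
        rss = np.maximum(rss, 1e-300)
        return -0.5 * (N * (LOG2PI + np.log(rss / N) + 1.0) + logdet)

    def mean_penalty(log_r2, log_s2ml):
        """sum_j max(ln I_jj, ln N); log_r2 (m,k), log_s2ml (m,G) or (G,)."""
        d = log_r2[..., None] - log_s2ml[:, None, :]  # (m, k, G)
        return np.maximum(d, logN).sum(axis=1)  # (m, G)

    for lam in lambda_grid if "BM" in models else []:  # BM sweep
        L, logdet = eng.whiten(None, lam)
        wy = solve_triangular(L, Ymat, lower=True)
        base_ss = (wy * wy).sum(axis=0)
        wx = solve_triangular(L, ones, lower=True)[:, 0]
        xdot = wx @ wx
        rss = base_ss - (wx @ wy) ** 2 / xdot
        logL = logl_from_rss(rss, logdet)
        log_s2 = np.log(np.maximum(rss / N, 1e-300))
        pen = np.maximum(math.log(xdot) - log_s2, logN)
        n_var_bm = 2 if free_lambda else 1
        pbic = -2.0 * logL + n_var_bm * logN + pen
        improved = pbic < bm_pbic
        bm_logL[improved] = logL[improved]
        bm_pbic[improved] = pbic[improved]
        bm_lam[improved] = lam

    for alpha in ALPHA_GRID:  # OU sweep (all configs batched per grid point)
        r, B = eng._bands(alpha)
        M = np.empty((N, 1 + n_edges))
        M[:, 0] = r[eng.idx]
        M[:, 1:] = B[eng.idx]
        for lam in lambda_grid:
            L, logdet = eng.whiten(alpha, lam)
            wy = solve_triangular(L, Ymat, lower=True)
            base_ss = (wy * wy).sum(axis=0)
            wM = solve_triangular(L, M, lower=True)
            for s, (base, A) in group_arrays.items():
                X = np.einsum("ni,mik->mnk", wM, A)  # (m, N, s+1)
                Q, R = np.linalg.qr(X)
                diagR = np.abs(np.diagonal(R, axis1=1, axis2=2))  # (m, s+1)
                # drop numerically dependent / empty columns, as lstsq would:
                # projecting on their arbitrary Q directions absorbs noise
                colscale = np.maximum(
                    np.linalg.norm(X, axis=1).max(axis=1, keepdims=True), 1e-300
                )
                keep = diagR > 1e-8 * colscale
                QtY = np.einsum("mnk,ng->mkg", Q, wy) * keep[:, :, None]
                rss = np.maximum(base_ss[None, :] - (QtY**2).sum(axis=1), 0.0)
                logL = logl_from_rss(rss, logdet)  # (m, G)
                log_s2 = np.log(np.maximum(rss / N, 1e-300))
                with np.errstate(divide="ignore"):
                    log_r2 = np.log(np.maximum(diagR, 1e-300) ** 2)  # (m, s+1)
                pen = mean_penalty(log_r2, log_s2)
                n_var_ou = 3 if free_lambda else 2
                pbic = (
                    -2.0 * logL
                    + n_var_ou * logN
                    + 2.0 * math.log(math.comb(n_edges, s))
                    + pen
                )
                sl = slice(base, base + X.shape[0])
                improved = pbic < ou_pbic[sl]
                ou_logL[sl][improved] = logL[improved]
                ou_pbic[sl][improved] = pbic[improved]
                ou_alpha[sl][improved] = alpha
                ou_lam[sl][improved] = lam

    n_shifts_of = np.array([len(r.shift_edges) for r in flat_regimes])
    ou1_ci = int(np.flatnonzero(n_shifts_of == 0)[0])
    oum_mask = n_shifts_of > 0

    # ---- per-gene assembly (with optional local refinement) ----
    fits: list[GeneFit] = []
    for g in range(G):
        if degenerate[g]:
            fits.append(
                GeneFit(
                    genes[g], tissue, fits={}, selected="degenerate", degenerate=True
                )
            )
            continue
        y = Ymat[:, g]
        fit_map: dict[str, ModelFit] = {}

        n_var_bm = 2 if free_lambda else 1
        n_var_ou = 3 if free_lambda else 2

        # BM
        if "BM" in models:
            lamb = (
                _refine_lambda(eng, y, bm_lam[g])
                if refine and free_lambda
                else bm_lam[g]
            )
            logL, s2, s2e, beta, info = eng.profile_loglik(y, None, lamb)
            fit_map["BM"] = ModelFit(
                "BM",
                logL,
                3,
                _pbic(logL, n_var_bm, N, n_edges, 0, info),
                0.0,
                s2,
                s2e,
                beta,
            )

        # OU1
        if "OU1" in models:
            a0, l0 = ou_alpha[ou1_ci, g], ou_lam[ou1_ci, g]
            a1, l1 = (
                _refine_alpha_lambda(eng, y, a0, l0, (), free_lambda)
                if refine
                else (a0, l0)
            )
            logL, s2, s2e, beta, info = eng.profile_loglik(y, a1, l1)
            fit_map["OU1"] = ModelFit(
                "OU1",
                logL,
                4,
                _pbic(logL, n_var_ou, N, n_edges, 0, info),
                a1,
                s2,
                s2e,
                beta,
            )

        # best OUM config by grid pBIC
        if "OUM" in models and oum_mask.any():
            cand = np.where(oum_mask, ou_pbic[:, g], np.inf)
            ci = int(cand.argmin())
            regime = flat_regimes[ci]
            shift_edges = tuple(sorted(regime.shift_edges))
            s = len(shift_edges)
            a0, l0 = ou_alpha[ci, g], ou_lam[ci, g]
            a2, l2 = (
                _refine_alpha_lambda(eng, y, a0, l0, shift_edges, free_lambda)
                if refine
                else (a0, l0)
            )
            logL, s2, s2e, theta, info = eng.profile_loglik(y, a2, l2, shift_edges)
            directions = _shift_directions(tree, regime, theta)
            fit_map["OUM"] = ModelFit(
                "OUM",
                logL,
                4 + s,
                _pbic(logL, n_var_ou, N, n_edges, s, info),
                a2,
                s2,
                s2e,
                theta,
                shift_edges,
                directions,
            )

        selected = _select(fit_map)
        fits.append(GeneFit(genes[g], tissue, fit_map, selected))
    return fits


def _select(fit_map: dict[str, ModelFit], tol: float = 1e-9) -> str:
    """Minimum pBIC; ties (within tol) go to fewer shifts, then BM < OU1."""
    order = {"BM": 0, "OU1": 1, "OUM": 2}
    best = min(fit_map[m].pbic for m in fit_map)
    tied = [m for m in fit_map if fit_map[m].pbic <= best + tol]
    return min(tied, key=lambda m: (fit_map[m].n_shifts, order[m]))


def _shift_directions(
    tree: SpeciesTree, regime: Regime, theta: np.ndarray
) -> dict[int, str]:
    directions = {}
    shift_order = {e: k + 1 for k, e in enumerate(sorted(regime.shift_edges))}
    for e in regime.shift_edges:
        par = tree.parent[e]
        par_idx = 0 if par == tree.root else regime.optimum_index[par]
        delta = theta[shift_order[e]] - theta[par_idx]
        directions[e] = "up" if delta > 0 else "down"
    return directions


def _penalized_nll(eng: _Engine, y, alpha, lam, shift_edges) -> float:
    """-logL plus half the mean-parameter information penalty.

    Minimizing this over the variance parameters minimizes the pBIC within
    a fixed model (the remaining pBIC terms are constants there); it keeps
    the search away from the degenerate large-alpha corner where the
    likelihood rises but the Laplace penalty rises faster.
    """
    logL, _, _, _, info = eng.profile_loglik(y, alpha, lam, shift_edges)
    logN = math.log(eng.N)
    with np.errstate(divide="ignore"):
        pen = float(np.maximum(np.log(np.maximum(info, 0.0)), logN).sum())
    return -logL + 0.5 * pen


def _refine_lambda(eng: _Engine, y: np.ndarray, lam0: float) -> float:
    def nll(p):
        return _penalized_nll(eng, y, None, float(np.exp(p[0])), ())

    res = minimize(
        nll,
        [math.log(max(lam0, LAMBDA_MIN))],
        method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-7, "maxiter": 80},
    )
    lam = float(np.exp(res.x[0]))
    return min(max(lam, LAMBDA_MIN), LAMBDA_MAX)


def _refine_alpha_lambda(eng, y, alpha0, lam0, shift_edges, free_lambda=True):
    if free_lambda:

        def nll(p):
            a = float(np.exp(p[0]))
            l = float(np.exp(p[1]))
            if not (ALPHA_MIN <= a <= ALPHA_MAX and LAMBDA_MIN <= l <= LAMBDA_MAX):
                return 1e12
            return _penalized_nll(eng, y, a, l, shift_edges)

        x0 = [math.log(max(alpha0, ALPHA_MIN)), math.log(max(lam0, LAMBDA_MIN))]
    else:

        def nll(p):
            a = float(np.exp(p[0]))
            if not ALPHA_MIN <= a <= ALPHA_MAX:
                return 1e12
            return _penalized_nll(eng, y, a, lam0, shift_edges)

        x0 = [math.log(max(alpha0, ALPHA_MIN))]

    res = minimize(
        nll,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-7, "maxiter": 150},
    )
    if not np.isfinite(res.fun) or res.fun >= 1e12:
        return alpha0, lam0
    a = min(max(float(np.exp(res.x[0])), ALPHA_MIN), ALPHA_MAX)
    if free_lambda:
        l = min(max(float(np.exp(res.x[1])), LAMBDA_MIN), LAMBDA_MAX)
    else:
        l = lam0
    return a, l


# --------------------------------------------------------------------------
# single-gene conveniences
# --------------------------------------------------------------------------


def _traits_to_matrix(traits: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """traits: species x replicates -> 1 x samples frame + species list."""
    values, species = [], []
    for sp, row in traits.iterrows():
        row = row.dropna()
        values.extend(row.to_list())
        species.extend([sp] * len(row))
    Y = pd.DataFrame([values], index=["gene"])
    return Y, species


def fit_bm(traits: pd.DataFrame, tree: SpeciesTree, reml: bool = True) -> ModelFit:
    """BM fit for one gene; traits is a species x replicates frame.

    Variance components are estimated by REML by default (the ML estimate of
    sigma2 is biased low with six species); the returned logL and pBIC are
    the ML values at the REML variance ratio, so fits remain comparable.
    """
    Y, species = _traits_to_matrix(traits)
    sp_idx = tree.tip_index(species)
    eng = _Engine(tree, sp_idx)
    y = Y.to_numpy(dtype=float)[0]
    if y.var() < DEGENERATE_VAR:
        return ModelFit("BM", math.inf, 3, math.inf, 0.0, 0.0, 0.0, np.zeros(1))
    best = (-np.inf, LAMBDA_GRID[0])
    for lam in LAMBDA_GRID:
        logL = eng.profile_loglik(y, None, lam, reml=reml)[0]
        if logL > best[0]:
            best = (logL, lam)

    def nll(p):
        lam = float(np.exp(p[0]))
        if not LAMBDA_MIN <= lam <= LAMBDA_MAX:
            return 1e12
        return -eng.profile_loglik(y, None, lam, reml=reml)[0]

    res = minimize(
        nll,
        [math.log(best[1])],
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-9, "maxiter": 100},
    )
    lam = min(max(float(np.exp(res.x[0])), LAMBDA_MIN), LAMBDA_MAX)
    logL, s2, s2e, beta, info = eng.profile_loglik(y, None, lam)
    return ModelFit(
        "BM", logL, 3, _pbic(logL, 2, eng.N, len(tree.edges), 0, info), 0.0, s2, s2e, beta
    )


def fit_bm_batch(
    Y: pd.DataFrame, species_of_sample, tree: SpeciesTree, reml: bool = True
) -> pd.DataFrame:
    """Vectorized BM fits for many genes (rows of Y).

    Returns a frame with root, sigma2, sigma2_e, logL per gene.  The
    replicate-noise ratio is fitted on a dense grid; variances by REML.
    """
    from scipy.linalg import solve_triangular

    sp_idx = tree.tip_index(list(species_of_sample))
    eng = _Engine(tree, sp_idx)
    Ymat = np.ascontiguousarray(Y.to_numpy(dtype=float).T)
    N, G = Ymat.shape
    grid = np.concatenate([[1e-8], np.geomspace(1e-5, LAMBDA_MAX, 80)])
    best_logL = np.full(G, -np.inf)
    best = {
        "lam": np.zeros(G),
        "rss": np.zeros(G),
        "root": np.zeros(G),
        "logdet": np.zeros(G),
    }
    for lam in grid:
        L, logdet = eng.whiten(None, lam)
        wy = solve_triangular(L, Ymat, lower=True)
        wx = solve_triangular(L, np.ones((N, 1)), lower=True)[:, 0]
        xdot = wx @ wx
        proj = wx @ wy
        rss = np.maximum((wy * wy).sum(axis=0) - proj**2 / xdot, 1e-300)
        if reml:
            df = N - 1
            s2 = rss / df
            logL = -0.5 * (
                df * (LOG2PI + np.log(s2) + 1.0) + logdet + math.log(xdot)
            )
        else:
            logL = -0.5 * (N * (LOG2PI + np.log(rss / N) + 1.0) + logdet)
        better = logL > best_logL
        best_logL[better] = logL[better]
        best["lam"][better] = lam
        best["rss"][better] = rss[better]
        best["root"][better] = (proj / xdot)[better]
    sigma2 = best["rss"] / (N - 1)
    return pd.DataFrame(
        {
            "root": best["root"],
            "sigma2": sigma2,
            "sigma2_e": best["lam"] * sigma2,
            "logL": best_logL,
        },
        index=Y.index,
    )


def fit_ou(
    traits: pd.DataFrame,
    tree: SpeciesTree,
    regime: Regime | None = None,
    reml: bool = False,
) -> ModelFit:
    """ML OU fit (single optimum, or the given shift regime) for one gene.

    ML keeps the nesting property (a regime's optimum never scores below
    the single-optimum fit) and the optimum estimates well-behaved;
    ``reml=True`` switches the variance-parameter objective to REML.
    """
    Y, species = _traits_to_matrix(traits)
    if regime is not None:
        regime.validate(tree)
    shift_edges = tuple(sorted(regime.shift_edges)) if regime else ()
    sp_idx = tree.tip_index(species)
    eng = _Engine(tree, sp_idx)
    y = Y.to_numpy(dtype=float)[0]
    if y.var() < DEGENERATE_VAR:
        return ModelFit("OU1", math.inf, 4, math.inf, 0.0, 0.0, 0.0, np.zeros(1))
    best = (-np.inf, ALPHA_GRID[0], LAMBDA_GRID[0])
    for a in ALPHA_GRID:
        for lam in LAMBDA_GRID:
            logL = eng.profile_loglik(y, a, lam, shift_edges, reml=reml)[0]
            if logL > best[0]:
                best = (logL, a, lam)

    def nll(p):
        a = float(np.exp(p[0]))
        lam = float(np.exp(p[1]))
        if not (ALPHA_MIN <= a <= ALPHA_MAX and LAMBDA_MIN <= lam <= LAMBDA_MAX):
            return 1e12
        return -eng.profile_loglik(y, a, lam, shift_edges, reml=reml)[0]

    res = minimize(
        nll,
        [math.log(best[1]), math.log(max(best[2], LAMBDA_MIN))],
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-9, "maxiter": 200},
    )
    if np.isfinite(res.fun) and res.fun < 1e12:
        a = min(max(float(np.exp(res.x[0])), ALPHA_MIN), ALPHA_MAX)
        lam = min(max(float(np.exp(res.x[1])), LAMBDA_MIN), LAMBDA_MAX)
    else:
        a, lam = best[1], best[2]
    logL, s2, s2e, theta, info = eng.profile_loglik(y, a, lam, shift_edges)
    s = len(shift_edges)
    model = "OUM" if s else "OU1"
    dirs = (
        _shift_directions(tree, regime, theta) if regime and s else {}
    )
    return ModelFit(
        model,
        logL,
        4 + s,
        _pbic(logL, 3, len(y), len(tree.edges), s, info),
        a,
        s2,
        s2e,
        theta,
        shift_edges,
        dirs,
    )


def select_model(
    traits: pd.DataFrame, tree: SpeciesTree, max_shifts: int = 3
) -> GeneFit:
    """Full model selection for one gene (species x replicates traits)."""
    Y, species = _traits_to_matrix(traits)
    return select_models(Y, species, tree, max_shifts=max_shifts)[0]


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------


def classify_branches(fits: list[GeneFit], tree: SpeciesTree) -> pd.DataFrame:
    """Per-edge counts of neutral / constrained / divergent branch calls.

    BM-selected genes contribute neutral on every edge, OU1 constrained on
    every edge, OUM divergent on shift edges and constrained elsewhere.
    Returns a frame indexed by edge label with class counts plus a
    ``fraction`` row aggregated over genes x edges.
    """
    counts = {
        tree.edge_label(e): {"neutral": 0, "constrained": 0, "divergent": 0}
        for e in tree.edges
    }
    n_used = 0
    for fit in fits:
        if fit.degenerate:
            continue
        n_used += 1
        for e, cls in fit.branch_classes(tree).items():
            counts[tree.edge_label(e)][cls] += 1
    out = pd.DataFrame(counts).T
    total = out.to_numpy().sum()
    fractions = out.sum(axis=0) / total if total else out.sum(axis=0)
    out.loc["__fraction__"] = fractions
    return out


def change_events(fits: list[GeneFit], tree: SpeciesTree, tissue: str) -> pd.DataFrame:
    """One row per (gene, tissue, shift edge) with direction of the change."""
    rows = []
    for fit in fits:
        if fit.degenerate or fit.selected != "OUM":
            continue
        best = fit.best
        for e in best.shift_edges:
            rows.append(
                {
                    "gene": fit.gene,
                    "tissue": tissue,
                    "edge": tree.edge_label(e),
                    "direction": best.directions[e],
                }
            )
    return pd.DataFrame(rows, columns=["gene", "tissue", "edge", "direction"])
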