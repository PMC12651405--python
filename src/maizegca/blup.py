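"""Multi-environment mixed model for testcross hybrids.

Model (one trait):

    y = mu + Env_j + Hybrid_i + (Hybrid x Env)_ij + (Env x Rep)_jn + e_ijn

with the intercept and environment effects fixed (sum-to-zero coded) and
hybrid, hybrid-by-environment and replicate-within-environment effects
random. Variance components are estimated by direct restricted maximum
likelihood: -2 log L_R is evaluated through the Woodbury identity with one
sparse LU factorization per evaluation and minimized over log variance
components with L-BFGS-B (deterministic start: the phenotypic variance
split equally over the four components). BLUPs are then solved from the
mixed-model equations at the estimates; the per-hybrid genetic value is
mu + Hybrid_i, the shrunken phenotype used for pooled GCA and GWAS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.sparse.linalg import splu

from .containers import InputError, validate_plot_table

HYBRID_SEP = ":"

_COMPONENTS = ("var_line", "var_line_env", "var_env_rep", "var_error")


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, last_objective: float):
        super().__init__(f"{message} (last -2 logL_R = {last_objective:.6g})")
        self.last_objective = last_objective


@dataclass
class BlupResult:
    trait: str
    grand_mean: float
    line_effects: pd.Series                # per-hybrid BLUP deviations
    env_effects: pd.Series                 # fixed, sum to 0
    interaction_effects: pd.DataFrame      # hybrid x env
    rep_within_env: pd.Series              # (env, rep) -> effect
    variance_components: dict[str, float]
    blup_values: pd.Series                 # grand_mean + line_effects
    objective_history: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True


@dataclass
class _Design:
    y: np.ndarray
    X: np.ndarray
    Z: sparse.csr_matrix
    slices: dict[str, slice]               # random-effect block -> Z columns
    hybrids: list[str]
    envs: list[str]
    hxe: list[tuple[str, str]]
    exr: list[tuple[str, str]]
    # precomputed cross-products
    ZtZ: sparse.csr_matrix = None
    ZtX: np.ndarray = None
    Zty: np.ndarray = None
    XtX: np.ndarray = None
    Xty: np.ndarray = None
    yty: float = 0.0


def _one_hot(codes: np.ndarray, n_levels: int) -> sparse.csr_matrix:
    n = len(codes)
    return sparse.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, n_levels))


def _build_design(df: pd.DataFrame, response: str) -> _Design:
    for col in ("hybrid", "env", "rep", response):
        if col not in df.columns:
            raise InputError(f"hybrid table missing column {col!r}")
    y = df[response].to_numpy(dtype=float)
    hyb = pd.Categorical(df["hybrid"])
    env = pd.Categorical(df["env"])
    rep = pd.Categorical(df["rep"])
    H, E = len(hyb.categories), len(env.categories)

    # fixed: intercept + sum-coded environments (last env = -sum of others)
    X = np.ones((len(df), E))
    ec = env.codes
    for j in range(E - 1):
        X[:, j + 1] = np.where(ec == j, 1.0, np.where(ec == E - 1, -1.0, 0.0))

    R = len(rep.categories)
    hc = np.asarray(hyb.codes, dtype=int)
    rc = np.asarray(rep.codes, dtype=int)
    ec_i = np.asarray(ec, dtype=int)
    Zh = _one_hot(hc, H)
    Zhe = _one_hot(hc * E + ec_i, H * E)
    Zer = _one_hot(ec_i * R + rc, E * R)
    Z = sparse.hstack([Zh, Zhe, Zer], format="csr")
    slices = {
        "var_line": slice(0, H),
        "var_line_env": slice(H, H + H * E),
        "var_env_rep": slice(H + H * E, Z.shape[1]),
    }
    d = _Design(y=y, X=X, Z=Z, slices=slices,
                hybrids=list(hyb.categories), envs=list(env.categories),
                hxe=[(h, e) for h in hyb.categories for e in env.categories],
                exr=[(e, r) for e in env.categories for r in rep.categories])
    d.ZtZ = (Z.T @ Z).tocsr()
    d.ZtX = Z.T @ X
    d.Zty = Z.T @ y
    d.XtX = X.T @ X
    d.Xty = X.T @ y
    d.yty = float(y @ y)
    return d


def _g_diag(design: _Design, variances: dict[str, float]) -> np.ndarray:
    g = np.empty(design.Z.shape[1])
    for name, sl in design.slices.items():
        g[sl] = variances[name]
    return g


def neg2_reml(design: _Design, variances: dict[str, float]) -> float:
    """-2 restricted log-likelihood (up to an additive constant)."""
    se2 = variances["var_error"]
    g = _g_diag(design, variances)
    n, q = design.Z.shape
    p = design.X.shape[1]
    W = (design.ZtZ + sparse.diags(se2 / g)).tocsc()
    lu = splu(W)
    logdet_w = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
    rhs = np.column_stack([design.Zty, design.ZtX])
    S = lu.solve(rhs)
    yVy = (design.yty - design.Zty @ S[:, 0]) / se2
    XVy = (design.Xty - design.ZtX.T @ S[:, 0]) / se2
    XVX = (design.XtX - design.ZtX.T @ S[:, 1:]) / se2
    beta = np.linalg.solve(XVX, XVy)
    ypy = yVy - XVy @ beta
    logdet_v = (n - q) * np.log(se2) + float(np.sum(np.log(g))) + logdet_w
    sign, logdet_xvx = np.linalg.slogdet(XVX)
    if sign <= 0:
        return np.inf
    return float(logdet_v + logdet_xvx + ypy)


def solve_blup_at(design: _Design, variances: dict[str, float]):
    """Fixed effects and random-effect BLUPs at the given variances.

    Random blocks with a zero variance component are shrunk entirely to
    zero (dropped from the equations).
    """
    se2 = variances["var_error"]
    if se2 <= 0:
        raise InputError("var_error must be > 0 to solve the mixed-model equations")
    g = _g_diag(design, variances)
    active = g > 0
    gv = np.where(active, g, 1.0)
    W = (design.ZtZ + sparse.diags(se2 / gv)).tocsc()
    # inactive blocks: force u = 0 by a huge ridge
    if not active.all():
        W = (W + sparse.diags(np.where(active, 0.0, 1e12))).tocsc()
    lu = splu(W)
    S = lu.solve(np.column_stack([design.Zty, design.ZtX]))
    XVy = (design.Xty - design.ZtX.T @ S[:, 0]) / se2
    XVX = (design.XtX - design.ZtX.T @ S[:, 1:]) / se2
    beta = np.linalg.solve(XVX, XVy)
    # u = G Z' Vinv (y - X beta)
    ztr = design.Zty - design.ZtX @ beta
    s = (ztr - design.ZtZ @ lu.solve(ztr)) / se2
    u = gv * s * active
    return beta, u


def fit_hybrid_model(
    df: pd.DataFrame,
    response: str = "y",
    trait: str | None = None,
    tol: float = 1e-13,
    max_iter: int = 500,
) -> BlupResult:
    """REML fit of the multi-environment hybrid model to a long table with
    columns ``hybrid, env, rep`` and the response."""
    for col in ("hybrid", "env", "rep", response):
        if col not in df.columns:
            raise InputError(f"hybrid table missing column {col!r}")
    if df["env"].nunique() < 2:
        raise InputError("need >= 2 environments")
    if df.groupby(["hybrid", "env"], observed=True).size().max() < 2 and df["rep"].nunique() < 2:
        raise InputError("need >= 2 replications")
    design = _build_design(df, response)
    vy = float(np.var(design.y))
    if vy == 0:
        # constant response: all variance at (numerically tiny) error
        variances = dict(zip(_COMPONENTS, [0.0, 0.0, 0.0, 1e-12]))
        history = []
    else:
        x0 = np.log(np.full(4, vy / 4.0))
        lb, ub = np.log(vy) - 18.0, np.log(vy) + 6.0
        history: list[float] = []

        def fun(x: np.ndarray) -> float:
            v = dict(zip(_COMPONENTS, np.exp(x)))
            return neg2_reml(design, v)

        def cb(xk: np.ndarray) -> None:
            history.append(fun(xk))

        history.append(fun(x0))
        res = optimize.minimize(
            fun, x0, method="L-BFGS-B",
            bounds=[(lb, ub)] * 4, callback=cb,
            options={"ftol": tol, "gtol": 1e-10, "maxiter": max_iter})
        if not res.success and res.status != 0 and "ITERATIONS" in str(res.message).upper():
            raise ConvergenceError("REML did not converge", float(res.fun))
        est = np.exp(res.x)
        # components driven to the lower bound are clamped to exactly zero
        at_floor = res.x <= lb + 1e-9
        if at_floor[:3].any():
            clamped = [c for c, a in zip(_COMPONENTS, at_floor) if a]
            warnings.warn(f"variance components clamped to 0: {clamped}", stacklevel=2)
        est = np.where(at_floor, 0.0, est)
        if est[3] == 0.0:
            est[3] = vy * 1e-8  # error variance floor keeps the MME solvable
        variances = dict(zip(_COMPONENTS, est))
        history = history if res.nit else history[:1]

    beta, u = solve_blup_at(design, {**variances,
                                     "var_error": max(variances["var_error"], vy * 1e-12 or 1e-12)})
    E = len(design.envs)
    env_eff = np.append(beta[1:E], -beta[1:E].sum())
    u_h = u[design.slices["var_line"]]
    u_he = u[design.slices["var_line_env"]].reshape(len(design.hybrids), E)
    u_er = u[design.slices["var_env_rep"]]
    mu = float(beta[0])
    line_effects = pd.Series(u_h, index=design.hybrids, name="line_effect")
    return BlupResult(
        trait=trait or response,
        grand_mean=mu,
        line_effects=line_effects,
        env_effects=pd.Series(env_eff, index=design.envs, name="env_effect"),
        interaction_effects=pd.DataFrame(u_he, index=design.hybrids, columns=design.envs),
        rep_within_env=pd.Series(u_er, index=pd.MultiIndex.from_tuples(design.exr,
                                                                       names=["env", "rep"])),
        variance_components=variances,
        blup_values=mu + line_effects.rename("blup"),
        objective_history=history,
        n_iter=len(history) - 1,
    )


def fit_multienv_blup(plots: pd.DataFrame, trait: str, **kwargs) -> BlupResult:
    """Fit the hybrid mixed model to plot data for one trait.

    A hybrid is a line x tester combination (id ``line:tester``); the
    environment is the trial location and the replicate is the block
    within location.
    """
    validate_plot_table(plots, traits=[trait])
    df = pd.DataFrame({
        "hybrid": plots["line_id"].astype(str) + HYBRID_SEP + plots["tester_id"].astype(str),
        "env": plots["location"],
        "rep": plots["block"],
        "y": plots[trait].to_numpy(dtype=float),
    })
    return fit_hybrid_model(df, "y", trait=trait, **kwargs)


def blup_table(results: dict[str, BlupResult | None]) -> pd.DataFrame:
    """Hybrid x trait matrix of BLUP-adjusted values."""
    cols = {}
    for trait, res in results.items():
        if res is None:
            warnings.warn(f"no BLUP result for trait {trait}; column omitted", stacklevel=2)
            continue
        cols[trait] = res.blup_values
    if not cols:
        raise InputError("no BLUP results to assemble")
    out = pd.DataFrame(cols)
    out.index.name = "hybrid_id"
    return out


def blup_cross_means(result: BlupResult) -> pd.DataFrame:
    """Lines x testers table of BLUP hybrid values (for pooled GCA)."""
    parts = [h.rsplit(HYBRID_SEP, 1) for h in result.blup_values.index]
    df = pd.DataFrame({
        "line_id": [p[0] for p in parts],
        "tester_id": [p[1] for p in parts],
        "value": result.blup_values.to_numpy(),
    })
    return df.pivot(index="line_id", columns="tester_id", values="value")
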