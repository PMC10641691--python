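"""REML variance components and BLUP solving for pedigree, genomic and
single-step models.

The model is y = X b + sum_k Z_k u_k + e with u_k ~ N(0, sigma2_k K_k) and
e ~ N(0, sigma2_e I). Variance components are estimated by restricted
maximum likelihood: a one-time eigendecomposition profile search when there
is a single non-residual term (exact, fast, robust), and average-information
updates with EM-style fallback steps otherwise. Solutions, prediction error
variances and reliabilities come from Henderson's mixed-model equations at
the converged components.

The genomic models follow a two-stage design: ABLUP on age-adjusted
phenotypes yields EBVs/EGVs, which then serve as the response ("pseudo
phenotypes") of GBLUP/HBLUP with an overall-mean fixed effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .kinship import KinshipMatrix

_VAR_FLOOR = 1e-10


class EvaluationError(ValueError):
    pass


# ----------------------------------------------------------------------
# Model specification
# ----------------------------------------------------------------------
@dataclass
class RandomTerm:
    """One random effect: its data column and covariance structure.

    ``covariance=None`` means i.i.d. levels (identity covariance over the
    distinct values of ``column``, e.g. blocks within trials).
    """

    label: str
    column: str
    covariance: Optional[KinshipMatrix] = None
    start: Optional[float] = None


@dataclass
class ModelSpec:
    response: str
    fixed: tuple[str, ...] = ()  # factor columns; intercept always included
    random: tuple[RandomTerm, ...] = ()
    tol: float = 1e-8
    max_iter: int = 200

    def __post_init__(self):
        if not self.random:
            raise EvaluationError("at least one random term is required")
        labels = [t.label for t in self.random]
        if len(set(labels)) != len(labels):
            raise EvaluationError("random term labels must be unique")


@dataclass
class ModelFit:
    """Converged (or flagged) REML fit with MME solutions."""

    components: dict  # label -> sigma2 (includes "residual")
    component_se: dict
    fixed_effects: pd.Series
    random_effects: dict  # label -> Series indexed by level id
    pev: dict  # label -> Series (prediction error variance)
    reliabilities: Optional[pd.Series]
    loglik_trace: list[float]
    converged: bool
    n_records: int

    def heritability(self) -> dict:
        return heritability(self.components)


# ----------------------------------------------------------------------
# Design matrices
# ----------------------------------------------------------------------
def _design_fixed(data: pd.DataFrame, fixed: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(data))]
    names = ["(intercept)"]
    for f in fixed:
        dummies = pd.get_dummies(data[f].astype(str), prefix=f, drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(float))
            names.append(c)
    X = np.column_stack(cols)
    # drop exactly collinear columns (rank safeguard)
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-9
    if not keep.all():
        X = X[:, keep]
        names = [n for n, k in zip(names, keep) if k]
    return X, names


def _design_random(data: pd.DataFrame, term: RandomTerm) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Incidence matrix Z, level ids, and covariance K for one term."""
    values = data[term.column].astype(str)
    if term.covariance is None:
        levels = list(dict.fromkeys(values))
        K = np.eye(len(levels))
    else:
        levels = term.covariance.ids
        missing = set(values) - set(levels)
        if missing:
            raise EvaluationError(
                f"term {term.label!r}: ids absent from covariance matrix: "
                f"{sorted(missing)[:5]}"
            )
        K = term.covariance.values
    index = {l: k for k, l in enumerate(levels)}
    Z = np.zeros((len(data), len(levels)))
    Z[np.arange(len(data)), [index[v] for v in values]] = 1.0
    return Z, levels, K


# ----------------------------------------------------------------------
# REML
# ----------------------------------------------------------------------
def reml_loglik(y: np.ndarray, X: np.ndarray, V_parts: list[np.ndarray], theta: np.ndarray) -> float:
    """Restricted log-likelihood at variance components ``theta``.

    ``V_parts`` excludes the residual; the last theta entry is sigma2_e.
    """
    n = len(y)
    V = theta[-1] * np.eye(n)
    for t, Vk in zip(theta[:-1], V_parts):
        V += t * Vk
    L = np.linalg.cholesky(V)
    Vinv_y = np.linalg.solve(V, y)
    Vinv_X = np.linalg.solve(V, X)
    XtVinvX = X.T @ Vinv_X
    logdet_V = 2.0 * np.sum(np.log(np.diag(L)))
    sign, logdet_X = np.linalg.slogdet(XtVinvX)
    beta = np.linalg.solve(XtVinvX, X.T @ Vinv_y)
    resid_term = float(y @ Vinv_y - (X.T @ Vinv_y) @ beta)
    return -0.5 * (logdet_V + logdet_X + resid_term)


def _reml_single_term(y, X, ZKZ, tol, max_iter):
    """Exact profile REML for one genetic term + residual via eigenrotation.

    Rotating by the eigenvectors of Z K Z' diagonalizes V, so the REML
    criterion is a cheap function of the ratio gamma = sigma2_g/sigma2_e,
    optimized by bounded scalar search; sigma2_e is then profiled out in
    closed form.
    """
    n = len(y)
    s, U = np.linalg.eigh(ZKZ)
    s = np.maximum(s, 0.0)
    y_r = U.T @ y
    X_r = U.T @ X
    p = X.shape[1]

    def neg_rll(log_gamma):
        gamma = np.exp(log_gamma)
        d = gamma * s + 1.0  # V = sigma2_e * diag(d)
        Xd = X_r / d[:, None]
        XtX = X_r.T @ Xd
        Xty = Xd.T @ y_r
        beta = np.linalg.solve(XtX, Xty)
        r = y_r - X_r @ beta
        quad = float(np.sum(r * r / d))
        sigma2_e = quad / (n - p)
        sign, logdet_X = np.linalg.slogdet(XtX / sigma2_e)
        ll = -0.5 * (
            np.sum(np.log(d)) + n * np.log(sigma2_e) + logdet_X + quad / sigma2_e
        )
        return -ll

    res = minimize_scalar(neg_rll, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-10})
    opt_x = float(res.x)
    # flat-likelihood tie-break (e.g. K = I makes gamma unidentifiable):
    # prefer the boundary, i.e. the most parsimonious genetic variance
    if neg_rll(-12.0) <= res.fun + 1e-9:
        opt_x = -12.0
    gamma = float(np.exp(opt_x))
    d = gamma * s + 1.0
    Xd = X_r / d[:, None]
    beta = np.linalg.solve(X_r.T @ Xd, Xd.T @ y_r)
    r = y_r - X_r @ beta
    sigma2_e = float(np.sum(r * r / d)) / (n - p)
    sigma2_g = gamma * sigma2_e
    ll = -neg_rll(opt_x)
    return np.array([sigma2_g, sigma2_e]), [ll], True


def _reml_ai(y, X, V_parts, theta0, tol, max_iter):
    """AI-REML with EM-style fallback and boundary projection."""
    n = len(y)
    m = len(V_parts)  # non-residual terms
    theta = theta0.copy()
    var_y = float(np.var(y))
    floor = max(_VAR_FLOOR, 1e-8 * var_y)
    trace = [reml_loglik(y, X, V_parts, theta)]
    converged = False
    for _ in range(max_iter):
        V = theta[-1] * np.eye(n)
        for t, Vk in zip(theta[:-1], V_parts):
            V += t * Vk
        Vinv = np.linalg.inv(V)
        Vinv_X = Vinv @ X
        XtVinvX_inv = np.linalg.inv(X.T @ Vinv_X)
        P = Vinv - Vinv_X @ XtVinvX_inv @ Vinv_X.T
        Py = P @ y
        all_parts = list(V_parts) + [np.eye(n)]
        PVk = [P @ Vk for Vk in all_parts[:-1]] + [P]
        VkPy = [Vk @ Py for Vk in all_parts[:-1]] + [Py]
        score = np.array(
            [
                -0.5 * (np.trace(PVk[k]) - float(Py @ VkPy[k]))
                for k in range(m + 1)
            ]
        )
        PVkPy = [P @ v for v in VkPy]
        AI = 0.5 * np.array(
            [[float(VkPy[k] @ PVkPy[l]) for l in range(m + 1)] for k in range(m + 1)]
        )
        step = None
        try:
            step = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            pass
        accepted = False
        if step is not None:
            frac = 1.0
            for _half in range(8):
                cand = theta + frac * step
                if np.all(cand >= floor):
                    ll = reml_loglik(y, X, V_parts, cand)
                    if ll >= trace[-1] - 1e-12:
                        theta, accepted = cand, True
                        trace.append(ll)
                        break
                frac *= 0.5
        if not accepted:
            # EM-style scaled-gradient ascent step (guaranteed direction)
            em = theta + (theta**2 / n) * 2.0 * score
            cand = np.maximum(em, floor)
            ll = reml_loglik(y, X, V_parts, cand)
            if ll < trace[-1]:
                # tiny safeguarded gradient step
                cand = np.maximum(theta + 1e-3 * theta * np.sign(score), floor)
                ll = reml_loglik(y, X, V_parts, cand)
                if ll < trace[-1]:
                    trace.append(trace[-1])
                    break
            theta = cand
            trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    return theta, trace, converged


def reml_estimate(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Estimate variance components by REML and solve the MME.

    Non-convergence is reported through ``ModelFit.converged`` (with the
    likelihood trace as diagnostics), never silently.
    """
    df = data.dropna(subset=[spec.response]).reset_index(drop=True)
    y = df[spec.response].to_numpy(float)
    X, fixed_names = _design_fixed(df, spec.fixed)
    if len(y) < X.shape[1] + 2:
        raise EvaluationError("too few records for the fixed-effect structure")
    designs = [_design_random(df, t) for t in spec.random]
    V_parts = [Z @ K @ Z.T for Z, _, K in designs]

    var_y = float(np.var(y))
    theta0 = np.array(
        [t.start if t.start is not None else var_y / (len(designs) + 1) for t in spec.random]
        + [var_y / (len(designs) + 1)]
    )
    if len(designs) == 1:
        theta, trace, converged = _reml_single_term(
            y, X, V_parts[0], spec.tol, spec.max_iter
        )
    else:
        theta, trace, converged = _reml_ai(y, X, V_parts, theta0, spec.tol, spec.max_iter)

    components = {t.label: float(v) for t, v in zip(spec.random, theta[:-1])}
    components["residual"] = float(theta[-1])
    sol = solve_mme(spec, components, df, designs=designs, X=X, fixed_names=fixed_names)
    sol.loglik_trace = trace
    sol.converged = converged
    return sol


# ----------------------------------------------------------------------
# Henderson's mixed model equations
# ----------------------------------------------------------------------
def solve_mme(
    spec: ModelSpec,
    components: dict,
    data: pd.DataFrame,
    designs=None,
    X=None,
    fixed_names=None,
) -> ModelFit:
    """BLUE/BLUP solutions and PEV at fixed variance components.

    Solved in the equivalent marginal (V-based) form, which tolerates
    singular covariance matrices (a centered G_A always has the ones
    vector in its null space): beta = (X'V^-1 X)^-1 X'V^-1 y and
    u_k = sigma2_k K_k Z_k' V^-1 (y - X beta); the prediction error
    variance is the corresponding block of Henderson's inverse,
    sigma2_k K - sigma2_k^2 K Z' P Z K.
    """
    df = data.dropna(subset=[spec.response]).reset_index(drop=True)
    y = df[spec.response].to_numpy(float)
    if X is None:
        X, fixed_names = _design_fixed(df, spec.fixed)
    if designs is None:
        designs = [_design_random(df, t) for t in spec.random]
    sigma2_e = components["residual"]
    if sigma2_e <= 0:
        raise EvaluationError("residual variance must be positive")

    n = len(y)
    V = sigma2_e * np.eye(n)
    for (Z, _, K), term in zip(designs, spec.random):
        V += max(components[term.label], 0.0) * (Z @ K @ Z.T)
    Vinv = np.linalg.inv(V)
    XtVinvX = X.T @ Vinv @ X
    rank = np.linalg.matrix_rank(XtVinvX)
    if rank < XtVinvX.shape[0]:
        raise EvaluationError(
            f"singular coefficient matrix: fixed-effect block rank {rank} "
            f"of {XtVinvX.shape[0]}"
        )
    XtVinvX_inv = np.linalg.inv(XtVinvX)
    beta = XtVinvX_inv @ (X.T @ (Vinv @ y))
    resid = y - X @ beta
    Vinv_resid = Vinv @ resid
    Vinv_X = Vinv @ X
    P = Vinv - Vinv_X @ XtVinvX_inv @ Vinv_X.T

    fixed = pd.Series(beta, index=fixed_names)
    random_effects, pev = {}, {}
    reliabilities = None
    for (Z, levels, K), term in zip(designs, spec.random):
        sigma2_k = max(components[term.label], 0.0)
        KZt = K @ Z.T  # q x n
        u = sigma2_k * (KZt @ Vinv_resid)
        PZK = P @ KZt.T  # n x q
        pev_diag = sigma2_k * np.diag(K) - sigma2_k**2 * np.sum(KZt * PZK.T, axis=1)
        u = pd.Series(u, index=levels, name=term.label)
        pv = pd.Series(np.maximum(pev_diag, 0.0), index=levels, name=f"PEV_{term.label}")
        random_effects[term.label] = u
        pev[term.label] = pv
        if term.covariance is not None and reliabilities is None:
            r2 = 1.0 - pv / max(components[term.label], _VAR_FLOOR)
            reliabilities = r2.clip(lower=0.0, upper=1.0).rename("reliability")
    return ModelFit(
        components=dict(components),
        component_se={},
        fixed_effects=fixed,
        random_effects=random_effects,
        pev=pev,
        reliabilities=reliabilities,
        loglik_trace=[],
        converged=True,
        n_records=len(y),
    )


# ----------------------------------------------------------------------
# Model families
# ----------------------------------------------------------------------
def fit_ablup(
    data: pd.DataFrame,
    A: KinshipMatrix,
    D: Optional[KinshipMatrix] = None,
    response: str = "mai",
    blocks: str = "random",
    id_column: str = "id",
) -> ModelFit:
    """Pedigree BLUP: fixed trial effects, random blocks-in-trials and
    additive (optionally + dominance) genetic effects.

    ``blocks='fixed'`` absorbs block contrasts into the fixed part, which
    keeps single-genetic-term models on the exact eigen-profile REML path.
    """
    df = data.copy()
    df["_block"] = df["trial"].astype(str) + ":" + df["block"].astype(str)
    fixed = ["trial"] if df["trial"].nunique() > 1 else []
    random = []
    if blocks == "random":
        random.append(RandomTerm("block", "_block"))
    elif df["_block"].nunique() > 1:
        fixed = fixed + ["_block"]
    random.append(RandomTerm("additive", id_column, covariance=A))
    if D is not None:
        random.append(RandomTerm("dominance", id_column, covariance=D))
    spec = ModelSpec(response=response, fixed=tuple(fixed), random=tuple(random))
    return reml_estimate(spec, df)


def ebv_table(fit: ModelFit) -> pd.DataFrame:
    """EBVs (+ dominance deviations and EGVs if fitted) per individual."""
    out = pd.DataFrame({"ebv": fit.random_effects["additive"]})
    if "dominance" in fit.random_effects:
        out["dominance"] = fit.random_effects["dominance"]
        out["egv"] = out["ebv"] + out["dominance"]
    if fit.reliabilities is not None:
        out["reliability"] = fit.reliabilities
    return out.rename_axis("id")


def fit_gblup(
    pseudo_phenotypes: pd.Series,
    GA: KinshipMatrix,
    GD: Optional[KinshipMatrix] = None,
) -> ModelFit:
    """GBLUP on EBV/EGV pseudo-phenotypes with an overall-mean fixed effect."""
    return _fit_genomic(pseudo_phenotypes, GA, GD, label="additive")


def fit_hblup(pseudo_phenotypes: pd.Series, H: KinshipMatrix) -> ModelFit:
    """Single-step BLUP: the additive covariance is the blended H matrix,
    so solutions exist for every pedigree id, genotyped or not."""
    return _fit_genomic(pseudo_phenotypes, H, None, label="additive")


def _fit_genomic(pseudo: pd.Series, K: KinshipMatrix, KD, label: str) -> ModelFit:
    ids = [str(i) for i in pseudo.index]
    missing = set(ids) - set(K.ids)
    if missing:
        raise EvaluationError(
            f"response ids absent from covariance matrix: {sorted(missing)[:5]}"
        )
    df = pd.DataFrame({"id": ids, "y": pseudo.to_numpy(float)})
    random = [RandomTerm(label, "id", covariance=K)]
    if KD is not None:
        random.append(RandomTerm("dominance", "id", covariance=KD))
    spec = ModelSpec(response="y", fixed=(), random=tuple(random))
    return reml_estimate(spec, df)


def genomic_values(fit: ModelFit) -> pd.DataFrame:
    """GEBVs (and GEGVs when dominance was fitted) for all covariance ids."""
    out = pd.DataFrame({"gebv": fit.random_effects["additive"]})
    if "dominance" in fit.random_effects:
        out["gegv"] = out["gebv"] + fit.random_effects["dominance"]
    return out.rename_axis("id")


# ----------------------------------------------------------------------
# Summaries
# ----------------------------------------------------------------------
def heritability(components: dict) -> dict:
    """Narrow- and broad-sense heritability from variance components.

    h2_a = s2_a / (s2_a + s2_d + s2_e); h2_g adds dominance to the
    numerator. Block/trial variances are excluded from the denominator.
    """
    s2_a = components.get("additive", 0.0)
    s2_d = components.get("dominance", 0.0)
    s2_e = components.get("residual", 0.0)
    denom = s2_a + s2_d + s2_e
    if denom <= 0:
        raise EvaluationError("zero total variance in heritability")
    return {"h2_narrow": s2_a / denom, "h2_broad": (s2_a + s2_d) / denom}


def deregress(ebv, reliability):
    """De-regressed EBVs: dEBV = EBV / r^2 (parent averages not removed)."""
    r2 = np.asarray(reliability, dtype=float)
    if np.any(r2 <= 0) or np.any(r2 > 1):
        raise EvaluationError("reliability must lie in (0, 1]")
    out = np.asarray(ebv, dtype=float) / r2
    if isinstance(ebv, pd.Series):
        return pd.Series(out, index=ebv.index, name="debv")
    return out if out.ndim else float(out)
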