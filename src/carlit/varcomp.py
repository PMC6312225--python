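"""REML variance partitioning of EQR panels with crossed random effects.

The model is

    eqr = mu + u_surveyor + v_wb + w_year + s_{wb, year} + eps

with independent Gaussian components: crossed random intercepts for
surveyor, water body and year, a per-water-body slope-within-year term
``s`` whose variance differs by water body (diagonal covariance across
water bodies), and iid residuals.  Estimation maximizes the restricted
likelihood; the share of total variance attributed to each component is

    P_samp(x) = 100 * sigma2_x / sigma2_T,
    sigma2_T  = sigma2_Year + sigma2_WB + sigma2_Surveyor
                + sum_wb sigma2_{wb|Year} + sigma2_R.

Optimization runs a bounded quasi-Newton search (L-BFGS-B with analytic
gradients) on the log-variance scale with three fixed-seed starts.  Exact
zeros are unreachable on the log scale, so estimates below 1e-10 x var(y)
are truncated to 0 — boundary components (e.g. a year or surveyor factor
contributing nothing) are therefore reported as exactly 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "ModelStructure",
    "VarianceComponents",
    "ComparedModel",
    "ConvergenceError",
    "ZeroTotalVarianceError",
    "validate_panel",
    "fit_reml",
    "variance_fractions",
    "residuals_vs_fitted",
    "compare_models",
    "round_half_away",
]

PANEL_COLUMNS = ("WB", "Year", "Surveyor", "EQR")

_ZERO_TRUNCATION = 1e-10  # relative to var(y)


class ConvergenceError(RuntimeError):
    """The restricted-likelihood optimization failed to converge."""


class ZeroTotalVarianceError(ZeroDivisionError):
    """Variance fractions are undefined when the total variance is zero."""


@dataclass(frozen=True)
class ModelStructure:
    """Which random terms enter the model; the residual is always present."""

    wb: bool = True
    year: bool = True
    surveyor: bool = True
    wb_slopes_in_year: bool = True

    @property
    def name(self) -> str:
        parts = [
            n
            for n, on in (
                ("WB", self.wb),
                ("Year", self.year),
                ("Surveyor", self.surveyor),
                ("WB|Year", self.wb_slopes_in_year),
            )
            if on
        ]
        return "+".join(parts) if parts else "residual-only"

    @classmethod
    def from_spec(cls, spec: str) -> "ModelStructure":
        """Parse a comma-separated term list, e.g. ``"wb,year,wb_slopes"``."""
        aliases = {
            "wb": "wb",
            "year": "year",
            "surveyor": "surveyor",
            "wb_slopes": "wb_slopes_in_year",
            "wb_slopes_in_year": "wb_slopes_in_year",
            "wb|year": "wb_slopes_in_year",
        }
        kwargs = {k: False for k in ("wb", "year", "surveyor", "wb_slopes_in_year")}
        for token in spec.split(","):
            token = token.strip().lower()
            if not token:
                continue
            if token not in aliases:
                raise ValueError(f"unknown model term {token!r}")
            kwargs[aliases[token]] = True
        return cls(**kwargs)


@dataclass
class VarianceComponents:
    """Estimated variance components, their total and P_samp fractions."""

    grand_mean: float
    var_year: float = 0.0
    var_wb: float = 0.0
    var_surveyor: float = 0.0
    var_wb_in_year: dict[str, float] = field(default_factory=dict)
    var_residual: float = 0.0
    converged: bool = True
    reml_criterion: Optional[float] = None
    n_obs: Optional[int] = None
    structure: Optional[ModelStructure] = None
    messages: tuple[str, ...] = ()

    @property
    def total(self) -> float:
        return (
            self.var_year
            + self.var_wb
            + self.var_surveyor
            + sum(self.var_wb_in_year.values())
            + self.var_residual
        )

    @property
    def n_variance_parameters(self) -> int:
        n = 1  # residual
        if self.structure is None:
            n += 3 + len(self.var_wb_in_year)
        else:
            n += sum(
                (self.structure.wb, self.structure.year, self.structure.surveyor)
            ) + (len(self.var_wb_in_year) if self.structure.wb_slopes_in_year else 0)
        return n

    def as_dict(self) -> dict[str, float]:
        out = {"WB": self.var_wb, "Year": self.var_year, "Surveyor": self.var_surveyor}
        for wb, v in self.var_wb_in_year.items():
            out[f"Year:{wb}"] = v
        out["Residual"] = self.var_residual
        return out

    def fractions(self, rounded: bool = False) -> dict[str, float]:
        return variance_fractions(self, rounded=rounded)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (Table-style rounding)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def variance_fractions(
    components: VarianceComponents, *, rounded: bool = False
) -> dict[str, float]:
    """P_samp: each component's percent share of the total variance.

    ``rounded`` applies integer presentation rounding (half away from zero).
    """
    total = components.total
    if total <= 0:
        raise ZeroTotalVarianceError(
            "variance fractions are undefined: total variance is zero"
        )
    exact = {k: 100.0 * v / total for k, v in components.as_dict().items()}
    if rounded:
        return {k: round_half_away(v) for k, v in exact.items()}
    return exact


def validate_panel(panel: pd.DataFrame, *, allow_replicates: bool = False) -> pd.DataFrame:
    """Check the WB/Year/Surveyor/EQR panel and return a normalized copy."""
    missing = set(PANEL_COLUMNS) - set(panel.columns)
    if missing:
        raise ValueError(f"panel missing columns: {sorted(missing)}")
    out = panel.loc[:, list(PANEL_COLUMNS)].copy()
    out["EQR"] = out["EQR"].astype(float)
    if not np.all(np.isfinite(out["EQR"].to_numpy())):
        raise ValueError("panel contains non-finite EQR values")
    for col in ("WB", "Year", "Surveyor"):
        out[col] = out[col].astype(str)
    if not allow_replicates:
        dup = out.duplicated(subset=["WB", "Year"])
        if dup.any():
            raise ValueError(
                "duplicated (WB, Year) cells; pass allow_replicates=True if intended"
            )
    return out


def _indicator(values: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = sorted(values.unique())
    Z = (values.to_numpy()[:, None] == np.array(levels)[None, :]).astype(float)
    return Z, levels


def _build_components(
    panel: pd.DataFrame, structure: ModelStructure
) -> list[tuple[str, np.ndarray]]:
    """Indicator design matrices for each scalar-variance random term."""
    comps: list[tuple[str, np.ndarray]] = []
    if structure.wb:
        Z, _ = _indicator(panel["WB"])
        comps.append(("WB", Z))
    if structure.year:
        Z, _ = _indicator(panel["Year"])
        comps.append(("Year", Z))
    if structure.surveyor:
        Z, _ = _indicator(panel["Surveyor"])
        comps.append(("Surveyor", Z))
    if structure.wb_slopes_in_year:
        Zy, _ = _indicator(panel["Year"])
        for wb in sorted(panel["WB"].unique()):
            mask = (panel["WB"] == wb).to_numpy().astype(float)
            comps.append((f"Year:{wb}", Zy * mask[:, None]))
    return comps


def _check_design(panel: pd.DataFrame, structure: ModelStructure) -> list[str]:
    messages: list[str] = []
    factors = {
        "WB": structure.wb or structure.wb_slopes_in_year,
        "Year": structure.year or structure.wb_slopes_in_year,
        "Surveyor": structure.surveyor,
    }
    for col, used in factors.items():
        if used and panel[col].nunique() < 2:
            raise ValueError(
                f"factor {col} needs >= 2 levels for the requested structure"
            )
    # confounding: two factors inducing the same row partition
    used_cols = [c for c, u in factors.items() if u]
    for i, a in enumerate(used_cols):
        for b in used_cols[i + 1 :]:
            ga = panel.groupby(a, sort=True).groups
            gb = panel.groupby(b, sort=True).groups
            parts_a = {frozenset(v) for v in ga.values()}
            parts_b = {frozenset(v) for v in gb.values()}
            if parts_a == parts_b:
                msg = f"factors {a} and {b} are confounded (identical groupings)"
                messages.append(msg)
                warnings.warn(msg, stacklevel=3)
    return messages


def _neg2_reml(
    theta: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    Gs: Sequence[np.ndarray],
) -> tuple[float, np.ndarray]:
    """Restricted -2 log-likelihood and its gradient on the log-variance scale.

    The last theta entry is the residual log-variance; ``Gs`` are the
    Z_k Z_k' matrices of the non-residual components.
    """
    n, p = X.shape
    variances = np.exp(theta)
    V = variances[-1] * np.eye(n)
    for v, G in zip(variances[:-1], Gs):
        V += v * G
    try:
        c = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros_like(theta)
    logdetV = 2.0 * np.sum(np.log(np.diag(c[0])))
    Vinv = cho_solve(c, np.eye(n))
    VinvX = Vinv @ X
    A = X.T @ VinvX
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf, np.zeros_like(theta)
    beta = np.linalg.solve(A, X.T @ (Vinv @ y))
    r = y - X @ beta
    Vinv_r = Vinv @ r
    crit = (n - p) * math.log(2 * math.pi) + logdetV + logdetA + float(r @ Vinv_r)

    P = Vinv - VinvX @ np.linalg.solve(A, VinvX.T)
    grad = np.empty_like(theta)
    for k, G in enumerate(Gs):
        grad[k] = variances[k] * (np.sum(P * G) - float(Vinv_r @ G @ Vinv_r))
    grad[-1] = variances[-1] * (np.trace(P) - float(Vinv_r @ Vinv_r))
    return crit, grad


def fit_reml(
    panel: pd.DataFrame,
    structure: ModelStructure = ModelStructure(),
    *,
    n_starts: int = 3,
    seed: int = 0,
    tol: float = 1e-8,
    allow_replicates: bool = False,
) -> VarianceComponents:
    """Fit the crossed random-effects model by REML.

    Parameters
    ----------
    panel
        Data frame with columns WB, Year, Surveyor, EQR.
    structure
        Which random terms to include; the residual is always estimated.
    n_starts
        Multi-start count for the bounded quasi-Newton search (fixed seeds).
    seed
        Seed for the start-point jitter.
    tol
        Convergence tolerance on the REML criterion.

    Raises
    ------
    ConvergenceError
        If no start converges; the error carries the criterion trace.
    """
    panel = validate_panel(panel, allow_replicates=allow_replicates)
    messages = _check_design(panel, structure)

    y = panel["EQR"].to_numpy(dtype=float)
    n = y.size
    X = np.ones((n, 1))
    comps = _build_components(panel, structure)
    names = [name for name, _ in comps]
    Gs = [Z @ Z.T for _, Z in comps]
    K = len(comps) + 1  # + residual

    if K >= max(2, n // 3):
        msg = (
            f"identifiability warning: {K} variance parameters estimated from "
            f"{n} observations; estimates may be poorly determined"
        )
        messages.append(msg)
        warnings.warn(msg, stacklevel=2)

    vy = float(np.var(y, ddof=1)) if n > 1 else 0.0
    # ptp == 0 catches exactly constant columns; the relative-epsilon term
    # catches numerically constant ones (np.var of identical floats can be
    # ~1e-32 from mean rounding, which would wreck the log-variance bounds)
    if np.ptp(y) == 0.0 or vy < (1e-10 * max(1.0, float(np.abs(y).max()))) ** 2:
        return VarianceComponents(
            grand_mean=float(y[0]) if n else float("nan"),
            var_wb_in_year={
                name.split(":", 1)[1]: 0.0 for name in names if name.startswith("Year:")
            },
            converged=True,
            reml_criterion=0.0,
            n_obs=n,
            structure=structure,
            messages=tuple(messages + ["constant response; zero-variance fit"]),
        )

    lb, ub = math.log(vy) - 35.0, math.log(vy) + 6.0
    bounds = [(lb, ub)] * K
    rng = np.random.default_rng(seed)
    base = np.full(K, math.log(vy / K))
    starts = [base] + [
        np.clip(base + rng.normal(0.0, 2.0, size=K), lb + 1, ub - 1)
        for _ in range(max(0, n_starts - 1))
    ]

    def projected_grad(x: np.ndarray, g: np.ndarray) -> np.ndarray:
        pg = g.copy()
        at_lb = (x <= lb + 1e-10) & (g > 0)
        at_ub = (x >= ub - 1e-10) & (g < 0)
        pg[at_lb | at_ub] = 0.0
        return pg

    best = None
    trace = []
    for x0 in starts:
        x = x0
        # L-BFGS-B occasionally reports success at a non-stationary point on
        # this criterion; restart from the stall point until the projected
        # gradient is genuinely small.
        for _ in range(6):
            res = optimize.minimize(
                _neg2_reml,
                x,
                args=(y, X, Gs),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 1000, "ftol": tol * 1e-4, "gtol": 1e-12},
            )
            fval, grad = _neg2_reml(res.x, y, X, Gs)
            pg = np.abs(projected_grad(res.x, grad)).max() if np.isfinite(fval) else np.inf
            stationary = pg < 1e-5 * (1.0 + abs(fval))
            if stationary or np.allclose(x, res.x):
                break
            x = res.x
        trace.append((fval, pg, res.message))
        if np.isfinite(fval) and stationary and (best is None or fval < best[0]):
            best = (fval, res.x)
    if best is None:
        raise ConvergenceError(f"REML optimization failed for all starts: {trace}")
    best_fun, best_x = best

    variances = np.exp(best_x)
    variances[variances < _ZERO_TRUNCATION * vy] = 0.0

    # GLS mean at the optimum
    V = variances[-1] * np.eye(n)
    for v, G in zip(variances[:-1], Gs):
        V += v * G
    Vinv_y = np.linalg.solve(V, y)
    Vinv_1 = np.linalg.solve(V, np.ones(n))
    grand_mean = float(np.ones(n) @ Vinv_y / (np.ones(n) @ Vinv_1))

    out = VarianceComponents(
        grand_mean=grand_mean,
        var_residual=float(variances[-1]),
        converged=True,
        reml_criterion=float(best_fun),
        n_obs=n,
        structure=structure,
        messages=tuple(messages),
    )
    for name, v in zip(names, variances[:-1]):
        if name == "WB":
            out.var_wb = float(v)
        elif name == "Year":
            out.var_year = float(v)
        elif name == "Surveyor":
            out.var_surveyor = float(v)
        else:
            out.var_wb_in_year[name.split(":", 1)[1]] = float(v)
    return out


def residuals_vs_fitted(
    panel: pd.DataFrame,
    components: VarianceComponents,
    structure: Optional[ModelStructure] = None,
) -> list[tuple[float, float]]:
    """Conditional (fitted, residual) pairs for model validation plots.

    Fitted values include the random-effect predictions (BLUPs); the
    conditional residual is ``sigma2_R * V^{-1} (y - X beta)``, so residuals
    sum to zero exactly under the intercept-only mean.
    """
    structure = structure or components.structure or ModelStructure()
    panel = validate_panel(panel, allow_replicates=True)
    y = panel["EQR"].to_numpy(dtype=float)
    n = y.size

    if components.total == 0.0:
        return [(float(v), 0.0) for v in y]

    comps = _build_components(panel, structure)
    by_name = components.as_dict()
    V = components.var_residual * np.eye(n)
    for name, Z in comps:
        V += by_name.get(name, 0.0) * (Z @ Z.T)
    ones = np.ones(n)
    Vinv_y = np.linalg.solve(V, y)
    Vinv_1 = np.linalg.solve(V, ones)
    beta = float(ones @ Vinv_y / (ones @ Vinv_1))
    r = y - beta
    Vinv_r = np.linalg.solve(V, r)
    resid = components.var_residual * Vinv_r
    fitted = y - resid
    return list(zip(fitted.tolist(), resid.tolist()))


@dataclass(frozen=True)
class ComparedModel:
    structure: ModelStructure
    aic: float
    reml_criterion: float
    n_parameters: int
    converged: bool
    rank: int
    tied: bool = False


def compare_models(
    panel: pd.DataFrame,
    structures: Sequence[ModelStructure],
    *,
    seed: int = 0,
    allow_replicates: bool = False,
) -> list[ComparedModel]:
    """Rank candidate random structures on the same data by AIC.

    AIC = REML criterion + 2 x (#variance parameters).  Caveat: comparing
    REML criteria across different random structures is only a heuristic
    (the restricted likelihoods condition on the same fixed part here, the
    intercept, which keeps them commensurable).  Structures that fail to
    converge are ranked last and flagged.  On a constant response every
    criterion is 0 by convention, so the simplest structure wins.
    """
    if len(structures) < 2:
        raise ValueError("need at least two candidate structures")
    fits: list[tuple[ModelStructure, Optional[VarianceComponents]]] = []
    for s in structures:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fits.append(
                    (s, fit_reml(panel, s, seed=seed, allow_replicates=allow_replicates))
                )
        except (ConvergenceError, ValueError):
            fits.append((s, None))

    rows = []
    for s, vc in fits:
        if vc is None:
            rows.append((s, math.inf, math.inf, 0, False))
        else:
            k = vc.n_variance_parameters
            rows.append((s, vc.reml_criterion + 2 * k, vc.reml_criterion, k, True))
    order = sorted(range(len(rows)), key=lambda i: (not rows[i][4], rows[i][1], rows[i][3]))
    out = []
    aics = [rows[i][1] for i in order]
    for rank, i in enumerate(order, start=1):
        s, aic, crit, k, ok = rows[i]
        tied = any(
            j != rank - 1 and math.isfinite(aic) and abs(aics[j] - aic) < 1e-9
            for j in range(len(aics))
        )
        out.append(
            ComparedModel(
                structure=s,
                aic=aic,
                reml_criterion=crit,
                n_parameters=k,
                converged=ok,
                rank=rank,
                tied=tied,
            )
        )
    return out
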