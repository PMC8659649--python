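"""Regularized maximum-entropy species distribution model, from scratch.

MaxEnt estimates a Gibbs distribution q(z) = exp(lambda . f(z)) / Z over
background cells that matches the presence sample's feature means as
closely as the L1 penalty allows.  The fitted weights maximize

    (1/m) sum_presences lambda . f  -  log Z(lambda)  -  sum_j beta_j |lambda_j|

with Z = sum_background exp(lambda . f).  This is concave; at the optimum
the KKT soft-matching condition holds for every feature:

    | E_q[f_j] - presence mean of f_j |  <=  beta_j.

The logistic output rescales the Gibbs density to a 0-1 suitability index
via c * q / (1 + c * q) with c = exp(H), H the entropy of q — the classic
default, under which a "typical" presence site scores about 0.5.

Feature classes are linear + quadratic for continuous covariates and 0/1
indicators for categorical ones (hinge features are an extension hook, not
implemented).  Prediction covariate values are clamped to the training
range.  Internally features are scaled to background mean 0 / sd 1 for
optimizer conditioning; reported weights are on the original feature scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .errors import ConfigError, DataError
from .roc import auc_value
from .stack import BINARY, CATEGORICAL, CONTINUOUS, CovariateStack


@dataclass
class FeatureExpansion:
    """Deterministic covariate -> feature mapping with training clamp ranges."""

    kinds: dict[str, str]
    quadratic: bool = True
    products: bool = False
    clamp_lo: dict[str, float] = field(default_factory=dict)
    clamp_hi: dict[str, float] = field(default_factory=dict)
    levels: dict[str, list] = field(default_factory=dict)
    feature_names: list[str] = field(default_factory=list)
    covariate_of: list[str] = field(default_factory=list)
    feature_classes: list[str] = field(default_factory=list)  # linear|quadratic|indicator|product
    _fitted: bool = False

    def fit(self, table: pd.DataFrame) -> "FeatureExpansion":
        """Record clamp ranges and categorical levels from training data."""
        self.feature_names = []
        self.covariate_of = []
        self.feature_classes = []
        for name, kind in self.kinds.items():
            col = table[name]
            if kind == CONTINUOUS:
                self.clamp_lo[name] = float(col.min())
                self.clamp_hi[name] = float(col.max())
                self.feature_names.append(name)
                self.covariate_of.append(name)
                self.feature_classes.append("linear")
                if self.quadratic:
                    self.feature_names.append(f"{name}^2")
                    self.covariate_of.append(name)
                    self.feature_classes.append("quadratic")
            elif kind == BINARY:
                self.feature_names.append(name)
                self.covariate_of.append(name)
                self.feature_classes.append("indicator")
            elif kind == CATEGORICAL:
                self.levels[name] = sorted(pd.unique(col).tolist())
                for lv in self.levels[name]:
                    self.feature_names.append(f"{name}={lv}")
                    self.covariate_of.append(name)
                    self.feature_classes.append("indicator")
            else:
                raise ConfigError(f"unknown covariate kind {kind!r} for {name!r}")
        if self.products:
            cont = [n for n, k in self.kinds.items() if k == CONTINUOUS]
            for i in range(len(cont)):
                for j in range(i + 1, len(cont)):
                    self.feature_names.append(f"{cont[i]}*{cont[j]}")
                    self.covariate_of.append(f"{cont[i]}*{cont[j]}")
                    self.feature_classes.append("product")
        self._fitted = True
        return self

    def transform(self, table: pd.DataFrame, clamp: bool = True) -> np.ndarray:
        if not self._fitted:
            raise ConfigError("FeatureExpansion must be fitted before transform")
        cols: list[np.ndarray] = []
        clamped: dict[str, np.ndarray] = {}
        for name, kind in self.kinds.items():
            raw = table[name].to_numpy()
            if kind == CONTINUOUS:
                vals = raw.astype(float)
                if clamp:
                    vals = np.clip(vals, self.clamp_lo[name], self.clamp_hi[name])
                clamped[name] = vals
                cols.append(vals)
                if self.quadratic:
                    cols.append(vals**2)
            elif kind == BINARY:
                cols.append(raw.astype(float))
            elif kind == CATEGORICAL:
                known = self.levels[name]
                unseen = set(pd.unique(raw)) - set(known)
                if unseen:
                    warnings.warn(
                        f"unseen {name!r} level(s) {sorted(map(str, unseen))}: "
                        "mapped to all-zero indicators"
                    )
                for lv in known:
                    cols.append((raw == lv).astype(float))
        if self.products:
            cont = [n for n, k in self.kinds.items() if k == CONTINUOUS]
            for i in range(len(cont)):
                for j in range(i + 1, len(cont)):
                    cols.append(clamped[cont[i]] * clamped[cont[j]])
        return np.column_stack(cols)

    def feature_indices_by_covariate(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, cov in enumerate(self.covariate_of):
            out.setdefault(cov, []).append(i)
        return out

    def to_dict(self) -> dict:
        return {
            "kinds": self.kinds,
            "quadratic": self.quadratic,
            "products": self.products,
            "clamp_lo": self.clamp_lo,
            "clamp_hi": self.clamp_hi,
            "levels": self.levels,
            "feature_names": self.feature_names,
            "covariate_of": self.covariate_of,
            "feature_classes": self.feature_classes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureExpansion":
        exp = cls(kinds=dict(d["kinds"]), quadratic=d["quadratic"], products=d["products"])
        exp.clamp_lo = dict(d["clamp_lo"])
        exp.clamp_hi = dict(d["clamp_hi"])
        exp.levels = {k: list(v) for k, v in d["levels"].items()}
        exp.feature_names = list(d["feature_names"])
        exp.covariate_of = list(d["covariate_of"])
        exp.feature_classes = list(d.get("feature_classes", []))
        exp._fitted = True
        return exp


def stack_table(stack: CovariateStack, cells: np.ndarray | None = None) -> pd.DataFrame:
    """Covariate table for flat cell indices (default: all valid cells)."""
    if cells is None:
        cells = stack.valid_indices()
    cells = np.asarray(cells, dtype=int)
    data = {name: stack[name].ravel()[cells] for name in stack.names()}
    return pd.DataFrame(data)


def maxent_objective(lam: np.ndarray, x_pres: np.ndarray, x_bg: np.ndarray,
                     beta: np.ndarray) -> float:
    """Penalized negative objective (to minimize): logZ - presence gain + L1."""
    eta_bg = x_bg @ lam
    return float(logsumexp(eta_bg) - (x_pres @ lam).mean() + np.sum(beta * np.abs(lam)))


def _smooth_grad(lam, x_pres, x_bg):
    eta = x_bg @ lam
    q = np.exp(eta - logsumexp(eta))
    return q @ x_bg - x_pres.mean(axis=0), q


def _newton_polish(lam, sp, sb, beta, tol, max_steps=50):
    """Active-set Newton refinement of the L1-penalized optimum.

    Quasi-Newton solvers stop with the KKT conditions satisfied only to
    moderate precision; a few Newton steps on the nonzero coordinates
    (sign held fixed, coordinates clamped to zero when they cross) sharpen
    the solution to near machine precision.  Falls back to the input on
    any numerical trouble or objective increase.
    """
    pres_mean = sp.mean(axis=0)

    def value(l):
        return float(logsumexp(sb @ l) - pres_mean @ l + beta @ np.abs(l))

    best = lam.copy()
    best_val = value(best)
    cur = lam.copy()
    for _ in range(max_steps):
        g, q = _smooth_grad(cur, sp, sb)
        free = cur != 0
        # activate zero coordinates whose gradient violates the bound
        free |= np.abs(g) > beta + 1e-12
        idx = np.flatnonzero(free)
        if idx.size == 0:
            break
        sign = np.where(cur[idx] != 0, np.sign(cur[idx]), -np.sign(g[idx]))
        xf = sb[:, idx]
        mu_q = q @ xf
        hess = (xf * q[:, None]).T @ xf - np.outer(mu_q, mu_q)
        rhs = g[idx] + sign * beta[idx]
        if np.max(np.abs(rhs)) <= max(tol, 1e-12):
            break
        try:
            step = np.linalg.solve(hess + 1e-12 * np.eye(idx.size), rhs)
        except np.linalg.LinAlgError:
            break
        new = cur[idx] - step
        crossed = (cur[idx] != 0) & (np.sign(new) != np.sign(cur[idx])) & (new != 0)
        new[crossed] = 0.0
        nxt = cur.copy()
        nxt[idx] = new
        if value(nxt) > best_val + 1e-12:
            break
        cur = nxt
        cur_val = value(cur)
        if cur_val < best_val:
            best, best_val = cur.copy(), cur_val
        if np.max(np.abs(step)) < 1e-14:
            break
    return best, best_val


@dataclass
class MaxEntModel:
    feature_names: list[str]
    lambda_: np.ndarray  # weights on the original feature scale
    log_partition: float  # log Z over the training background
    entropy_H: float
    beta: np.ndarray
    converged: bool
    n_iterations: int
    kkt_gap: np.ndarray  # |E_q[f] - presence mean| - beta, per feature
    expansion: FeatureExpansion | None = None

    # -- prediction --------------------------------------------------------
    def raw(self, features: np.ndarray) -> np.ndarray:
        """Gibbs density relative to the training background (sums to 1 there)."""
        return np.exp(np.asarray(features) @ self.lambda_ - self.log_partition)

    def logistic(self, features: np.ndarray) -> np.ndarray:
        # c*raw/(1+c*raw) computed as an overflow-safe sigmoid
        from scipy.special import expit

        eta = np.asarray(features) @ self.lambda_ - self.log_partition + self.entropy_H
        return expit(eta)

    def predict(self, features: np.ndarray, output: str = "logistic") -> np.ndarray:
        if output == "raw":
            return self.raw(features)
        if output == "logistic":
            return self.logistic(features)
        raise ConfigError(f"unknown output {output!r}")

    def predict_stack(self, stack: CovariateStack, output: str = "logistic") -> np.ndarray:
        """Suitability grid over a stack's valid cells (NaN elsewhere).

        Prediction cells are clamped to the training covariate ranges, so
        the model extrapolates flat outside them.
        """
        if self.expansion is None:
            raise ConfigError("model has no feature expansion attached")
        cells = stack.valid_indices()
        feats = self.expansion.transform(stack_table(stack, cells), clamp=True)
        grid = np.full(stack.grid.shape, np.nan)
        grid.ravel()[cells] = self.predict(feats, output=output)
        return grid

    def extrapolation_mask(self, stack: CovariateStack) -> np.ndarray:
        """True where any continuous covariate lies outside its training range."""
        if self.expansion is None:
            raise ConfigError("model has no feature expansion attached")
        out = np.zeros(stack.grid.shape, dtype=bool)
        for name, kind in self.expansion.kinds.items():
            if kind != CONTINUOUS:
                continue
            vals = stack[name]
            out |= (vals < self.expansion.clamp_lo[name]) | (vals > self.expansion.clamp_hi[name])
        return out & stack.mask

    # -- persistence -------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "lambda": self.lambda_.tolist(),
            "log_partition": self.log_partition,
            "entropy_H": self.entropy_H,
            "beta": self.beta.tolist(),
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "kkt_gap": self.kkt_gap.tolist(),
            "expansion": self.expansion.to_dict() if self.expansion else None,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MaxEntModel":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_names=list(d["feature_names"]),
            lambda_=np.asarray(d["lambda"]),
            log_partition=float(d["log_partition"]),
            entropy_H=float(d["entropy_H"]),
            beta=np.asarray(d["beta"]),
            converged=bool(d["converged"]),
            n_iterations=int(d["n_iterations"]),
            kkt_gap=np.asarray(d["kkt_gap"]),
            expansion=FeatureExpansion.from_dict(d["expansion"]) if d["expansion"] else None,
        )


#: relative regularization strength per feature class, echoing the
#: convention that indicator features are penalized harder than smooth ones
CLASS_BETA_MULTIPLIER = {"linear": 1.0, "quadratic": 1.0, "product": 1.0, "indicator": 2.0}


def default_beta(
    x_pres: np.ndarray,
    x_bg: np.ndarray,
    beta0: float = 1.0,
    feature_classes: list[str] | None = None,
) -> np.ndarray:
    """Per-feature regularization beta_j = beta0 * c_class * sd_j / sqrt(m).

    sd_j is the presence-sample sd of feature j (background sd fallback for
    constant presence features), m the presence count — the standard
    scaling that shrinks harder for small, noisy presence samples.
    Indicator features carry a heavier class multiplier: a handful of
    clustered presences can otherwise hand spurious weight to a category.
    """
    m = len(x_pres)
    sd = x_pres.std(axis=0, ddof=1) if m > 1 else np.zeros(x_pres.shape[1])
    fallback = x_bg.std(axis=0, ddof=1) if len(x_bg) > 1 else np.ones(x_bg.shape[1])
    sd = np.where(sd > 0, sd, fallback)
    sd = np.where(sd > 0, sd, 1.0)
    beta = beta0 * sd / np.sqrt(max(m, 1))
    if feature_classes is not None:
        mult = np.array([CLASS_BETA_MULTIPLIER.get(c, 1.0) for c in feature_classes])
        beta = beta * mult
    return beta


def fit_maxent(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    beta: np.ndarray | float | None = None,
    beta0: float = 1.0,
    tol: float = 1e-7,
    max_iter: int = 2000,
    expansion: FeatureExpansion | None = None,
    feature_names: list[str] | None = None,
) -> MaxEntModel:
    """Fit the L1-penalized MaxEnt weights by convex optimization.

    The nonsmooth L1 term is handled by the standard positive/negative
    split lambda = a - b with a, b >= 0, turning the problem into a smooth
    bound-constrained one solved deterministically with L-BFGS-B.
    """
    x_pres = np.asarray(presence_features, dtype=float)
    x_bg = np.asarray(background_features, dtype=float)
    if x_pres.ndim != 2 or x_bg.ndim != 2 or x_pres.shape[1] != x_bg.shape[1]:
        raise DataError("presence and background feature matrices must share columns")
    if len(x_pres) < 1:
        raise DataError("need at least one presence")
    if len(x_bg) < 10:
        raise DataError("need at least 10 background points")
    k = x_pres.shape[1]
    if beta is None:
        classes = None
        if expansion is not None and len(expansion.feature_classes) == k:
            classes = expansion.feature_classes
        beta_vec = default_beta(x_pres, x_bg, beta0, feature_classes=classes)
    else:
        beta_vec = np.broadcast_to(np.asarray(beta, dtype=float), (k,)).copy()
    if np.any(beta_vec < 0):
        raise ConfigError("beta must be nonnegative")

    # internal scaling for conditioning
    mu = x_bg.mean(axis=0)
    sigma = x_bg.std(axis=0)
    sigma = np.where(sigma > 0, sigma, 1.0)
    sp = (x_pres - mu) / sigma
    sb = (x_bg - mu) / sigma
    # lambda'_j = lambda_j * sigma_j, so the L1 coefficient in scaled space
    # is beta_j / sigma_j
    beta_s = beta_vec / sigma

    pres_mean = sp.mean(axis=0)

    def objective(ab):
        lam = ab[:k] - ab[k:]
        g, _ = _smooth_grad(lam, sp, sb)
        val = float(logsumexp(sb @ lam) - pres_mean @ lam + beta_s @ np.abs(lam))
        grad = np.concatenate([g + beta_s, -g + beta_s])
        return val, grad

    res = minimize(
        objective,
        np.zeros(2 * k),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0, None)] * (2 * k),
        options={
            "maxiter": max_iter,
            "maxfun": 50 * max_iter,
            "ftol": 1e-12,
            "gtol": tol,
            "maxls": 50,
        },
    )
    lam_scaled = res.x[:k] - res.x[k:]
    lam_scaled, polished = _newton_polish(lam_scaled, sp, sb, beta_s, tol)
    lam = lam_scaled / sigma

    eta_bg = x_bg @ lam
    log_z = float(logsumexp(eta_bg))
    q = np.exp(eta_bg - log_z)
    entropy = float(-np.sum(q * np.log(np.clip(q, 1e-300, None))))
    kkt_gap = np.abs(q @ x_bg - x_pres.mean(axis=0)) - beta_vec
    # converged when the optimizer certifies success or the KKT soft-matching
    # condition holds featurewise (in scaled units) to 10x the tolerance
    gap_scaled, _ = _smooth_grad(lam_scaled, sp, sb)
    kkt_scaled = np.abs(gap_scaled) - beta_s
    converged = bool(res.success) or bool(np.max(kkt_scaled) <= max(10 * tol, 1e-6))
    if not converged:
        warnings.warn(f"MaxEnt optimizer did not converge: {res.message}")
    return MaxEntModel(
        feature_names=list(feature_names or (expansion.feature_names if expansion else [f"f{i}" for i in range(k)])),
        lambda_=lam,
        log_partition=log_z,
        entropy_H=entropy,
        beta=beta_vec,
        converged=converged,
        n_iterations=int(res.nit),
        kkt_gap=kkt_gap,
        expansion=expansion,
    )


def variable_contribution(
    model: MaxEntModel,
    presence_features: np.ndarray,
    background_features: np.ndarray,
    n_permutations: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Permutation importance per covariate, normalized to sum 100.

    All features derived from one covariate are permuted jointly across the
    pooled presence+background sample; the drop in training AUC (presence
    vs background, logistic output), averaged over permutations and floored
    at zero, is the covariate's contribution.
    """
    if model.expansion is None:
        groups = {name: [i] for i, name in enumerate(model.feature_names)}
    else:
        groups = model.expansion.feature_indices_by_covariate()
    x_pres = np.asarray(presence_features, dtype=float)
    x_bg = np.asarray(background_features, dtype=float)
    m = len(x_pres)
    pooled = np.vstack([x_pres, x_bg])
    base = auc_value(model.logistic(x_pres), model.logistic(x_bg))
    rng = np.random.default_rng(seed)
    drops = {}
    for cov, idx in groups.items():
        vals = []
        for _ in range(n_permutations):
            perm = pooled.copy()
            order = rng.permutation(len(pooled))
            perm[:, idx] = perm[order][:, idx]
            vals.append(base - auc_value(model.logistic(perm[:m]), model.logistic(perm[m:])))
        drops[cov] = max(0.0, float(np.mean(vals)))
    out = pd.Series(drops)
    total = out.sum()
    if total > 0:
        out = 100 * out / total
    return out.sort_values(ascending=False)
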