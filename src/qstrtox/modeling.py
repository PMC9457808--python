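"""QSTR model fitting, validation and applicability domain.

The model is ordinary multiple linear regression of the toxicity response
log(1/C) on ten molecular descriptors.  Validation follows standard QSAR
practice:

* R^2 = 1 - SSE/SST on the fitted data,
* Q^2_LOO = 1 - PRESS/SST, the leave-one-out cross-validated coefficient
  (model deemed acceptable when Q^2_LOO > 0.5),
* k-fold cross-validation (mean out-of-fold R^2, RMSE, MAE),
* applicability domain by leverage: h_i = x_i (X'X)^-1 x_i' with cutoff
  h* = 3(p+1)/n, visualised as a Williams plot of standardized residuals
  against leverage.

Descriptor subsets are selected with a genetic algorithm over the
pre-filtered descriptor pool.  The published ten-descriptor model is
bundled as the frozen constant :data:`PUBLISHED_MODEL`.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)


@dataclass
class ModelSpec:
    """A frozen linear model: descriptor names, coefficients, intercept."""

    names: list[str]
    coeffs: list[float]
    intercept: float

    def __post_init__(self) -> None:
        if len(self.names) != len(self.coeffs):
            raise ValueError("names and coeffs must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("descriptor names must be unique")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"names": self.names, "coeffs": self.coeffs, "intercept": self.intercept},
            indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelSpec":
        d = json.loads(Path(path).read_text())
        return cls(names=d["names"], coeffs=d["coeffs"], intercept=d["intercept"])


#: The published ten-descriptor carbamate toxicity model.
PUBLISHED_MODEL = ModelSpec(
    names=["EA", "qC", "LOC", "SpPosA_RG", "H4m",
           "nCt", "nROCON", "B05_CN", "B05_NO", "DLS_05"],
    coeffs=[0.3231, -34.0837, -0.6319, -22.6053, -1.5012,
            0.2275, -0.6919, 0.6524, 0.3996, 0.6244],
    intercept=18.7033,
)


@dataclass
class FitResult:
    spec: ModelSpec
    std_coeffs: list[float]
    conf_int95: list[float]      # half-widths, per coefficient (same order as names)
    p_values: list[float]
    r2: float
    q2_loo: float
    rmse: float                  # sqrt(SSE/n)
    mae: float
    n_train: int
    intercept_conf95: float = float("nan")
    intercept_p: float = float("nan")

    def summary(self) -> str:
        lines = [f"n = {self.n_train}   R2 = {self.r2:.4f}   "
                 f"Q2_LOO = {self.q2_loo:.4f}   RMSE = {self.rmse:.4f}   "
                 f"MAE = {self.mae:.4f}",
                 f"{'variable':<12}{'coeff':>12}{'std coeff':>12}"
                 f"{'conf int 95':>14}{'p-value':>12}"]
        for name, c, s, ci, p in zip(self.spec.names, self.spec.coeffs,
                                     self.std_coeffs, self.conf_int95,
                                     self.p_values):
            lines.append(f"{name:<12}{c:>12.4f}{s:>12.4f}{ci:>14.4f}{p:>12.3e}")
        lines.append(f"{'intercept':<12}{self.spec.intercept:>12.4f}"
                     f"{'':>12}{self.intercept_conf95:>14.4f}{self.intercept_p:>12.3e}")
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "names": self.spec.names, "coeffs": self.spec.coeffs,
            "intercept": self.spec.intercept, "std_coeffs": self.std_coeffs,
            "conf_int95": self.conf_int95, "p_values": self.p_values,
            "r2": self.r2, "q2_loo": self.q2_loo, "rmse": self.rmse,
            "mae": self.mae, "n_train": self.n_train,
        }, indent=2))


@dataclass
class SplitPlan:
    train_ids: list
    test_ids: list
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")


@dataclass
class GAConfig:
    """Genetic-algorithm settings for descriptor subset selection."""

    subset_size: int = 10
    population: int = 100
    generations: int = 200
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    tournament_size: int = 3
    elitism: int = 1
    fitness: str = "q2_loo"      # or "r2"
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.fitness not in ("q2_loo", "r2"):
            raise ValueError("fitness must be 'q2_loo' or 'r2'")
        if self.subset_size < 1 or self.population < 1:
            raise ValueError("subset_size and population must be >= 1")


# ---------------------------------------------------------------------------
# helpers

def _as_matrix(X, names: Optional[Sequence[str]] = None):
    """Coerce X to (ndarray, names)."""
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if names is None:
        names = [f"x{j}" for j in range(arr.shape[1])]
    return arr, list(names)


def _check_full_rank(X1: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X1)
    if rank < X1.shape[1]:
        # identify columns involved in the collinearity by leave-one-out rank
        guilty = []
        for j in range(1, X1.shape[1]):
            sub = np.delete(X1, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                guilty.append(names[j - 1])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {guilty}")


# ---------------------------------------------------------------------------
# pre-filtering

def prefilter(table: pd.DataFrame, y: Sequence[float],
              corr_threshold: float = 0.90) -> tuple[pd.DataFrame, list[str]]:
    """Drop constant columns and one member of each highly correlated pair.

    For each pair with |Pearson r| > ``corr_threshold`` the member less
    correlated (in absolute value) with the response is dropped; ties drop
    the later column in input order.  Returns the reduced table and a
    human-readable removal log.
    """
    if len(table) < 2:
        raise ValueError("prefilter needs at least 2 rows")
    y = np.asarray(y, dtype=float)
    cols = [c for c in table.columns if c not in ("id", "set", "log_inv_c")]
    removal_log: list[str] = []
    kept: list[str] = []
    for c in cols:
        v = table[c].to_numpy(dtype=float)
        if np.all(v == v[0]):
            removal_log.append(f"{c}: constant column removed")
        else:
            kept.append(c)

    ycorr = {}
    for c in kept:
        v = table[c].to_numpy(dtype=float)
        ycorr[c] = abs(np.corrcoef(v, y)[0, 1])

    removed: set[str] = set()
    for ai in range(len(kept)):
        a = kept[ai]
        if a in removed:
            continue
        for bi in range(ai + 1, len(kept)):
            b = kept[bi]
            if b in removed:
                continue
            r = np.corrcoef(table[a].to_numpy(dtype=float),
                            table[b].to_numpy(dtype=float))[0, 1]
            if abs(r) > corr_threshold:
                # drop the member with lower |correlation to y|; ties drop b
                drop = a if ycorr[a] < ycorr[b] else b
                removed.add(drop)
                removal_log.append(
                    f"{drop}: |r({a},{b})| = {abs(r):.3f} > {corr_threshold}; "
                    f"kept {'b' if drop == a else 'a'} = {b if drop == a else a}")
                if drop == a:
                    break
    survivors = [c for c in kept if c not in removed]
    if not survivors:
        raise ValueError("prefilter removed every column")
    keep_cols = [c for c in table.columns if c in ("id", "set", "log_inv_c")] + survivors
    return table[keep_cols].copy(), removal_log


# ---------------------------------------------------------------------------
# fitting and validation

def ols_fit(X, y, names: Optional[Sequence[str]] = None) -> FitResult:
    """Ordinary least squares through a QR/pinv factorisation route.

    Returns coefficients with standardized coefficients
    (coeff * sd(x)/sd(y), population standard deviations), 95% confidence
    half-widths and two-sided t-test p-values, plus R^2, Q^2_LOO,
    RMSE = sqrt(SSE/n) and MAE.
    """
    Xm, names = _as_matrix(X, names)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (got n={n}, p={p})")
    X1 = np.column_stack([np.ones(n), Xm])
    _check_full_rank(X1, names)

    res = sm.OLS(y, X1).fit()
    coeffs = res.params[1:].tolist()
    intercept = float(res.params[0])
    ci = res.conf_int(alpha=0.05)
    half = ((ci[:, 1] - ci[:, 0]) / 2.0)

    sd_y = float(np.std(y))
    sd_x = np.std(Xm, axis=0)
    std_coeffs = (np.array(coeffs) * sd_x / sd_y).tolist() if sd_y > 0 else [0.0] * p

    resid = y - res.fittedvalues
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    rmse = math.sqrt(sse / n)
    mae = float(np.mean(np.abs(resid)))
    q2 = q2_loo(Xm, y)

    return FitResult(
        spec=ModelSpec(names=names, coeffs=coeffs, intercept=intercept),
        std_coeffs=std_coeffs,
        conf_int95=half[1:].tolist(),
        p_values=res.pvalues[1:].tolist(),
        r2=r2, q2_loo=q2, rmse=rmse, mae=mae, n_train=n,
        intercept_conf95=float(half[0]), intercept_p=float(res.pvalues[0]),
    )


def leverage(X_train, X_new=None) -> np.ndarray:
    """Hat-matrix diagonal h_i = x_i (X'X)^-1 x_i', intercept prepended.

    Computed through the thin QR factorisation of the training design; new
    points are projected with the training (X'X)^-1.  Sums to p+1 over the
    training rows.
    """
    Xm, names = _as_matrix(X_train)
    n, p = Xm.shape
    X1 = np.column_stack([np.ones(n), Xm])
    _check_full_rank(X1, names)
    q, r = np.linalg.qr(X1)
    if X_new is None:
        return np.sum(q * q, axis=1)
    Xn, _ = _as_matrix(X_new)
    X1n = np.column_stack([np.ones(Xn.shape[0]), Xn])
    # h_new = || R^-T x ||^2
    z = np.linalg.solve(r.T, X1n.T)
    return np.sum(z * z, axis=0)


def critical_leverage(p: int, n: int) -> float:
    """Applicability-domain cutoff h* = 3(p+1)/n."""
    if p < 1 or n <= p + 1:
        raise ValueError(f"need p >= 1 and n > p + 1 (got p={p}, n={n})")
    return 3.0 * (p + 1) / n


def q2_loo(X, y, method: str = "hat") -> float:
    """Leave-one-out cross-validated determination coefficient.

    Q^2 = 1 - sum (y_i - yhat_(-i))^2 / sum (y_i - ybar)^2, with ybar the
    full-sample mean.  ``method="hat"`` uses the exact hat-matrix shortcut
    e_i/(1 - h_ii); ``method="refit"`` runs the explicit n-fold refit loop
    (both are algebraically identical for OLS).
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n <= p + 2:
        raise ValueError(f"q2_loo needs n > p + 2 (got n={n}, p={p})")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return 0.0  # constant response carries no explainable variance
    if method == "hat":
        X1 = np.column_stack([np.ones(n), Xm])
        _check_full_rank(X1, names)
        beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
        e = y - X1 @ beta
        h = leverage(Xm)
        if np.any(h >= 1.0 - 1e-12):
            raise ValueError("a leverage of 1 makes the LOO residual undefined")
        press = float(np.sum((e / (1.0 - h)) ** 2))
    elif method == "refit":
        press = 0.0
        idx = np.arange(n)
        for i in range(n):
            keep = idx != i
            X1 = np.column_stack([np.ones(n - 1), Xm[keep]])
            beta, *_ = np.linalg.lstsq(X1, y[keep], rcond=None)
            pred = beta[0] + Xm[i] @ beta[1:]
            press += (y[i] - pred) ** 2
    else:
        raise ValueError(f"unknown method {method!r}")
    return 1.0 - press / sst


def kfold_cv(X, y, k: int = 5, seed: int = 0,
             mode: str = "random") -> dict:
    """k-fold cross-validation; returns per-fold and mean R^2, RMSE, MAE.

    Rows are shuffled by ``seed`` and split into k near-equal folds.  The
    out-of-fold R^2 of each fold uses that fold's own response mean.
    ``mode="median_r2"`` draws 25 candidate fold assignments and keeps the
    one whose mean out-of-fold R^2 is the median of the candidates.
    """
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n < 2 * k:
        raise ValueError(f"kfold_cv needs n >= 2k (got n={n}, k={k})")

    def run(fold_seed: int) -> dict:
        rng = np.random.default_rng(fold_seed)
        order = rng.permutation(n)
        folds = np.array_split(order, k)
        r2s, rmses, maes = [], [], []
        for fold in folds:
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            if mask.sum() < p + 2:
                raise ValueError("a fold leaves too few training rows")
            X1 = np.column_stack([np.ones(mask.sum()), Xm[mask]])
            beta, *_ = np.linalg.lstsq(X1, y[mask], rcond=None)
            pred = beta[0] + Xm[fold] @ beta[1:]
            e = y[fold] - pred
            sst = float(np.sum((y[fold] - y[fold].mean()) ** 2))
            r2s.append(1.0 - float(e @ e) / sst if sst > 0 else 0.0)
            rmses.append(math.sqrt(float(e @ e) / len(fold)))
            maes.append(float(np.mean(np.abs(e))))
        return {"r2": r2s, "rmse": rmses, "mae": maes,
                "mean_r2": float(np.mean(r2s)),
                "mean_rmse": float(np.mean(rmses)),
                "mean_mae": float(np.mean(maes)),
                "seed": fold_seed}

    if mode == "random":
        out = run(seed)
    elif mode == "median_r2":
        rng = np.random.default_rng(seed)
        cands = [run(int(s)) for s in rng.integers(0, 2**31 - 1, size=25)]
        cands.sort(key=lambda d: d["mean_r2"])
        out = cands[len(cands) // 2]
        logger.info("median_r2 mode kept fold seed %d (mean R2 %.4f)",
                    out["seed"], out["mean_r2"])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out["k"] = k
    out["mode"] = mode
    return out


def split_train_test(ids: Sequence, test_fraction: float = 0.15,
                     seed: int = 0) -> SplitPlan:
    """Random train/test split holding out int(test_fraction * n) compounds.

    The test-set size is the truncated product (n = 178 at 15% gives 26
    test / 152 training compounds, the split used for the published model).
    """
    ids = list(ids)
    n = len(ids)
    if n < 7:
        raise ValueError("need at least 7 compounds to split")
    n_test = int(test_fraction * n)
    rng = np.random.default_rng(seed)
    test_idx = set(rng.choice(n, size=n_test, replace=False).tolist())
    train = [ids[i] for i in range(n) if i not in test_idx]
    test = [ids[i] for i in range(n) if i in test_idx]
    return SplitPlan(train_ids=train, test_ids=test, seed=seed)


# ---------------------------------------------------------------------------
# genetic-algorithm subset selection

def _subset_fitness(Xm: np.ndarray, y: np.ndarray, subset: tuple[int, ...],
                    statistic: str, cache: dict) -> float:
    if subset in cache:
        return cache[subset]
    Xs = Xm[:, subset]
    try:
        if statistic == "r2":
            n = Xs.shape[0]
            X1 = np.column_stack([np.ones(n), Xs])
            beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
            e = y - X1 @ beta
            sst = float(np.sum((y - y.mean()) ** 2))
            fit = 1.0 - float(e @ e) / sst
        else:
            fit = q2_loo(Xs, y)
    except (ValueError, np.linalg.LinAlgError):
        fit = -np.inf
    cache[subset] = fit
    return fit


def ga_select(table, y, cfg: GAConfig) -> list[tuple[list[str], float]]:
    """Genetic-algorithm search for the best fixed-size descriptor subset.

    Chromosomes are descriptor-index subsets of size ``cfg.subset_size``;
    fitness is R^2 or Q^2_LOO of the OLS fit on the supplied rows.
    Tournament selection, uniform crossover repaired to the fixed subset
    size, single-member swap mutation, elitism of 1.  Deterministic for a
    given seed.  Returns the hall of fame: up to 10 unique subsets as
    (descriptor names, fitness), best first; fitness ties keep first-seen
    order.
    """
    Xm, names = _as_matrix(table)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if cfg.subset_size > p:
        raise ValueError(f"subset_size {cfg.subset_size} exceeds {p} columns")
    rng = np.random.default_rng(cfg.seed)
    cache: dict = {}
    all_idx = np.arange(p)

    def fitness(sub: tuple[int, ...]) -> float:
        return _subset_fitness(Xm, y, sub, cfg.fitness, cache)

    def random_subset() -> tuple[int, ...]:
        return tuple(sorted(rng.choice(p, size=cfg.subset_size, replace=False).tolist()))

    def repair(members: set[int]) -> tuple[int, ...]:
        members = set(members)
        while len(members) > cfg.subset_size:
            members.remove(int(rng.choice(sorted(members))))
        if len(members) < cfg.subset_size:
            pool = np.setdiff1d(all_idx, sorted(members))
            extra = rng.choice(pool, size=cfg.subset_size - len(members), replace=False)
            members.update(int(e) for e in extra)
        return tuple(sorted(members))

    def mutate(sub: tuple[int, ...]) -> tuple[int, ...]:
        members = set(sub)
        out_pool = np.setdiff1d(all_idx, sub)
        if out_pool.size == 0:
            return sub
        members.remove(int(rng.choice(sub)))
        members.add(int(rng.choice(out_pool)))
        return tuple(sorted(members))

    population = [random_subset() for _ in range(cfg.population)]
    hall: dict[tuple[int, ...], float] = {}

    def record(sub: tuple[int, ...], fit: float) -> None:
        if sub not in hall:
            hall[sub] = fit

    fits = [fitness(s) for s in population]
    for s, f in zip(population, fits):
        record(s, f)

    for _gen in range(cfg.generations):
        new_pop: list[tuple[int, ...]] = []
        # elitism: carry over the best
        if cfg.elitism > 0:
            order = sorted(range(len(population)), key=lambda i: -fits[i])
            new_pop.extend(population[i] for i in order[:cfg.elitism])
        while len(new_pop) < cfg.population:
            def tournament() -> tuple[int, ...]:
                picks = rng.integers(0, len(population), size=cfg.tournament_size)
                best = max(picks, key=lambda i: fits[i])
                return population[best]
            p1, p2 = tournament(), tournament()
            if rng.random() < cfg.crossover_rate:
                union = sorted(set(p1) | set(p2))
                inter = set(p1) & set(p2)
                # uniform: each non-shared member kept with prob 1/2, then repair
                child = set(inter)
                for m in union:
                    if m not in inter and rng.random() < 0.5:
                        child.add(m)
                child_t = repair(child)
            else:
                child_t = p1
            if rng.random() < cfg.mutation_rate:
                child_t = mutate(child_t)
            new_pop.append(child_t)
        population = new_pop
        fits = [fitness(s) for s in population]
        for s, f in zip(population, fits):
            record(s, f)

    # hall of fame: top 10 unique subsets, ties keep insertion (first-seen) order
    ranked = sorted(hall.items(), key=lambda kv: -kv[1])
    top = ranked[:10]
    return [([names[i] for i in sub], fit) for sub, fit in top]


# ---------------------------------------------------------------------------
# prediction and applicability domain

def predict(spec: ModelSpec, row) -> float | np.ndarray:
    """Evaluate a frozen linear model on one row or a table of rows.

    ``row`` may be a mapping, a DescriptorRow-like object, a pandas Series
    or a DataFrame; every descriptor named in ``spec`` must be present and
    non-missing.
    """
    if isinstance(row, pd.DataFrame):
        missing = [nm for nm in spec.names if nm not in row.columns]
        if missing:
            raise KeyError(f"missing descriptors: {missing}")
        sub = row[spec.names].to_numpy(dtype=float)
        if np.any(~np.isfinite(sub)):
            bad = [spec.names[j] for j in np.where(~np.isfinite(sub))[1]]
            raise ValueError(f"missing/non-finite descriptor values: {sorted(set(bad))}")
        return spec.intercept + sub @ np.asarray(spec.coeffs)
    if isinstance(row, pd.Series):
        get = row.get
    elif isinstance(row, dict):
        get = row.get
    else:
        get = lambda nm, default=None: getattr(row, nm, default)
    total = spec.intercept
    for nm, c in zip(spec.names, spec.coeffs):
        v = get(nm)
        if v is None or (isinstance(v, float) and not math.isfinite(v)):
            raise KeyError(f"missing descriptor: {nm}")
        total += c * float(v)
    return float(total)


def williams_data(fit: FitResult, X, y, ids: Optional[Sequence] = None,
                  X_new=None, y_new=None, ids_new: Optional[Sequence] = None,
                  sigma_limit: float = 3.0) -> pd.DataFrame:
    """Williams-plot table: leverage, standardized residual, domain flags.

    Training rows get leverages from their own design; optional new points
    are projected with the training (X'X)^-1 and standardized by the
    training RMSE.  ``in_domain`` means h <= h* = 3(p+1)/n_train;
    ``outlier`` means |standardized residual| > ``sigma_limit``.
    """
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    h_star = critical_leverage(p, n)
    pred = fit.spec.intercept + Xm @ np.asarray(fit.spec.coeffs)
    resid = y - pred
    if fit.rmse <= 0:
        raise ValueError("training RMSE is zero; standardized residuals undefined")
    rows = {
        "id": list(ids) if ids is not None else list(range(n)),
        "set": ["train"] * n,
        "leverage": leverage(Xm),
        "std_residual": resid / fit.rmse,
    }
    df = pd.DataFrame(rows)
    if X_new is not None:
        Xn, _ = _as_matrix(X_new)
        h_new = leverage(Xm, Xn)
        pred_new = fit.spec.intercept + Xn @ np.asarray(fit.spec.coeffs)
        if y_new is not None:
            std_new = (np.asarray(y_new, dtype=float) - pred_new) / fit.rmse
        else:
            std_new = np.full(Xn.shape[0], np.nan)
        df_new = pd.DataFrame({
            "id": list(ids_new) if ids_new is not None else
                  [f"new{i}" for i in range(Xn.shape[0])],
            "set": ["test"] * Xn.shape[0],
            "leverage": h_new,
            "std_residual": std_new,
        })
        df = pd.concat([df, df_new], ignore_index=True)
    df["in_domain"] = df["leverage"] <= h_star
    df["outlier"] = df["std_residual"].abs() > sigma_limit
    df.attrs["h_star"] = h_star
    df.attrs["sigma_limit"] = sigma_limit
    return df


def plot_williams(df: pd.DataFrame, path: str | Path) -> None:
    """Render a Williams plot (leverage vs standardized residual) to file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    h_star = df.attrs.get("h_star")
    sigma = df.attrs.get("sigma_limit", 3.0)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for label, marker, color in (("train", "o", "tab:blue"), ("test", "s", "tab:purple")):
        sub = df[df["set"] == label]
        if len(sub):
            ax.scatter(sub["leverage"], sub["std_residual"], s=18,
                       marker=marker, color=color, label=label, alpha=0.75)
    ax.axhline(sigma, ls="--", color="gray")
    ax.axhline(-sigma, ls="--", color="gray")
    if h_star is not None:
        ax.axvline(h_star, ls="--", color="red", label=f"h* = {h_star:.3f}")
    ax.set_xlabel("leverage h")
    ax.set_ylabel("standardized residual")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
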