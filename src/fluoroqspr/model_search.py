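"""Exhaustive 1- and 2-descriptor linear regression search.

Every single descriptor and every unordered descriptor pair is fitted by
ordinary least squares (intercept always included) against the response, and
models are ranked on in-sample metrics: R^2 first, ties broken by MAE, RMSE,
parsimony (fewer terms), and finally lexical term order.  Collinear pairs are
fitted but flagged degenerate: they stay in the model count yet are excluded
from the ranking.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .descriptor_engine import DescriptorTable, apply_scaling
from .errors import DomainError, MissingDescriptorError, CorrelationError

#: two scaled descriptors more correlated than this make a pair degenerate
COLLINEARITY_R = 0.999
#: R^2 differences below this are ties for model selection
R2_TIE_TOL = 1e-6


@dataclass
class CandidateModel:
    terms: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    r2: float
    mae: float
    rmse: float
    degenerate: bool = False
    rank: int | None = None
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "coefficients": list(self.coefficients),
            "intercept": self.intercept,
            "r2": self.r2,
            "mae": self.mae,
            "rmse": self.rmse,
            "degenerate": self.degenerate,
            "rank": self.rank,
            "scaling": {k: list(v) for k, v in self.scaling.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CandidateModel":
        return cls(
            terms=tuple(d["terms"]),
            coefficients=tuple(d["coefficients"]),
            intercept=float(d["intercept"]),
            r2=float(d["r2"]),
            mae=float(d["mae"]),
            rmse=float(d["rmse"]),
            degenerate=bool(d.get("degenerate", False)),
            rank=d.get("rank"),
            scaling={k: tuple(v) for k, v in d.get("scaling", {}).items()},
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CandidateModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class SearchReport:
    n_models: int
    ranked: list[CandidateModel]
    best: CandidateModel
    criteria: dict


def metrics(residuals: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """In-sample (R^2, MAE, RMSE) from a residual vector and its response."""
    residuals = np.asarray(residuals, dtype=float)
    y = np.asarray(y, dtype=float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise DomainError("zero response variance: R^2 undefined")
    ss_res = float(np.sum(residuals ** 2))
    r2 = 1.0 - ss_res / ss_tot
    mae = float(np.mean(np.abs(residuals)))
    rmse = float(np.sqrt(np.mean(residuals ** 2)))
    return r2, mae, rmse


def fit_ols(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    terms: tuple[str, ...] | None = None,
    scaling: dict[str, tuple[float, float]] | None = None,
) -> CandidateModel:
    """Least-squares fit of ``y`` on the given descriptor columns + intercept."""
    if isinstance(X, pd.DataFrame):
        terms = tuple(X.columns) if terms is None else tuple(terms)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        terms = tuple(terms or (f"x{i}" for i in range(Xv.shape[1])))
    y = np.asarray(y, dtype=float)
    n, k = Xv.shape
    if n <= k + 1:
        raise DomainError(f"need more than {k + 1} observations, got {n}")
    A = np.column_stack([np.ones(n), Xv])
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    degenerate = rank < k + 1
    if k == 2 and not degenerate:
        sx = Xv.std(axis=0)
        if np.all(sx > 0):
            r = float(np.corrcoef(Xv[:, 0], Xv[:, 1])[0, 1])
            if abs(r) > COLLINEARITY_R:
                degenerate = True
    residuals = y - A @ beta
    r2, mae, rmse = metrics(residuals, y)
    return CandidateModel(
        terms=terms,
        coefficients=tuple(float(b) for b in beta[1:]),
        intercept=float(beta[0]),
        r2=r2,
        mae=mae,
        rmse=rmse,
        degenerate=degenerate,
        scaling={t: scaling[t] for t in terms} if scaling else {},
    )


def _rank_key(m: CandidateModel) -> tuple:
    return (-m.r2, m.mae, m.rmse, len(m.terms), m.terms)


def _fit_all_subsets(
    Xdf: pd.DataFrame,
    y: np.ndarray,
    cols: list[str],
    scaling: dict[str, tuple[float, float]] | None,
) -> list[CandidateModel]:
    """Fit all singles and pairs via precomputed normal equations.

    Numerically equivalent to calling :func:`fit_ols` per subset (same normal
    equations), but avoids per-model least-squares setup cost so that full
    >24,000-model searches stay fast.
    """
    X = Xdf.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    if n <= 3:
        raise DomainError(f"need more than 3 observations for pair models, got {n}")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise DomainError("zero response variance: R^2 undefined")
    G = X.T @ X
    s = X.sum(axis=0)
    Xy = X.T @ y
    sy = float(y.sum())
    std = X.std(axis=0)
    if d > 1:
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(X, rowvar=False)
    else:
        C = np.ones((1, 1))

    def finish(terms, beta, xsub, degenerate):
        resid = y - beta[0] - xsub @ beta[1:]
        ss_res = float(resid @ resid)
        r2 = 1.0 - ss_res / ss_tot
        mae = float(np.mean(np.abs(resid)))
        rmse = float(np.sqrt(ss_res / n))
        return CandidateModel(
            terms=terms,
            coefficients=tuple(float(b) for b in beta[1:]),
            intercept=float(beta[0]),
            r2=r2, mae=mae, rmse=rmse, degenerate=degenerate,
            scaling={t_: scaling[t_] for t_ in terms} if scaling else {},
        )

    models: list[CandidateModel] = []
    for i in range(d):
        if std[i] < 1e-12:
            beta = np.array([y.mean(), 0.0])
            models.append(finish((cols[i],), beta, X[:, i:i + 1], True))
            continue
        M = np.array([[n, s[i]], [s[i], G[i, i]]])
        beta = np.linalg.solve(M, np.array([sy, Xy[i]]))
        models.append(finish((cols[i],), beta, X[:, i:i + 1], False))
    for i, j in itertools.combinations(range(d), 2):
        degenerate = bool(
            std[i] < 1e-12
            or std[j] < 1e-12
            or (np.isfinite(C[i, j]) and abs(C[i, j]) > COLLINEARITY_R)
        )
        M = np.array([
            [n, s[i], s[j]],
            [s[i], G[i, i], G[i, j]],
            [s[j], G[i, j], G[j, j]],
        ])
        v = np.array([sy, Xy[i], Xy[j]])
        try:
            beta = np.linalg.solve(M, v)
        except np.linalg.LinAlgError:
            beta, *_ = np.linalg.lstsq(
                np.column_stack([np.ones(n), X[:, [i, j]]]), y, rcond=None
            )
            degenerate = True
        models.append(finish((cols[i], cols[j]), beta, X[:, [i, j]], degenerate))
    return models


def enumerate_models(
    t: DescriptorTable,
    response: pd.Series | np.ndarray,
    max_terms: int = 2,
) -> SearchReport:
    """Fit every single descriptor and every unordered pair exactly once."""
    if max_terms != 2:
        raise DomainError("only max_terms=2 is supported")
    if isinstance(response, pd.Series):
        response = response.reindex(t.values.index)
        keep = response.notna()
        y = response[keep].to_numpy(dtype=float)
        X = t.values.loc[keep]
    else:
        y = np.asarray(response, dtype=float)
        keep = np.isfinite(y)
        y = y[keep]
        X = t.values.loc[keep]
    cols = list(X.columns)
    d = len(cols)
    models = _fit_all_subsets(X, y, cols, t.scaling or None)
    n_models = len(models)
    assert n_models == d + d * (d - 1) // 2
    ranked = sorted((m for m in models if not m.degenerate), key=_rank_key)
    for i, m in enumerate(ranked):
        m.rank = i + 1
    best = select_best_from(ranked)
    return SearchReport(
        n_models=n_models,
        ranked=ranked,
        best=best,
        criteria={
            "sort": ["r2 desc", "mae asc", "rmse asc", "n_terms asc", "lexical"],
            "r2_tie_tol": R2_TIE_TOL,
            "n_descriptors": d,
            "n_compounds": int(len(y)),
        },
    )


def select_best_from(ranked: list[CandidateModel]) -> CandidateModel:
    """Best model: max R^2; ties (< ``R2_TIE_TOL``) broken by MAE, RMSE,
    fewer terms, lexical term order."""
    if not ranked:
        raise DomainError("no fitted (non-degenerate) models to select from")
    top_r2 = max(m.r2 for m in ranked)
    pool = [m for m in ranked if top_r2 - m.r2 < R2_TIE_TOL]
    return min(pool, key=lambda m: (m.mae, m.rmse, len(m.terms), m.terms))


def select_best(report: SearchReport) -> CandidateModel:
    return select_best_from(report.ranked)


def predict(
    model: CandidateModel,
    t: DescriptorTable,
    ids: list | None = None,
) -> pd.Series:
    """Predicted response per compound id.

    If the model carries training (min, max) records and the table is
    unscaled, the records are applied first; inputs leaving [0,1] raise an
    extrapolation warning but are evaluated.
    """
    ids = list(t.values.index) if ids is None else list(ids)
    missing_ids = [i for i in ids if i not in set(t.values.index)]
    if missing_ids:
        raise MissingDescriptorError(f"no descriptor rows for ids {missing_ids!r}")
    missing_cols = [c for c in model.terms if c not in t.values.columns]
    if missing_cols:
        raise MissingDescriptorError(
            f"table lacks descriptor column(s) {missing_cols!r}"
        )
    sub = t.values.loc[ids, list(model.terms)]
    if model.scaling and not t.is_scaled:
        sub = apply_scaling(model.scaling, sub)
    yhat = model.intercept + sub.to_numpy(dtype=float) @ np.asarray(model.coefficients)
    return pd.Series(yhat, index=ids, name="predicted")


def unscale_model(model: CandidateModel) -> tuple[dict[str, float], float]:
    """Express a model fitted on scaled descriptors in raw descriptor units."""
    if not model.scaling:
        raise DomainError("model carries no scaling records")
    coeffs: dict[str, float] = {}
    intercept = model.intercept
    for term, c in zip(model.terms, model.coefficients):
        lo, hi = model.scaling[term]
        coeffs[term] = c / (hi - lo)
        intercept -= c * lo / (hi - lo)
    return coeffs, intercept


def correlate(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pearson correlation of two equal-length vectors and its square."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise CorrelationError("inputs must be equal-length 1-D vectors")
    if len(a) < 3:
        raise CorrelationError("need at least 3 points")
    if a.std() == 0 or b.std() == 0:
        raise CorrelationError("correlation undefined for constant input")
    r = float(np.corrcoef(a, b)[0, 1])
    return r, r * r


def fit_fixed_terms(
    t: DescriptorTable, response: pd.Series, terms: tuple[str, ...]
) -> CandidateModel:
    """Confirmatory fit with a fixed term set (e.g. {"#F", "1/q_S"})."""
    response = response.reindex(t.values.index)
    keep = response.notna()
    missing = [c for c in terms if c not in t.values.columns]
    if missing:
        raise MissingDescriptorError(f"table lacks descriptor column(s) {missing!r}")
    return fit_ols(
        t.values.loc[keep, list(terms)],
        response[keep].to_numpy(dtype=float),
        terms=tuple(terms),
        scaling=t.scaling or None,
    )
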