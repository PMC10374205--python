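"""Cox proportional-hazards regression, from-scratch partial likelihood.

Implements Newton-Raphson maximization of the Efron-tie-corrected log
partial likelihood (Breslow available for cross-checks), Wald standard
errors from the inverse observed information, and the four nested adjustment
models used for the dietary-cluster / CVD association:

    crude   : cluster dummies only (healthy = reference)
    model1  : + age (continuous), sex, socioeconomic status
    model2  : + smoking, physical activity (continuous), general obesity
    model3  : + residency, family history of CVD, abdominal obesity,
              hypertension, dyslipidemia
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoxFit",
    "ConvergenceError",
    "build_design",
    "cox_fit",
    "hazard_ratio_ci",
    "nested_models",
    "records_from_cohort",
    "MODEL_COVARIATES",
    "CATEGORICAL_LEVELS",
]


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge within the iteration budget."""


#: Declared level order for categorical covariates; the first level is the
#: dummy-coding reference.
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "cluster_label": ("healthy", "unhealthy", "mixed"),
    "sex": ("female", "male"),
    "ses": ("low", "moderate", "high"),
    "ses_collapsed": ("low", "not-low"),
    "smoking": ("non-smoker", "smoker", "ex-smoker"),
    "residency": ("rural", "urban"),
}

#: Adjustment sets of the nested models (cluster_label always included).
MODEL_COVARIATES: dict[str, tuple[str, ...]] = {
    "crude": (),
    "model1": ("age", "sex", "ses"),
    "model2": ("age", "sex", "ses", "smoking", "physical_activity",
               "general_obesity"),
    "model3": ("age", "sex", "ses", "smoking", "physical_activity",
               "general_obesity", "residency", "family_history",
               "abdominal_obesity", "hypertension", "dyslipidemia"),
}


@dataclass
class CoxFit:
    """Result of a proportional-hazards fit."""

    model_name: str
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    n: int
    n_events: int
    ties: str = "efron"

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    def ci(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        z = stats.norm.ppf(0.5 + level / 2.0)
        return np.exp(self.beta - z * self.se), np.exp(self.beta + z * self.se)

    @property
    def p_values(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se > 0, self.beta / self.se, np.inf * np.sign(self.beta))
        return 2.0 * stats.norm.sf(np.abs(z))

    def coefficient(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        return float(self.beta[i]), float(self.se[i])

    def summary(self) -> pd.DataFrame:
        lo, hi = self.ci()
        return pd.DataFrame(
            {
                "coef": self.beta,
                "se": self.se,
                "HR": self.hr,
                "ci_lower": lo,
                "ci_upper": hi,
                "p": self.p_values,
            },
            index=self.names,
        )


def build_design(
    data: pd.DataFrame, covariates: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Dummy-coded design matrix in the declared covariate order.

    Numeric columns enter as-is; declared categoricals are coded against
    their first level; undeclared string columns against their first sorted
    level.  0/1 integer flags pass through unchanged.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for cov in covariates:
        if cov not in data.columns:
            raise ValueError(f"missing covariate column: {cov!r}")
        col = data[cov]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(float))
            names.append(cov)
            continue
        values = col.to_numpy(object)
        levels = CATEGORICAL_LEVELS.get(cov)
        if levels is None:
            levels = tuple(sorted(pd.unique(values)))
        unknown = set(values) - set(levels)
        if unknown:
            raise ValueError(
                f"column {cov!r} has undeclared level(s) {sorted(unknown)}"
            )
        # drop levels absent from the data so the design stays full rank
        levels = tuple(lev for lev in levels if lev in set(values))
        for lev in levels[1:]:
            cols.append((values == lev).astype(float))
            names.append(f"{cov}_{lev}")
    if not cols:
        raise ValueError("empty design: no covariates given")
    return np.column_stack(cols), names


def _efron_quantities(
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    beta: np.ndarray,
    ties: str,
) -> tuple[float, np.ndarray, np.ndarray]:
    """(log partial likelihood, score, observed information) at ``beta``."""
    n, p = X.shape
    order = np.argsort(time, kind="stable")
    t = time[order]
    d = event[order].astype(bool)
    Xs = X[order]

    eta = Xs @ beta
    w = np.exp(eta)
    wx = w[:, None] * Xs
    wxx = np.einsum("i,ij,ik->ijk", w, Xs, Xs)

    # suffix sums over the risk set {j : t_j >= t}
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))

    event_times = np.unique(t[d])
    first_idx = np.searchsorted(t, event_times, side="left")
    for et, f in zip(event_times, first_idx):
        death_mask = (t == et) & d
        D = int(death_mask.sum())
        wd = w[death_mask]
        loglik += float(eta[death_mask].sum())
        grad += Xs[death_mask].sum(axis=0)

        if ties == "efron" and D > 1:
            frac = np.arange(D) / D
        else:
            frac = np.zeros(D)
        wd_sum = wd.sum()
        wxd_sum = wx[death_mask].sum(axis=0)
        wxxd_sum = wxx[death_mask].sum(axis=0)

        denom = S0[f] - frac * wd_sum                       # (D,)
        num1 = S1[f][None, :] - frac[:, None] * wxd_sum     # (D, p)
        num2 = S2[f][None, :, :] - frac[:, None, None] * wxxd_sum  # (D, p, p)

        loglik -= float(np.log(denom).sum())
        r1 = num1 / denom[:, None]
        grad -= r1.sum(axis=0)
        info += (num2 / denom[:, None, None]).sum(axis=0)
        info -= np.einsum("lj,lk->jk", r1, r1)
    return loglik, grad, info


def cox_fit(
    data: pd.DataFrame,
    covariates: Sequence[str],
    time_col: str = "time",
    event_col: str = "event",
    ties: str = "efron",
    model_name: str = "custom",
    max_iter: int = 50,
    tol_score: float = 1e-8,
    tol_loglik: float = 1e-10,
) -> CoxFit:
    """Maximize the partial likelihood by Newton-Raphson from beta = 0.

    Convergence when max |score| < 1e-8 or the relative log-likelihood change
    is < 1e-10; standard errors from the inverse observed information at the
    optimum.  Raises on no events, on rank-deficient designs (naming the
    offending column) and on non-convergence.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie correction {ties!r}")
    time = data[time_col].to_numpy(float)
    event = data[event_col].to_numpy(int)
    if np.any(time <= 0):
        raise ValueError("all follow-up times must be > 0")
    if not set(np.unique(event)) <= {0, 1}:
        raise ValueError("event indicator must be 0/1")
    n_events = int(event.sum())
    if n_events < 1:
        raise ValueError("cannot fit a Cox model with no events")

    X, names = build_design(data, covariates)
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = names[int(np.argmin(sds))]
        raise ValueError(f"rank-deficient design: column {bad!r} is constant")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        # name one redundant column
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others - others.mean(axis=0)) == np.linalg.matrix_rank(
                X - X.mean(axis=0)
            ):
                raise ValueError(
                    f"rank-deficient design: column {names[j]!r} is collinear"
                )
        raise ValueError("rank-deficient design")  # pragma: no cover

    beta = np.zeros(X.shape[1])
    loglik, grad, info = _efron_quantities(time, event, X, beta, ties)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol_score:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"singular information matrix at iteration {it}"
            ) from exc
        # step-halving safeguards against overshooting
        for _ in range(30):
            new_beta = beta + step
            new_ll, new_grad, new_info = _efron_quantities(
                time, event, X, new_beta, ties
            )
            if np.isfinite(new_ll) and new_ll >= loglik - 1e-12:
                break
            step = step / 2.0
        rel_change = abs(new_ll - loglik) / max(abs(loglik), 1.0)
        beta, grad, info = new_beta, new_grad, new_info
        prev_ll, loglik = loglik, new_ll
        if rel_change < tol_loglik:
            converged = True
            break
    if not converged and np.max(np.abs(grad)) < tol_score:
        converged = True
    if not converged:
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations "
            f"(max |score| = {np.max(np.abs(grad)):.3g}, loglik = {loglik:.6g})"
        )

    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    return CoxFit(
        model_name=model_name,
        names=names,
        beta=beta,
        se=se,
        loglik=float(loglik),
        converged=converged,
        n_iter=it,
        n=len(time),
        n_events=n_events,
        ties=ties,
    )


def hazard_ratio_ci(
    beta: float, se: float, level: float = 0.95
) -> tuple[float, float, float]:
    """(HR, lower, upper): HR = exp(beta), bounds exp(beta -/+ z * se)."""
    if se < 0:
        raise ValueError("standard error must be >= 0")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se))


def records_from_cohort(
    cohort: pd.DataFrame, cluster_label: np.ndarray | pd.Series | str
) -> pd.DataFrame:
    """Survival records: cohort covariates plus a ``cluster_label`` column.

    ``cluster_label`` may be an array of labels or the name of a cohort
    column (e.g. ``"true_cluster"``) to copy.
    """
    df = cohort.copy()
    if isinstance(cluster_label, str):
        labels = df[cluster_label].to_numpy(object)
    else:
        labels = np.asarray(cluster_label, object)
    if len(labels) != len(df):
        raise ValueError("cluster_label length mismatch")
    df["cluster_label"] = labels
    return df


def nested_models(
    records: pd.DataFrame,
    collapse_ses: bool = False,
    ties: str = "efron",
    models: Sequence[str] = ("crude", "model1", "model2", "model3"),
) -> dict[str, CoxFit]:
    """Fit the four nested adjustment models on a shared record set."""
    records = records.copy()
    if "cluster_label" not in records.columns:
        raise ValueError("missing covariate column: 'cluster_label'")
    if collapse_ses and "ses" in records.columns:
        records["ses"] = np.where(
            records["ses"].to_numpy(object) == "low", "low", "not-low"
        )
    fits: dict[str, CoxFit] = {}
    for name in models:
        if name not in MODEL_COVARIATES:
            raise ValueError(f"unknown model {name!r}")
        covs = ["cluster_label"] + list(MODEL_COVARIATES[name])
        missing = [c for c in covs if c not in records.columns]
        if missing:
            raise ValueError(f"model {name!r}: missing covariate {missing[0]!r}")
        local = records
        if collapse_ses and "ses" in covs:
            # coded against the collapsed level set
            local = records.rename(columns={"ses": "ses_collapsed"})
            covs = ["ses_collapsed" if c == "ses" else c for c in covs]
        fits[name] = cox_fit(local, covs, ties=ties, model_name=name)
    return fits
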