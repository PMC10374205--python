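"""End-to-end orchestration: simulate -> cluster -> label -> survival -> report.

Every stage reads and writes plain delimited text or JSON, so intermediates
are inspectable and each stage can be re-run from saved outputs (the MCMC
stage is the slow one and is cacheable).  Reports carry the seed and library
versions for reproducibility.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, defaults
from .config import PipelineConfig, config_to_dict
from .cohort import generate_cohort
from .cox import nested_models, records_from_cohort
from .dpm import DPMPosterior, FFQMatrix, fit_dpm
from .labeling import ClusterAssignment, assign_labels
from .stats import incidence_proportion

log = logging.getLogger("dietclust")

__all__ = ["RunReport", "run_pipeline", "load_cohort",
           "save_posterior", "load_posterior"]

REQUIRED_COLUMNS = list(defaults.FOOD_GROUPS) + ["time", "event"]


def load_cohort(path: str | Path) -> pd.DataFrame:
    """Load and validate a cohort table; unknown columns are preserved.

    Validation errors name the offending row (first) and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    for g in defaults.FOOD_GROUPS:
        vals = df[g].to_numpy(float)
        bad = np.where(~np.isfinite(vals) | (vals < 0))[0]
        if len(bad):
            raise ValueError(
                f"negative or non-finite frequency in column {g!r}, row {bad[0]}"
            )
    t = df["time"].to_numpy(float)
    bad = np.where(~np.isfinite(t) | (t <= 0))[0]
    if len(bad):
        raise ValueError(f"nonpositive follow-up time in row {bad[0]}")
    ev = df["event"].to_numpy()
    bad = np.where(~np.isin(ev, (0, 1)))[0]
    if len(bad):
        raise ValueError(f"event indicator not 0/1 in row {bad[0]}")
    return df


def save_posterior(posterior: DPMPosterior, out_dir: str | Path) -> None:
    """Posterior summary as JSON plus the allocation-probability matrix as CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {
        "group_names": list(posterior.group_names),
        "weights": posterior.weights.tolist(),
        "means": posterior.means.tolist(),
        "variances": posterior.variances.tolist(),
        "occupancy": posterior.occupancy.tolist(),
        "occupied_count": posterior.occupied_count,
        "column_means": posterior.column_means.tolist(),
        "column_sds": posterior.column_sds.tolist(),
        "alpha_mean": float(np.mean(posterior.alpha_trace)),
        "occupied_trace_counts": {
            str(k): int(v)
            for k, v in zip(*np.unique(posterior.occupied_trace, return_counts=True))
        },
    }
    (out / "posterior.json").write_text(json.dumps(summary, indent=2))
    K = posterior.allocation_probs.shape[1]
    pd.DataFrame(
        posterior.allocation_probs, columns=[f"comp_{k}" for k in range(K)]
    ).to_csv(out / "allocation_probs.csv", index=False)


def load_posterior(out_dir: str | Path) -> DPMPosterior:
    """Rebuild a (summary-level) posterior from saved stage outputs."""
    out = Path(out_dir)
    summary = json.loads((out / "posterior.json").read_text())
    probs = pd.read_csv(out / "allocation_probs.csv").to_numpy(float)
    means = np.asarray(summary["means"], float)
    occupied_trace = np.concatenate(
        [
            np.full(c, int(k))
            for k, c in summary["occupied_trace_counts"].items()
        ]
    )
    return DPMPosterior(
        weights=np.asarray(summary["weights"], float),
        means=means,
        variances=np.asarray(summary["variances"], float),
        means_fit=means,
        variances_fit=np.asarray(summary["variances"], float),
        allocation_probs=probs,
        occupancy=np.asarray(summary["occupancy"], float),
        occupied_count=int(summary["occupied_count"]),
        occupied_trace=occupied_trace,
        alpha_trace=np.asarray([summary["alpha_mean"]]),
        mean_trace=means[None, :, :],
        occupancy_trace=np.asarray(summary["occupancy"], float)[None, :],
        group_names=tuple(summary["group_names"]),
        column_means=np.asarray(summary["column_means"], float),
        column_sds=np.asarray(summary["column_sds"], float),
    )


@dataclass
class RunReport:
    """Machine-readable pipeline report (Table 2/3/4-style payloads)."""

    seed: int
    n: int
    cluster_sizes: dict
    food_profiles: dict       # label -> {group: (mean, sd)}
    covariate_profiles: dict  # label -> {covariate: summary}
    events: dict              # label -> {"events": int, "censored": int, "pct": float}
    hr_table: dict            # model -> {contrast: {HR, ci, p}}
    occupied_count: int
    versions: dict

    def to_dict(self) -> dict:
        return config_to_dict(self)

    def to_text(self) -> str:
        lines = [
            f"dietclust run report (seed={self.seed}, n={self.n})",
            f"occupied components (modal): {self.occupied_count}",
            "",
            "Cluster sizes:",
        ]
        for lab, sz in self.cluster_sizes.items():
            ev = self.events[lab]
            lines.append(
                f"  {lab:>9}: n={sz}, events={ev['events']} ({ev['pct']}%), "
                f"censored={ev['censored']}"
            )
        lines.append("")
        lines.append("Food-group profiles (mean +/- SD, times/week):")
        groups = list(next(iter(self.food_profiles.values())).keys())
        header = "  group".ljust(18) + "".join(f"{lab:>18}" for lab in self.food_profiles)
        lines.append(header)
        for g in groups:
            row = f"  {g:<16}"
            for lab in self.food_profiles:
                m, s = self.food_profiles[lab][g]
                row += f"{m:>9.2f} ± {s:<5.2f}"
            lines.append(row)
        lines.append("")
        lines.append("Hazard ratios vs healthy cluster (95% CI):")
        for model, rows in self.hr_table.items():
            lines.append(f"  {model}:")
            for contrast, cell in rows.items():
                lines.append(
                    f"    {contrast:>9}: HR {cell['hr']:.3f} "
                    f"({cell['ci_lower']:.3f}, {cell['ci_upper']:.3f}), "
                    f"p={cell['p']:.3f}"
                )
        return "\n".join(lines)


def _label_order(labels: list[str]) -> list[str]:
    order = {"healthy": 0, "unhealthy": 1, "mixed": 2}
    return sorted(labels, key=lambda s: order.get(s, 99))


def run_pipeline(
    config: PipelineConfig,
    cohort: pd.DataFrame | None = None,
    output_dir: str | Path | None = None,
) -> RunReport:
    """Execute all stages on a generated (or supplied) cohort and write
    cohort, assignment, posterior and report files under ``output_dir``."""
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    try:
        if cohort is None:
            log.info("simulate: generating cohort (n=%d, seed=%d)",
                     config.generator.n_participants, config.generator.seed)
            cohort = generate_cohort(config.generator, out / "cohort.csv")
        else:
            cohort.to_csv(out / "cohort.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    if len(cohort) < 100:
        warnings.warn(
            f"cohort of n={len(cohort)} is small; cluster estimates will be noisy",
            RuntimeWarning,
            stacklevel=2,
        )

    try:
        log.info("cluster: fitting DPM (K=%d, %d+%d iterations)",
                 config.dpm.truncation_K, config.dpm.n_burnin, config.dpm.n_samples)
        ffq = FFQMatrix.from_dataframe(cohort)
        posterior = fit_dpm(ffq, config.dpm)
        save_posterior(posterior, out)
    except Exception as exc:
        raise RuntimeError(f"stage 'cluster' failed: {exc}") from exc

    try:
        assignment = assign_labels(
            posterior, config.healthy_groups, config.unhealthy_groups
        )
        pd.DataFrame(
            {
                "id": cohort["id"] if "id" in cohort else np.arange(1, len(cohort) + 1),
                "component": assignment.component_index,
                "label": assignment.label,
                "map_probability": assignment.map_probability,
            }
        ).to_csv(out / "assignments.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'label' failed: {exc}") from exc

    labels = assignment.label
    present = _label_order(list(pd.unique(labels)))
    sizes = {lab: int((labels == lab).sum()) for lab in present}
    small = [lab for lab, sz in sizes.items() if sz < 30]
    if small:
        warnings.warn(
            f"small cluster(s) {small}; hazard ratios will be unstable",
            RuntimeWarning,
            stacklevel=2,
        )

    try:
        records = records_from_cohort(cohort, labels)
        fits = nested_models(
            records, collapse_ses=config.collapse_ses, models=config.models
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'survival' failed: {exc}") from exc

    try:
        report = build_report(config, cohort, assignment, posterior, fits)
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
        (out / "report.txt").write_text(report.to_text() + "\n")
    except Exception as exc:
        raise RuntimeError(f"stage 'report' failed: {exc}") from exc
    return report


def build_report(
    config: PipelineConfig,
    cohort: pd.DataFrame,
    assignment: ClusterAssignment,
    posterior: DPMPosterior,
    fits: dict,
) -> RunReport:
    labels = assignment.label
    present = _label_order(list(pd.unique(labels)))
    sizes = {lab: int((labels == lab).sum()) for lab in present}

    food_profiles = {}
    covariate_profiles = {}
    events = {}
    cont_covs = ["age", "whr", "bmi", "physical_activity"]
    for lab in present:
        sub = cohort.loc[np.asarray(labels) == lab]
        food_profiles[lab] = {
            g: (float(sub[g].mean()), float(sub[g].std(ddof=1)) if len(sub) > 1 else 0.0)
            for g in defaults.FOOD_GROUPS
        }
        prof = {}
        for c in cont_covs:
            if c in sub:
                prof[c] = (float(sub[c].mean()),
                           float(sub[c].std(ddof=1)) if len(sub) > 1 else 0.0)
        for c in ("hypertension", "dyslipidemia", "general_obesity",
                  "abdominal_obesity", "family_history"):
            if c in sub and len(sub):
                prof[c] = incidence_proportion(int(sub[c].sum()), len(sub))
        covariate_profiles[lab] = prof
        n_ev = int(sub["event"].sum())
        events[lab] = {
            "events": n_ev,
            "censored": int(len(sub) - n_ev),
            "pct": incidence_proportion(n_ev, len(sub)) if len(sub) else 0.0,
        }

    hr_table = {}
    for model, fit in fits.items():
        rows = {}
        lo, hi = fit.ci()
        for i, name in enumerate(fit.names):
            if not name.startswith("cluster_label_"):
                continue
            rows[name.removeprefix("cluster_label_")] = {
                "hr": float(fit.hr[i]),
                "ci_lower": float(lo[i]),
                "ci_upper": float(hi[i]),
                "p": float(fit.p_values[i]),
                "coef": float(fit.beta[i]),
                "se": float(fit.se[i]),
            }
        hr_table[model] = rows

    import scipy

    return RunReport(
        seed=config.generator.seed,
        n=len(cohort),
        cluster_sizes=sizes,
        food_profiles=food_profiles,
        covariate_profiles=covariate_profiles,
        events=events,
        hr_table=hr_table,
        occupied_count=posterior.occupied_count,
        versions={
            "dietclust": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    )
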