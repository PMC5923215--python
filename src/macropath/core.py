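"""Phylogenetic path analysis: evaluate, rank, estimate and average models.

The driver tests every model's d-separation claims with phylogenetic
regressions, combines the claim p-values into Fisher's C statistic,

    C = -2 Σ ln p_i ,

refers C to a chi-square with 2k degrees of freedom (k = number of claims;
a significant C rejects the model), and ranks models by the small-sample
C-statistic information criterion

    CICc = C + 2 q n / (n - 1 - q) ,

with q = edges + vertices.  Relative likelihoods l = exp(-ΔCICc/2) and
weights w = l / Σl support model averaging, either *conditional* (a path is
averaged only over models that contain it, weights renormalized per path) or
*full* (absent paths count as zero, shrinking uncertain paths toward zero).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .dag import (
    CausalDAG,
    DSepStatement,
    ModelSet,
    consensus_order,
    dedupe_statements,
    parameter_count,
)
from .engines import (
    RegressionFit,
    detect_variable_kinds,
    fit_pgls,
    fit_phylo_logistic,
    standardize_continuous,
)
from .trees import Phylogeny, align_tip_data, phylo_covariance

logger = logging.getLogger("macropath")

__all__ = [
    "PPAResult",
    "ComparisonRow",
    "FittedDAG",
    "phylo_path",
    "c_statistic",
    "c_pvalue",
    "cicc",
    "compare_models",
    "est_dag",
    "best",
    "choice",
    "average",
]

DEFAULT_SEED = 20180425


def c_statistic(ps=None, log_ps=None) -> float:
    """Fisher's C = -2 Σ ln p over a basis set's p-values.

    Pass ``log_ps`` (natural logs) for an underflow-safe path; tiny p-values
    then contribute their log-survival value instead of -2·ln(0).
    """
    if log_ps is None:
        if ps is None:
            raise ValueError("provide ps or log_ps")
        ps = np.asarray(ps, dtype=float)
        if np.any(ps <= 0) or np.any(ps > 1):
            raise ValueError("p-values must lie in (0, 1]; pass log_ps for tiny p")
        log_ps = np.log(ps)
    log_ps = np.asarray(log_ps, dtype=float)
    return float(-2.0 * np.sum(log_ps))


def c_pvalue(C: float, k: int) -> float:
    """Upper-tail chi-square probability of C at 2k degrees of freedom."""
    if C < 0:
        raise ValueError("C statistic must be non-negative")
    if k == 0:
        return 1.0
    return float(stats.chi2.sf(C, 2 * k))


def cicc(C: float, q: int, n: int) -> float:
    """Small-sample C-statistic information criterion C + 2qn/(n-1-q)."""
    if n - 1 - q <= 0:
        raise ValueError(f"sample too small for q parameters (n={n}, q={q})")
    return float(C + 2.0 * q * n / (n - 1 - q))


@dataclass
class ComparisonRow:
    model: str
    k: int
    q: int
    C: float
    p: float
    CICc: float
    delta: float = math.nan
    l: float = math.nan
    w: float = math.nan


def compare_models(rows: list[ComparisonRow]) -> list[ComparisonRow]:
    """Fill ΔCICc, relative likelihoods and weights; sort ascending by CICc.

    Ties in CICc are broken by model name for deterministic output.
    """
    if not rows:
        raise ValueError("no models to compare")
    rows = sorted(rows, key=lambda r: (r.CICc, r.model))
    base = rows[0].CICc
    for r in rows:
        r.delta = r.CICc - base
        r.l = math.exp(-r.delta / 2.0)
    total = sum(r.l for r in rows)
    for r in rows:
        r.w = r.l / total
    return rows


@dataclass
class FittedDAG:
    """A causal model whose paths carry standardized coefficients."""

    dag: CausalDAG | None
    coefficients: dict[tuple[str, str], float]
    std_errors: dict[tuple[str, str], float]
    ci_lower: dict[tuple[str, str], float] = field(default_factory=dict)
    ci_upper: dict[tuple[str, str], float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for edge, beta in self.coefficients.items():
            row = {
                "from": edge[0],
                "to": edge[1],
                "coef": beta,
                "se": self.std_errors.get(edge, math.nan),
            }
            if edge in self.ci_lower:
                row["lower"] = self.ci_lower[edge]
                row["upper"] = self.ci_upper[edge]
            rows.append(row)
        return pd.DataFrame(rows, columns=["from", "to", "coef", "se"]
                            + (["lower", "upper"] if self.ci_lower else []))


@dataclass
class PPAResult:
    """Everything `phylo_path` computed, plus the settings used downstream."""

    model_set: ModelSet
    data: pd.DataFrame  # aligned, continuous columns standardized
    tree: Phylogeny
    kinds: dict[str, str]
    order: list[str]
    statements: dict[str, list[DSepStatement]]
    fits: dict[tuple[str, tuple[str, ...]], RegressionFit]
    total_statements: int
    rows: list[ComparisonRow]
    settings: dict

    @property
    def n(self) -> int:
        return len(self.data)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "model": r.model, "k": r.k, "q": r.q, "C": r.C, "p": r.p,
                    "CICc": r.CICc, "delta_CICc": r.delta, "l": r.l, "w": r.w,
                }
                for r in self.rows
            ]
        )

    def d_sep(self, model: str) -> pd.DataFrame:
        rows = []
        for stmt in self.statements[model]:
            fit = self.fits[stmt.canonical_key]
            rows.append(
                {"d_sep": stmt.render(), "p": fit.focal_p,
                 "phylo_par": fit.phylo_par}
            )
        return pd.DataFrame(rows, columns=["d_sep", "p", "phylo_par"])

    def banner(self) -> str:
        cont = [v for v in self.order if self.kinds[v] == "continuous"]
        binary = [v for v in self.order if self.kinds[v] == "binary"]
        uniq = len(self.fits)
        return "\n".join(
            [
                "A phylogenetic path analysis, on the variables:",
                f"Continuous: {' '.join(cont)}",
                f"Binary: {' '.join(binary)}",
                "",
                f"Evaluated for these models: {' '.join(self.model_set.names)}",
                "",
                f"Containing {self.total_statements} phylogenetic regressions, "
                f"of which {uniq} unique",
            ]
        )

    def to_json(self) -> str:
        payload = {
            "settings": self.settings,
            "n": self.n,
            "variables": {v: self.kinds[v] for v in self.order},
            "summary": self.summary().to_dict(orient="records"),
            "d_sep": {
                name: self.d_sep(name).to_dict(orient="records")
                for name in self.model_set.names
            },
        }
        return json.dumps(payload, indent=2)


def _fit_statement(
    stmt: DSepStatement,
    data: pd.DataFrame,
    V,
    kinds: dict[str, str],
    evo_model: str,
) -> RegressionFit:
    try:
        if kinds[stmt.dependent] == "binary":
            return fit_phylo_logistic(
                stmt.dependent, stmt.terms, data, V, kinds=kinds, focal=stmt.focal
            )
        return fit_pgls(
            stmt.dependent, stmt.terms, data, V, evo_model=evo_model,
            kinds=kinds, focal=stmt.focal,
        )
    except Exception as exc:
        raise type(exc)(f"while testing {stmt.render()!r}: {exc}") from exc


def phylo_path(
    ms: ModelSet,
    data: pd.DataFrame,
    tree: Phylogeny,
    evo_model: str = "lambda",
    seed: int = DEFAULT_SEED,
) -> PPAResult:
    """Run the full phylogenetic path analysis on a model set.

    Aligns data and tree, standardizes continuous traits, derives every
    model's basis set under the consensus causal order, fits each unique
    regression exactly once (shared across models), and assembles the
    C / CICc comparison table.
    """
    missing = [v for v in ms.variables if v not in data.columns]
    if missing:
        raise ValueError(f"trait table lacks model variables: {missing}")
    tree, data = align_tip_data(tree, data)
    data = data[list(ms.variables)]
    kinds = detect_variable_kinds(data)
    data = standardize_continuous(data, kinds)
    V = phylo_covariance(tree)
    order = consensus_order(ms)

    total, unique, per_model = dedupe_statements(ms)
    fits = {
        key: _fit_statement(stmt, data, V, kinds, evo_model)
        for key, stmt in unique.items()
    }

    n = len(data)
    rows = []
    for name, statements in per_model.items():
        k = len(statements)
        log_ps = [fits[s.canonical_key].focal_log_p for s in statements]
        C = c_statistic(log_ps=log_ps) if statements else 0.0
        q = parameter_count(ms.models[name])
        rows.append(
            ComparisonRow(
                model=name, k=k, q=q, C=C, p=c_pvalue(C, k), CICc=cicc(C, q, n)
            )
        )
    rows = compare_models(rows)
    settings = {"evo_model": evo_model, "seed": seed, "n": n}
    return PPAResult(
        model_set=ms, data=data, tree=tree, kinds=kinds, order=order,
        statements=per_model, fits=fits, total_statements=total, rows=rows,
        settings=settings,
    )


def est_dag(
    dag: CausalDAG,
    data: pd.DataFrame,
    V,
    kinds: dict[str, str],
    evo_model: str = "lambda",
    boot: int = 0,
    seed: int = DEFAULT_SEED,
) -> FittedDAG:
    """Estimate standardized path coefficients of one causal model.

    One regression per vertex with parents: the child on all its parents
    (PGLS for continuous children, phylogenetic logistic for binary ones).
    ``boot`` > 0 adds percentile confidence intervals from a parametric
    bootstrap that resimulates residuals from the fitted evolution model.
    """
    coefficients: dict[tuple[str, str], float] = {}
    std_errors: dict[tuple[str, str], float] = {}
    ci_lower: dict[tuple[str, str], float] = {}
    ci_upper: dict[tuple[str, str], float] = {}
    rng = np.random.default_rng(seed)
    for child in dag.vertices:
        parents = dag.parents(child)
        if not parents:
            continue
        if kinds[child] == "binary":
            fit = fit_phylo_logistic(child, tuple(parents), data, V, kinds=kinds)
        else:
            fit = fit_pgls(
                child, tuple(parents), data, V, evo_model=evo_model, kinds=kinds
            )
        for parent in parents:
            coefficients[(parent, child)] = float(fit.coefficients[parent])
            std_errors[(parent, child)] = float(fit.std_errors[parent])
        if boot > 0:
            draws = _parametric_bootstrap(fit, parents, data, V, kinds,
                                          evo_model, boot, rng)
            for parent in parents:
                lo, hi = np.percentile(draws[parent], [2.5, 97.5])
                ci_lower[(parent, child)] = float(lo)
                ci_upper[(parent, child)] = float(hi)
    return FittedDAG(dag, coefficients, std_errors, ci_lower, ci_upper)


def _parametric_bootstrap(
    fit: RegressionFit,
    parents: list[str],
    data: pd.DataFrame,
    V,
    kinds: dict[str, str],
    evo_model: str,
    boot: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Resimulate the child under the fitted model; refit per replicate."""
    from .engines import _design_matrix, _lambda_matrix  # shared internals

    child = fit.dependent
    X = _design_matrix(fit.terms, data, kinds)
    eta = X @ fit.coefficients.to_numpy()
    draws: dict[str, list[float]] = {p: [] for p in parents}
    boot_data = data.copy()
    if fit.dependent_kind == "binary":
        mu = 1.0 / (1.0 + np.exp(-eta))
        for _ in range(boot):
            boot_data[child] = np.where(rng.random(len(mu)) < mu, "b1", "b0")
            refit = fit_phylo_logistic(child, fit.terms, boot_data, V, kinds=kinds)
            for p in parents:
                draws[p].append(float(refit.coefficients[p]))
    else:
        n = len(eta)
        Vlam = _lambda_matrix(V.matrix, fit.phylo_par)
        resid_df = n - X.shape[1]
        # sigma^2 on the standardized scale, recovered from the fit SEs
        Xt = linalg.cholesky(Vlam, lower=True)
        Xw = linalg.solve_triangular(Xt, X, lower=True)
        yw = linalg.solve_triangular(
            Xt, data[child].to_numpy(dtype=float), lower=True
        )
        rss = float(np.sum((yw - Xw @ np.linalg.lstsq(Xw, yw, rcond=None)[0]) ** 2))
        sigma2 = rss / resid_df
        L = linalg.cholesky(sigma2 * Vlam, lower=True)
        for _ in range(boot):
            boot_data[child] = eta + L @ rng.standard_normal(n)
            refit = fit_pgls(child, fit.terms, boot_data, V,
                             evo_model=evo_model, kinds=kinds)
            for p in parents:
                draws[p].append(float(refit.coefficients[p]))
    return {p: np.asarray(v) for p, v in draws.items()}


def best(result: PPAResult, boot: int = 0, seed: int | None = None) -> FittedDAG:
    """Estimate the top-ranked (lowest CICc) model's path coefficients."""
    return choice(result, result.rows[0].model, boot=boot, seed=seed)


def choice(
    result: PPAResult, name: str, boot: int = 0, seed: int | None = None
) -> FittedDAG:
    """Estimate the paths of a named model from the analysis."""
    if name not in result.model_set.models:
        raise KeyError(
            f"unknown model {name!r}; choose from {result.model_set.names}"
        )
    V = phylo_covariance(result.tree)
    return est_dag(
        result.model_set.models[name],
        result.data,
        V,
        result.kinds,
        evo_model=result.settings["evo_model"],
        boot=boot,
        seed=result.settings["seed"] if seed is None else seed,
    )


def average(
    result: PPAResult,
    avg_method: str = "conditional",
    cut_off: float = 2.0,
    boot: int = 0,
) -> FittedDAG:
    """CICc-weighted average of the path coefficients of the top models.

    Models with ΔCICc ≤ ``cut_off`` are included (``cut_off=inf`` averages
    all); their weights are renormalized.  ``conditional``: a path is
    averaged only over the included models that contain it, with weights
    renormalized per path.  ``full``: missing paths count as zero, shrinking
    paths that are absent from some models toward zero.  Standard errors are
    averaged with the same weights.
    """
    if avg_method not in ("conditional", "full"):
        raise ValueError("avg_method must be 'conditional' or 'full'")
    included = [r for r in result.rows if r.delta <= cut_off]
    if not included:
        raise ValueError(f"no model within cut_off={cut_off} CICc")
    for r in included:
        if r.p < 0.05:
            logger.warning(
                "model %r has a significant C statistic (p=%.3g); averaging "
                "over unsupported models is discouraged", r.model, r.p,
            )
    wsum = sum(r.w for r in included)
    weights = {r.model: r.w / wsum for r in included}
    fitted = {
        r.model: choice(result, r.model, boot=boot) for r in included
    }
    edges = sorted({e for f in fitted.values() for e in f.coefficients})
    coefficients: dict[tuple[str, str], float] = {}
    std_errors: dict[tuple[str, str], float] = {}
    for edge in edges:
        carriers = [m for m in weights if edge in fitted[m].coefficients]
        if avg_method == "conditional":
            wnorm = sum(weights[m] for m in carriers)
            coefficients[edge] = sum(
                weights[m] / wnorm * fitted[m].coefficients[edge] for m in carriers
            )
            std_errors[edge] = sum(
                weights[m] / wnorm * fitted[m].std_errors[edge] for m in carriers
            )
        else:
            coefficients[edge] = sum(
                weights[m] * fitted[m].coefficients[edge] for m in carriers
            )
            std_errors[edge] = sum(
                weights[m] * fitted[m].std_errors[edge] for m in carriers
            )
    return FittedDAG(None, coefficients, std_errors)
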