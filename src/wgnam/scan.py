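"""The WGNAM forward-selection genome scan.

Each iteration tests whether the whole-genome founder-probability component
still carries variance (mixture-chi2 LRT of the polygenic-plus-selected-QTL
model against the same model with the common marker kernel added).  While the
test is significant, the marker with the largest outlier statistic

    t2_j = sum_l a~_jl^2 / sum_l var(a~_jl)

is moved out of the common kernel into its own variance component, and the
process repeats.  No multiple-testing correction is applied: the common
component is a single test per iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import (
    FitError,
    GroupTerm,
    MarkerBlup,
    MixedModelFit,
    MixedModelSpec,
    RandomTerm,
    VarianceComponents,
    fit_reml,
    lrt_variance_component,
)
from .probs import FounderProbabilities
from .types import AnalysisConfig, DataError, GeneticMap, PhenotypeTable

T2_DENOM_TOL = 1e-12

POLYGENIC = "polygenic"
KERNEL = "kernel"


@dataclass(frozen=True)
class OutlierScan:
    """Outlier statistics for every marker outside the selected set."""

    marker_ids: tuple[str, ...]
    t2: np.ndarray
    argmax_marker: str
    argmax_lg: str
    argmax_pos: float


@dataclass(frozen=True)
class IterationRecord:
    iteration: int
    loglik_reduced: float
    loglik_complete: float
    likelihood_ratio: float
    p_value: float
    outlier_statistic: float | None
    marker_id: str | None
    linkage_group: str | None
    position: float | None


@dataclass
class ScanState:
    """Result of the forward selection: the ordered selected set S, the
    per-iteration records, and the final (selected-QTL only) model fit."""

    selected: list[str]
    iterations: list[IterationRecord]
    final_fit: MixedModelFit | None
    termination: str  # 'p_above_alpha' | 'max_iterations' | 'zero_variance'
    kernel_scale: float | None = None
    config: AnalysisConfig | None = None

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def outlier_statistic(blup: MarkerBlup) -> float:
    """Ratio of summed squared founder BLUPs to summed BLUP variances;
    zero for uninformative markers (vanishing denominator)."""
    denom = float(np.trace(blup.blup_variance))
    if denom < T2_DENOM_TOL:
        return 0.0
    return float(blup.effects @ blup.effects) / denom


def build_model_spec(phenotypes: PhenotypeTable,
                     line_ids: tuple[str, ...],
                     terms: list[RandomTerm],
                     config: AnalysisConfig) -> MixedModelSpec:
    """Assemble the design: intercept plus one fixed column per check entry,
    replicate handled per ``config.replicate_effect``, population entries
    mapped onto the genetic random effects."""
    df = phenotypes.records
    df = df[df["value"].notna()].reset_index(drop=True)
    if df.empty:
        raise DataError("no observed phenotype values")
    N = len(df)
    line_pos = {l: i for i, l in enumerate(line_ids)}

    line_index = np.full(N, -1, dtype=int)
    pop = df["entry_type"] == "population"
    unknown = sorted(set(df.loc[pop, "entry"]) - set(line_pos))
    if unknown:
        raise DataError(f"population entries without genotypes: {unknown[:5]}")
    line_index[pop.to_numpy()] = df.loc[pop, "entry"].map(line_pos).to_numpy()

    cols = [np.ones(N)]
    names = ["intercept"]
    for check in sorted(set(df.loc[~pop, "entry"])):
        cols.append((df["entry"] == check).to_numpy(dtype=float))
        names.append(f"check:{check}")

    group_terms: list[GroupTerm] = []
    if config.replicate_effect == "fixed":
        reps = sorted(df["replicate"].unique())
        for rep in reps[1:]:  # first level absorbed by the intercept
            cols.append((df["replicate"] == rep).to_numpy(dtype=float))
            names.append(f"rep:{rep}")
    elif config.replicate_effect == "random":
        codes = pd.Categorical(df["replicate"]).codes.astype(int)
        group_terms.append(GroupTerm(name="replicate", codes=codes))

    return MixedModelSpec(
        y=df["value"].to_numpy(dtype=float),
        X=np.column_stack(cols),
        line_index=line_index,
        n_lines=len(line_ids),
        terms=terms,
        group_terms=group_terms,
        fixed_names=names)


class _KernelTracker:
    """Incrementally maintains K = c * sum_{j not in S} Q_j Q_j'."""

    def __init__(self, probs: FounderProbabilities):
        self.probs = probs
        n_g = probs.n_lines
        Q = probs.p.reshape(n_g, -1)
        self.K0 = Q @ Q.T
        self.trace = float(np.trace(self.K0))
        if self.trace <= 0:
            raise DataError("founder-probability kernel has zero trace")
        self.n_g = n_g

    def exclude(self, marker_id: str) -> None:
        j = self.probs.marker_ids.index(marker_id)
        Qj = self.probs.marker_slab(j)
        self.K0 -= Qj @ Qj.T
        self.trace -= float(np.sum(Qj * Qj))

    @property
    def c(self) -> float:
        return self.n_g / self.trace

    def kernel_term(self) -> RandomTerm:
        return RandomTerm(name=KERNEL, kernel=self.c * self.K0)


def scan_outliers(fit_complete: MixedModelFit,
                  probs: FounderProbabilities,
                  selected: list[str],
                  gmap: GeneticMap,
                  kernel_scale: float) -> OutlierScan:
    """Outlier statistic for every marker outside S from one complete-model
    fit (a score-type computation: no per-marker refitting).

    Ties in the argmax resolve to the smallest genome order, which is the map
    order of the marker list.
    """
    sigma2 = kernel_scale * fit_complete.varcomps.components[KERNEL]
    n_g, n_m, n_f = probs.p.shape
    Qall = probs.p.reshape(n_g, n_m * n_f)
    a_all = sigma2 * (Qall.T @ fit_complete.q_V).reshape(n_m, n_f)
    TQ = fit_complete.T_V @ Qall
    var_diag = sigma2**2 * np.einsum("ij,ij->j", Qall, TQ).reshape(n_m, n_f)

    num = np.sum(a_all**2, axis=1)
    den = np.sum(var_diag, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t2 = np.where(den < T2_DENOM_TOL, 0.0, num / np.maximum(den, T2_DENOM_TOL))

    sel = set(selected)
    keep = np.array([m not in sel for m in probs.marker_ids])
    marker_ids = tuple(m for m in probs.marker_ids if m not in sel)
    t2_kept = t2[keep]
    if not np.all(np.isfinite(t2_kept)) or np.any(t2_kept < 0):
        raise FitError("outlier statistics are not finite and non-negative")
    best = int(np.argmax(t2_kept))  # first max = smallest genome order
    best_marker = marker_ids[best]
    gi = gmap.marker_index()[best_marker]
    return OutlierScan(marker_ids=marker_ids, t2=t2_kept,
                       argmax_marker=best_marker,
                       argmax_lg=gmap.linkage_groups[gi],
                       argmax_pos=float(gmap.positions[gi]))


def _selected_terms(selected: list[str], probs: FounderProbabilities) -> list[RandomTerm]:
    terms = []
    for m in selected:
        j = probs.marker_ids.index(m)
        terms.append(RandomTerm(name=m, factor=probs.marker_slab(j).copy()))
    return terms


def wgnam_select(phenotypes: PhenotypeTable,
                 probs: FounderProbabilities,
                 gmap: GeneticMap,
                 config: AnalysisConfig | None = None) -> ScanState:
    """Run the full forward-selection genome scan.

    Iteration 1 compares the polygenic-only model against polygenic plus the
    whole-genome kernel.  While the mixture-chi2 p-value is at most
    ``config.alpha``, the argmax-t2 marker is moved into S with its own
    variance component and the pair of models is refitted.  Terminates on
    non-significance, a zero whole-genome variance, or ``max_iterations``.
    """
    config = config or AnalysisConfig()
    tracker = _KernelTracker(probs)
    selected: list[str] = []
    records: list[IterationRecord] = []
    warm_r: VarianceComponents | None = None
    warm_c: VarianceComponents | None = None
    termination = "max_iterations"
    final_fit: MixedModelFit | None = None

    for it in range(1, config.max_iterations + 1):
        sel_terms = _selected_terms(selected, probs)
        reduced_spec = build_model_spec(
            phenotypes, probs.line_ids, [RandomTerm(POLYGENIC)] + sel_terms, config)
        fit_r = fit_reml(reduced_spec, start=warm_r,
                         loglik_tol=config.reml_loglik_tol,
                         max_iter=config.reml_max_iter)
        complete_spec = build_model_spec(
            phenotypes, probs.line_ids,
            [RandomTerm(POLYGENIC), tracker.kernel_term()] + sel_terms, config)
        start_c = warm_c or VarianceComponents(
            fit_r.sigma2_e, {**fit_r.varcomps.components, KERNEL: 0.05 * fit_r.sigma2_e})
        fit_c = fit_reml(complete_spec, start=start_c,
                         loglik_tol=config.reml_loglik_tol,
                         max_iter=config.reml_max_iter)
        lam, p = lrt_variance_component(fit_r, fit_c)
        sigma2_kernel = fit_c.varcomps.components[KERNEL]

        if p > config.alpha or sigma2_kernel == 0.0:
            records.append(IterationRecord(
                iteration=it, loglik_reduced=fit_r.loglik,
                loglik_complete=fit_c.loglik, likelihood_ratio=lam, p_value=p,
                outlier_statistic=None, marker_id=None, linkage_group=None,
                position=None))
            final_fit = fit_r
            termination = "zero_variance" if sigma2_kernel == 0.0 else "p_above_alpha"
            break

        scan = scan_outliers(fit_c, probs, selected, gmap, tracker.c)
        best = scan.argmax_marker
        t2_best = float(scan.t2[scan.marker_ids.index(best)])
        records.append(IterationRecord(
            iteration=it, loglik_reduced=fit_r.loglik, loglik_complete=fit_c.loglik,
            likelihood_ratio=lam, p_value=p, outlier_statistic=t2_best,
            marker_id=best, linkage_group=scan.argmax_lg, position=scan.argmax_pos))
        selected.append(best)
        tracker.exclude(best)
        # warm starts: the new marker inherits a share of the kernel variance
        sigma2_new = tracker.c * sigma2_kernel
        warm_r = VarianceComponents(
            fit_c.sigma2_e, {**{k: v for k, v in fit_c.varcomps.components.items()
                                if k != KERNEL}, best: max(sigma2_new, 1e-6)})
        warm_c = VarianceComponents(
            fit_c.sigma2_e, {**fit_c.varcomps.components, best: max(sigma2_new, 1e-6)})
    else:
        # iteration cap reached with the last marker still unabsorbed into a
        # reduced fit: fit the final selected-QTL model once more
        termination = "max_iterations"
        spec = build_model_spec(
            phenotypes, probs.line_ids,
            [RandomTerm(POLYGENIC)] + _selected_terms(selected, probs), config)
        final_fit = fit_reml(spec, start=warm_r, max_iter=config.reml_max_iter)

    return ScanState(selected=selected, iterations=records, final_fit=final_fit,
                     termination=termination, kernel_scale=tracker.c, config=config)


def refit_final_model(phenotypes: PhenotypeTable,
                      probs: FounderProbabilities,
                      state: ScanState,
                      config: AnalysisConfig | None = None) -> MixedModelFit:
    """Fit the final model (polygenic + one variance component per selected
    QTL, no common kernel) from scratch; equals the last reduced fit."""
    config = config or state.config or AnalysisConfig()
    spec = build_model_spec(
        phenotypes, probs.line_ids,
        [RandomTerm(POLYGENIC)] + _selected_terms(state.selected, probs), config)
    return fit_reml(spec, max_iter=config.reml_max_iter)


def iteration_table(state: ScanState) -> pd.DataFrame:
    """One row per iteration: model log-likelihoods, LRT, p-value, outlier
    statistic and identified position (empty on the final iteration)."""
    rows = []
    for rec in state.iterations:
        rows.append({
            "iteration": rec.iteration,
            "loglik_reduced": rec.loglik_reduced,
            "loglik_complete": rec.loglik_complete,
            "likelihood_ratio": rec.likelihood_ratio,
            "p_value": rec.p_value,
            "outlier_statistic": rec.outlier_statistic,
            "marker": rec.marker_id,
            "linkage_group": rec.linkage_group,
            "distance_cm": rec.position,
        })
    return pd.DataFrame(rows)
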