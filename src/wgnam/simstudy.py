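"""Type-I-error and power studies for the genome scan.

Each replicate regenerates the full NAM bundle (map, founders, RILs,
phenotypes), computes founder probabilities from the marker data, runs the
forward-selection scan at the nominal alpha, and classifies every selected
marker as either a detection of a true QTL (same linkage group, within the
detection window) or a false positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .assess import assess_final_model
from .probs import FounderProbabilities, compute_founder_probabilities
from .scan import ScanState, wgnam_select
from .simulate import (
    QTLSpec,
    SimulatedBundle,
    preset_scenario,
)
from .types import AnalysisConfig, GeneticMap


@dataclass(frozen=True)
class DetectionOutcome:
    """Classification of one simulation's selections against the truth."""

    sim_index: int
    selected: tuple[str, ...]
    selected_positions: tuple[tuple[str, float], ...]  # (lg, cM)
    detected: dict[str, bool]            # true QTL marker -> detected?
    distances: dict[str, float]          # nearest selected distance (detections)
    assignments: dict[str, str | None]   # selected marker -> true QTL or None
    false_positives: tuple[str, ...]
    effect_errors: pd.DataFrame | None = None  # qtl, founder, estimated, true


@dataclass
class StudySummary:
    n_sims: int
    n_failed: int
    prob_ge1_false: float
    mean_selections: float
    mean_false_positives: float
    detection_rate: dict[str, float]
    mean_abs_position_error: float
    outcomes: list[DetectionOutcome] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"metric": "n_sims", "value": self.n_sims},
                {"metric": "n_failed", "value": self.n_failed},
                {"metric": "prob_ge1_false", "value": self.prob_ge1_false},
                {"metric": "mean_selections", "value": self.mean_selections},
                {"metric": "mean_false_positives", "value": self.mean_false_positives},
                {"metric": "mean_abs_position_error",
                 "value": self.mean_abs_position_error}]
        for q, r in self.detection_rate.items():
            rows.append({"metric": f"power_{q}", "value": r})
        return pd.DataFrame(rows)


def classify_detections(selected: list[str],
                        truth_qtl: tuple[QTLSpec, ...],
                        gmap: GeneticMap,
                        window_cm: float = 10.0,
                        sim_index: int = 0) -> DetectionOutcome:
    """Assign each selected marker to the nearest true QTL on its linkage
    group within the window; unassigned selections are false positives.
    A true QTL with at least one assigned marker counts as detected once."""
    midx = gmap.marker_index()
    labels = [f"QTL{k + 1}" for k in range(len(truth_qtl))]
    assignments: dict[str, str | None] = {}
    detected = {lab: False for lab in labels}
    distances: dict[str, float] = {}
    sel_pos = []
    for m in selected:
        gi = midx[m]
        lg, pos = gmap.linkage_groups[gi], float(gmap.positions[gi])
        sel_pos.append((lg, pos))
        best, best_d = None, np.inf
        for lab, q in zip(labels, truth_qtl):  # truth order breaks ties low
            if q.linkage_group != lg:
                continue
            d = abs(pos - q.position)
            if d <= window_cm and d < best_d:
                best, best_d = lab, d
        assignments[m] = best
        if best is not None:
            detected[best] = True
            distances[best] = min(distances.get(best, np.inf), best_d)
    false_pos = tuple(m for m in selected if assignments[m] is None)
    return DetectionOutcome(
        sim_index=sim_index, selected=tuple(selected),
        selected_positions=tuple(sel_pos), detected=detected,
        distances=distances, assignments=assignments, false_positives=false_pos)


def _probability_cube(bundle: SimulatedBundle,
                      source: str) -> FounderProbabilities:
    """Probability cube handed to the scan.

    'multipoint' uses the simulator's true founder origins, standing in for
    the dense-map multipoint (HMM) IBD probabilities the scan is normally
    run with — on a map this dense those are numerically indistinguishable
    from the truth for inbred lines.  'single_marker' recomputes the cube
    from the marker data alone with the parent-comparison rules, which
    leaves 0.5/0.5 rows wherever a family does not segregate.
    """
    if source == "multipoint":
        t = bundle.truth
        return FounderProbabilities(p=t.origin, line_ids=t.line_ids,
                                    marker_ids=t.marker_ids,
                                    founder_ids=t.founder_ids)
    if source == "single_marker":
        probs, _ = compute_founder_probabilities(
            bundle.founders, bundle.lines, bundle.design, bundle.gmap)
        return probs
    raise ValueError("probability_source must be 'multipoint' or 'single_marker'")


def _run_one(which: str, sim_index: int, base_seed: int,
             config: AnalysisConfig, collect_effects: bool,
             probability_source: str = "multipoint") -> DetectionOutcome | None:
    seed = (base_seed + 7919 * sim_index) % (2**31)
    bundle = preset_scenario(which, seed=seed)
    probs = _probability_cube(bundle, probability_source)
    try:
        state = wgnam_select(bundle.phenotypes, probs, bundle.gmap, config)
    except Exception:
        return None
    outcome = classify_detections(
        state.selected, bundle.scenario.qtl, bundle.gmap,
        window_cm=config.detection_window_cm, sim_index=sim_index)
    if collect_effects and state.selected:
        outcome = _attach_effect_errors(outcome, state, probs, bundle)
    return outcome


def _attach_effect_errors(outcome: DetectionOutcome, state: ScanState,
                          probs: FounderProbabilities,
                          bundle: SimulatedBundle) -> DetectionOutcome:
    """Estimated minus true founder effects for detected QTL, both centered
    (the scan's predictions are zero centered; true effect vectors are
    centered per QTL before differencing)."""
    assessments = assess_final_model(state, probs, bundle.founders, bundle.gmap)
    by_marker = {a.marker_id: a for a in assessments}
    qtl_by_label = {f"QTL{k + 1}": q for k, q in enumerate(bundle.scenario.qtl)}
    rows = []
    for sel, truth_id in outcome.assignments.items():
        if truth_id is None or sel not in by_marker:
            continue
        q = qtl_by_label[truth_id]
        true_centered = q.effects - q.effects.mean()
        a = by_marker[sel]
        est = np.array([fe.size for fe in a.founder_effects])
        est_centered = est - est.mean()
        for l, founder in enumerate(probs.founder_ids):
            rows.append({"qtl": truth_id, "founder": founder,
                         "estimated": est_centered[l], "true": true_centered[l],
                         "error": est_centered[l] - true_centered[l]})
    df = pd.DataFrame(rows) if rows else None
    return DetectionOutcome(**{**outcome.__dict__, "effect_errors": df})


def _summarize(outcomes: list[DetectionOutcome | None],
               truth_qtl: tuple[QTLSpec, ...]) -> StudySummary:
    ok = [o for o in outcomes if o is not None]
    n_failed = len(outcomes) - len(ok)
    n = len(ok)
    if n == 0:
        return StudySummary(0, n_failed, float("nan"), float("nan"), float("nan"),
                            {}, float("nan"))
    n_sel = np.array([len(o.selected) for o in ok], dtype=float)
    n_false = np.array([len(o.false_positives) for o in ok], dtype=float)
    rates = {}
    for k in range(len(truth_qtl)):
        lab = f"QTL{k + 1}"
        rates[lab] = float(np.mean([o.detected[lab] for o in ok]))
    dists = [d for o in ok for d in o.distances.values()]
    return StudySummary(
        n_sims=n, n_failed=n_failed,
        prob_ge1_false=float(np.mean(n_false >= 1)),
        mean_selections=float(np.mean(n_sel)),
        mean_false_positives=float(np.mean(n_false)),
        detection_rate=rates,
        mean_abs_position_error=float(np.mean(dists)) if dists else float("nan"),
        outcomes=ok)


def run_null_study(n_sims: int,
                   config: AnalysisConfig | None = None,
                   base_seed: int = 0,
                   n_jobs: int = 1,
                   probability_source: str = "multipoint") -> StudySummary:
    """Type-I-error study: fresh null-scenario bundles, full scan at the
    nominal alpha, every selection counted as false."""
    config = config or AnalysisConfig()
    run = delayed(_run_one)
    outcomes = Parallel(n_jobs=n_jobs)(
        run("null", i, base_seed, config, False, probability_source)
        for i in range(n_sims))
    return _summarize(list(outcomes), truth_qtl=())


def run_power_study(n_sims: int,
                    config: AnalysisConfig | None = None,
                    base_seed: int = 0,
                    n_jobs: int = 1,
                    collect_effects: bool = True,
                    probability_source: str = "multipoint") -> StudySummary:
    """Power study under the eight-QTL scenario: per-QTL detection rates at
    the detection window, false-positive statistics, and (optionally)
    founder-effect estimation errors for detected QTL."""
    config = config or AnalysisConfig()
    run = delayed(_run_one)
    outcomes = Parallel(n_jobs=n_jobs)(
        run("eight_qtl", i, base_seed, config, collect_effects,
            probability_source)
        for i in range(n_sims))
    from .simulate import PRESET_QTL_TABLE

    n_qtl = len(PRESET_QTL_TABLE)
    return _summarize(list(outcomes), truth_qtl=tuple(range(n_qtl)))  # labels only


def effect_recovery(outcomes: list[DetectionOutcome]) -> pd.DataFrame:
    """Distribution summaries of estimated-minus-true founder effects over
    the simulations in which each QTL was detected."""
    frames = [o.effect_errors for o in outcomes if o.effect_errors is not None]
    if not frames:
        return pd.DataFrame(columns=["qtl", "founder", "n", "mean_error",
                                     "sd_error", "q25", "median", "q75"])
    df = pd.concat(frames, ignore_index=True)
    g = df.groupby(["qtl", "founder"], sort=True)["error"]
    out = g.agg(n="count", mean_error="mean", sd_error="std",
                q25=lambda s: s.quantile(0.25), median="median",
                q75=lambda s: s.quantile(0.75)).reset_index()
    return out
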