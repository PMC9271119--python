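"""Final-model QTL summaries.

For each selected QTL the founder-effect BLUPs a~_j and their prediction
error variance (PEV) yield: an overall strength probability

    p_j = P( (a_j - a~_j)' PEV^- (a_j - a~_j) > a~_j' PEV^- a~_j )

evaluated as a chi-square tail with degrees of freedom equal to the
numerical rank of the PEV (exact under the mixed-model normal conditional);
the LOGP score -log10(p_j); founder-specific probabilities from the
standardized BLUPs; and the percentage of line genetic variance attributed
to the QTL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .lmm import MarkerBlup, MixedModelFit, blup_marker_effects
from .probs import FounderProbabilities
from .scan import ScanState
from .types import MISSING, DataError, FounderGenotypes, GeneticMap

RANK_TOL = 1e-8
SE_TOL = 1e-12
#: significance threshold on the LOGP scale, -log10(0.05)
LOGP_THRESHOLD = 1.30


@dataclass(frozen=True)
class FounderEffect:
    founder: str
    marker_genotype: int | None  # the founder's own call at the marker
    size: float
    probability: float
    score: float


@dataclass(frozen=True)
class QTLAssessment:
    marker_id: str
    linkage_group: str
    position: float
    overall_probability: float
    overall_logp: float
    percent_genetic_variance: float
    founder_effects: tuple[FounderEffect, ...]


def overall_probability(blup: MarkerBlup) -> tuple[float, float]:
    """Overall QTL strength probability and LOGP score.

    Uses the Moore-Penrose pseudoinverse of the PEV; the quadratic form is
    chi-square with df = rank(PEV) (eigenvalues above RANK_TOL x largest).
    """
    pev = blup.pev
    vals, vecs = np.linalg.eigh(pev)
    top = float(vals.max()) if vals.size else 0.0
    keep = vals > RANK_TOL * max(top, 0.0)
    nu = int(keep.sum())
    if nu == 0:
        warnings.warn(f"marker {blup.marker_id}: PEV has rank 0")
        return 1.0, 0.0
    inv_vals = np.zeros_like(vals)
    inv_vals[keep] = 1.0 / vals[keep]
    pinv = (vecs * inv_vals) @ vecs.T
    stat = float(blup.effects @ pinv @ blup.effects)
    p = float(chi2.sf(stat, df=nu))
    p = min(max(p, 1e-300), 1.0)
    return p, -float(np.log10(p))


def founder_probabilities_scores(blup: MarkerBlup) -> list[tuple[float, float]]:
    """Per-founder (probability, score): one-sided normal tail of the
    standardized BLUP, p = 1 - Phi(|a~_jl| / se_jl).

    A zero effect gives probability 0.5 (score 0.30); degenerate zero-PEV
    diagonals with zero effect likewise.
    """
    out = []
    se = np.sqrt(np.clip(np.diag(blup.pev), 0.0, None))
    for a, s in zip(blup.effects, se):
        if s < SE_TOL:
            p = 0.5 if a == 0.0 else 1e-300
        else:
            p = float(norm.sf(abs(a) / s))
            p = min(max(p, 1e-300), 1.0)
        out.append((p, -float(np.log10(p))))
    return out


def percent_genetic_variance(final_fit: MixedModelFit,
                             probs: FounderProbabilities,
                             selected: list[str]) -> dict[str, float]:
    """Share of the empirical line-level genetic variance attributed to each
    QTL: 100 * Var_i(Q_j a~_j) / Var_i(total genetic BLUP)."""
    if not selected:
        return {}
    total = final_fit.blup_lines()
    denom = float(np.var(total))
    if denom <= 0:
        warnings.warn("degenerate total genetic variance; %var set to 0")
        return {m: 0.0 for m in selected}
    out = {}
    for m in selected:
        out[m] = 100.0 * float(np.var(final_fit.blup_lines(m))) / denom
    return out


def assess_final_model(state: ScanState,
                       probs: FounderProbabilities,
                       founders: FounderGenotypes,
                       gmap: GeneticMap) -> list[QTLAssessment]:
    """One assessment per selected QTL from the final model fit."""
    if state.final_fit is None:
        raise DataError("scan state has no final fit")
    fit = state.final_fit
    midx = gmap.marker_index()
    fidx = {f: i for i, f in enumerate(founders.founder_ids)}
    pvar = percent_genetic_variance(fit, probs, state.selected)
    out = []
    for m in state.selected:
        blup = blup_marker_effects(fit, probs, m, which_variance="selected")
        p_j, logp_j = overall_probability(blup)
        per_founder = founder_probabilities_scores(blup)
        gi = midx[m]
        effects = []
        for l, founder in enumerate(probs.founder_ids):
            call = int(founders.calls[fidx[founder], gi]) if founder in fidx else None
            call = None if call == MISSING else call
            effects.append(FounderEffect(
                founder=founder, marker_genotype=call,
                size=float(blup.effects[l]),
                probability=per_founder[l][0], score=per_founder[l][1]))
        out.append(QTLAssessment(
            marker_id=m, linkage_group=gmap.linkage_groups[gi],
            position=float(gmap.positions[gi]),
            overall_probability=p_j, overall_logp=logp_j,
            percent_genetic_variance=pvar[m],
            founder_effects=tuple(effects)))
    return out


def assessment_table(assessments: list[QTLAssessment]) -> pd.DataFrame:
    """Long-format report: one row per QTL x founder with the founder
    specific size/probability/score next to the QTL's overall columns."""
    rows = []
    for a in assessments:
        for fe in a.founder_effects:
            rows.append({
                "marker": a.marker_id,
                "linkage_group": a.linkage_group,
                "distance_cm": a.position,
                "founder": fe.founder,
                "marker_genotype": fe.marker_genotype,
                "size": fe.size,
                "probability": fe.probability,
                "score": fe.score,
                "overall_probability": a.overall_probability,
                "overall_pct_var": a.percent_genetic_variance,
                "overall_score": a.overall_logp,
            })
    return pd.DataFrame(rows)


def summary_table(assessments: list[QTLAssessment],
                  threshold: float = LOGP_THRESHOLD) -> pd.DataFrame:
    """Thresholded summary: QTL whose overall or any founder-specific LOGP
    score exceeds ``threshold``, with effect type 'overall'/'specific'."""
    rows = []
    for a in assessments:
        strong = [fe for fe in a.founder_effects if fe.score > threshold]
        types = []
        if a.overall_logp > threshold:
            types.append("overall")
        if strong:
            types.append("specific")
        if not types:
            continue
        rows.append({
            "linkage_group": a.linkage_group,
            "distance_cm": a.position,
            "marker": a.marker_id,
            "effect_type": "+".join(types),
            "overall_pct_var": a.percent_genetic_variance if "overall" in types else np.nan,
            "overall_score": a.overall_logp if "overall" in types else np.nan,
            "specific_effects": "; ".join(
                f"{fe.founder} (size={fe.size:.2f}; score={fe.score:.2f})"
                for fe in strong),
        })
    return pd.DataFrame(rows)
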