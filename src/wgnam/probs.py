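"""Marker QC, parental imputation and founder-allele inheritance probabilities.

For a NAM family (donor D x reference R) each marker is treated independently:
if the two parents carry different homozygous genotypes, a line matching one
parent inherited that parent's allele with probability 1; a heterozygous line
gets 0.5/0.5; if the parents share a genotype the marker is uninformative and
every line gets 0.5/0.5 on the two parents.  Founders that are not parents of
the line's family always get probability 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    DataError,
    Diagnostic,
    FounderGenotypes,
    GeneticMap,
    LineGenotypes,
    NamDesign,
)

PROB_SUM_TOL = 1e-12
EXTERNAL_SUM_TOL = 1e-6


@dataclass(frozen=True)
class FounderProbabilities:
    """Cube of probabilities p[i, j, l] that line i inherited its allele at
    marker j from founder l.  Rows (over founders) sum to one."""

    p: np.ndarray  # (n_g, n_m, n_f) float64
    line_ids: tuple[str, ...]
    marker_ids: tuple[str, ...]
    founder_ids: tuple[str, ...]

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if p.shape != (len(self.line_ids), len(self.marker_ids), len(self.founder_ids)):
            raise DataError("probability cube shape does not match ids")
        if np.any(p < 0) or np.any(p > 1):
            raise DataError("probabilities outside [0, 1]")
        object.__setattr__(self, "p", p)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_founders(self) -> int:
        return len(self.founder_ids)

    def marker_slab(self, j: int) -> np.ndarray:
        """(n_g, n_f) probability matrix Q_j for marker index j."""
        return self.p[:, j, :]


@dataclass(frozen=True)
class QCReport:
    """Per-marker filter outcome; a marker is kept iff it has no reasons."""

    table: pd.DataFrame  # marker_id, kept, reasons, overall_missing, maf + per-family rates

    @property
    def kept_markers(self) -> list[str]:
        return list(self.table.loc[self.table["kept"], "marker_id"])

    @property
    def dropped_markers(self) -> list[str]:
        return list(self.table.loc[~self.table["kept"], "marker_id"])

    def to_tsv(self, path) -> None:
        df = self.table.copy()
        df["reasons"] = df["reasons"].map(lambda r: ",".join(r) if r else "")
        df.to_csv(path, sep="\t", index=False)


def clean_founder_genotypes(founders: FounderGenotypes) -> FounderGenotypes:
    """Recode heterozygous founder calls as missing (founders are inbred, so a
    heterozygous call is a genotyping artefact)."""
    calls = founders.calls.copy()
    calls[calls == 1] = MISSING
    return FounderGenotypes(founder_ids=founders.founder_ids, calls=calls)


def qc_filter_markers(founders: FounderGenotypes,
                      lines: LineGenotypes,
                      design: NamDesign,
                      gmap: GeneticMap,
                      max_family_missing: float = 0.5,
                      max_overall_missing: float = 0.1,
                      min_maf: float = 0.01,
                      parent_conflict_freq: float = 0.05) -> QCReport:
    """Flag markers for exclusion.

    Filters: within-family line missing rate above ``max_family_missing`` in
    any family; overall line missing rate above ``max_overall_missing``; minor
    allele frequency across population lines below ``min_maf`` (fixed markers
    have MAF 0 and are excluded); and parent conflict — in a family whose two
    parents share the same non-missing genotype, both homozygote classes
    observed among the family's lines at frequency above
    ``parent_conflict_freq`` each.
    """
    for name, v in [("max_family_missing", max_family_missing),
                    ("max_overall_missing", max_overall_missing),
                    ("min_maf", min_maf),
                    ("parent_conflict_freq", parent_conflict_freq)]:
        if not 0 <= v <= 1:
            raise DataError(f"{name} must be in [0, 1]")

    calls = lines.calls
    n_g, n_m = calls.shape
    miss = calls == MISSING
    overall_missing = miss.mean(axis=0)

    line_index = {l: i for i, l in enumerate(lines.line_ids)}
    fam_lines = {fam: np.array([line_index[l] for l in ls if l in line_index], dtype=int)
                 for fam, ls in design.lines_by_family().items()}

    fam_missing: dict[str, np.ndarray] = {}
    for fam, idx in fam_lines.items():
        fam_missing[fam] = miss[idx].mean(axis=0) if idx.size else np.zeros(n_m)

    # allele frequency of the "2" allele over non-missing population calls
    obs = ~miss
    allele_counts = np.where(obs, calls, 0).sum(axis=0).astype(float)
    denom = 2.0 * obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(denom > 0, allele_counts / denom, 0.0)
    maf = np.minimum(freq, 1.0 - freq)

    # parent conflict: parents share a genotype but the family segregates
    conflict = np.zeros(n_m, dtype=bool)
    fidx = {f: i for i, f in enumerate(founders.founder_ids)}
    for fam in design.families:
        idx = fam_lines.get(fam.family_id, np.array([], dtype=int))
        if idx.size == 0:
            continue
        d = founders.calls[fidx[fam.donor]]
        r = founders.calls[fidx[fam.reference]]
        same = (d == r) & (d != MISSING)
        sub = calls[idx]
        n_obs = (sub != MISSING).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f0 = np.where(n_obs > 0, (sub == 0).sum(axis=0) / n_obs, 0.0)
            f2 = np.where(n_obs > 0, (sub == 2).sum(axis=0) / n_obs, 0.0)
        conflict |= same & (f0 > parent_conflict_freq) & (f2 > parent_conflict_freq)

    records = []
    for j, marker in enumerate(gmap.marker_ids):
        reasons = []
        if any(fam_missing[fam][j] > max_family_missing for fam in fam_missing):
            reasons.append("FAMILY_MISSING")
        if overall_missing[j] > max_overall_missing:
            reasons.append("OVERALL_MISSING")
        if maf[j] < min_maf:
            reasons.append("LOW_MAF")
        if conflict[j]:
            reasons.append("PARENT_CONFLICT")
        rec = {
            "marker_id": marker,
            "kept": not reasons,
            "reasons": reasons,
            "overall_missing": overall_missing[j],
            "maf": maf[j],
        }
        for fam in fam_missing:
            rec[f"missing_{fam}"] = fam_missing[fam][j]
        records.append(rec)
    return QCReport(table=pd.DataFrame.from_records(records))


def impute_from_parents(lines: LineGenotypes,
                        founders: FounderGenotypes,
                        design: NamDesign) -> LineGenotypes:
    """Fill missing line calls where both family parents agree.

    A missing call is forced to the shared parental genotype (the marker does
    not segregate in that family); calls where the parents differ or are
    missing are left untouched.
    """
    calls = lines.calls.copy()
    fidx = {f: i for i, f in enumerate(founders.founder_ids)}
    for i, line in enumerate(lines.line_ids):
        donor, ref = design.parents_of_line(line)
        d = founders.calls[fidx[donor]]
        r = founders.calls[fidx[ref]]
        fill = (calls[i] == MISSING) & (d == r) & (d != MISSING)
        calls[i, fill] = d[fill]
    return LineGenotypes(line_ids=lines.line_ids, calls=calls)


def compute_founder_probabilities(founders: FounderGenotypes,
                                  lines: LineGenotypes,
                                  design: NamDesign,
                                  gmap: GeneticMap,
                                  kept_markers: list[str] | None = None,
                                  ) -> tuple[FounderProbabilities, list[Diagnostic]]:
    """Founder inheritance probabilities from single-marker parent comparison.

    Returns the cube restricted to ``kept_markers`` (map order preserved) and
    a list of warning diagnostics for degenerate calls (missing parents,
    parent-inconsistent line calls), which fall back to the uninformative
    0.5/0.5 assignment on the two family parents.
    """
    marker_pos = gmap.marker_index()
    if kept_markers is None:
        kept_markers = list(gmap.marker_ids)
    else:
        unknown = [m for m in kept_markers if m not in marker_pos]
        if unknown:
            raise DataError(f"kept markers absent from the map: {unknown[:5]}")
        kept_markers = [m for m in gmap.marker_ids if m in set(kept_markers)]
    cols = np.array([marker_pos[m] for m in kept_markers], dtype=int)

    n_g = lines.n_lines
    n_m = len(cols)
    n_f = founders.n_founders
    p = np.zeros((n_g, n_m, n_f))
    diagnostics: list[Diagnostic] = []

    fidx = {f: i for i, f in enumerate(founders.founder_ids)}
    line_index = {l: i for i, l in enumerate(lines.line_ids)}
    n_missing_parent = 0
    n_inconsistent = 0

    for fam in design.families:
        idx = np.array([line_index[l] for l in design.lines_by_family()[fam.family_id]
                        if l in line_index], dtype=int)
        if idx.size == 0:
            continue
        di, ri = fidx[fam.donor], fidx[fam.reference]
        d = founders.calls[di, cols]
        r = founders.calls[ri, cols]
        sub = lines.calls[np.ix_(idx, cols)]

        parent_missing = (d == MISSING) | (r == MISSING)
        segregating = ~parent_missing & (d != r)
        n_missing_parent += int(parent_missing.sum())

        pd_fam = np.full((idx.size, n_m), 0.5)
        # segregating markers: match the donor -> 1, match the reference -> 0,
        # heterozygote -> 0.5; anything else is inconsistent -> 0.5 + warning
        seg = np.broadcast_to(segregating, sub.shape)
        match_d = seg & (sub == d[None, :])
        match_r = seg & (sub == r[None, :])
        het = seg & (sub == 1)
        pd_fam[match_d] = 1.0
        pd_fam[match_r] = 0.0
        pd_fam[het] = 0.5
        unresolved = seg & ~match_d & ~match_r & ~het & (sub != MISSING)
        n_inconsistent += int(unresolved.sum())
        # non-segregating shared-parent markers where the line call disagrees
        # with the shared parental genotype are likewise inconsistent
        shared = np.broadcast_to(~parent_missing & (d == r), sub.shape)
        n_inconsistent += int((shared & (sub != MISSING) & (sub != d[None, :])).sum())

        p[np.ix_(idx, cols_local := np.arange(n_m), [di])] = pd_fam[:, :, None]
        p[np.ix_(idx, cols_local, [ri])] = 1.0 - pd_fam[:, :, None]

    if n_missing_parent:
        diagnostics.append(Diagnostic(
            "warning", f"{n_missing_parent} family-marker cells had a missing parent "
                       f"genotype; assigned the uninformative 0.5/0.5"))
    if n_inconsistent:
        diagnostics.append(Diagnostic(
            "warning", f"{n_inconsistent} line calls were inconsistent with the family "
                       f"parents; treated as missing (0.5/0.5)"))

    cube = FounderProbabilities(
        p=p, line_ids=lines.line_ids, marker_ids=tuple(kept_markers),
        founder_ids=founders.founder_ids)
    return cube, diagnostics


def write_probabilities(probs: FounderProbabilities, path) -> None:
    """Write the cube in long format (line, marker, founder, prob), omitting
    structural zeros on non-parent founders would lose information for
    externally computed cubes, so all entries are written."""
    n_g, n_m, n_f = probs.p.shape
    df = pd.DataFrame({
        "line": np.repeat(probs.line_ids, n_m * n_f),
        "marker": np.tile(np.repeat(probs.marker_ids, n_f), n_g),
        "founder": np.tile(probs.founder_ids, n_g * n_m),
        "prob": probs.p.reshape(-1),
    })
    df.to_csv(path, index=False)


def load_external_probabilities(path,
                                gmap: GeneticMap,
                                lines: LineGenotypes,
                                design: NamDesign,
                                founder_ids: tuple[str, ...],
                                ) -> tuple[FounderProbabilities, list[Diagnostic]]:
    """Load a long-format probability file produced by another method (e.g.
    a hidden-Markov multipoint calculation).

    Rows are renormalized to sum to one when within 1e-6 of one, otherwise an
    error is raised.  Probability mass on founders that are not parents of the
    line's family is reported as a warning, not an error, since multipoint
    methods may spread mass.
    """
    df = pd.read_csv(path, dtype={"line": str, "marker": str, "founder": str})
    for col in ("line", "marker", "founder", "prob"):
        if col not in df.columns:
            raise DataError(f"{path}: missing column {col!r}")
    if (df["prob"] < 0).any() or (df["prob"] > 1).any():
        raise DataError(f"{path}: probability outside [0, 1]")

    line_idx = {l: i for i, l in enumerate(lines.line_ids)}
    founder_idx = {f: i for i, f in enumerate(founder_ids)}
    markers = [m for m in gmap.marker_ids if m in set(df["marker"])]
    marker_idx = {m: j for j, m in enumerate(markers)}
    unknown_markers = set(df["marker"]) - set(marker_idx)
    if unknown_markers:
        raise DataError(f"{path}: markers not on the map: {sorted(unknown_markers)[:5]}")
    unknown_lines = set(df["line"]) - set(line_idx)
    if unknown_lines:
        raise DataError(f"{path}: unknown lines: {sorted(unknown_lines)[:5]}")
    unknown_founders = set(df["founder"]) - set(founder_idx)
    if unknown_founders:
        raise DataError(f"{path}: unknown founders: {sorted(unknown_founders)[:5]}")

    p = np.zeros((len(line_idx), len(markers), len(founder_idx)))
    p[df["line"].map(line_idx), df["marker"].map(marker_idx),
      df["founder"].map(founder_idx)] = df["prob"].to_numpy()

    sums = p.sum(axis=2)
    bad = np.abs(sums - 1.0) > EXTERNAL_SUM_TOL * (1 + 1e-9)  # float-safe edge
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DataError(f"{path}: probabilities for line {lines.line_ids[i]!r} at "
                        f"marker {markers[j]!r} sum to {sums[i, j]:.8f}, not 1")
    p = p / sums[:, :, None]

    diagnostics: list[Diagnostic] = []
    parent_mask = np.zeros((len(line_idx), len(founder_idx)), dtype=bool)
    for line, i in line_idx.items():
        donor, ref = design.parents_of_line(line)
        parent_mask[i, founder_idx[donor]] = True
        parent_mask[i, founder_idx[ref]] = True
    off = p * ~parent_mask[:, None, :]
    mass = float(off.sum())
    if mass > 0:
        diagnostics.append(Diagnostic(
            "warning", f"external probabilities place total mass {mass:.3g} on "
                       f"non-parent founders; retained as supplied"))
    cube = FounderProbabilities(p=p, line_ids=lines.line_ids,
                                marker_ids=tuple(markers), founder_ids=tuple(founder_ids))
    return cube, diagnostics
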