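"""Core domain types for NAM/MR-NAM QTL analysis.

Genotype calls are coded as counts of an (arbitrary but consistent) reference
allele: 0, 1 or 2, with ``MISSING`` (-1) for no-calls.  Map positions are in
centiMorgans; there are no physical coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in integer call matrices.
MISSING: int = -1

_VALID_CALLS = frozenset({0, 1, 2, MISSING})


class DataError(ValueError):
    """Raised when an input object violates a structural invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise DataError(f"duplicate {what}: {dups[:5]}")


def _check_calls(calls: np.ndarray, what: str) -> np.ndarray:
    calls = np.asarray(calls)
    if not np.isin(calls, list(_VALID_CALLS)).all():
        bad = sorted(set(np.unique(calls)) - _VALID_CALLS)
        raise DataError(f"{what}: genotype codes outside {{0,1,2,NA}}: {bad[:5]}")
    return calls.astype(np.int8)


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker map: marker id, linkage group and position (cM).

    Markers are stored in genome order; within each linkage group positions
    must be non-decreasing.
    """

    marker_ids: tuple[str, ...]
    linkage_groups: tuple[str, ...]
    positions: np.ndarray  # cM, aligned with marker_ids

    def __post_init__(self):
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        if not (len(self.marker_ids) == len(self.linkage_groups) == len(self.positions)):
            raise DataError("map fields have mismatched lengths")
        if len(self.marker_ids) == 0:
            raise DataError("map must contain at least one marker")
        _check_unique(self.marker_ids, "marker ids")
        if np.any(self.positions < 0) or not np.all(np.isfinite(self.positions)):
            raise DataError("map positions must be finite and non-negative")
        lgs = np.asarray(self.linkage_groups)
        for lg in pd.unique(lgs):
            pos = self.positions[lgs == lg]
            if np.any(np.diff(pos) < 0):
                raise DataError(f"positions not sorted within linkage group {lg!r}")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def lg_names(self) -> list[str]:
        return list(pd.unique(np.asarray(self.linkage_groups)))

    def marker_index(self) -> dict[str, int]:
        return {m: i for i, m in enumerate(self.marker_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": self.marker_ids,
                "linkage_group": self.linkage_groups,
                "pos_cm": self.positions,
            }
        )


@dataclass(frozen=True)
class FounderGenotypes:
    """Founder (parent) call matrix, rows aligned to ``founder_ids`` and
    columns to the genetic map."""

    founder_ids: tuple[str, ...]
    calls: np.ndarray  # (n_f, n_m) int8

    def __post_init__(self):
        object.__setattr__(self, "calls", _check_calls(self.calls, "founder calls"))
        _check_unique(self.founder_ids, "founder ids")
        if self.calls.shape[0] != len(self.founder_ids):
            raise DataError("founder calls row count != number of founder ids")

    @property
    def n_founders(self) -> int:
        return len(self.founder_ids)

    def index_of(self, founder: str) -> int:
        return self.founder_ids.index(founder)


@dataclass(frozen=True)
class Family:
    family_id: str
    donor: str
    reference: str


@dataclass(frozen=True)
class NamDesign:
    """Crossing design: families (donor x reference) and line membership."""

    families: tuple[Family, ...]
    membership: Mapping[str, str]  # line_id -> family_id

    def __post_init__(self):
        _check_unique([f.family_id for f in self.families], "family ids")
        pairs = set()
        for f in self.families:
            if f.donor == f.reference:
                raise DataError(f"family {f.family_id!r}: donor == reference ({f.donor!r})")
            if (f.donor, f.reference) in pairs:
                raise DataError(f"duplicate (donor, reference) pair {(f.donor, f.reference)}")
            pairs.add((f.donor, f.reference))
        fam_ids = {f.family_id for f in self.families}
        for line, fam in self.membership.items():
            if fam not in fam_ids:
                raise DataError(f"line {line!r} assigned to unknown family {fam!r}")

    @property
    def family_ids(self) -> list[str]:
        return [f.family_id for f in self.families]

    def family(self, family_id: str) -> Family:
        for f in self.families:
            if f.family_id == family_id:
                return f
        raise KeyError(family_id)

    def parents_of_line(self, line_id: str) -> tuple[str, str]:
        fam = self.family(self.membership[line_id])
        return fam.donor, fam.reference

    def lines_by_family(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {f.family_id: [] for f in self.families}
        for line, fam in self.membership.items():
            out[fam].append(line)
        return out


@dataclass(frozen=True)
class LineGenotypes:
    """Population line call matrix, columns aligned to the genetic map."""

    line_ids: tuple[str, ...]
    calls: np.ndarray  # (n_g, n_m) int8

    def __post_init__(self):
        object.__setattr__(self, "calls", _check_calls(self.calls, "line calls"))
        _check_unique(self.line_ids, "line ids")
        if self.calls.shape[0] != len(self.line_ids):
            raise DataError("line calls row count != number of line ids")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)


#: Entry types in a phenotype table.  ``population`` entries receive random
#: genetic effects; ``check`` entries (standards) enter as fixed effects.
ENTRY_TYPES = ("population", "check")


@dataclass(frozen=True)
class PhenotypeTable:
    """Plot-level phenotype records.

    Columns: plot, entry, entry_type ('population'/'check'), replicate, value.
    Missing trait values are NaN.
    """

    records: pd.DataFrame

    def __post_init__(self):
        req = ["plot", "entry", "entry_type", "replicate", "value"]
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise DataError(f"phenotype table missing columns: {missing}")
        bad = set(self.records["entry_type"]) - set(ENTRY_TYPES)
        if bad:
            raise DataError(f"unknown entry_type values: {sorted(bad)}")
        df = self.records.copy()
        df["value"] = pd.to_numeric(df["value"], errors="coerce")
        object.__setattr__(self, "records", df.reset_index(drop=True))

    @property
    def n_observed(self) -> int:
        return int(self.records["value"].notna().sum())

    def population_entries(self) -> list[str]:
        mask = self.records["entry_type"] == "population"
        return list(pd.unique(self.records.loc[mask, "entry"]))

    def check_entries(self) -> list[str]:
        mask = self.records["entry_type"] == "check"
        return list(pd.unique(self.records.loc[mask, "entry"]))


@dataclass(frozen=True)
class AnalysisConfig:
    """Tuning knobs for the genome scan.

    alpha is the nominal type-I error rate of the forward-selection stopping
    rule; detection_window_cm the distance within which a selected marker
    counts as a detection of a true QTL in simulation studies.
    """

    alpha: float = 0.05
    max_iterations: int = 40
    detection_window_cm: float = 10.0
    seed: int = 0
    #: absolute REML log-likelihood convergence tolerance
    reml_loglik_tol: float = 1e-6
    #: maximum relative change in a variance component at convergence
    reml_param_tol: float = 1e-4
    reml_max_iter: int = 100
    #: how replicate blocks enter the model: 'none', 'fixed' or 'random'
    replicate_effect: str = "none"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise DataError("alpha must be in (0, 1)")
        if self.max_iterations < 1:
            raise DataError("max_iterations must be positive")
        if self.detection_window_cm < 0:
            raise DataError("detection_window_cm must be non-negative")
        if self.replicate_effect not in ("none", "fixed", "random"):
            raise DataError("replicate_effect must be 'none', 'fixed' or 'random'")

    def with_(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class Diagnostic:
    """Human-readable validation finding, tagged fatal or warning."""

    severity: str  # 'fatal' | 'warning'
    message: str

    def __post_init__(self):
        if self.severity not in ("fatal", "warning"):
            raise DataError("severity must be 'fatal' or 'warning'")
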