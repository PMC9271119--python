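"""Readers and writers for the tabular interchange formats.

All files are comma-separated UTF-8 with a mandatory header row.  Genotype
calls are 0/1/2 with "NA" for missing; probabilities are written long-format
(line, marker, founder, prob).
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    DataError,
    Diagnostic,
    Family,
    FounderGenotypes,
    GeneticMap,
    LineGenotypes,
    NamDesign,
    PhenotypeTable,
)


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")


# ---------------------------------------------------------------- map

def read_map(path: str | os.PathLike) -> GeneticMap:
    df = pd.read_csv(path, dtype={"marker": str, "linkage_group": str})
    _require_columns(df, ["marker", "linkage_group", "pos_cm"], str(path))
    return GeneticMap(
        marker_ids=tuple(df["marker"]),
        linkage_groups=tuple(df["linkage_group"]),
        positions=df["pos_cm"].to_numpy(dtype=float),
    )


def write_map(gmap: GeneticMap, path: str | os.PathLike) -> None:
    gmap.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------- genotypes

def _read_calls(path: str | os.PathLike, gmap: GeneticMap) -> tuple[tuple[str, ...], np.ndarray]:
    df = pd.read_csv(path, na_values=["NA"])
    if df.shape[1] < 2:
        raise DataError(f"{path}: expected an id column plus marker columns")
    id_col = df.columns[0]
    ids = tuple(df[id_col].astype(str))
    marker_cols = list(df.columns[1:])
    known = set(gmap.marker_ids)
    unknown = [m for m in marker_cols if m not in known]
    if unknown:
        raise DataError(f"{path}: markers not on the map: {unknown[:5]}")
    absent = [m for m in gmap.marker_ids if m not in set(marker_cols)]
    if absent:
        raise DataError(f"{path}: markers on the map but absent from file: {absent[:5]}")
    # reorder columns to map order
    values = df[list(gmap.marker_ids)].to_numpy(dtype=float)
    calls = np.where(np.isnan(values), MISSING, values)
    if not np.isin(calls, [0, 1, 2, MISSING]).all():
        raise DataError(f"{path}: genotype codes outside {{0,1,2,NA}}")
    return ids, calls.astype(np.int8)


def _write_calls(ids: Iterable[str], calls: np.ndarray, gmap: GeneticMap,
                 id_name: str, path: str | os.PathLike) -> None:
    out = pd.DataFrame(calls.astype(object), columns=list(gmap.marker_ids))
    out = out.mask(out == MISSING, other=pd.NA)
    out.insert(0, id_name, list(ids))
    out.to_csv(path, index=False, na_rep="NA")


def read_founders(path: str | os.PathLike, gmap: GeneticMap) -> FounderGenotypes:
    ids, calls = _read_calls(path, gmap)
    return FounderGenotypes(founder_ids=ids, calls=calls)


def write_founders(founders: FounderGenotypes, gmap: GeneticMap, path) -> None:
    _write_calls(founders.founder_ids, founders.calls, gmap, "founder", path)


def read_lines(path: str | os.PathLike, gmap: GeneticMap) -> LineGenotypes:
    ids, calls = _read_calls(path, gmap)
    return LineGenotypes(line_ids=ids, calls=calls)


def write_lines(lines: LineGenotypes, gmap: GeneticMap, path) -> None:
    _write_calls(lines.line_ids, lines.calls, gmap, "line", path)


# ---------------------------------------------------------------- design

def read_design(design_path, membership_path) -> NamDesign:
    fam_df = pd.read_csv(design_path, dtype=str)
    _require_columns(fam_df, ["family", "donor", "reference"], str(design_path))
    mem_df = pd.read_csv(membership_path, dtype=str)
    _require_columns(mem_df, ["line", "family"], str(membership_path))
    families = tuple(
        Family(family_id=r.family, donor=r.donor, reference=r.reference)
        for r in fam_df.itertuples()
    )
    membership = dict(zip(mem_df["line"], mem_df["family"]))
    if len(membership) != len(mem_df):
        raise DataError(f"{membership_path}: duplicate line ids")
    return NamDesign(families=families, membership=membership)


def write_design(design: NamDesign, design_path, membership_path) -> None:
    pd.DataFrame(
        {
            "family": [f.family_id for f in design.families],
            "donor": [f.donor for f in design.families],
            "reference": [f.reference for f in design.families],
        }
    ).to_csv(design_path, index=False)
    pd.DataFrame(
        {"line": list(design.membership), "family": list(design.membership.values())}
    ).to_csv(membership_path, index=False)


# ---------------------------------------------------------------- phenotypes

def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, na_values=["NA"],
                     dtype={"plot": str, "entry": str, "entry_type": str, "replicate": str})
    _require_columns(df, ["plot", "entry", "entry_type", "replicate", "value"], str(path))
    return PhenotypeTable(records=df)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.records.to_csv(path, index=False, na_rep="NA")


# ---------------------------------------------------------------- validation

def validate_bundle(gmap: GeneticMap,
                    founders: FounderGenotypes,
                    lines: LineGenotypes,
                    design: NamDesign,
                    phenotypes: PhenotypeTable | None = None) -> list[Diagnostic]:
    """Cross-check a full input bundle; returns diagnostics, never raises.

    An empty list means all cross-references resolve and dimensions agree.
    """
    out: list[Diagnostic] = []
    n_m = gmap.n_markers
    if founders.calls.shape[1] != n_m:
        out.append(Diagnostic("fatal", f"founder matrix has {founders.calls.shape[1]} "
                                       f"columns but the map has {n_m} markers"))
    if lines.calls.shape[1] != n_m:
        out.append(Diagnostic("fatal", f"line matrix has {lines.calls.shape[1]} "
                                       f"columns but the map has {n_m} markers"))
    founder_set = set(founders.founder_ids)
    for fam in design.families:
        for parent in (fam.donor, fam.reference):
            if parent not in founder_set:
                out.append(Diagnostic("fatal", f"family {fam.family_id!r}: parent "
                                               f"{parent!r} not in founder genotypes"))
    member_set = set(design.membership)
    for line in lines.line_ids:
        if line not in member_set:
            out.append(Diagnostic("fatal", f"line {line!r} has no family membership"))
    line_set = set(lines.line_ids)
    for line in design.membership:
        if line not in line_set:
            out.append(Diagnostic("warning", f"membership lists line {line!r} "
                                             f"with no genotypes"))
    n_het = int((founders.calls == 1).sum())
    if n_het:
        out.append(Diagnostic("warning", f"founders contain {n_het} heterozygous "
                                         f"calls; they are treated as missing by cleaning"))
    if phenotypes is not None:
        for entry in phenotypes.population_entries():
            if entry not in line_set:
                out.append(Diagnostic("fatal", f"population entry {entry!r} in the "
                                               f"phenotype table has no line genotypes"))
        if phenotypes.n_observed == 0:
            out.append(Diagnostic("fatal", "phenotype table has no observed values"))
    return out
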