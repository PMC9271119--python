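"""Simulation of NAM populations and phenotypes.

The generator emulates a wheat NAM scenario: one reference parent crossed to
five donors, five families of 100 recombinant inbred lines (RILs) over seven
linkage groups (~895 markers), with phenotypes drawn either under a pure
polygenic null or with eight QTL of founder-specific effects.

Meioses follow the Haldane model (no crossover interference): the
recombination fraction over d cM is r = (1 - exp(-2d/100)) / 2.  Fully inbred
RILs are drawn from the selfing-limit process, in which the effective
recombination fraction between adjacent markers is R = 2r / (1 + 2r)
(Haldane-Waddington).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    DataError,
    Family,
    FounderGenotypes,
    GeneticMap,
    LineGenotypes,
    NamDesign,
    PhenotypeTable,
)

INFINITE = "INFINITE"

#: Founders of the simulated scenario; the first is the reference parent.
PRESET_FOUNDERS = ("Suntop", "SeriM82", "ZWB10.37", "Drysdale", "Westonia", "Dharwah dry")

#: The eight-QTL architecture: (lg, pos_cm, effects per founder in
#: PRESET_FOUNDERS order).
PRESET_QTL_TABLE = (
    ("1B", 94.39, (0.4, -0.2, -0.2, 0.0, 0.0, 0.0)),
    ("2B", 17.84, (0.5, -0.1, -0.1, -0.1, -0.1, -0.1)),
    ("3B", 19.00, (0.4, 0.0, 0.0, -0.4, 0.0, 0.0)),
    ("4B", 62.27, (0.0, -0.6, 0.0, 0.0, 0.0, 0.6)),
    ("5B", 60.11, (0.2, 0.0, 0.0, -0.1, 0.0, -0.1)),
    ("6B", 57.39, (0.2, -0.04, -0.04, -0.04, -0.04, -0.04)),
    ("7B", 101.51, (0.2, 0.0, 0.0, 0.0, 0.0, -0.2)),
    ("1B", 161.57, (0.0, -0.3, 0.0, 0.0, 0.3, 0.0)),
)

#: Marker counts per linkage group for the preset map (each within [77, 223],
#: totalling 895).
PRESET_MARKERS_PER_LG = (140, 120, 110, 130, 145, 123, 127)
PRESET_LGS = ("1B", "2B", "3B", "4B", "5B", "6B", "7B")


def haldane_r(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Map distance (cM) -> recombination fraction, Haldane (no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def ril_r(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Effective recombination fraction between fully inbred selfed RILs."""
    r = haldane_r(d_cm)
    return 2.0 * r / (1.0 + 2.0 * r)


@dataclass(frozen=True)
class QTLSpec:
    marker_id: str
    linkage_group: str
    position: float
    effects: np.ndarray  # one effect per founder

    def __post_init__(self):
        object.__setattr__(self, "effects", np.asarray(self.effects, dtype=float))


@dataclass(frozen=True)
class SimulationScenario:
    """Phenotype-generation parameters.

    Defaults follow the simulated NAM study: trait mean 7, polygenic variance
    0.5, residual variance 1, two replicates.
    """

    mu: float = 7.0
    var_polygenic: float = 0.5
    var_residual: float = 1.0
    n_rep: int = 2
    qtl: tuple[QTLSpec, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.var_polygenic < 0 or self.var_residual < 0:
            raise DataError("variances must be non-negative")
        if self.n_rep < 1:
            raise DataError("n_rep must be positive")


@dataclass(frozen=True)
class TruthRecord:
    """True founder-origin indicators per line x marker (the generative
    probability cube: 0/1 for inbred lines, 0.5/0.5 under residual
    heterozygosity)."""

    origin: np.ndarray  # (n_g, n_m, n_f)
    line_ids: tuple[str, ...]
    marker_ids: tuple[str, ...]
    founder_ids: tuple[str, ...]

    def marker_index(self) -> dict[str, int]:
        return {m: j for j, m in enumerate(self.marker_ids)}


@dataclass(frozen=True)
class SimulatedBundle:
    gmap: GeneticMap
    founders: FounderGenotypes
    design: NamDesign
    lines: LineGenotypes
    truth: TruthRecord
    phenotypes: PhenotypeTable
    scenario: SimulationScenario


# ------------------------------------------------------------------ map

def simulate_map(n_lg: int,
                 markers_per_lg: list[int],
                 lengths_cm: list[float],
                 seed: int,
                 lg_names: list[str] | None = None,
                 forced_positions: dict[str, list[float]] | None = None) -> GeneticMap:
    """Random marker map: uniform positions per linkage group, both
    chromosome ends always included, optional forced positions."""
    if len(markers_per_lg) != n_lg or len(lengths_cm) != n_lg:
        raise DataError("markers_per_lg and lengths_cm must have length n_lg")
    if any(c < 2 for c in markers_per_lg):
        raise DataError("each linkage group needs at least 2 markers")
    if any(l <= 0 for l in lengths_cm):
        raise DataError("linkage group lengths must be positive")
    if lg_names is None:
        lg_names = [f"LG{i + 1}" for i in range(n_lg)]
    forced_positions = forced_positions or {}
    rng = np.random.default_rng(seed)

    marker_ids, lgs, positions = [], [], []
    for lg, count, length in zip(lg_names, markers_per_lg, lengths_cm):
        forced = sorted(set(forced_positions.get(lg, [])) | {0.0, float(length)})
        if any(p < 0 or p > length for p in forced):
            raise DataError(f"forced position outside [0, {length}] on {lg}")
        n_random = count - len(forced)
        if n_random < 0:
            raise DataError(f"{lg}: marker count {count} below forced-position count")
        pos = np.sort(np.concatenate([np.asarray(forced),
                                      rng.uniform(0, length, size=n_random)]))
        marker_ids.extend(f"M{lg}.{k + 1}" for k in range(count))
        lgs.extend([lg] * count)
        positions.extend(pos.tolist())
    return GeneticMap(marker_ids=tuple(marker_ids), linkage_groups=tuple(lgs),
                      positions=np.asarray(positions))


def preset_b_genome(seed: int = 0) -> GeneticMap:
    """Preset seven-linkage-group map (1B-7B, 895 markers) with markers
    forced at every preset QTL position.  Lengths are max(QTL position on the
    LG, 180) cM."""
    forced: dict[str, list[float]] = {lg: [] for lg in PRESET_LGS}
    for lg, pos, _ in PRESET_QTL_TABLE:
        forced[lg].append(pos)
    lengths = [max([180.0] + forced[lg]) for lg in PRESET_LGS]
    return simulate_map(len(PRESET_LGS), list(PRESET_MARKERS_PER_LG), lengths,
                        seed=seed, lg_names=list(PRESET_LGS), forced_positions=forced)


# ------------------------------------------------------------------ founders

def simulate_founders(gmap: GeneticMap,
                      founder_ids: list[str],
                      reference_id: str,
                      block_persistence: float = 0.9,
                      diff_rate: float = 0.4,
                      seed: int = 0) -> FounderGenotypes:
    """Homozygous founder profiles with block-structured donor/reference
    differences.

    Along each linkage group, whether a donor differs from the reference
    follows a two-state Markov chain with stationary difference frequency
    ``diff_rate`` and per-marker persistence ``block_persistence``.  Columns
    where no donor differs from the reference are redrawn (independently per
    donor, conditioned on at least one difference) so that every marker
    segregates in at least one family.
    """
    if reference_id not in founder_ids:
        raise DataError("reference_id must be one of founder_ids")
    if not 0 <= block_persistence < 1:
        raise DataError("block_persistence must be in [0, 1)")
    if not 0 < diff_rate <= 1:
        raise DataError("diff_rate must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_m = gmap.n_markers
    donors = [f for f in founder_ids if f != reference_id]

    ref_calls = rng.choice([0, 2], size=n_m).astype(np.int8)
    lgs = np.asarray(gmap.linkage_groups)
    new_lg = np.ones(n_m, dtype=bool)
    new_lg[1:] = lgs[1:] != lgs[:-1]

    diff = np.empty((len(donors), n_m), dtype=bool)
    for k in range(len(donors)):
        state = False
        for j in range(n_m):
            if new_lg[j]:
                state = rng.random() < diff_rate
            else:
                if rng.random() < block_persistence:
                    pass  # persist
                else:
                    state = rng.random() < diff_rate
            diff[k, j] = state

    # enforce segregation: redraw monomorphic columns conditioned on >=1 diff
    mono = ~diff.any(axis=0)
    for j in np.flatnonzero(mono):
        col = np.zeros(len(donors), dtype=bool)
        while not col.any():
            col = rng.random(len(donors)) < diff_rate
        diff[:, j] = col

    calls = np.tile(ref_calls, (len(founder_ids), 1))
    ref_row = founder_ids.index(reference_id)
    k = 0
    for i, f in enumerate(founder_ids):
        if i == ref_row:
            continue
        calls[i] = np.where(diff[k], 2 - ref_calls, ref_calls)
        k += 1
    return FounderGenotypes(founder_ids=tuple(founder_ids), calls=calls.astype(np.int8))


# ------------------------------------------------------------------ RILs

def _meiosis(parent: np.ndarray, r_adj: np.ndarray, new_lg: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """One gamete per row of ``parent`` (shape (n, 2, n_m) haplotype pairs).

    Crossovers between adjacent markers occur with probability ``r_adj``;
    the starting haplotype on each linkage group is random.
    """
    n, _, n_m = parent.shape
    cross = rng.random((n, n_m)) < r_adj[None, :]
    cross[:, new_lg] = rng.random((n, int(new_lg.sum()))) < 0.5
    which = np.cumsum(cross, axis=1) % 2
    return np.take_along_axis(parent, which[:, None, :], axis=1)[:, 0, :]


def simulate_ril_family(donor: str,
                        reference: str,
                        n_lines: int,
                        gmap: GeneticMap,
                        generations: int | str = INFINITE,
                        seed: int = 0,
                        line_prefix: str | None = None,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Founder-origin haplotypes for one biparental RIL family.

    Returns ``origin`` of shape (n_lines, 2, n_m) with 0 = donor, 1 =
    reference per haplotype, and the marker-distance grid used.  With
    ``generations=INFINITE`` the two haplotypes are identical (fully inbred),
    drawn as a Markov chain along each linkage group with switch probability
    R = 2r/(1+2r) between adjacent markers.  Finite ``generations`` (k >= 2
    meaning selfing up to F_k) simulates the meioses explicitly, so residual
    heterozygosity remains.
    """
    if n_lines < 1:
        raise DataError("n_lines must be >= 1")
    rng = np.random.default_rng(seed)
    n_m = gmap.n_markers
    lgs = np.asarray(gmap.linkage_groups)
    new_lg = np.ones(n_m, dtype=bool)
    new_lg[1:] = lgs[1:] != lgs[:-1]
    d_adj = np.zeros(n_m)
    d_adj[1:] = np.diff(gmap.positions)
    d_adj[new_lg] = 0.0

    if generations == INFINITE:
        R = np.asarray(ril_r(d_adj))
        switch = rng.random((n_lines, n_m)) < R[None, :]
        switch[:, new_lg] = rng.random((n_lines, int(new_lg.sum()))) < 0.5
        hap = np.cumsum(switch, axis=1) % 2
        origin = np.stack([hap, hap], axis=1)
        return origin.astype(np.int8), d_adj

    if not (isinstance(generations, int) and generations >= 2):
        raise DataError("generations must be an integer >= 2 or INFINITE")
    r_adj = np.asarray(haldane_r(d_adj))
    # F1: one donor haplotype (0), one reference haplotype (1)
    plants = np.zeros((n_lines, 2, n_m), dtype=np.int8)
    plants[:, 1, :] = 1
    # selfing F1 -> F2 -> ... -> F_generations by single seed descent
    for _ in range(generations - 1):
        g1 = _meiosis(plants, r_adj, new_lg, rng)
        g2 = _meiosis(plants, r_adj, new_lg, rng)
        plants = np.stack([g1, g2], axis=1).astype(np.int8)
    return plants, d_adj


def _origin_to_genotypes(origin: np.ndarray, donor_calls: np.ndarray,
                         ref_calls: np.ndarray) -> np.ndarray:
    """Translate founder-origin haplotypes into 0/1/2 marker calls.

    Each haplotype contributes the corresponding parent's allele dose / 2;
    a missing parental call makes the line call missing.
    """
    par = np.stack([donor_calls, ref_calls])  # (2, n_m)
    allele = np.where(par == MISSING, np.nan, par / 2.0)  # allele dose 0/1
    doses = allele[origin, np.arange(origin.shape[2])[None, None, :]]
    geno = doses.sum(axis=1)
    out = np.where(np.isnan(geno), MISSING, np.rint(geno)).astype(np.int8)
    return out


def simulate_nam_population(design: NamDesign,
                            gmap: GeneticMap,
                            founders: FounderGenotypes,
                            n_per_family: int,
                            generations: int | str = INFINITE,
                            seed: int = 0) -> tuple[LineGenotypes, TruthRecord]:
    """Concatenated per-family RIL simulations.

    Per-family seeds are derived deterministically from the base seed and the
    family index, so any family can be regenerated in isolation.
    """
    fidx = {f: i for i, f in enumerate(founders.founder_ids)}
    n_f = founders.n_founders
    n_m = gmap.n_markers
    all_ids: list[str] = []
    call_blocks, origin_blocks = [], []
    for fam_no, fam in enumerate(design.families):
        fam_seed = (seed + 1000003 * (fam_no + 1)) % (2**31)
        origin, _ = simulate_ril_family(fam.donor, fam.reference, n_per_family,
                                        gmap, generations, seed=fam_seed)
        di, ri = fidx[fam.donor], fidx[fam.reference]
        calls = _origin_to_genotypes(origin, founders.calls[di], founders.calls[ri])
        cube = np.zeros((n_per_family, n_m, n_f))
        # each haplotype carries probability 0.5 of its parent of origin
        for hap in (0, 1):
            is_donor = origin[:, hap, :] == 0
            np.add.at(cube, (slice(None),), 0)  # no-op keeps shape explicit
            cube[:, :, di] += 0.5 * is_donor
            cube[:, :, ri] += 0.5 * (~is_donor)
        ids = [f"{fam.family_id}_L{k + 1:03d}" for k in range(n_per_family)]
        all_ids.extend(ids)
        call_blocks.append(calls)
        origin_blocks.append(cube)

    lines = LineGenotypes(line_ids=tuple(all_ids), calls=np.vstack(call_blocks))
    truth = TruthRecord(origin=np.concatenate(origin_blocks, axis=0),
                        line_ids=tuple(all_ids), marker_ids=gmap.marker_ids,
                        founder_ids=founders.founder_ids)
    return lines, truth


# ------------------------------------------------------------------ phenotypes

def simulate_phenotypes(lines: LineGenotypes,
                        truth: TruthRecord,
                        scenario: SimulationScenario) -> PhenotypeTable:
    """Draw plot-level phenotypes: mean + QTL contributions (from the truth
    cube) + one polygenic deviate per line + iid residual per plot."""
    rng = np.random.default_rng(scenario.seed)
    n_g = lines.n_lines
    midx = truth.marker_index()
    qtl_part = np.zeros(n_g)
    for q in scenario.qtl:
        if q.marker_id not in midx:
            raise DataError(f"QTL marker {q.marker_id!r} absent from the truth record")
        qtl_part += truth.origin[:, midx[q.marker_id], :] @ q.effects
    u = rng.normal(0.0, math.sqrt(scenario.var_polygenic), size=n_g)
    records = []
    for r in range(scenario.n_rep):
        e = rng.normal(0.0, math.sqrt(scenario.var_residual), size=n_g)
        y = scenario.mu + qtl_part + u + e
        for i, line in enumerate(lines.line_ids):
            records.append((f"P{r + 1}_{i + 1:04d}", line, "population",
                            f"rep{r + 1}", y[i]))
    df = pd.DataFrame.from_records(
        records, columns=["plot", "entry", "entry_type", "replicate", "value"])
    return PhenotypeTable(records=df)


# ------------------------------------------------------------------ preset

def preset_design() -> NamDesign:
    ref = PRESET_FOUNDERS[0]
    families = tuple(
        Family(family_id=f"F{k + 1}", donor=d, reference=ref)
        for k, d in enumerate(PRESET_FOUNDERS[1:])
    )
    return NamDesign(families=families, membership={})


def preset_qtl_specs(gmap: GeneticMap) -> tuple[QTLSpec, ...]:
    """Attach each preset QTL to the marker at its forced map position."""
    lgs = np.asarray(gmap.linkage_groups)
    specs = []
    for lg, pos, effects in PRESET_QTL_TABLE:
        on_lg = np.flatnonzero((lgs == lg) & np.isclose(gmap.positions, pos))
        if on_lg.size == 0:
            raise DataError(f"no marker at {pos} cM on {lg}")
        specs.append(QTLSpec(marker_id=gmap.marker_ids[on_lg[0]], linkage_group=lg,
                             position=pos, effects=np.asarray(effects)))
    return tuple(specs)


def preset_scenario(which: str,
                          seed: int = 0,
                          n_per_family: int = 100,
                          generations: int | str = INFINITE,
                          diff_rate: float = 0.4,
                          block_persistence: float = 0.9) -> SimulatedBundle:
    """Full simulated bundle under the study conditions.

    ``which`` is 'null' (no QTL) or 'eight_qtl' (the preset architecture).
    Five families of ``n_per_family`` RILs from one reference and five donors
    on the seven-linkage-group preset map.
    """
    if which not in ("null", "eight_qtl"):
        raise DataError("which must be 'null' or 'eight_qtl'")
    base = int(seed) % (2**31)
    gmap = preset_b_genome(seed=base)
    founders = simulate_founders(gmap, list(PRESET_FOUNDERS), PRESET_FOUNDERS[0],
                                 block_persistence=block_persistence,
                                 diff_rate=diff_rate, seed=base + 1)
    design0 = preset_design()
    lines, truth = simulate_nam_population(design0, gmap, founders, n_per_family,
                                           generations, seed=base + 2)
    membership = {}
    per_fam = lines.n_lines // len(design0.families)
    for k, fam in enumerate(design0.families):
        for line in lines.line_ids[k * per_fam:(k + 1) * per_fam]:
            membership[line] = fam.family_id
    design = NamDesign(families=design0.families, membership=membership)

    qtl = preset_qtl_specs(gmap) if which == "eight_qtl" else ()
    scenario = SimulationScenario(qtl=qtl, seed=base + 3)
    phenotypes = simulate_phenotypes(lines, truth, scenario)
    return SimulatedBundle(gmap=gmap, founders=founders, design=design, lines=lines,
                           truth=truth, phenotypes=phenotypes, scenario=scenario)
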