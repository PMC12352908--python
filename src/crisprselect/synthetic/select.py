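"""Simulator for CRISPR knock-in selection experiments.

A cell population is modeled as a mixture of diploid genotypes, each
with two allele outcomes (Mut knock-in, WT* knock-in, unedited, or an
InDel at the cut site) and genotype-specific per-day growth multipliers
with and without drug. Growth is discrete daily multiplicative update;
amplicon reads sample alleles independently from pooled genomic DNA
(reads cannot phase the two alleles of one cell), with optional uniform
per-base substitution errors.

The returned :class:`SimTruth` carries the closed-form expectation of
the baseline-normalized Mut:WT* ratio

    R(t, condition) = [f_Mut/f_WT*](t, condition) / [f_Mut/f_WT*](baseline)

against which classifier and statistic recovery are tested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ..amplicon import AmpliconDesign
from ..classify import INDEL, MUT_KI, OutcomeTable, UNEDITED, WTSTAR_KI

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

UNTREATED = "untreated"
TREATED = "treated"

DEFAULT_BASELINE_DAY = 2
DEFAULT_ENDPOINT_DAY = 12
DEFAULT_QUALITY_CHAR = chr(33 + 37)  # constant Q37


@dataclass(frozen=True)
class Allele:
    """One allele outcome; ``indel`` is (position, net_length) for INDEL."""

    kind: str  # MUT_KI | WTSTAR_KI | UNEDITED | INDEL
    indel: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.kind == INDEL:
            if self.indel is None or self.indel[1] == 0:
                raise ValueError("INDEL allele requires (position, net_length != 0)")
        elif self.indel is not None:
            raise ValueError(f"{self.kind} allele cannot carry an indel")


@dataclass(frozen=True)
class GenotypeSpec:
    """Diploid genotype with per-day growth multipliers.

    ``cisplatin_fitness`` applies on days inside the treatment window of
    the treated condition; ``base_fitness`` applies otherwise.
    """

    allele1: Allele
    allele2: Allele
    base_fitness: float = 1.0
    cisplatin_fitness: float | None = None

    def __post_init__(self) -> None:
        for w in (self.base_fitness, self.cisplatin_fitness):
            if w is not None and not (np.isfinite(w) and w >= 0):
                raise ValueError("fitness multipliers must be finite and >= 0")

    @property
    def drug_fitness(self) -> float:
        return self.base_fitness if self.cisplatin_fitness is None else self.cisplatin_fitness


def allele_sequence(design: AmpliconDesign, allele: Allele) -> str:
    """Amplicon sequence carried by one allele."""
    if allele.kind == MUT_KI:
        return design.mut_sequence
    if allele.kind == WTSTAR_KI:
        return design.wtstar_sequence
    if allele.kind == UNEDITED:
        return design.reference
    pos, net = allele.indel  # type: ignore[misc]
    ref = design.reference
    if net < 0:
        return ref[:pos] + ref[pos - net:]
    # insertion: pick bases differing from both flanks so the event
    # anchors unambiguously in the alignment
    flanks = {ref[pos - 1] if pos > 0 else "", ref[pos] if pos < len(ref) else ""}
    base = next(b for b in "ACGT" if b not in flanks)
    return ref[:pos] + base * net + ref[pos:]


ALLELE_CATEGORY = {MUT_KI: MUT_KI, WTSTAR_KI: WTSTAR_KI, UNEDITED: UNEDITED, INDEL: INDEL}


@dataclass
class SimTruth:
    """Ground truth of one simulated selection experiment."""

    baseline_day: int
    timepoints: tuple[int, ...]
    conditions: tuple[str, ...]
    genotype_frequencies: dict  # (day, condition) -> {genotype index: frequency}
    allele_fractions: dict  # (day, condition) -> {allele key: fraction}
    expected_ratio: dict  # (day, condition) -> E[f_Mut]/E[f_WT*]
    expected_R: dict  # (day, condition) -> normalized ratio
    seed: int | None = None
    genotypes: tuple[GenotypeSpec, ...] = ()

    def to_json(self, path: str | Path) -> None:
        def keyed(d):
            return {f"{day}:{cond}": v for (day, cond), v in d.items()}

        payload = {
            "baseline_day": self.baseline_day,
            "timepoints": list(self.timepoints),
            "conditions": list(self.conditions),
            "genotype_frequencies": keyed(
                {k: {str(i): f for i, f in v.items()} for k, v in self.genotype_frequencies.items()}
            ),
            "allele_fractions": keyed(
                {k: {str(a): f for a, f in v.items()} for k, v in self.allele_fractions.items()}
            ),
            "expected_ratio": keyed(self.expected_ratio),
            "expected_R": keyed(self.expected_R),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _daily_multiplier(
    g: GenotypeSpec, day: int, condition: str, window: tuple[int, int]
) -> float:
    if condition == TREATED and window[0] < day <= window[1]:
        return g.drug_fitness
    return g.base_fitness


def _genotype_masses(
    genotypes: Sequence[GenotypeSpec],
    freq0: np.ndarray,
    day: int,
    condition: str,
    window: tuple[int, int],
) -> np.ndarray:
    mass = np.array(
        [
            f0 * np.prod([_daily_multiplier(g, t, condition, window) for t in range(1, day + 1)])
            for g, f0 in zip(genotypes, freq0)
        ]
    )
    total = mass.sum()
    if total == 0:
        raise ValueError(f"population extinct at day {day} ({condition})")
    return mass / total


def _allele_key(a: Allele) -> tuple:
    return (a.kind, a.indel or (-1, 0))


def _allele_fractions(
    genotypes: Sequence[GenotypeSpec], genotype_freq: np.ndarray
) -> dict[tuple, float]:
    fractions: dict[tuple, float] = {}
    for g, f in zip(genotypes, genotype_freq):
        for a in (g.allele1, g.allele2):
            key = _allele_key(a)
            fractions[key] = fractions.get(key, 0.0) + 0.5 * f
    return fractions


def _category_fraction(fractions: Mapping[tuple, float], category: str) -> float:
    return sum(f for (kind, _), f in fractions.items() if kind == category)


def compute_truth(
    genotype_mix: Mapping[GenotypeSpec, float],
    timepoints: Sequence[int],
    conditions: Sequence[str],
    treatment_window: tuple[int, int],
    baseline_day: int,
    seed: int | None = None,
) -> SimTruth:
    genotypes = tuple(genotype_mix.keys())
    freq0 = np.array([genotype_mix[g] for g in genotypes], dtype=float)
    if abs(freq0.sum() - 1.0) > 1e-9:
        raise ValueError(f"genotype frequencies sum to {freq0.sum()}, not 1")
    if baseline_day not in timepoints:
        raise ValueError(f"baseline day {baseline_day} missing from timepoints")

    genotype_frequencies, allele_fractions, ratio, normR = {}, {}, {}, {}
    for cond in conditions:
        for day in timepoints:
            gf = _genotype_masses(genotypes, freq0, day, cond, treatment_window)
            af = _allele_fractions(genotypes, gf)
            genotype_frequencies[(day, cond)] = dict(enumerate(gf))
            allele_fractions[(day, cond)] = af
            f_mut = _category_fraction(af, MUT_KI)
            f_wts = _category_fraction(af, WTSTAR_KI)
            ratio[(day, cond)] = f_mut / f_wts if f_wts > 0 else float("nan")
    for cond in conditions:
        base = ratio[(baseline_day, cond)]
        for day in timepoints:
            normR[(day, cond)] = ratio[(day, cond)] / base
    return SimTruth(
        baseline_day=baseline_day,
        timepoints=tuple(timepoints),
        conditions=tuple(conditions),
        genotype_frequencies=genotype_frequencies,
        allele_fractions=allele_fractions,
        expected_ratio=ratio,
        expected_R=normR,
        seed=seed,
        genotypes=genotypes,
    )


def _deterministic_counts(fractions: np.ndarray, depth: int) -> np.ndarray:
    """Largest-remainder rounding of depth * fractions to integers."""
    raw = fractions * depth
    counts = np.floor(raw).astype(int)
    short = depth - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def _mutate_reads(seq: str, n: int, error_rate: float, rng: np.random.Generator) -> list[str]:
    arr = np.tile(np.frombuffer(seq.encode(), dtype=np.uint8), (n, 1))
    if error_rate > 0:
        mask = rng.random(arr.shape) < error_rate
        k = int(mask.sum())
        if k:
            idx = _BASE_INDEX[arr[mask]]
            arr[mask] = BASES[(idx + rng.integers(1, 4, size=k)) % 4]
    return [row.tobytes().decode() for row in arr]


def simulate_select_experiment(
    design: AmpliconDesign,
    genotype_mix: Mapping[GenotypeSpec, float],
    out_dir: str | Path,
    timepoints: Sequence[int] = (DEFAULT_BASELINE_DAY, DEFAULT_ENDPOINT_DAY),
    conditions: Sequence[str] = (UNTREATED, TREATED),
    treatment_window: tuple[int, int] = (DEFAULT_BASELINE_DAY, DEFAULT_ENDPOINT_DAY),
    depth: int = 5000,
    error_rate: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
    deterministic: bool = False,
    baseline_day: int | None = None,
) -> tuple[dict[tuple[int, str, int], Path], SimTruth]:
    """Simulate an experiment and write one FASTQ per sample.

    Returns a map (timepoint, condition, replicate) -> FASTQ path, and
    the ground truth. Byte-identical output for identical arguments.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not (0 <= error_rate < 1):
        raise ValueError("error_rate must be in [0,1)")
    baseline_day = timepoints[0] if baseline_day is None else baseline_day
    truth = compute_truth(
        genotype_mix, timepoints, conditions, treatment_window, baseline_day, seed=seed
    )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    allele_seqs: dict[tuple, str] = {}
    for g in truth.genotypes:
        for a in (g.allele1, g.allele2):
            allele_seqs.setdefault(_allele_key(a), allele_sequence(design, a))

    paths: dict[tuple[int, str, int], Path] = {}
    for cond in truth.conditions:
        for day in truth.timepoints:
            fractions = truth.allele_fractions[(day, cond)]
            keys = sorted(fractions)
            frac = np.array([fractions[k] for k in keys])
            for rep in range(1, replicates + 1):
                if deterministic:
                    counts = _deterministic_counts(frac, depth)
                else:
                    counts = rng.multinomial(depth, frac / frac.sum())
                path = out_dir / f"{design.name}_{cond}_D{day}_rep{rep}.fastq"
                with open(path, "w") as fh:
                    i = 0
                    for key, n in zip(keys, counts):
                        if n == 0:
                            continue
                        for read in _mutate_reads(allele_seqs[key], int(n), error_rate, rng):
                            fh.write(
                                f"@{design.name}:{cond}:D{day}:rep{rep}:{i}\n{read}\n"
                                f"+\n{DEFAULT_QUALITY_CHAR * len(read)}\n"
                            )
                            i += 1
                paths[(day, cond, rep)] = path
    return paths, truth


def simulate_select_counts(
    genotype_mix: Mapping[GenotypeSpec, float],
    timepoints: Sequence[int] = (DEFAULT_BASELINE_DAY, DEFAULT_ENDPOINT_DAY),
    conditions: Sequence[str] = (UNTREATED, TREATED),
    treatment_window: tuple[int, int] = (DEFAULT_BASELINE_DAY, DEFAULT_ENDPOINT_DAY),
    depth: int = 5000,
    replicates: int = 3,
    seed: int = 0,
    deterministic: bool = False,
    baseline_day: int | None = None,
) -> tuple[list[OutcomeTable], SimTruth]:
    """Count-level shortcut: sample outcome tables directly from truth.

    Equivalent to error-free simulation followed by perfect
    classification; used where only sampling noise matters (e.g. type-I
    error studies of the replicate tests).
    """
    baseline_day = timepoints[0] if baseline_day is None else baseline_day
    truth = compute_truth(
        genotype_mix, timepoints, conditions, treatment_window, baseline_day, seed=seed
    )
    rng = np.random.default_rng(seed)
    tables: list[OutcomeTable] = []
    for cond in truth.conditions:
        for day in truth.timepoints:
            fractions = truth.allele_fractions[(day, cond)]
            keys = sorted(fractions)
            frac = np.array([fractions[k] for k in keys])
            for rep in range(1, replicates + 1):
                if deterministic:
                    counts = _deterministic_counts(frac, depth)
                else:
                    counts = rng.multinomial(depth, frac / frac.sum())
                table = OutcomeTable(timepoint=day, condition=cond, replicate=rep)
                for (kind, indel), n in zip(keys, counts):
                    table.counts[kind] += int(n)
                    if kind == INDEL:
                        table.indel_strata[("frameshift", "exonic")] = (
                            table.indel_strata.get(("frameshift", "exonic"), 0) + int(n)
                        )
                tables.append(table)
    return tables, truth


def standard_select_mix(
    design: AmpliconDesign,
    mut_base_fitness: float = 1.0,
    mut_cisplatin_fitness: float = 1.0,
    indel_base_fitness: float = 1.0,
    indel_cisplatin_fitness: float | None = None,
    intron_guide: bool = False,
) -> dict[GenotypeSpec, float]:
    """Default genotype mixture for a knock-in selection experiment.

    Mirrors the dominant editing outcomes of the assay: knock-in on one
    allele paired with a cut-site InDel on the other, plus InDel/InDel
    and partially edited cells; 82% of alleles are modified. For
    intron-targeting guides the second-allele InDel falls in the intron
    (single-allele editing); for exon guides it is a coding frameshift.
    """
    offset = 1 if intron_guide else -1
    indel_pos = design.cut_site + (2 if intron_guide else -2)
    indel_pos = max(1, min(len(design) - 2, indel_pos))
    fs = Allele(INDEL, (indel_pos, offset))
    mut, wts, wt = Allele(MUT_KI), Allele(WTSTAR_KI), Allele(UNEDITED)
    ind = GenotypeSpec  # alias
    mix = {
        ind(mut, fs, mut_base_fitness, mut_cisplatin_fitness): 0.18,
        ind(wts, fs, 1.0, 1.0): 0.18,
        ind(fs, fs, indel_base_fitness, indel_cisplatin_fitness): 0.38,
        ind(wt, fs, 1.0, 1.0): 0.16,
        ind(wt, wt, 1.0, 1.0): 0.10,
    }
    return mix


def modified_allele_fraction(genotype_mix: Mapping[GenotypeSpec, float]) -> float:
    """Fraction of alleles carrying any edit at time zero."""
    total = 0.0
    for g, f in genotype_mix.items():
        for a in (g.allele1, g.allele2):
            if a.kind != UNEDITED:
                total += 0.5 * f
    return total
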