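"""Synthetic selection + sequencing simulator.

Generates ground-truth fitness landscapes over a saturation library,
applies positive / negative selection as a one-step exponential tilt of the
variant frequency vector, and emits barcoded Illumina-style paired-end reads
so the whole analysis pipeline can be exercised without real data.

Model
-----
Each variant ``v`` has a multiplicative true fitness

    w(v) = prod_i pref[i][v_i] * prod_{i<j} coup[(i, v_i), (j, v_j)]

with the wild-type base preference fixed at 1 per position, so w(WT) = 1
whenever no coupling involves wild-type pairs.  Selection reweights the
current frequency vector:

    positive:    freq' ∝ freq * w**s_pos
    negative:    freq' ∝ freq * w**(-s_neg)
    unselected:  freq' = freq

collapsing the study's serial growth-competition + FACS sort into a single
tunable tilt per arm.  Sequencing draws reads multinomially from the
post-selection frequencies and applies independent per-base substitution
errors (no indels).
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

from .designs import (
    CONDITIONS,
    RNA_BASES,
    BarcodeScheme,
    LibraryDesign,
    reverse_complement,
    rna_to_dna,
)

_BASE_INDEX = {b: i for i, b in enumerate(RNA_BASES)}
# fixed per-condition stream indices for child-seed derivation
_CONDITION_INDEX = {c: i for i, c in enumerate(CONDITIONS)}

READ_LENGTH = 150
_DNA = "ACGT"


def variant_index_matrix(design: LibraryDesign) -> np.ndarray:
    """(4**k, k) matrix of base indices (A=0,C=1,G=2,U=3), rows in the
    lexicographic order of :meth:`LibraryDesign.variants`."""
    n, k = design.diversity, design.k
    powers = 4 ** np.arange(k - 1, -1, -1)
    return (np.arange(n)[:, None] // powers) % 4


@dataclass
class TruthModel:
    """Ground-truth multiplicative fitness landscape.

    ``prefs[position][base]`` holds the per-position preference of each base
    (wild-type base 1 by convention); ``couplings`` maps pairs of
    (position, base) to a multiplicative interaction factor (1 = none).
    """

    design: LibraryDesign
    prefs: dict[int, dict[str, float]]
    couplings: dict[tuple[tuple[int, str], tuple[int, str]], float] = field(
        default_factory=dict
    )
    s_pos: float = 1.0
    s_neg: float = 1.0

    def __post_init__(self) -> None:
        for pos in self.design.positions:
            row = self.prefs.get(pos)
            if row is None:
                raise ValueError(f"missing preference row for position {pos}")
            for base in RNA_BASES:
                if base not in row:
                    raise ValueError(f"missing preference for {base}{pos}")
                if row[base] <= 0:
                    raise ValueError("preferences must be positive")
        for pair, c in self.couplings.items():
            if c <= 0:
                raise ValueError("couplings must be positive")
            (pa, _), (pb, _) = pair
            if pa == pb:
                raise ValueError("coupling must join two distinct positions")

    def true_fitness(self, variant: str) -> float:
        """w(v): product of per-position preferences and pairwise couplings."""
        d = self.design
        if len(variant) != d.k:
            raise ValueError("variant length does not match design")
        w = 1.0
        for pos, base in zip(d.positions, variant):
            w *= self.prefs[pos][base]
        for ((pa, ba), (pb, bb)), c in self.couplings.items():
            if variant[d.position_index(pa)] == ba and variant[d.position_index(pb)] == bb:
                w *= c
        return w

    def fitness_vector(self) -> np.ndarray:
        """w over all 4**k variants, aligned with design.variants() order."""
        d = self.design
        idx = variant_index_matrix(d)
        logw = np.zeros(d.diversity)
        for col, pos in enumerate(d.positions):
            row = np.array([math.log(self.prefs[pos][b]) for b in RNA_BASES])
            logw += row[idx[:, col]]
        for ((pa, ba), (pb, bb)), c in self.couplings.items():
            ca, cb = d.position_index(pa), d.position_index(pb)
            mask = (idx[:, ca] == _BASE_INDEX[ba]) & (idx[:, cb] == _BASE_INDEX[bb])
            logw[mask] += math.log(c)
        return np.exp(logw)


@dataclass
class SimulatedExperiment:
    """A complete in silico selection + sequencing experiment."""

    design: LibraryDesign
    truth: TruthModel
    depth_per_condition: int
    error_rate: float = 0.0
    seed: int = 0
    initial_frequencies: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.design.diversity
        if self.initial_frequencies is None:
            self.initial_frequencies = np.full(n, 1.0 / n)
        else:
            f = np.asarray(self.initial_frequencies, dtype=float)
            if f.shape != (n,) or (f < 0).any():
                raise ValueError("initial_frequencies must be a nonnegative 4**k vector")
            if abs(f.sum() - 1.0) > 1e-9:
                raise ValueError("initial_frequencies must sum to 1")
            self.initial_frequencies = f
        if self.depth_per_condition < 0:
            raise ValueError("depth must be >= 0")
        if not 0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must be in [0, 0.25)")

    @classmethod
    def with_depth_per_variant(
        cls, design, truth, depth_per_variant, **kwargs
    ) -> "SimulatedExperiment":
        return cls(
            design=design,
            truth=truth,
            depth_per_condition=int(depth_per_variant) * design.diversity,
            **kwargs,
        )

    def condition_rng(self, condition: str, stream: int = 0) -> np.random.Generator:
        """Independent, reproducible random stream per condition.

        ``stream`` separates the sampling draw (0) from the sequencing-error
        draw (1) so both are deterministic functions of (seed, condition).
        """
        return np.random.default_rng(
            np.random.SeedSequence(
                [int(self.seed), _CONDITION_INDEX[condition], int(stream)]
            )
        )


def apply_selection(experiment: SimulatedExperiment, condition: str) -> np.ndarray:
    """Post-selection frequency vector for one condition (sums to 1)."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    freq = experiment.initial_frequencies
    if condition == "unselected":
        return freq.copy()
    w = experiment.truth.fitness_vector()
    s = experiment.truth.s_pos if condition == "positive" else -experiment.truth.s_neg
    # tilt in log space to avoid under/overflow with extreme fitness values
    logmass = np.where(freq > 0, np.log(np.where(freq > 0, freq, 1.0)), -np.inf)
    logmass = logmass + s * np.log(w)
    m = logmass.max()
    if not np.isfinite(m):
        raise ValueError("selection removed all mass from the library")
    mass = np.exp(logmass - m)
    return mass / mass.sum()


def sample_variant_counts(
    experiment: SimulatedExperiment, condition: str
) -> np.ndarray:
    """Multinomial read counts per variant for one condition."""
    freq = apply_selection(experiment, condition)
    rng = experiment.condition_rng(condition)
    return rng.multinomial(experiment.depth_per_condition, freq)


def _amplicon(design: LibraryDesign, scheme: BarcodeScheme, condition: str,
              variant: str) -> str:
    fwd, rev = scheme.forward(condition), scheme.reverse(condition)
    return (
        fwd
        + design.upstream_anchor
        + rna_to_dna(variant)
        + design.downstream_anchor
        + reverse_complement(rev)
    )


def sample_reads(
    experiment: SimulatedExperiment,
    condition: str,
    scheme: BarcodeScheme,
) -> Iterator[tuple[str, str, str, str, str]]:
    """Simulated read pairs for one condition.

    Yields ``(read_id, seq1, qual1, seq2, qual2)`` tuples.  R1 starts with
    the condition's forward barcode, R2 with the reverse barcode; both mates
    cover the full amplicon (barcode, anchor, window, anchor).  Per-base
    substitution errors are applied at ``experiment.error_rate``.  Output is
    deterministic for a fixed experiment seed.
    """
    design = experiment.design
    counts = sample_variant_counts(experiment, condition)
    rng = experiment.condition_rng(condition, stream=1)
    err = experiment.error_rate
    serial = 0
    for variant, n in zip(design.variants(), counts):
        if n == 0:
            continue
        amplicon = _amplicon(design, scheme, condition, variant)
        r1 = amplicon[:READ_LENGTH]
        r2 = reverse_complement(amplicon)[:READ_LENGTH]
        q1, q2 = "I" * len(r1), "I" * len(r2)
        if err > 0:
            n_err = rng.binomial(len(r1) + len(r2), err, size=n)
        else:
            n_err = np.zeros(n, dtype=int)
        for i in range(n):
            serial += 1
            rid = f"sim:{condition}:{serial}"
            if n_err[i] == 0:
                yield rid, r1, q1, r2, q2
            else:
                s1, s2 = _corrupt(r1, r2, int(n_err[i]), rng)
                yield rid, s1, q1, s2, q2


def _corrupt(r1: str, r2: str, n_err: int, rng: np.random.Generator):
    l1 = len(r1)
    merged = list(r1 + r2)
    for pos in rng.choice(len(merged), size=n_err, replace=False):
        old = merged[pos]
        choices = [b for b in _DNA if b != old]
        merged[pos] = choices[rng.integers(3)]
    joined = "".join(merged)
    return joined[:l1], joined[l1:]


def write_fastq(
    experiment: SimulatedExperiment,
    scheme: BarcodeScheme,
    outdir,
    conditions=CONDITIONS,
    compress: bool = False,
) -> dict[str, tuple[Path, Path]]:
    """Write one R1/R2 FASTQ pair per condition; returns the paths.

    Also writes ``truth.tsv`` (variant, true_fitness) and ``experiment.json``
    (full simulation parameters) for provenance.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = ".fastq.gz" if compress else ".fastq"
    opener = (lambda p: gzip.open(p, "wt")) if compress else (lambda p: open(p, "w"))
    paths: dict[str, tuple[Path, Path]] = {}
    for cond in conditions:
        p1 = outdir / f"{cond}_R1{suffix}"
        p2 = outdir / f"{cond}_R2{suffix}"
        with opener(p1) as f1, opener(p2) as f2:
            for rid, s1, q1, s2, q2 in sample_reads(experiment, cond, scheme):
                f1.write(f"@{rid}/1\n{s1}\n+\n{q1}\n")
                f2.write(f"@{rid}/2\n{s2}\n+\n{q2}\n")
        paths[cond] = (p1, p2)
    w = experiment.truth.fitness_vector()
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("variant\ttrue_fitness\n")
        for v, wi in zip(experiment.design.variants(), w):
            fh.write(f"{v}\t{wi:.10g}\n")
    with open(outdir / "experiment.json", "w") as fh:
        json.dump(experiment_config(experiment), fh, indent=2)
    return paths


def experiment_config(experiment: SimulatedExperiment) -> dict:
    """JSON-serializable record of all simulation parameters."""
    t = experiment.truth
    return {
        "region_id": experiment.design.region_id,
        "depth_per_condition": experiment.depth_per_condition,
        "error_rate": experiment.error_rate,
        "seed": int(experiment.seed),
        "s_pos": t.s_pos,
        "s_neg": t.s_neg,
        "prefs": {str(p): dict(row) for p, row in t.prefs.items()},
        "couplings": [
            {"a": [pa, ba], "b": [pb, bb], "value": c}
            for ((pa, ba), (pb, bb)), c in t.couplings.items()
        ],
        "initial_frequencies": "uniform"
        if np.allclose(
            experiment.initial_frequencies,
            1.0 / experiment.design.diversity,
        )
        else [float(x) for x in experiment.initial_frequencies],
    }


# ---------------------------------------------------------------------------
# Truth-model factories


def neutral_truth(design: LibraryDesign, s_pos: float = 1.0, s_neg: float = 1.0) -> TruthModel:
    """All preferences 1 (no selection signal)."""
    prefs = {pos: {b: 1.0 for b in RNA_BASES} for pos in design.positions}
    return TruthModel(design, prefs, s_pos=s_pos, s_neg=s_neg)


def lethal_position_truth(
    design: LibraryDesign,
    position: int,
    lethal_pref: float = 1e-6,
) -> TruthModel:
    """Every non-WT base at ``position`` lethal; all other positions neutral."""
    truth = neutral_truth(design)
    wt_base = design.wt_bases[design.position_index(position)]
    for b in RNA_BASES:
        if b != wt_base:
            truth.prefs[position][b] = lethal_pref
    return truth


# Scattered-severity preferences used by the recovery benchmark: per window
# position, the preferences of the three non-WT bases in alphabetical order.
# A few bases are severely deleterious (distinct severities, distinct
# positions); the rest carry graded mild-to-moderate costs.  This emulates a
# library in which single bases are strongly disfavored but no position is
# uniformly lethal.
_BENCHMARK_ROWS = (
    (2e-4, 0.45, 0.70),
    (1.5e-3, 0.60, 0.85),
    (0.25, 8e-3, 0.90),
    (0.15, 0.55, 0.80),
    (0.50, 0.35, 0.75),
    (0.65, 0.30, 0.85),
)


def benchmark_truth(design: LibraryDesign, s_pos: float = 1.0, s_neg: float = 1.0) -> TruthModel:
    """Fixed scattered-severity landscape used for parameter-recovery checks."""
    prefs = {}
    for i, pos in enumerate(design.positions):
        wt_base = design.wt_bases[i]
        row = {wt_base: 1.0}
        others = [b for b in RNA_BASES if b != wt_base]
        for b, val in zip(others, _BENCHMARK_ROWS[i % len(_BENCHMARK_ROWS)]):
            row[b] = val
        prefs[pos] = row
    return TruthModel(design, prefs, s_pos=s_pos, s_neg=s_neg)


def mild_truth(
    design: LibraryDesign,
    seed: int = 7,
    low: float = 0.85,
    high: float = 1.0,
) -> TruthModel:
    """Weak-effect multiplicative landscape (non-WT prefs ~ U(low, high)).

    In this regime the enrichment-ratio fitness is approximately affine in
    log fitness, so the multiplicative epistasis null should hold to second
    order; used by the epistasis null checks.
    """
    rng = np.random.default_rng(seed)
    prefs = {}
    for i, pos in enumerate(design.positions):
        wt_base = design.wt_bases[i]
        row = {b: float(rng.uniform(low, high)) for b in RNA_BASES}
        row[wt_base] = 1.0
        prefs[pos] = row
    return TruthModel(design, prefs)


def coupled_truth(
    design: LibraryDesign,
    pair_a: tuple[int, str],
    pair_b: tuple[int, str],
    coupling: float,
    base_truth: TruthModel | None = None,
) -> TruthModel:
    """Plant a single pairwise coupling on top of a base landscape."""
    base = base_truth if base_truth is not None else neutral_truth(design)
    couplings = dict(base.couplings)
    couplings[(pair_a, pair_b)] = coupling
    return TruthModel(
        design, {p: dict(r) for p, r in base.prefs.items()}, couplings,
        s_pos=base.s_pos, s_neg=base.s_neg,
    )


def skewed_initial_frequencies(
    design: LibraryDesign, seed: int = 0, concentration: float = 2.0
) -> np.ndarray:
    """Dirichlet-skewed naive library composition (biased cloning)."""
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.full(design.diversity, concentration))
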