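"""End-to-end orchestration: simulate -> count -> fitness -> landscape ->
epistasis, with a serializable run configuration and a reproducibility
manifest.  The CLI in :mod:`ptcscape.cli` is a thin wrapper over this
module; everything here is equally callable from Python.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import spearmanr

from . import __version__
from .designs import BarcodeScheme, LibraryDesign, builtin_barcodes, get_design
from .epistasis import epistasis_pipeline
from .fitness import fitness_pipeline, write_fitness_tsv
from .landscape import (
    pairwise_long,
    pairwise_map,
    position_profiles,
    structure_annotation,
)
from .reads import VariantCountTable, count_fastq, count_variants
from .simulate import SimulatedExperiment, TruthModel, sample_reads


@dataclass
class RunConfig:
    """All tunable stage parameters with their defaults, serializable."""

    region_id: str = "2058-2062"
    seed: int = 0
    # simulation
    depth_per_variant: int = 200
    error_rate: float = 0.001
    s_pos: float = 1.0
    s_neg: float = 1.0
    # read processing
    min_mean_q: float = 20.0
    barcode_mismatch: int = 1
    anchor_mismatch: int = 1
    swap_mates: bool = False
    # fitness
    pseudocount: float = 0.5
    abundance_unit: str = "frequency"
    convention: str = "oriented"
    denom_tol: float = 1e-6
    sd_ddof: int = 0
    # landscape
    score: str = "enrich_pos"
    prob_mode: str = "positive_part"
    softmax_tau: float = 1.0
    low_cut: float = 0.3
    high_cut: float = 1.3
    # epistasis
    epistasis_scale: str = "unit_interval"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {k: raw[k] for k in raw if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class AnalysisResult:
    """Bundle of every stage's output for one library."""

    design: LibraryDesign
    counts: VariantCountTable
    fitness: pd.DataFrame
    profiles: pd.DataFrame
    pairwise: pd.DataFrame
    epistasis: pd.DataFrame
    recovery: dict = field(default_factory=dict)


def analyze_counts(
    table: VariantCountTable, design: LibraryDesign, config: RunConfig | None = None
) -> AnalysisResult:
    """Count table -> fitness, profiles, pairwise map, epistasis."""
    cfg = config or RunConfig(region_id=design.region_id)
    ft = fitness_pipeline(
        table,
        design,
        pseudocount=cfg.pseudocount,
        unit=cfg.abundance_unit,
        convention=cfg.convention,
        denom_tol=cfg.denom_tol,
        ddof=cfg.sd_ddof,
    )
    profiles = position_profiles(
        ft,
        design,
        score=cfg.score,
        mode=cfg.prob_mode,
        tau=cfg.softmax_tau,
        low_cut=cfg.low_cut,
        high_cut=cfg.high_cut,
    )
    pw = pairwise_long(pairwise_map(ft, design, score=cfg.score))
    em = epistasis_pipeline(ft, design, mode=cfg.epistasis_scale)
    return AnalysisResult(
        design=design, counts=table, fitness=ft,
        profiles=profiles, pairwise=pw, epistasis=em,
    )


def analyze_fastq(
    fastq_pairs, design: LibraryDesign, scheme: BarcodeScheme | None = None,
    config: RunConfig | None = None,
) -> AnalysisResult:
    """FASTQ (R1, R2) path pairs -> full analysis."""
    cfg = config or RunConfig(region_id=design.region_id)
    table = count_fastq(
        fastq_pairs,
        design,
        scheme or builtin_barcodes(),
        min_mean_q=cfg.min_mean_q,
        barcode_mismatch=cfg.barcode_mismatch,
        anchor_mismatch=cfg.anchor_mismatch,
        swap_mates=cfg.swap_mates,
    )
    return analyze_counts(table, design, cfg)


def simulate_and_analyze(
    truth: TruthModel,
    config: RunConfig | None = None,
    initial_frequencies=None,
) -> AnalysisResult:
    """Full in-memory round trip: simulated reads -> analysis -> recovery.

    The simulated read pairs are streamed straight into the counting
    pipeline (no files); the result's ``recovery`` dict reports Spearman
    rank correlation between the inferred z-fitness and log true fitness.
    """
    design = truth.design
    cfg = config or RunConfig(region_id=design.region_id)
    truth.s_pos, truth.s_neg = cfg.s_pos, cfg.s_neg
    exp = SimulatedExperiment.with_depth_per_variant(
        design,
        truth,
        cfg.depth_per_variant,
        error_rate=cfg.error_rate,
        seed=cfg.seed,
        initial_frequencies=initial_frequencies,
    )
    scheme = builtin_barcodes()

    def stream():
        for cond in ("positive", "negative", "unselected"):
            yield from sample_reads(exp, cond, scheme)

    table = count_variants(
        stream(),
        design,
        scheme,
        min_mean_q=cfg.min_mean_q,
        barcode_mismatch=cfg.barcode_mismatch,
        anchor_mismatch=cfg.anchor_mismatch,
    )
    result = analyze_counts(table, design, cfg)
    w = truth.fitness_vector()
    z = result.fitness["z"].to_numpy(dtype=float)
    ok = ~np.isnan(z)
    rho = spearmanr(z[ok], np.log(w[ok])).statistic if ok.sum() > 2 else float("nan")
    result.recovery = {
        "spearman_z_vs_log_fitness": float(rho),
        "n_variants_scored": int(ok.sum()),
        "n_variants_total": int(design.diversity),
    }
    return result


def manifest(config: RunConfig, extra: dict | None = None) -> dict:
    """Reproducibility record: package version, platform, full config."""
    record = {
        "package": "ptcscape",
        "version": __version__,
        "python": platform.python_version(),
        "config": config.to_dict(),
    }
    if extra:
        record.update(extra)
    return record


def write_results(result: AnalysisResult, outdir, config: RunConfig | None = None) -> dict:
    """Write every stage's tables plus a markdown report and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config or RunConfig(region_id=result.design.region_id)
    result.counts.to_tsv(outdir / "counts.tsv")
    write_fitness_tsv(result.fitness, outdir / "fitness.tsv")
    result.profiles.to_csv(outdir / "profiles.tsv", sep="\t")
    result.pairwise.to_csv(outdir / "pairwise.tsv", sep="\t", index=False)
    result.epistasis.to_csv(outdir / "epistasis.tsv", sep="\t", index=False)
    structure_annotation(result.profiles).to_csv(
        outdir / "structure_annotation.tsv", sep="\t", index=False
    )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest(cfg, {"tallies": result.counts.tallies}), fh, indent=2)
    report = _markdown_report(result, cfg)
    (outdir / "report.md").write_text(report)
    return {"outdir": str(outdir)}


def _markdown_report(result: AnalysisResult, cfg: RunConfig) -> str:
    t = result.counts
    ft = result.fitness
    lines = [
        f"# ptcscape report: library {result.design.region_id}",
        "",
        "## Read accounting",
        f"- reads in: {t.reads_in}",
    ]
    for cond, n in t.totals.items():
        lines.append(f"- counted ({cond}): {n}")
    for key, n in t.tallies.items():
        lines.append(f"- discarded ({key}): {n}")
    lines += [
        "",
        "## Fitness",
        f"- convention: {ft.attrs.get('convention')}",
        f"- mean / SD used for z: {ft.attrs.get('mu_f'):.4g} / {ft.attrs.get('sigma_f'):.4g}",
        f"- normality (skewness, excess kurtosis): "
        f"{ft.attrs.get('skewness'):.3f}, {ft.attrs.get('excess_kurtosis'):.3f}",
        f"- missing fitness values: {int(ft['f'].isna().sum())}",
        "",
        "## Mutational flexibility (Shannon entropy, bits)",
    ]
    for pos, row in result.profiles.iterrows():
        lines.append(
            f"- {pos}: H = {row['entropy_bits']:.3f} ({row['flexibility']})"
        )
    em = result.epistasis
    lines += [
        "",
        "## Epistasis",
        f"- pairs: {len(em)} (missing: {int(em['eps_raw'].isna().sum())})",
        f"- scale mode: {em.attrs.get('scale_mode')}",
    ]
    if result.recovery:
        lines += ["", "## Simulation recovery"]
        for k, v in result.recovery.items():
            lines.append(f"- {k}: {v}")
    return "\n".join(lines) + "\n"


def load_truth_config(path, design: LibraryDesign) -> TruthModel:
    """Read a truth model from YAML/JSON: prefs {position: {base: value}},
    optional couplings [{a: [pos, base], b: [pos, base], value: v}]."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    prefs = {
        int(pos): {b: float(x) for b, x in row.items()}
        for pos, row in raw["prefs"].items()
    }
    couplings = {
        ((int(c["a"][0]), c["a"][1]), (int(c["b"][0]), c["b"][1])): float(c["value"])
        for c in raw.get("couplings", [])
    }
    return TruthModel(
        design,
        prefs,
        couplings,
        s_pos=float(raw.get("s_pos", 1.0)),
        s_neg=float(raw.get("s_neg", 1.0)),
    )


def resolve_design(region_or_path: str) -> LibraryDesign:
    """A built-in region label, or a YAML config path holding one design."""
    try:
        return get_design(region_or_path)
    except KeyError:
        pass
    from .designs import load_config

    designs, _ = load_config(region_or_path)
    if len(designs) != 1:
        raise ValueError("design config must contain exactly one design")
    return designs[0]
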