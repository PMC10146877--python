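"""Enrichment and fitness inference from variant count tables.

Abundances are depth-normalized per condition (frequencies by default, so
unequal sequencing depths across conditions do not masquerade as selection),
with a pseudocount applied to every variant of the design before
normalization.  Enrichment is the signed abundance difference against the
unselected population; fitness is the enrichment ratio

    oriented (default):  f = (Ap - A0) / (A0 - An)
    literal:             f = (Ap - A0) / (An - A0)

where Ap, An, A0 are the abundances in the positive selection, negative
selection and unselected population.  The oriented convention flips the
denominator sign so that variants enriched in the positive arm AND depleted
in the negative arm score positive.  Variants *enriched* in the negative arm
(A0 - An < 0) also come out positive under this ratio even though they are
nonfunctional; they are flagged ``discordant`` rather than silently ranked.
Raw fitness is z-normalized per library by its mean and SD.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .designs import CONDITIONS, LibraryDesign, hamming_to_wt
from .reads import VariantCountTable

FREQUENCY = "frequency"
RPM = "rpm"


def normalize_abundance(
    table: VariantCountTable,
    design: LibraryDesign,
    pseudocount: float = 0.5,
    unit: str = FREQUENCY,
) -> pd.DataFrame:
    """Counts -> per-condition abundances and signed enrichments.

    Rows cover every variant of the design (absent variants get count 0 and
    carry only pseudocount mass).  Columns: count_*, Ap, An, A0, enrich_pos,
    enrich_neg, hamming.
    """
    missing = [c for c in CONDITIONS if c not in table.counts]
    if missing:
        raise ValueError(f"count table lacks conditions: {missing}")
    variants = list(design.variants())
    df = pd.DataFrame(index=pd.Index(variants, name="variant"))
    scale = 1.0 if unit == FREQUENCY else 1e6
    if unit not in (FREQUENCY, RPM):
        raise ValueError(f"unknown abundance unit {unit!r}")
    colname = {"positive": "Ap", "negative": "An", "unselected": "A0"}
    for cond in CONDITIONS:
        cv = table.counts[cond]
        counts = np.array([cv.get(v, 0) for v in variants], dtype=float)
        df[f"count_{cond}"] = counts.astype(int)
        padded = counts + pseudocount
        total = padded.sum()
        if total == 0:
            raise ValueError(f"condition {cond!r} has zero total mass")
        df[colname[cond]] = scale * padded / total
    df["enrich_pos"] = df["Ap"] - df["A0"]
    df["enrich_neg"] = df["An"] - df["A0"]
    df["hamming"] = [hamming_to_wt(v, design) for v in variants]
    df.attrs["pseudocount"] = pseudocount
    df.attrs["unit"] = unit
    return df


def compute_fitness(
    enrichment: pd.DataFrame,
    convention: str = "oriented",
    denom_tol: float = 1e-6,
) -> pd.DataFrame:
    """Add raw fitness ``f`` and the ``discordant`` flag.

    ``f`` is missing (NaN) where the denominator magnitude is below
    ``denom_tol`` (in abundance units).  ``discordant`` marks variants
    enriched in the negative arm, whose ratio sign is not a valid
    functionality ranking (see module docstring).
    """
    if convention not in ("oriented", "literal"):
        raise ValueError(f"unknown convention {convention!r}")
    df = enrichment.copy()
    num = df["Ap"] - df["A0"]
    denom = df["A0"] - df["An"] if convention == "oriented" else df["An"] - df["A0"]
    f = num / denom
    f[denom.abs() < denom_tol] = np.nan
    df["f"] = f
    df["discordant"] = (df["A0"] - df["An"]) < 0
    df.attrs.update(enrichment.attrs)
    df.attrs["convention"] = convention
    df.attrs["denom_tol"] = denom_tol
    return df


def normalize_fitness(ft: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """z-normalize raw fitness per library (population SD by default).

    Missing fitness values are excluded from the mean/SD and stay missing.
    The normalization constants are recorded in ``attrs['mu_f']`` and
    ``attrs['sigma_f']``.
    """
    df = ft.copy()
    values = df["f"].dropna()
    if len(values) < 2:
        raise ValueError("need at least 2 non-missing fitness values")
    mu = float(values.mean())
    sigma = float(values.std(ddof=ddof))
    if sigma == 0:
        raise ValueError("degenerate library: fitness SD is zero")
    df["z"] = (df["f"] - mu) / sigma
    df.attrs.update(ft.attrs)
    df.attrs["mu_f"] = mu
    df.attrs["sigma_f"] = sigma
    df.attrs["ddof"] = ddof
    return df


def normality_summary(ft: pd.DataFrame | pd.Series) -> tuple[float, float]:
    """Moment-based (skewness, excess kurtosis) of the raw fitness values.

    Reported, not gated: the study observed approximately normal fitness
    distributions per library, and this summary lets a user eyeball that on
    their own data.
    """
    values = (ft["f"] if isinstance(ft, pd.DataFrame) else ft).dropna().to_numpy()
    if len(values) < 8:
        raise ValueError("need at least 8 fitness values")
    return float(stats.skew(values)), float(stats.kurtosis(values, fisher=True))


def fitness_pipeline(
    table: VariantCountTable,
    design: LibraryDesign,
    pseudocount: float = 0.5,
    unit: str = FREQUENCY,
    convention: str = "oriented",
    denom_tol: float = 1e-6,
    ddof: int = 0,
) -> pd.DataFrame:
    """Counts -> enrichment -> raw fitness -> z-fitness, with the normality
    summary stored in ``attrs['skewness']`` / ``attrs['excess_kurtosis']``."""
    enr = normalize_abundance(table, design, pseudocount=pseudocount, unit=unit)
    ft = compute_fitness(enr, convention=convention, denom_tol=denom_tol)
    ft = normalize_fitness(ft, ddof=ddof)
    skew, kurt = normality_summary(ft)
    ft.attrs["skewness"] = skew
    ft.attrs["excess_kurtosis"] = kurt
    return ft


def write_fitness_tsv(ft: pd.DataFrame, path) -> None:
    cols = [
        "hamming", "count_positive", "count_negative", "count_unselected",
        "Ap", "An", "A0", "enrich_pos", "enrich_neg", "f", "z", "discordant",
    ]
    ft[cols].to_csv(path, sep="\t", float_format="%.8g")


def read_fitness_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="variant")
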