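"""Pairwise epistasis under the multiplicative null.

For every pair of point mutations A and B at distinct positions,

    eps = f(AB) - f(A) * f(B)

where f(AB) is the fitness of the double mutant and f(A), f(B) the fitness
of the constituent single mutants; only Hamming distance <= 2 variants enter
the analysis.  A product null needs nonnegative fitness on a meaningful
scale, while the enrichment-ratio fitness can be negative, so fitness is
rescaled per library before the null is applied (mode recorded in the
output):

    unit_interval (default): affine map of the library's raw fitness to [0, 1]
    wt_relative:             affine shift so the minimum is 0, then divide by
                             the shifted wild-type fitness (WT -> 1)
    raw:                     pass through unchanged

Raw epistasis values are then z-normalized per library by their mean and SD.
Negative eps = aggravating interaction, positive eps = compensating.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd

from .designs import RNA_BASES, LibraryDesign

SCALE_MODES = ("unit_interval", "wt_relative", "raw")


def _mutant(design: LibraryDesign, *muts: tuple[int, str]) -> str:
    window = list(design.wt_bases)
    for pos, base in muts:
        window[design.position_index(pos)] = base
    return "".join(window)


def rescale_for_epistasis(
    ft: pd.DataFrame, design: LibraryDesign, mode: str = "unit_interval"
) -> dict[str, float]:
    """Rescaled fitness for the WT and every Hamming <= 2 variant.

    The affine constants are taken over the non-missing raw fitness of the
    variants that enter the analysis (WT, singles and doubles).  Anchoring
    on the whole library instead would let far-from-WT variants with
    near-zero enrichment denominators (arbitrarily extreme ratios) dictate
    the scale.  Variants with missing raw fitness are absent from the
    returned map.
    """
    if mode not in SCALE_MODES:
        raise ValueError(f"unknown scale mode {mode!r}")
    f = ft.loc[ft["hamming"] <= 2, "f"]
    fmin, fmax = f.min(), f.max()
    wt = design.wt_bases
    if math.isnan(f.get(wt, float("nan"))):
        raise ValueError("wild-type fitness is missing")
    if mode == "unit_interval":
        span = fmax - fmin
        if span == 0:
            raise ValueError("zero fitness range")
        transform = lambda x: (x - fmin) / span
    elif mode == "wt_relative":
        denom = f[wt] - fmin
        if denom == 0:
            raise ValueError("wild-type sits at the library minimum")
        transform = lambda x: (x - fmin) / denom
    else:
        transform = lambda x: x
    near = ft.loc[ft["hamming"] <= 2, "f"].dropna()
    return {v: float(transform(x)) for v, x in near.items()}


def compute_epistasis(
    scaled: dict[str, float], design: LibraryDesign, scale_mode: str = ""
) -> pd.DataFrame:
    """eps for every admissible ((posA, baseA), (posB, baseB)) pair.

    Long-format frame with one row per pair (posA < posB, both bases
    non-WT): columns posA, baseA, posB, baseB, f_A, f_B, f_AB, eps_raw,
    eps_z.  Pairs with any missing constituent have NaN eps.  A complete
    k-position library yields C(k, 2) * 9 rows.  attrs record mu_eps,
    sigma_eps and the fitness scale mode.
    """
    rows = []
    for ia, ib in itertools.combinations(range(design.k), 2):
        pa, pb = design.positions[ia], design.positions[ib]
        wt_a, wt_b = design.wt_bases[ia], design.wt_bases[ib]
        for ba in RNA_BASES:
            if ba == wt_a:
                continue
            for bb in RNA_BASES:
                if bb == wt_b:
                    continue
                fa = scaled.get(_mutant(design, (pa, ba)))
                fb = scaled.get(_mutant(design, (pb, bb)))
                fab = scaled.get(_mutant(design, (pa, ba), (pb, bb)))
                eps = (
                    fab - fa * fb
                    if None not in (fa, fb, fab)
                    else np.nan
                )
                rows.append((pa, ba, pb, bb, fa, fb, fab, eps))
    df = pd.DataFrame(
        rows,
        columns=["posA", "baseA", "posB", "baseB", "f_A", "f_B", "f_AB", "eps_raw"],
    )
    values = df["eps_raw"].dropna()
    if len(values) >= 2 and values.std(ddof=0) > 0:
        mu = float(values.mean())
        sigma = float(values.std(ddof=0))
        df["eps_z"] = (df["eps_raw"] - mu) / sigma
    else:
        mu, sigma = float("nan"), float("nan")
        df["eps_z"] = np.nan
    df.attrs["mu_eps"] = mu
    df.attrs["sigma_eps"] = sigma
    df.attrs["scale_mode"] = scale_mode
    return df


def epistasis_pipeline(
    ft: pd.DataFrame, design: LibraryDesign, mode: str = "unit_interval"
) -> pd.DataFrame:
    scaled = rescale_for_epistasis(ft, design, mode=mode)
    return compute_epistasis(scaled, design, scale_mode=mode)


def epistasis_matrix(em: pd.DataFrame, design: LibraryDesign) -> pd.DataFrame:
    """Square (position, base) x (position, base) matrix of eps_z for
    heatmap display; the lower triangle mirrors the upper."""
    labels = [
        (pos, b)
        for i, pos in enumerate(design.positions)
        for b in RNA_BASES
        if b != design.wt_bases[i]
    ]
    idx = pd.MultiIndex.from_tuples(labels, names=["position", "base"])
    mat = pd.DataFrame(np.nan, index=idx, columns=idx)
    for row in em.itertuples(index=False):
        a = (row.posA, row.baseA)
        b = (row.posB, row.baseB)
        mat.loc[a, b] = row.eps_z
        mat.loc[b, a] = row.eps_z
    return mat


def epistasis_recovery_check(
    truth, em: pd.DataFrame, margin: float = 0.1
) -> pd.DataFrame:
    """Sign concordance between measured eps_z and planted couplings.

    For each pair cell, reports the true log coupling and whether the sign
    of eps_z matches it; only couplings with |log coupling| > margin are
    judged (weaker couplings are background).  attrs carry the aggregate
    sign-agreement fraction over judged cells.
    """
    log_coup = {}
    for ((pa, ba), (pb, bb)), c in truth.couplings.items():
        key = (pa, ba, pb, bb) if pa < pb else (pb, bb, pa, ba)
        log_coup[key] = math.log(c)
    df = em.copy()
    df["log_coupling"] = [
        log_coup.get((r.posA, r.baseA, r.posB, r.baseB), 0.0)
        for r in em.itertuples(index=False)
    ]
    df["judged"] = df["log_coupling"].abs() > margin
    df["sign_match"] = np.sign(df["eps_z"]) == np.sign(df["log_coupling"])
    judged = df[df["judged"] & df["eps_z"].notna()]
    df.attrs["n_judged"] = int(len(judged))
    df.attrs["sign_agreement"] = (
        float(judged["sign_match"].mean()) if len(judged) else float("nan")
    )
    return df


def plot_epistasis_heatmap(em: pd.DataFrame, design: LibraryDesign, ax=None):
    """eps_z heatmap arranged as (position x base) rows/columns."""
    import matplotlib.pyplot as plt

    mat = epistasis_matrix(em, design)
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6))
    data = mat.to_numpy(dtype=float)
    vmax = np.nanmax(np.abs(data)) or 1.0
    im = ax.imshow(data, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ticks = [f"{p}{b}" for p, b in mat.index]
    ax.set_xticks(range(len(ticks)), ticks, rotation=90, fontsize=7)
    ax.set_yticks(range(len(ticks)), ticks, fontsize=7)
    plt.colorbar(im, ax=ax, label="epistasis (z)")
    return ax
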