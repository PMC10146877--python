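"""Per-position landscape profiles: marginal base scores, Shannon-entropy
mutational flexibility, and pairwise base-combination maps.

The flexibility of a position is quantified as the Shannon entropy (bits)

    H(X) = -sum_b P(b) log2 P(b)

over a base-probability vector derived from the per-base marginal scores at
that position: H = 0 when a single base dominates, H = 2 when all four bases
are equally tolerated.  The marginal score defaults to the positive-arm
enrichment (mean Ap - A0 over variants carrying the base); the z-normalized
fitness or the positive-arm abundance can be used instead.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .designs import RNA_BASES, LibraryDesign

#: marginal score choices: column drawn from the fitness table
SCORES = ("enrich_pos", "z", "f", "abundance_pos")

LOW_CUT_DEFAULT = 0.3
HIGH_CUT_DEFAULT = 1.3


def _score_series(ft: pd.DataFrame, score: str) -> pd.Series:
    if score == "abundance_pos":
        return ft["Ap"]
    if score == "z_fitness":  # accepted alias
        score = "z"
    if score not in ft.columns:
        raise ValueError(f"score column {score!r} not in fitness table")
    return ft[score]


def marginal_scores(
    ft: pd.DataFrame, design: LibraryDesign, score: str = "enrich_pos"
) -> pd.DataFrame:
    """Mean score per (position, base): rows = 23S positions, cols = A,C,G,U.

    marginal[p][b] averages the score of all variants carrying base b at
    position p; variants with a missing score are excluded.
    """
    s = _score_series(ft, score)
    out = pd.DataFrame(
        index=pd.Index(design.positions, name="position"),
        columns=list(RNA_BASES),
        dtype=float,
    )
    variants = ft.index.to_numpy()
    values = s.to_numpy(dtype=float)
    ok = ~np.isnan(values)
    for col, pos in enumerate(design.positions):
        col_bases = np.array([v[col] for v in variants])
        for b in RNA_BASES:
            mask = ok & (col_bases == b)
            if not mask.any():
                raise ValueError(f"no scored variants with {b} at position {pos}")
            out.loc[pos, b] = values[mask].mean()
    out.attrs["score"] = score
    return out


def entropy_probabilities(
    marginal, mode: str = "positive_part", tau: float = 1.0
) -> np.ndarray:
    """Turn a 4-vector of marginal scores into base probabilities.

    positive_part (default): negative scores contribute zero probability and
    the positive part is renormalized; if no score is positive the most
    favored base takes all the mass (ties broken lexicographically A<C<G<U),
    reproducing "entropy 0 when only a single base is tolerated".
    softmax: P ∝ exp(m / tau).
    """
    m = np.asarray(marginal, dtype=float)
    if m.shape != (4,):
        raise ValueError("marginal must be a 4-vector")
    if np.isnan(m).any():
        raise ValueError("marginal contains NaN")
    if mode == "positive_part":
        pos = np.clip(m, 0.0, None)
        total = pos.sum()
        if total == 0.0:
            p = np.zeros(4)
            p[int(np.argmax(m))] = 1.0
            return p
        return pos / total
    if mode == "softmax":
        e = np.exp((m - m.max()) / tau)
        return e / e.sum()
    raise ValueError(f"unknown probability mode {mode!r}")


def shannon_entropy(p, atol: float = 1e-6) -> float:
    """Shannon entropy in bits of a base-probability 4-vector (0 <= H <= 2)."""
    p = np.asarray(p, dtype=float)
    if (p < -atol).any() or abs(p.sum() - 1.0) > atol:
        raise ValueError("p is not a probability vector")
    nz = p[p > 0]
    return float(abs(-(nz * np.log2(nz)).sum()))  # abs() normalizes -0.0


def classify_flexibility(
    h: float, low_cut: float = LOW_CUT_DEFAULT, high_cut: float = HIGH_CUT_DEFAULT
) -> str:
    """low / intermediate / high mutational flexibility from entropy (bits).

    The thresholds are repo conventions (the source color scale prints no
    numbers): below ``low_cut`` a position effectively tolerates one base;
    above ``high_cut`` it tolerates most bases.
    """
    if not 0 <= h <= 2 + 1e-9:
        raise ValueError("entropy out of [0, 2]")
    if low_cut >= high_cut:
        raise ValueError("low_cut must be below high_cut")
    if h < low_cut:
        return "low"
    if h > high_cut:
        return "high"
    return "intermediate"


def position_profiles(
    ft: pd.DataFrame,
    design: LibraryDesign,
    score: str = "enrich_pos",
    mode: str = "positive_part",
    tau: float = 1.0,
    low_cut: float = LOW_CUT_DEFAULT,
    high_cut: float = HIGH_CUT_DEFAULT,
) -> pd.DataFrame:
    """Per-position profile: marginals, probabilities, entropy, class.

    Columns: marginal_A..U, p_A..U, entropy_bits, flexibility.
    """
    marg = marginal_scores(ft, design, score=score)
    rows = []
    for pos in design.positions:
        m = marg.loc[pos].to_numpy(dtype=float)
        p = entropy_probabilities(m, mode=mode, tau=tau)
        h = shannon_entropy(p)
        rows.append(
            dict(
                position=pos,
                **{f"marginal_{b}": m[i] for i, b in enumerate(RNA_BASES)},
                **{f"p_{b}": p[i] for i, b in enumerate(RNA_BASES)},
                entropy_bits=h,
                flexibility=classify_flexibility(h, low_cut, high_cut),
            )
        )
    out = pd.DataFrame(rows).set_index("position")
    out.attrs["score"] = score
    out.attrs["mode"] = mode
    return out


def pairwise_map(
    ft: pd.DataFrame, design: LibraryDesign, score: str = "enrich_pos"
) -> dict[tuple[int, int], pd.DataFrame]:
    """(posA, posB) -> 4x4 mean-score matrix over base combinations.

    Cell (a, b) averages the score of every variant carrying base a at posA
    and base b at posB; combinations with no scored variant are NaN.
    """
    s = _score_series(ft, score)
    variants = ft.index.to_numpy()
    values = s.to_numpy(dtype=float)
    ok = ~np.isnan(values)
    cols = {
        col: np.array([v[col] for v in variants]) for col in range(design.k)
    }
    out = {}
    for ia, ib in itertools.combinations(range(design.k), 2):
        pa, pb = design.positions[ia], design.positions[ib]
        mat = pd.DataFrame(
            index=pd.Index(RNA_BASES, name=f"base_{pa}"),
            columns=pd.Index(RNA_BASES, name=f"base_{pb}"),
            dtype=float,
        )
        for a in RNA_BASES:
            mask_a = ok & (cols[ia] == a)
            for b in RNA_BASES:
                mask = mask_a & (cols[ib] == b)
                mat.loc[a, b] = values[mask].mean() if mask.any() else np.nan
        out[(pa, pb)] = mat
    return out


def pairwise_long(pmap: dict[tuple[int, int], pd.DataFrame]) -> pd.DataFrame:
    """Long-format pairwise map (posA, posB, baseA, baseB, mean_score)."""
    rows = [
        (pa, pb, a, b, mat.loc[a, b])
        for (pa, pb), mat in pmap.items()
        for a in RNA_BASES
        for b in RNA_BASES
    ]
    return pd.DataFrame(
        rows, columns=["posA", "posB", "baseA", "baseB", "mean_score"]
    )


def structure_annotation(profiles: pd.DataFrame) -> pd.DataFrame:
    """Flat (position, entropy_bits, flexibility) table for coloring a 3D
    structure viewer by 23S residue number; no coordinates are touched."""
    return profiles.reset_index()[["position", "entropy_bits", "flexibility"]]


def plot_entropy_bars(profiles: pd.DataFrame, ax=None):
    """Bar chart of entropy (bits) per position, colored by flexibility."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(profiles), 3))
    colors = {"low": "#c0392b", "intermediate": "#27ae60", "high": "#2980b9"}
    ax.bar(
        [str(p) for p in profiles.index],
        profiles["entropy_bits"],
        color=[colors[c] for c in profiles["flexibility"]],
    )
    ax.set_ylim(0, 2)
    ax.set_ylabel("Shannon entropy (bits)")
    ax.set_xlabel("23S rRNA position")
    return ax


def plot_marginal_heatmap(marg: pd.DataFrame, ax=None):
    """Heatmap of per-base marginal scores (positions x A,C,G,U)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(3, 0.6 * len(marg)))
    data = marg.to_numpy(dtype=float)
    vmax = np.nanmax(np.abs(data)) or 1.0
    im = ax.imshow(data, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(4), list(RNA_BASES))
    ax.set_yticks(range(len(marg)), [str(p) for p in marg.index])
    plt.colorbar(im, ax=ax, label=marg.attrs.get("score", "score"))
    return ax
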