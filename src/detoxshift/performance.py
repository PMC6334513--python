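"""Survival-assay statistics.

Replicate survival proportions are arcsine-square-root transformed, analysed
by balanced two-way ANOVA (species x plant, Type-I sums of squares), and
followed by pairwise Welch t-tests under the sequential Dunn-Šidák
(step-down) correction, with a compact letter display of the resulting
non-significance groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import SurvivalTable, ValidationError

__all__ = [
    "arcsine_sqrt",
    "two_way_anova",
    "AnovaResult",
    "dunn_sidak_pairwise",
    "PairwiseResult",
    "performance_report",
]


def arcsine_sqrt(p):
    """Arcsine-square-root transform of a proportion, in radians."""
    arr = np.asarray(p, dtype=float)
    if ((arr < 0) | (arr > 1)).any() or not np.isfinite(arr).all():
        raise ValidationError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


@dataclass(frozen=True)
class AnovaResult:
    """Two-way ANOVA table: one row per effect plus the residual."""

    table: pd.DataFrame  # index: species/plant/interaction/residual; cols SS, df, F, p

    def p(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])


def two_way_anova(survival: SurvivalTable, transform: bool = True) -> AnovaResult:
    """Balanced two-factor ANOVA of (transformed) survival proportions.

    Requires every species x plant cell to have the same number (>= 2) of
    replicates.  With a balanced design the Type-I decomposition reported
    here coincides with Types II and III.
    """
    t = survival.table
    y = t["proportion_survived"].to_numpy(dtype=float)
    if transform:
        y = arcsine_sqrt(y)
    species = sorted(t["species"].unique())
    plants = sorted(t["plant"].unique())
    reps = None
    cells = {}
    for s in species:
        for p in plants:
            vals = y[(t["species"] == s).to_numpy() & (t["plant"] == p).to_numpy()]
            if vals.size == 0:
                raise ValidationError(f"empty survival cell ({s}, {p})")
            if reps is None:
                reps = vals.size
            elif vals.size != reps:
                raise ValidationError(
                    f"unbalanced design: cell ({s}, {p}) has {vals.size} replicates, "
                    f"expected {reps}"
                )
            cells[(s, p)] = vals
    assert reps is not None
    if reps < 2:
        raise ValidationError("interaction term requires >=2 replicates per cell")

    a, b, n = len(species), len(plants), reps
    grand = y.mean()
    cell_mean = {k: v.mean() for k, v in cells.items()}
    sp_mean = {s: np.mean([cell_mean[(s, p)] for p in plants]) for s in species}
    pl_mean = {p: np.mean([cell_mean[(s, p)] for s in species]) for p in plants}

    ss_a = b * n * sum((sp_mean[s] - grand) ** 2 for s in species)
    ss_b = a * n * sum((pl_mean[p] - grand) ** 2 for p in plants)
    ss_ab = n * sum(
        (cell_mean[(s, p)] - sp_mean[s] - pl_mean[p] + grand) ** 2
        for s in species
        for p in plants
    )
    ss_res = sum(((cells[(s, p)] - cell_mean[(s, p)]) ** 2).sum() for s in species for p in plants)

    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_res = a * b * (n - 1)
    ms_res = ss_res / df_res if df_res else np.nan

    def frow(ss: float, df: int) -> tuple[float, float]:
        if ms_res == 0:
            return (0.0, 1.0) if ss == 0 else (np.inf, 0.0)
        f = (ss / df) / ms_res
        return f, float(stats.f.sf(f, df, df_res))

    f_a, p_a = frow(ss_a, df_a)
    f_b, p_b = frow(ss_b, df_b)
    f_ab, p_ab = frow(ss_ab, df_ab)
    table = pd.DataFrame(
        {
            "SS": [ss_a, ss_b, ss_ab, ss_res],
            "df": [df_a, df_b, df_ab, df_res],
            "F": [f_a, f_b, f_ab, np.nan],
            "p": [p_a, p_b, p_ab, np.nan],
        },
        index=["species", "plant", "interaction", "residual"],
    )
    return AnovaResult(table)


def sequential_sidak_levels(alpha: float, m: int) -> list[float]:
    """Per-step levels alpha'_i = 1 - (1 - alpha)^(1/(m - i + 1)), i = 1..m."""
    return [1.0 - (1.0 - alpha) ** (1.0 / (m - i + 1)) for i in range(1, m + 1)]


def sequential_sidak_reject(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Step-down Dunn-Šidák decisions for a vector of p-values.

    P-values are ranked ascending; the i-th smallest is rejected iff every
    p up to and including it beats its step level (testing stops at the
    first non-rejection).  Returns a boolean array in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p, kind="mergesort")
    levels = sequential_sidak_levels(alpha, p.size)
    reject = np.zeros(p.size, dtype=bool)
    for step, idx in enumerate(order):
        if p[idx] <= levels[step]:
            reject[idx] = True
        else:
            break
    return reject


@dataclass(frozen=True)
class PairwiseResult:
    """Pairwise comparisons with sequential Dunn-Šidák decisions."""

    comparisons: pd.DataFrame  # columns: a, b, t, p, level, reject (sorted by p)
    letters: dict[str, str]  # compact letter display per group


def dunn_sidak_pairwise(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> PairwiseResult:
    """All pairwise Welch t-tests under sequential Dunn-Šidák correction.

    P-values are ordered ascending; at step i (with m comparisons in total)
    the observed p is compared against 1 - (1 - alpha)^(1/(m - i + 1)) and
    testing stops at the first non-rejection.  Groups sharing a letter in the
    compact display are not significantly different.
    """
    names = sorted(groups)
    if len(names) < 2:
        raise ValidationError("need at least 2 groups")
    for name in names:
        if len(np.asarray(groups[name])) < 2:
            raise ValidationError(f"group {name!r} has fewer than 2 observations")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            tstat, p = stats.ttest_ind(groups[a], groups[b], equal_var=False)
            rows.append({"a": a, "b": b, "t": float(tstat), "p": float(p)})
    comp = pd.DataFrame(rows).sort_values("p", kind="mergesort").reset_index(drop=True)
    comp["level"] = sequential_sidak_levels(alpha, len(comp))
    comp["reject"] = sequential_sidak_reject(comp["p"].to_numpy(), alpha)

    letters = _letter_display(names, comp, groups)
    return PairwiseResult(comparisons=comp, letters=letters)


def _letter_display(
    names: list[str], comp: pd.DataFrame, groups: dict[str, np.ndarray]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display from the rejection graph."""
    different = {
        frozenset((r.a, r.b)) for r in comp.itertuples() if r.reject
    }
    # process groups by descending mean; deterministic tie-break by name
    order = sorted(names, key=lambda g: (-float(np.mean(groups[g])), g))
    cliques: list[set[str]] = []
    for g in order:
        placed = False
        for clique in cliques:
            if all(frozenset((g, other)) not in different for other in clique):
                clique.add(g)
                placed = True
        if not placed:
            cliques.append({g})
    # absorb cliques fully contained in another
    cliques = [
        c
        for i, c in enumerate(cliques)
        if not any(i != j and c < other for j, other in enumerate(cliques))
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in names}
    for letter, clique in zip(alphabet, cliques):
        for g in sorted(clique):
            letters[g] += letter
    return {g: "".join(sorted(l)) for g, l in letters.items()}


def performance_report(
    survival: SurvivalTable, alpha: float = 0.05, per_plant: bool = True
) -> dict:
    """ANOVA table plus per-plant (or overall) pairwise letter groupings."""
    anova = two_way_anova(survival)
    t = survival.table
    y = arcsine_sqrt(t["proportion_survived"].to_numpy(dtype=float))
    t = t.assign(_y=y)
    pairwise = {}
    if per_plant:
        for plant in sorted(t["plant"].unique()):
            sub = t.loc[t["plant"] == plant]
            groups = {
                s: sub.loc[sub["species"] == s, "_y"].to_numpy()
                for s in sorted(sub["species"].unique())
            }
            pairwise[plant] = dunn_sidak_pairwise(groups, alpha=alpha)
    else:
        groups = {
            s: t.loc[t["species"] == s, "_y"].to_numpy()
            for s in sorted(t["species"].unique())
        }
        pairwise["all"] = dunn_sidak_pairwise(groups, alpha=alpha)
    return {"anova": anova, "pairwise": pairwise}
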