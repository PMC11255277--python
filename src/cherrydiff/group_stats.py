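"""One-way ANOVA, Tukey-Kramer HSD, Scheffe contrasts and letter displays.

Used to compare effective diffusivities across study conditions with
unequal sample sizes, reproducing the letters-in-a-column annotation
style of diffusivity summary tables.  By default diffusivities are
compared on the log10 scale (their SDs are of the same order as their
means, so the log transform stabilises variance); callers may pass raw
values for a literal reproduction.

The studentized-range distribution behind the Tukey-Kramer p-values is
evaluated by direct numerical double quadrature of its CDF rather than
table lookup, which supports arbitrary (k, df) and is independently
testable against library implementations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special

from .model_core import DomainError

__all__ = [
    "GroupSummary",
    "ComparisonTable",
    "anova_oneway",
    "tukey_kramer",
    "scheffe",
    "letter_display",
    "studentized_range_cdf",
    "studentized_range_crit",
]


@dataclass(frozen=True)
class GroupSummary:
    """One treatment group: label and its replicate estimates."""

    label: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise DomainError(f"group {self.label!r} needs >= 2 values")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1))

    @classmethod
    def from_values(cls, label: str, values: Sequence[float]) -> "GroupSummary":
        return cls(label=label, values=tuple(float(v) for v in values))


@dataclass
class ComparisonTable:
    """Pairwise multiple-comparison results plus a compact letter display.

    Two groups share a letter iff their pairwise p-value >= alpha.
    """

    pairwise: pd.DataFrame  # columns: group_i, group_j, statistic, p_value
    letters: dict[str, str]
    alpha: float = 0.05
    method: str = ""
    meta: dict = field(default_factory=dict)

    def p_matrix(self, labels: Sequence[str]) -> pd.DataFrame:
        mat = pd.DataFrame(1.0, index=list(labels), columns=list(labels))
        for _, row in self.pairwise.iterrows():
            mat.loc[row["group_i"], row["group_j"]] = row["p_value"]
            mat.loc[row["group_j"], row["group_i"]] = row["p_value"]
        return mat


def _pooled(groups: Sequence[GroupSummary]) -> tuple[float, int, float]:
    """(MSE, within-group df, grand mean) of the one-way layout."""
    n_tot = sum(g.n for g in groups)
    k = len(groups)
    df_within = n_tot - k
    ss_within = sum((g.n - 1) * g.sd**2 for g in groups)
    grand = sum(g.n * g.mean for g in groups) / n_tot
    return ss_within / df_within, df_within, grand


def _f_sf(F: float, df1: int, df2: int) -> float:
    """Upper tail of the F distribution via the regularized incomplete beta."""
    if F <= 0:
        return 1.0
    x = df2 / (df2 + df1 * F)
    return float(special.betainc(df2 / 2.0, df1 / 2.0, x))


def anova_oneway(groups: Sequence[GroupSummary]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA with unequal group sizes.

    Returns (F, p) from the usual between/within decomposition; the
    p-value comes from the F distribution evaluated through the
    regularized incomplete beta function.
    """
    if len(groups) < 2:
        raise DomainError("need at least 2 groups")
    k = len(groups)
    n_tot = sum(g.n for g in groups)
    if n_tot <= k:
        raise DomainError("total sample size must exceed the number of groups")
    mse, df_within, grand = _pooled(groups)
    ss_between = sum(g.n * (g.mean - grand) ** 2 for g in groups)
    ms_between = ss_between / (k - 1)
    if mse == 0.0:
        if ss_between == 0.0:
            raise DomainError("all values identical; F undefined")
        return math.inf, 0.0
    F = ms_between / mse
    return float(F), _f_sf(F, k - 1, df_within)


# ---------------------------------------------------------------------------
# Studentized range distribution by direct quadrature
# ---------------------------------------------------------------------------


def _range_cdf_std(w: float, k: int) -> float:
    """P(range of k iid standard normals <= w)."""
    if w <= 0:
        return 0.0

    def inner(z: float) -> float:
        return (
            math.exp(-0.5 * z * z) / math.sqrt(2 * math.pi)
            * (special.ndtr(z) - special.ndtr(z - w)) ** (k - 1)
        )

    val, _ = integrate.quad(inner, -8.0 - w, 8.0, epsabs=1e-10, limit=200)
    return k * val


def studentized_range_cdf(q: float, k: int, df: int) -> float:
    """CDF of the studentized range by numerical double quadrature.

    P(Q <= q) = int_0^inf f_S(s) * P(range <= q s) ds where S is the
    scaled chi estimate sqrt(chi2_df/df) of the common standard error.
    Absolute tolerance about 1e-6.
    """
    if q <= 0:
        return 0.0
    if k < 2 or df < 1:
        raise DomainError("need k >= 2 groups and df >= 1")
    ln_norm = (df / 2.0) * math.log(df) - math.lgamma(df / 2.0) - (df / 2.0 - 1.0) * math.log(2.0)

    def outer(s: float) -> float:
        if s <= 0:
            return 0.0
        ln_f = ln_norm + (df - 1) * math.log(s) - df * s * s / 2.0
        return math.exp(ln_f) * _range_cdf_std(q * s, k)

    val, err = integrate.quad(outer, 0.0, 8.0, epsabs=1e-8, limit=200)
    if err > 1e-6:
        raise RuntimeError(
            f"studentized-range quadrature did not reach tolerance (err={err:.2e})"
        )
    return min(max(val, 0.0), 1.0)


def studentized_range_crit(alpha: float, k: int, df: int) -> float:
    """Upper critical value q(alpha, k, df) by root-finding on the CDF."""
    target = 1.0 - alpha
    return float(
        optimize.brentq(lambda q: studentized_range_cdf(q, k, df) - target, 1e-3, 50.0)
    )


def tukey_kramer(
    groups: Sequence[GroupSummary], alpha: float = 0.05
) -> ComparisonTable:
    """Tukey-Kramer HSD pairwise comparisons for unequal sample sizes.

    q_ij = |mean_i - mean_j| / sqrt((MSE/2)(1/n_i + 1/n_j)); p-values from
    the studentized range with k groups and the within-group df.  With
    equal n the Kramer adjustment vanishes and this is classical Tukey HSD.
    """
    if len(groups) < 2:
        raise DomainError("need at least 2 groups")
    mse, df_within, _ = _pooled(groups)
    if mse <= 0:
        raise DomainError("within-group mean square must be positive")
    k = len(groups)
    rows = []
    for gi, gj in combinations(groups, 2):
        se = math.sqrt((mse / 2.0) * (1.0 / gi.n + 1.0 / gj.n))
        q = abs(gi.mean - gj.mean) / se
        p = 1.0 - studentized_range_cdf(q, k, df_within)
        rows.append(
            {"group_i": gi.label, "group_j": gj.label, "statistic": q, "p_value": p}
        )
    pairwise = pd.DataFrame(rows)
    letters = letter_display(pairwise, [g.label for g in groups], alpha)
    return ComparisonTable(
        pairwise=pairwise,
        letters=letters,
        alpha=alpha,
        method="tukey_kramer",
        meta={"mse": mse, "df": df_within, "k": k},
    )


def scheffe(groups: Sequence[GroupSummary], alpha: float = 0.05) -> ComparisonTable:
    """Scheffe pairwise contrasts.

    The pairwise contrast F-ratio is referred to (k-1) F_{k-1, df}; for
    k = 2 this reduces exactly to the ANOVA F test.  Scheffe protects all
    contrasts simultaneously, so its pairwise p-values are never smaller
    than Tukey-Kramer's.
    """
    if len(groups) < 2:
        raise DomainError("need at least 2 groups")
    mse, df_within, _ = _pooled(groups)
    if mse <= 0:
        raise DomainError("within-group mean square must be positive")
    k = len(groups)
    rows = []
    for gi, gj in combinations(groups, 2):
        var = mse * (1.0 / gi.n + 1.0 / gj.n)
        F_contrast = (gi.mean - gj.mean) ** 2 / var / (k - 1)
        p = _f_sf(F_contrast, k - 1, df_within)
        rows.append(
            {
                "group_i": gi.label,
                "group_j": gj.label,
                "statistic": F_contrast,
                "p_value": p,
            }
        )
    pairwise = pd.DataFrame(rows)
    letters = letter_display(pairwise, [g.label for g in groups], alpha)
    return ComparisonTable(
        pairwise=pairwise,
        letters=letters,
        alpha=alpha,
        method="scheffe",
        meta={"mse": mse, "df": df_within, "k": k},
    )


def letter_display(
    pairwise: pd.DataFrame, labels: Sequence[str], alpha: float = 0.05
) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb algorithm.

    Produces the minimal letter set such that two groups share a letter
    iff their pairwise p-value >= alpha.  Never errors on inconsistent
    (non-transitive) inputs; letters simply multiply.
    """
    labels = list(labels)
    sig: set[frozenset[str]] = set()
    seen: set[frozenset[str]] = set()
    for _, row in pairwise.iterrows():
        pair = frozenset((row["group_i"], row["group_j"]))
        seen.add(pair)
        if row["p_value"] < alpha:
            sig.add(pair)
    expected = {frozenset(p) for p in combinations(labels, 2)}
    if expected - seen:
        raise DomainError("pairwise matrix incomplete for letter display")

    # start with one letter covering everything; split on each significant pair
    columns: list[set[str]] = [set(labels)]
    for pair in sorted(sig, key=sorted):
        a, b = sorted(pair)
        new_cols: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_cols.extend(({x for x in col if x != a}, {x for x in col if x != b}))
            else:
                new_cols.append(col)
        # absorb duplicates / subsets
        columns = []
        for col in sorted(new_cols, key=len, reverse=True):
            if not any(col <= kept for kept in columns):
                columns.append(col)
    # ensure every non-significant pair still shares a column (guards the
    # iff-invariant when splits were over-eager)
    for pair in expected - sig:
        if not any(pair <= col for col in columns):
            columns.append(set(pair))
    # drop columns that would wrongly join a significant pair
    columns = [col for col in columns if not any(p <= col for p in sig)]
    # order columns by first appearance of their members
    rank = {lab: i for i, lab in enumerate(labels)}
    columns.sort(key=lambda col: min(rank[x] for x in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for i, col in enumerate(columns):
        letter = alphabet[i] if i < len(alphabet) else f"z{i}"
        for lab in col:
            out[lab] += letter
    for lab in labels:  # isolated groups still need a letter
        if not out[lab]:
            columns.append({lab})
            letter = alphabet[len(columns) - 1] if len(columns) <= 26 else f"z{len(columns)}"
            out[lab] = letter
    return out
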