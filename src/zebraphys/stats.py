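"""Group-comparison layer: Kruskal–Wallis + Dunn, one-way ANOVA + Fisher's
LSD, two-way ANOVA, and compact letter displays.

Conventions:

* Dunn's pairwise z statistics use pooled mid-ranks with the tie-corrected
  variance and are Bonferroni-adjusted over all pairs (conservative and
  reproducible; Šidák is available as an alternative).
* Fisher's LSD is the protected form: pairwise t tests on the pooled MSE are
  reported unadjusted, and letters separate groups only when the omnibus F
  is itself significant.
* Compact letter displays use the insert-and-absorb algorithm; groups share
  at least one letter iff their adjusted pairwise test is non-significant.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, InsufficientDataError


@dataclass
class GroupedEndpoint:
    """Per-group measurement vectors for one endpoint."""

    endpoint_name: str
    groups: list[str]
    values: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ConfigurationError("need >= 2 groups")
        if len(self.groups) != len(self.values):
            raise ConfigurationError("groups and values length mismatch")
        self.values = [np.asarray(v, dtype=float) for v in self.values]
        for g, v in zip(self.groups, self.values):
            if v.size == 0:
                raise InsufficientDataError(f"group {g!r} is empty")

    @classmethod
    def from_endpoint_table(cls, table: pd.DataFrame, endpoint_name: str) -> "GroupedEndpoint":
        sub = table[table["endpoint_name"] == endpoint_name]
        if sub.empty:
            raise ConfigurationError(f"endpoint {endpoint_name!r} not in table")
        groups = sorted(sub["group_label"].unique())
        values = [sub.loc[sub["group_label"] == g, "value"].to_numpy() for g in groups]
        return cls(endpoint_name, groups, values)


@dataclass
class ComparisonResult:
    """Omnibus + pairwise comparison with a compact letter display."""

    endpoint_name: str
    test: str
    omnibus_stat: float
    omnibus_p: float
    pairwise: pd.DataFrame  # group_i, group_j, statistic, p_raw, p_adj
    letters: dict[str, str]
    alpha: float = 0.05


def _bonferroni(p: np.ndarray, m: int) -> np.ndarray:
    return np.minimum(1.0, p * m)


def _sidak(p: np.ndarray, m: int) -> np.ndarray:
    return 1.0 - (1.0 - p) ** m


def kruskal_dunn(
    data: GroupedEndpoint, alpha: float = 0.05, adjust: str = "bonferroni"
) -> ComparisonResult:
    """Kruskal–Wallis omnibus with Dunn's pairwise post hoc.

    The H statistic is tie-corrected (scipy).  Dunn's z for groups i, j uses
    pooled mid-ranks:

        z = (R̄ᵢ − R̄ⱼ) / sqrt([N(N+1)/12 − ΣT/(12(N−1))] (1/nᵢ + 1/nⱼ))

    with ΣT = Σ(t³ − t) over tie groups; two-sided p, adjusted over all
    k(k−1)/2 pairs.
    """
    k = len(data.groups)
    pooled = np.concatenate(data.values)
    n = np.array([len(v) for v in data.values])
    N = pooled.size
    if N < 3:
        raise InsufficientDataError("Kruskal–Wallis needs total n >= 3")
    if np.all(pooled == pooled[0]):
        h, p_omni = 0.0, 1.0
        zs = np.zeros(k * (k - 1) // 2)
        praw = np.ones_like(zs)
    else:
        h, p_omni = sps.kruskal(*data.values)
        ranks = sps.rankdata(pooled)
        mean_ranks = []
        start = 0
        for ni in n:
            mean_ranks.append(ranks[start : start + ni].mean())
            start += ni
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = ((counts**3 - counts).sum()) / (12.0 * (N - 1))
        base_var = N * (N + 1) / 12.0 - tie_term
        zs, praw = [], []
        for i, j in itertools.combinations(range(k), 2):
            se = np.sqrt(base_var * (1.0 / n[i] + 1.0 / n[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            zs.append(z)
            praw.append(2.0 * sps.norm.sf(abs(z)))
        zs, praw = np.array(zs), np.array(praw)
    m = k * (k - 1) // 2
    adj_fn = {"bonferroni": _bonferroni, "sidak": _sidak}.get(adjust)
    if adj_fn is None:
        raise ConfigurationError(f"unknown adjustment {adjust!r}")
    padj = adj_fn(praw, m)
    pairs = list(itertools.combinations(range(k), 2))
    pairwise = pd.DataFrame(
        {
            "group_i": [data.groups[i] for i, _ in pairs],
            "group_j": [data.groups[j] for _, j in pairs],
            "statistic": zs,
            "p_raw": praw,
            "p_adj": padj,
        }
    )
    letters = letter_display(data.groups, pairwise, alpha)
    return ComparisonResult(data.endpoint_name, "kruskal_dunn", float(h), float(p_omni), pairwise, letters, alpha)


def anova_lsd(data: GroupedEndpoint, alpha: float = 0.05) -> ComparisonResult:
    """One-way ANOVA omnibus with Fisher's (protected) LSD pairwise t tests.

    Pairwise t = (x̄ᵢ − x̄ⱼ)/sqrt(MSE(1/nᵢ + 1/nⱼ)) on N − k degrees of
    freedom, reported unadjusted.  Letters separate groups only when the
    omnibus p < alpha; otherwise all groups share one letter.
    """
    k = len(data.groups)
    n = np.array([len(v) for v in data.values])
    if np.any(n < 2):
        raise InsufficientDataError("ANOVA needs n >= 2 per group")
    N = int(n.sum())
    means = np.array([v.mean() for v in data.values])
    sse = float(sum(((v - v.mean()) ** 2).sum() for v in data.values))
    grand = np.concatenate(data.values).mean()
    ssb = float((n * (means - grand) ** 2).sum())
    df_b, df_w = k - 1, N - k
    mse = sse / df_w if df_w > 0 else 0.0
    if mse == 0.0:
        # zero within-group variance: unequal means give F -> inf, p -> 0
        if ssb > 0:
            f_stat, p_omni = np.inf, 0.0
        else:
            f_stat, p_omni = 0.0, 1.0
    else:
        f_stat = (ssb / df_b) / mse
        p_omni = float(sps.f.sf(f_stat, df_b, df_w))
    pairs = list(itertools.combinations(range(k), 2))
    ts, praw = [], []
    for i, j in pairs:
        se = np.sqrt(mse * (1.0 / n[i] + 1.0 / n[j]))
        if se == 0:
            t = 0.0 if means[i] == means[j] else np.inf * np.sign(means[i] - means[j])
            p = 1.0 if means[i] == means[j] else 0.0
        else:
            t = (means[i] - means[j]) / se
            p = 2.0 * sps.t.sf(abs(t), df_w)
        ts.append(t)
        praw.append(p)
    pairwise = pd.DataFrame(
        {
            "group_i": [data.groups[i] for i, _ in pairs],
            "group_j": [data.groups[j] for _, j in pairs],
            "statistic": ts,
            "p_raw": praw,
            "p_adj": praw,  # LSD is reported unadjusted
        }
    )
    if p_omni < alpha:
        letters = letter_display(data.groups, pairwise, alpha)
    else:
        letters = {g: "a" for g in data.groups}
    return ComparisonResult(data.endpoint_name, "anova_lsd", float(f_stat), float(p_omni), pairwise, letters, alpha)


def letter_display(groups: list[str], pairwise: pd.DataFrame, alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Groups not significantly different (adjusted p >= alpha) share at least
    one letter; significantly different groups share none.  Letters are
    assigned in group order so output is deterministic.
    """
    idx = {g: i for i, g in enumerate(groups)}
    sig = set()
    for _, row in pairwise.iterrows():
        if row["p_adj"] < alpha:
            sig.add(frozenset((idx[row["group_i"]], idx[row["group_j"]])))
    letters: list[set[int]] = [set(range(len(groups)))]
    for pair in sorted(sig, key=lambda s: sorted(s)):
        i, j = sorted(pair)
        new = []
        for cls in letters:
            if i in cls and j in cls:
                new.append(cls - {i})
                new.append(cls - {j})
            else:
                new.append(cls)
        # absorb classes that are subsets of another
        new = [c for c in new if c]
        letters = [
            c for a, c in enumerate(new)
            if not any(b != a and c < new[b] for b in range(len(new)))
        ]
        # drop duplicates, keep first occurrence
        seen, uniq = [], []
        for c in letters:
            if c not in seen:
                seen.append(c)
                uniq.append(c)
        letters = uniq
    letters.sort(key=lambda c: min(c))
    alphabet = string.ascii_lowercase
    out = {g: "" for g in groups}
    for li, cls in enumerate(letters):
        ch = alphabet[li % len(alphabet)]
        if li >= len(alphabet):
            ch = ch * (li // len(alphabet) + 1)
        for gi in sorted(cls):
            out[groups[gi]] += ch
    return out


def letters_consistent(groups: list[str], pairwise: pd.DataFrame, letters: dict[str, str], alpha: float) -> bool:
    """Brute-force check that letter sharing equals pairwise non-significance."""
    for _, row in pairwise.iterrows():
        share = bool(set(letters[row["group_i"]]) & set(letters[row["group_j"]]))
        nonsig = row["p_adj"] >= alpha
        if share != nonsig:
            return False
    return all(letters[g] for g in groups)


@dataclass
class TwoWayResult:
    """Type II two-way ANOVA: main effects and interaction."""

    endpoint_name: str
    effects: pd.DataFrame  # index: effect name; columns: sum_sq, df, F, PR(>F)
    alpha: float = 0.05

    @property
    def interaction_p(self) -> float:
        inter = [i for i in self.effects.index if ":" in str(i)]
        return float(self.effects.loc[inter[0], "PR(>F)"])


def two_way_anova(
    values, factor_a, factor_b, endpoint_name: str = "", alpha: float = 0.05
) -> TwoWayResult:
    """Two-way ANOVA with interaction, Type II sums of squares.

    Accepts per-observation vectors of values and the two factor labels.
    Type II is well-defined for unbalanced layouts without an ordering
    assumption.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "a": pd.Categorical([str(x) for x in factor_a]),
            "b": pd.Categorical([str(x) for x in factor_b]),
        }
    )
    if df["a"].nunique() < 2 or df["b"].nunique() < 2:
        raise ConfigurationError("both factors need >= 2 levels")
    model = smf.ols("value ~ C(a) + C(b) + C(a):C(b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return TwoWayResult(endpoint_name, table, alpha)


def compare_endpoints(
    table: pd.DataFrame, test: str = "kruskal_dunn", alpha: float = 0.05
) -> list[ComparisonResult]:
    """Run one test per endpoint_name present in an endpoint table."""
    fn = {"kruskal_dunn": kruskal_dunn, "anova_lsd": anova_lsd}.get(test)
    if fn is None:
        raise ConfigurationError(f"unknown test {test!r}")
    out = []
    for name in sorted(table["endpoint_name"].unique()):
        data = GroupedEndpoint.from_endpoint_table(table, name)
        out.append(fn(data, alpha))
    return out


def results_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Flatten comparison results into one tidy frame (for CSV output)."""
    rows = []
    for r in results:
        for _, pr in r.pairwise.iterrows():
            rows.append(
                {
                    "endpoint_name": r.endpoint_name,
                    "test": r.test,
                    "omnibus_stat": r.omnibus_stat,
                    "omnibus_p": r.omnibus_p,
                    "group_i": pr["group_i"],
                    "group_j": pr["group_j"],
                    "statistic": pr["statistic"],
                    "p_raw": pr["p_raw"],
                    "p_adj": pr["p_adj"],
                    "letters_i": r.letters[pr["group_i"]],
                    "letters_j": r.letters[pr["group_j"]],
                }
            )
    return pd.DataFrame(rows)
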