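"""Inferential layer: mixed ANOVA, post-hoc contrasts, corrections, power.

The central design is a mixed (split-plot) ANOVA with one between-subject
factor (experimental condition: dynamic vs static) and one or two
within-subject factors (electrode cluster, emotion).  Effects are tested with
the conventional univariate error strata (subjects within groups for the
between effect; factor x subjects-within-groups for each within stratum), no
sphericity correction by default, and partial eta squared
``df1*F / (df1*F + df2)`` as the effect size.  Post-hoc pairwise t-tests are
gated by the omnibus test (Fisher's LSD logic for families of at most three
means) with Holm-Bonferroni adjustment where a family holds more than one
comparison; FDR (Benjamini-Hochberg) is available for families of omnibus
tests.  The a-priori power computation inverts the noncentral-F power of the
within-between interaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult",
    "ContrastResult",
    "mixed_anova",
    "posthoc",
    "one_sample_t",
    "paired_t",
    "independent_t",
    "holm_bonferroni",
    "fdr_bh",
    "power_rm_anova",
    "null_type_one_error",
]

logger = logging.getLogger(__name__)


class StatsError(ValueError):
    pass


@dataclass
class AnovaResult:
    effect: str
    F: float
    df1: float
    df2: float
    p: float
    partial_eta_sq: float


@dataclass
class ContrastResult:
    pair: tuple[str, str]
    t: float
    df: float
    p_raw: float
    p_adjusted: float
    cohens_d: float
    method: str


# ---------------------------------------------------------------------------
# mixed ANOVA core (vectorised over leading batch axes)

def _mixed_anova_cells(Y: np.ndarray, group_sizes) -> list[tuple[str, float, float, np.ndarray]]:
    """Split-plot ANOVA on a cell-mean array ``Y`` of shape (..., N, b[, c]).

    Subjects (axis -3 or -2) must be ordered group-wise according to
    ``group_sizes``.  Returns a list of (effect key, df1, df2, F array) with
    effect keys "A", "B", "C", "AB", "AC", "BC", "ABC" (within-factor effects
    only when the corresponding axis has more than one level).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim < 2:
        raise StatsError("Y must have at least (subjects, within) axes")
    N_expected = int(sum(group_sizes))
    # normalise to (..., N, b, c); a singleton c axis marks a one-within design
    if Y.ndim >= 3 and Y.shape[-3] == N_expected:
        had_c = True
    elif Y.shape[-2] == N_expected:
        Y = Y[..., np.newaxis]
        had_c = False
    else:
        raise StatsError("could not locate the subject axis from group sizes")
    n_g = np.asarray(group_sizes, dtype=int)
    a = n_g.size
    N = int(n_g.sum())
    if Y.shape[-3] != N:
        raise StatsError(f"subject axis ({Y.shape[-3]}) does not match group sizes {group_sizes}")
    b, c = Y.shape[-2], Y.shape[-1]
    starts = np.concatenate([[0], np.cumsum(n_g)[:-1]])

    m_sjk = Y
    m_sj = Y.mean(-1)
    m_sk = Y.mean(-2)
    m_s = Y.mean((-1, -2))
    grand = m_s.mean(-1)

    def gstack(arr, sub_axis):
        """Group means along the subject axis -> stacked on a new axis."""
        pieces = [
            arr.take(range(s, s + n), axis=sub_axis).mean(axis=sub_axis)
            for s, n in zip(starts, n_g)
        ]
        return np.stack(pieces, axis=sub_axis)

    m_g = gstack(m_s, -1)            # (..., a)
    m_gj = gstack(m_sj, -2)          # (..., a, b)
    m_gk = gstack(m_sk, -2)          # (..., a, c)
    m_gjk = gstack(m_sjk, -3)        # (..., a, b, c)
    w = n_g / N
    m_j = np.einsum("...ab,a->...b", m_gj, w)
    m_k = np.einsum("...ac,a->...c", m_gk, w)
    m_jk = np.einsum("...abc,a->...bc", m_gjk, w)

    # subject -> group broadcast helpers
    rep = np.repeat(np.arange(a), n_g)
    mg_s = m_g[..., rep]             # (..., N)
    mgj_s = m_gj[..., rep, :]        # (..., N, b)
    mgk_s = m_gk[..., rep, :]        # (..., N, c)
    mgjk_s = m_gjk[..., rep, :, :]   # (..., N, b, c)

    e = np.newaxis
    ss = {}
    ss["A"] = b * c * np.einsum("...a,a->...", (m_g - grand[..., e]) ** 2, n_g.astype(float))
    ss["SwA"] = b * c * ((m_s - mg_s) ** 2).sum(-1)
    ss["B"] = c * N * ((m_j - grand[..., e]) ** 2).sum(-1)
    dev_ab = m_gj - m_g[..., e] - m_j[..., e, :] + grand[..., e, e]
    ss["AB"] = c * np.einsum("...ab,a->...", dev_ab**2, n_g.astype(float))
    dev_bs = m_sj - m_s[..., e] - mgj_s + mg_s[..., e]
    ss["BSwA"] = c * (dev_bs**2).sum((-1, -2))
    ss["C"] = b * N * ((m_k - grand[..., e]) ** 2).sum(-1)
    dev_ac = m_gk - m_g[..., e] - m_k[..., e, :] + grand[..., e, e]
    ss["AC"] = b * np.einsum("...ac,a->...", dev_ac**2, n_g.astype(float))
    dev_cs = m_sk - m_s[..., e] - mgk_s + mg_s[..., e]
    ss["CSwA"] = b * (dev_cs**2).sum((-1, -2))
    dev_bc = m_jk - m_j[..., e] - m_k[..., e, :] + grand[..., e, e]
    ss["BC"] = N * (dev_bc**2).sum((-1, -2))
    dev_abc = (
        m_gjk - m_gj[..., e] - m_gk[..., e, :] + m_g[..., e, e]
        - dev_bc[..., e, :, :]
    )
    ss["ABC"] = np.einsum("...abc,a->...", dev_abc**2, n_g.astype(float))
    dev_res = (
        m_sjk - m_sj[..., e] - m_sk[..., e, :] + m_s[..., e, e]
        - (m_gjk - m_gj[..., e] - m_gk[..., e, :] + m_g[..., e, e])[..., rep, :, :]
    )
    ss["BCSwA"] = (dev_res**2).sum((-1, -2, -3))

    out = []

    def add(name, ss_eff, df1, ss_err, df2):
        if df1 <= 0 or df2 <= 0:
            return
        F = (ss_eff / df1) / (ss_err / df2)
        out.append((name, float(df1), float(df2), F))

    add("A", ss["A"], a - 1, ss["SwA"], N - a)
    if b > 1:
        add("B", ss["B"], b - 1, ss["BSwA"], (N - a) * (b - 1))
        add("AB", ss["AB"], (a - 1) * (b - 1), ss["BSwA"], (N - a) * (b - 1))
    if c > 1 and had_c:
        add("C", ss["C"], c - 1, ss["CSwA"], (N - a) * (c - 1))
        add("AC", ss["AC"], (a - 1) * (c - 1), ss["CSwA"], (N - a) * (c - 1))
    if b > 1 and c > 1 and had_c:
        add("BC", ss["BC"], (b - 1) * (c - 1), ss["BCSwA"], (N - a) * (b - 1) * (c - 1))
        add(
            "ABC",
            ss["ABC"],
            (a - 1) * (b - 1) * (c - 1),
            ss["BCSwA"],
            (N - a) * (b - 1) * (c - 1),
        )
    return out


def mixed_anova(
    table: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    between: str = "condition",
    within=("emotion",),
) -> pd.DataFrame:
    """Mixed-design ANOVA with one between and one or two within factors.

    The table must be balanced in the within factors (every subject has every
    within-cell exactly once); a missing cell raises an error naming the
    subject and cell.  Returns a DataFrame with columns effect, F, df1, df2,
    p, partial_eta_sq.
    """
    if isinstance(within, str):
        within = (within,)
    within = tuple(within)
    if not 1 <= len(within) <= 2:
        raise StatsError("one or two within factors supported")
    cols = [subject, between, *within, dv]
    missing_cols = [c for c in cols if c not in table.columns]
    if missing_cols:
        raise StatsError(f"table lacks columns {missing_cols}")
    df = table.loc[:, cols].copy()

    groups = sorted(df[between].unique())
    levels = {w: sorted(df[w].unique()) for w in within}
    n_cells = int(np.prod([len(levels[w]) for w in within]))
    subj_group = df.groupby(subject)[between].agg(lambda s: sorted(set(s)))
    multi = subj_group[subj_group.map(len) > 1]
    if len(multi):
        raise StatsError(f"subject {multi.index[0]!r} appears in multiple groups")

    pivot = df.pivot_table(index=[between, subject], columns=list(within), values=dv)
    if pivot.isna().any().any() or pivot.shape[1] != n_cells:
        bad = pivot.isna().stack([*range(pivot.columns.nlevels)], future_stack=True)
        bad = bad[bad]
        if len(bad):
            idx = bad.index[0]
            raise StatsError(f"missing cell for subject/cell {idx}")
        raise StatsError("unbalanced within-factor design")
    counts = df.groupby([subject] + list(within)).size()
    if (counts != 1).any():
        raise StatsError(f"duplicate rows for {counts[counts != 1].index[0]}")

    pivot = pivot.sort_index()
    group_sizes = [int((pivot.index.get_level_values(0) == g).sum()) for g in groups]
    shape = [sum(group_sizes)] + [len(levels[w]) for w in within]
    Y = pivot.to_numpy().reshape(shape)

    raw = _mixed_anova_cells(Y, group_sizes)
    name_map = {
        "A": between,
        "B": within[0],
        "AB": f"{between} * {within[0]}",
    }
    if len(within) == 2:
        name_map.update(
            {
                "C": within[1],
                "AC": f"{between} * {within[1]}",
                "BC": f"{within[0]} * {within[1]}",
                "ABC": f"{between} * {within[0]} * {within[1]}",
            }
        )
    rows = []
    for key, df1, df2, F in raw:
        F = float(F)
        p = float(sps.f.sf(F, df1, df2))
        rows.append(
            {
                "effect": name_map[key],
                "F": F,
                "df1": df1,
                "df2": df2,
                "p": p,
                "partial_eta_sq": df1 * F / (df1 * F + df2),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# contrasts

def _cohens_d_paired(diff: np.ndarray) -> float:
    return float(np.mean(diff) / np.std(diff, ddof=1))


def paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Paired two-tailed t-test; returns (t, df, p, cohen's d of differences)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    diff = x - y
    n = diff.size
    if n < 2:
        raise StatsError("paired t needs n >= 2")
    t, p = sps.ttest_rel(x, y)
    return float(t), float(n - 1), float(p), _cohens_d_paired(diff)


def independent_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Independent-samples two-tailed t (pooled variance) with Cohen's d."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = x.size, y.size
    if min(n1, n2) < 2:
        raise StatsError("independent t needs n >= 2 per group")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    sp = np.sqrt(((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (n1 + n2 - 2))
    d = float((np.mean(x) - np.mean(y)) / sp)
    return float(t), float(n1 + n2 - 2), float(p), d


def one_sample_t(values, mu0: float = 0.0) -> ContrastResult:
    """Two-tailed one-sample t against ``mu0`` with Cohen's d = mean/sd."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise StatsError("one-sample t needs n >= 2")
    sd = np.std(values, ddof=1)
    if sd == 0:
        raise StatsError("zero variance: t statistic undefined")
    t, p = sps.ttest_1samp(values, popmean=mu0)
    d = float((values.mean() - mu0) / sd)
    return ContrastResult(
        pair=("sample", f"mu0={mu0:g}"),
        t=float(t),
        df=float(values.size - 1),
        p_raw=float(p),
        p_adjusted=float(p),
        cohens_d=d,
        method="none",
    )


def posthoc(
    table: pd.DataFrame,
    factor: str,
    omnibus_p: float,
    dv: str = "value",
    subject: str = "subject",
    paired: bool = True,
    alpha: float = 0.05,
    gate: str = "lsd-when-3-means",
    correction: str = "holm",
) -> list[ContrastResult]:
    """Pairwise post-hoc contrasts over the levels of ``factor``.

    Contrasts run only if the gated omnibus test is significant (Fisher's LSD
    logic, valid for families of at most three means; for larger families the
    gate still applies but Holm provides the family-wise protection).  Paired
    t-tests are used for within-subject factors, independent t otherwise.
    Holm adjustment is applied when the family holds more than one comparison.
    Returns an empty list, with the reason logged, when the gate fails.
    """
    levels = sorted(table[factor].unique())
    if gate == "lsd-when-3-means" and omnibus_p > alpha:
        logger.info(
            "post-hoc gate: omnibus p=%.4g > alpha=%.3g for factor %r; no contrasts",
            omnibus_p,
            alpha,
            factor,
        )
        return []
    pairs, stats = [], []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            la, lb = levels[i], levels[j]
            if paired:
                wide = table.pivot_table(index=subject, columns=factor, values=dv)
                t, dfree, p, d = paired_t(wide[la].to_numpy(), wide[lb].to_numpy())
            else:
                xa = table.loc[table[factor] == la, dv].to_numpy()
                xb = table.loc[table[factor] == lb, dv].to_numpy()
                t, dfree, p, d = independent_t(xa, xb)
            pairs.append((la, lb))
            stats.append((t, dfree, p, d))
    p_raw = np.array([s[2] for s in stats])
    if correction == "holm" and len(pairs) > 1:
        p_adj = holm_bonferroni(p_raw)
        method = "holm"
    else:
        p_adj = p_raw.copy()
        method = "lsd-gated" if len(levels) <= 3 else "none"
    out = []
    for k, pair in enumerate(pairs):
        t, dfree, _, d = stats[k]
        out.append(
            ContrastResult(
                pair=pair,
                t=t,
                df=dfree,
                p_raw=float(p_raw[k]),
                p_adjusted=float(max(p_adj[k], p_raw[k])),
                cohens_d=d,
                method=method,
            )
        )
    return out


def holm_bonferroni(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    pvalues = np.asarray(pvalues, dtype=float)
    return multipletests(pvalues, method="holm")[1]


def fdr_bh(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up at level ``q``: (reject flags, adjusted p)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if np.any((pvalues <= 0) | (pvalues > 1)):
        raise StatsError("p-values must be in (0, 1]")
    reject, p_adj, _, _ = multipletests(pvalues, alpha=q, method="fdr_bh")
    return reject, p_adj


# ---------------------------------------------------------------------------
# power

def power_rm_anova(
    f: float = 0.25,
    alpha: float = 0.05,
    power: float = 0.80,
    n_groups: int = 2,
    n_measures: int = 3,
    rho: float = 0.5,
    epsilon: float = 1.0,
    n_max: int = 10**6,
) -> int:
    """Required total N for the within-between interaction of a mixed ANOVA.

    Follows the common power-software convention: noncentrality
    ``lambda = f^2 * N * m / (1 - rho) * epsilon`` with numerator df
    ``(k-1)(m-1)*epsilon`` and denominator df ``(N-k)(m-1)*epsilon``, where k
    is the number of groups, m the number of repeated measures, rho the
    assumed correlation among repeated measures and epsilon the nonsphericity
    correction.  Returns the smallest N whose power reaches the target.
    """
    if f <= 0 or not 0 < alpha < 1 or not 0 < power < 1 or not 0 <= rho < 1:
        raise StatsError("invalid power-analysis parameters")
    df1 = (n_groups - 1) * (n_measures - 1) * epsilon
    for N in range(n_groups + 1, n_max + 1):
        df2 = (N - n_groups) * (n_measures - 1) * epsilon
        lam = f**2 * N * n_measures / (1.0 - rho) * epsilon
        fcrit = sps.f.ppf(1.0 - alpha, df1, df2)
        achieved = float(sps.ncf.sf(fcrit, df1, df2, lam))
        if achieved >= power:
            return N
    raise StatsError(f"target power unreachable within N <= {n_max}")


# ---------------------------------------------------------------------------
# Monte-Carlo calibration

def null_type_one_error(
    n_reps: int = 1000,
    group_sizes=(19, 19),
    n_b: int = 2,
    n_c: int = 3,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Type-I error of every mixed-ANOVA effect under a pure-noise null.

    Simulates ``n_reps`` studies of i.i.d. standard-normal cell means and
    returns the rejection rate at ``alpha`` per effect.
    """
    rng = np.random.default_rng(seed)
    N = int(sum(group_sizes))
    Y = rng.standard_normal((n_reps, N, n_b, n_c))
    rates = {}
    for key, df1, df2, F in _mixed_anova_cells(Y, group_sizes):
        p = sps.f.sf(F, df1, df2)
        rates[key] = float(np.mean(p < alpha))
    return rates
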