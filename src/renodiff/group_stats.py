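"""Group-comparison statistics: paired Wilcoxon signed-rank tests and
one-way MANOVA (Wilks' lambda) with Bonferroni-corrected pairwise
contrasts.

Observations are lesion-level (one value per lesion/tissue region), not
voxel-level.  Zero paired differences are dropped before ranking; ties
get mid-ranks with a variance correction in the normal-approximation
branch.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from renodiff.exceptions import DegenerateDataError, ValidationError

log = logging.getLogger(__name__)

ALPHA = 0.05

PARAMETERS = ("MD", "FA", "f_star", "D_bi", "f_fast", "f_interm", "D_tri")


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def wilcoxon_signed_rank(paired_a, paired_b, exact_threshold: int = 12):
    """Two-sided paired Wilcoxon signed-rank test.

    Statistic W is the smaller of the positive/negative rank sums
    (min-rank-sum convention).  For n <= ``exact_threshold`` non-zero
    differences the p-value is exact, from full enumeration of all 2^n
    sign assignments (mid-ranks kept under ties); otherwise a normal
    approximation with continuity and tie corrections is used.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired samples must be 1D and of equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    if n < 5:
        raise DegenerateDataError(
            f"only {n} non-zero differences; need at least 5 for a meaningful test"
        )
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))
    w_minus = float(np.sum(ranks[d < 0]))
    w = min(w_plus, w_minus)

    if n <= exact_threshold:
        # enumerate every sign assignment; T = sum of ranks given + sign
        signs = np.array(list(itertools.product([0.0, 1.0], repeat=n)))
        t_null = signs @ ranks
        p = 2.0 * np.mean(t_null <= w + 1e-12)
        p = min(1.0, p)
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        # tie correction on mid-ranks
        _, counts = np.unique(np.abs(d), return_counts=True)
        var -= np.sum(counts**3 - counts) / 48.0
        z = (w - mean + 0.5) / np.sqrt(var)  # continuity correction
        p = min(1.0, 2.0 * stats.norm.cdf(z))
    return w, float(p)


# ---------------------------------------------------------------------------
# MANOVA


@dataclass
class ComparisonResult:
    """One group contrast: per-parameter statistics with Bonferroni
    adjustment and significance flags at alpha = 0.05."""

    name: str
    letter: str
    kind: str  # {"manova-pairwise", "wilcoxon"}
    per_parameter: dict = field(default_factory=dict)
    # per_parameter[param] = {"statistic", "p_raw", "p_adjusted", "significant"}

    def __post_init__(self):
        for p, d in self.per_parameter.items():
            if d["p_adjusted"] < d["p_raw"] - 1e-15:
                raise ValidationError(f"adjusted p < raw p for {p}")

    def significant_parameters(self):
        return [p for p, d in self.per_parameter.items() if d["significant"]]


@dataclass
class MANOVAResult:
    wilks_lambda: float
    F: float
    df1: float
    df2: float
    p: float
    contrasts: list = field(default_factory=list)


def _wilks_to_f(lam: float, p: int, nu_h: int, nu_e: int):
    """Rao's F transformation of Wilks' lambda (exact for p <= 2 or
    nu_h <= 2, which covers the univariate-equals-ANOVA identity)."""
    if p == 1 or nu_h == 1:
        t = 1.0
    else:
        num = p * p * nu_h * nu_h - 4.0
        den = p * p + nu_h * nu_h - 5.0
        t = np.sqrt(num / den) if den > 0 and num > 0 else 1.0
    w = nu_e + nu_h - (p + nu_h + 1) / 2.0
    df1 = p * nu_h
    df2 = w * t - (p * nu_h - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    F = (1.0 - lam_t) / lam_t * df2 / df1
    return F, df1, df2


def manova_groups(table: pd.DataFrame, group_column: str, parameter_columns, alpha: float = ALPHA) -> MANOVAResult:
    """One-way MANOVA across groups plus pairwise per-parameter contrasts.

    The overall test is Wilks' lambda with Rao's F approximation.
    Pairwise contrasts use t-tests with the pooled within-group variance
    of the full model (df = N - k); each parameter's family of pairwise
    contrasts is Bonferroni-corrected.
    """
    parameter_columns = list(parameter_columns)
    groups = list(dict.fromkeys(table[group_column]))
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    counts = table.groupby(group_column, sort=False).size()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValidationError(f"groups {small} have fewer than 2 observations")
    X = table[parameter_columns].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValidationError("parameter columns contain non-finite values")
    g = table[group_column].to_numpy()
    N, p = X.shape
    k = len(groups)

    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for name in groups:
        sub = X[g == name]
        mu = sub.mean(axis=0)
        c = sub - mu
        W += c.T @ c
        d = (mu - grand)[:, None]
        B += len(sub) * (d @ d.T)

    nu_e = N - k
    sign, logdet_w = np.linalg.slogdet(W)
    if sign <= 0 or nu_e < p or np.linalg.cond(W) > 1e12:
        raise ValidationError(
            "within-group covariance is singular; reduce the number of "
            "parameters or pool groups"
        )
    sign_t, logdet_t = np.linalg.slogdet(W + B)
    lam = float(np.exp(logdet_w - logdet_t))
    F, df1, df2 = _wilks_to_f(lam, p, k - 1, nu_e)
    p_overall = float(stats.f.sf(F, df1, df2)) if df2 > 0 else np.nan

    # pairwise contrasts with pooled error; Bonferroni per parameter
    # across the family of group pairs
    pairs = list(itertools.combinations(groups, 2))
    m = len(pairs)
    mse = np.diag(W) / nu_e
    contrasts = []
    for g1, g2 in pairs:
        x1, x2 = X[g == g1], X[g == g2]
        per = {}
        for j, param in enumerate(parameter_columns):
            se = np.sqrt(mse[j] * (1.0 / len(x1) + 1.0 / len(x2)))
            tstat = (x1[:, j].mean() - x2[:, j].mean()) / se if se > 0 else np.inf
            p_raw = float(2.0 * stats.t.sf(abs(tstat), nu_e))
            p_adj = min(1.0, m * p_raw)
            per[param] = {
                "statistic": float(tstat), "p_raw": p_raw,
                "p_adjusted": p_adj, "significant": bool(p_adj < alpha),
            }
        contrasts.append(ComparisonResult(
            name=f"{g1} vs {g2}", letter="", kind="manova-pairwise", per_parameter=per,
        ))
    return MANOVAResult(wilks_lambda=lam, F=float(F), df1=df1, df2=df2,
                        p=p_overall, contrasts=contrasts)


# ---------------------------------------------------------------------------
# the full contrast grid

#: pairwise MANOVA contrasts and their annotation letters
PAIRWISE_LETTERS = {
    "a": ("cortex", "rcc"),
    "b": ("cortex", "cyst"),
    "c": ("cortex", "benign"),
    "d": ("medulla", "rcc"),
    "e": ("medulla", "cyst"),
    "f": ("medulla", "benign"),
    "g": ("rcc", "cyst"),
    "h": ("rcc", "benign"),
    "i": ("benign", "cyst"),
    "j": ("cortex", "medulla"),
}

#: paired Wilcoxon contrasts (healthy tissue vs all solid lesions, and
#: cortex vs medulla), matched within patient
WILCOXON_LETTERS = {
    "x": ("cortex", "solid"),
    "y": ("medulla", "solid"),
    "z": ("cortex", "medulla"),
}

_SOLID_GROUPS = ("rcc", "benign")


def _paired_values(table, group_a, group_b, param):
    """Patient-matched means of ``param`` for two tissue groups."""
    a_vals, b_vals = [], []
    for _, sub in table.groupby("patient"):
        if group_a == "solid":
            xa = sub[sub.group.isin(_SOLID_GROUPS)][param]
        else:
            xa = sub[sub.group == group_a][param]
        if group_b == "solid":
            xb = sub[sub.group.isin(_SOLID_GROUPS)][param]
        else:
            xb = sub[sub.group == group_b][param]
        if len(xa) and len(xb):
            a_vals.append(float(xa.mean()))
            b_vals.append(float(xb.mean()))
    return np.array(a_vals), np.array(b_vals)


def run_group_contrasts(table: pd.DataFrame, parameters=PARAMETERS, alpha: float = ALPHA) -> dict:
    """Execute the full contrast grid on a cohort table.

    ``table`` needs columns ``group`` (cortex / medulla / rcc / cyst /
    benign), ``patient`` (for the paired Wilcoxon contrasts) and the
    parameter columns.  Pairwise contrasts a-j come from a one-way
    MANOVA over the available groups (Bonferroni per parameter over the
    pairwise family); contrasts x/y/z are patient-paired Wilcoxon tests
    (Bonferroni over that family of 3).  Missing groups are skipped with
    a warning.  Returns ``{letter: ComparisonResult}``.
    """
    parameters = [p for p in parameters if p in table.columns]
    if not parameters:
        raise ValidationError("no parameter columns found in the table")
    present = set(table["group"])
    results: dict = {}

    manova_groups_present = [
        g for g in ("cortex", "medulla", "rcc", "cyst", "benign")
        if g in present and (table.group == g).sum() >= 2
    ]
    if len(manova_groups_present) >= 2:
        sub = table[table.group.isin(manova_groups_present)]
        res = manova_groups(sub, "group", parameters, alpha=alpha)
        by_pair = {}
        for c in res.contrasts:
            g1, g2 = c.name.split(" vs ")
            by_pair[frozenset((g1, g2))] = c
        for letter, (g1, g2) in PAIRWISE_LETTERS.items():
            c = by_pair.get(frozenset((g1, g2)))
            if c is None:
                warnings.warn(f"contrast {letter} ({g1} vs {g2}) skipped: group missing")
                continue
            c.letter = letter
            results[letter] = c
    else:
        warnings.warn("fewer than 2 MANOVA-eligible groups; pairwise contrasts skipped")

    n_wilcoxon = len(WILCOXON_LETTERS)
    for letter, (g1, g2) in WILCOXON_LETTERS.items():
        per = {}
        try:
            for param in parameters:
                a, b = _paired_values(table, g1, g2, param)
                w, p_raw = wilcoxon_signed_rank(a, b)
                p_adj = min(1.0, n_wilcoxon * p_raw)
                per[param] = {
                    "statistic": w, "p_raw": p_raw,
                    "p_adjusted": p_adj, "significant": bool(p_adj < alpha),
                }
        except (DegenerateDataError, ValidationError) as exc:
            warnings.warn(f"contrast {letter} ({g1} vs {g2}) skipped: {exc}")
            continue
        results[letter] = ComparisonResult(
            name=f"{g1} vs {g2} (paired)", letter=letter, kind="wilcoxon",
            per_parameter=per,
        )
    return results


def significance_annotation(results: dict, parameters=PARAMETERS) -> dict:
    """Per-parameter comma-separated letters of the significant contrasts,
    the shape of a summary table's significance row."""
    out = {}
    for param in parameters:
        letters = [
            letter for letter, c in sorted(results.items())
            if param in c.per_parameter and c.per_parameter[param]["significant"]
        ]
        out[param] = ", ".join(letters)
    return out


def contrasts_to_frame(results: dict) -> pd.DataFrame:
    """Tidy frame of every contrast x parameter (for TSV export)."""
    rows = []
    for letter, c in sorted(results.items()):
        for param, d in c.per_parameter.items():
            rows.append({
                "letter": letter, "contrast": c.name, "kind": c.kind,
                "parameter": param, "statistic": d["statistic"],
                "p_raw": d["p_raw"], "p_adjusted": d["p_adjusted"],
                "significant": d["significant"],
            })
    return pd.DataFrame(rows)
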