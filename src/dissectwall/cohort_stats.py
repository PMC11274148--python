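"""Two-group cohort statistics and summary tables.

The comparison pipeline mirrors common clinical-paper practice: Shapiro-Wilk
normality screening per group, a log transform for strictly positive
non-normal data with a re-test, an unpaired two-sided t-test when normality
holds and a Mann-Whitney U test otherwise; Fisher's exact test (full
hypergeometric enumeration) for categorical variables; Pearson correlation
with a t-distributed p-value. Significance is read at two-tailed p < 0.05 and
no multiple-testing correction is applied (per-variable reporting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "compare_groups",
    "fisher_exact",
    "correlate",
    "cohort_report",
    "outcome_rates",
    "report_to_markdown",
]


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a normality-gated two-sample comparison."""

    test: str  # "t" or "mann-whitney"
    transformed: bool
    p: float
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("p-value outside [0, 1]")


def _shapiro_p(x: np.ndarray) -> float | None:
    """Shapiro-Wilk p, or None when undefined (constant sample)."""
    if np.ptp(x) == 0:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.shapiro(x).pvalue)


def compare_groups(x, y, alpha_norm: float = 0.05) -> ComparisonResult:
    """Normality-gated unpaired two-sided comparison of two samples.

    Shapiro-Wilk on each group; if either is non-normal and the data are
    strictly positive, both groups are log-transformed and re-tested; if
    normality still fails (or the data admit no log transform) a Mann-Whitney
    U test is used (exact when both n <= 10 and tie-free, otherwise the normal
    approximation with tie correction), else the pooled-variance t-test.
    Reported means and sds are always on the original scale.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    summary = dict(
        mean_x=float(x.mean()), sd_x=float(x.std(ddof=1)),
        mean_y=float(y.mean()), sd_y=float(y.std(ddof=1)),
    )

    px, py = _shapiro_p(x), _shapiro_p(y)
    if px is None or py is None:
        warnings.warn("constant sample: normality undefined, using Mann-Whitney", stacklevel=2)
        return ComparisonResult("mann-whitney", False, _mannwhitney_p(x, y), **summary)

    transformed = False
    tx, ty = x, y
    if min(px, py) < alpha_norm:
        if x.min() > 0 and y.min() > 0:
            lx, ly = np.log(x), np.log(y)
            plx, ply = _shapiro_p(lx), _shapiro_p(ly)
            if plx is not None and ply is not None and min(plx, ply) >= alpha_norm:
                tx, ty, transformed = lx, ly, True
            else:
                return ComparisonResult("mann-whitney", False, _mannwhitney_p(x, y), **summary)
        else:
            return ComparisonResult("mann-whitney", False, _mannwhitney_p(x, y), **summary)

    p = float(sps.ttest_ind(tx, ty, equal_var=True).pvalue)
    return ComparisonResult("t", transformed, p, **summary)


def _mannwhitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney p: exact for small tie-free samples, else the
    tie-corrected normal approximation (z = 0 gives p = 1 for identical
    samples)."""
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 10 and len(y) <= 10 and not has_ties) else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    Sums the probabilities of every table with the observed margins whose
    probability does not exceed the observed one (1e-12 relative slack).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a 2x2 table of nonnegative integer counts")
    a, b = t[0]
    c, d = t[1]
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        raise ValueError("both margins must be positive")
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    probs = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = sps.hypergeom.pmf(a, n, r1, c1)
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def correlate(x, y) -> tuple[float, float]:
    """Pearson product-moment r with the two-tailed t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need matched samples of length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return r, p


# -------------------------------------------------------- cohort reporting

#: (display name, record field, kind) in table order
REPORT_ROWS: tuple[tuple[str, str, str], ...] = (
    ("Age [years]", "age", "cont"),
    ("Male sex", "sex", "cat"),
    ("Initial aortic diameter [mm]", "initial_diameter_mm", "cont"),
    ("TL/DA area ratio", "tl_da_ratio", "cont"),
    ("Entry tear size [mm2]", "tear_area_mm2", "cont"),
    ("Number of re-entry tears", "n_reentry_tears", "cont"),
    ("Tortuosity", "tortuosity", "cont"),
    ("FL flow [%]", "fl_flow_pct", "cont"),
    ("Peak TAWSS (entry tear) [Pa]", "peak_tear_tawss_pa", "cont"),
    ("TAWSS x margins (entry tear) [Pa mm]", "tawss_margins_pa_mm", "cont"),
)

MORTALITY_ROWS = ("fl_flow_pct", "tortuosity", "tawss_margins_pa_mm")


def records_to_frame(records) -> pd.DataFrame:
    from dataclasses import asdict

    return pd.DataFrame([asdict(r) for r in records])


def _two_group_table(df: pd.DataFrame, split: pd.Series, names: tuple[str, str]) -> pd.DataFrame:
    rows = []
    ga, gb = df[split], df[~split]
    for label, field, kind in REPORT_ROWS:
        if field not in df.columns:
            raise ValueError(f"cohort table is missing column '{field}'")
        if kind == "cat":
            ka = int((ga[field] == "M").sum())
            kb = int((gb[field] == "M").sum())
            try:
                p = fisher_exact([[ka, len(ga) - ka], [kb, len(gb) - kb]])
            except ValueError:
                p = float("nan")
            rows.append({
                "variable": label,
                names[0]: f"{ka} ({100 * ka / len(ga):.0f}%)",
                names[1]: f"{kb} ({100 * kb / len(gb):.0f}%)",
                "p": p, "test": "fisher",
            })
        else:
            xa = ga[field].to_numpy(float)
            xb = gb[field].to_numpy(float)
            try:
                res = compare_groups(xa, xb)
                p, test = res.p, res.test
            except ValueError:
                p, test = float("nan"), "undefined"
            fmt = lambda v: f"{np.mean(v):.2f} ± {np.std(v, ddof=1):.2f}"
            rows.append({
                "variable": label, names[0]: fmt(xa), names[1]: fmt(xb),
                "p": p, "test": test,
            })
    return pd.DataFrame(rows).set_index("variable")


def outcome_rates(records) -> dict[str, float]:
    """Whole-cohort re-intervention and death percentages."""
    df = records_to_frame(records)
    n = len(df)
    return {
        "reintervention_pct": round(100.0 * df["reintervention"].sum() / n),
        "death_pct": round(100.0 * df["death"].sum() / n),
        "n": n,
    }


def cohort_report(records) -> dict[str, pd.DataFrame]:
    """Group, subgroup and mortality summary tables for a cohort.

    Accepts a list of records or an equivalent DataFrame. Returns
    ``{"groups", "subgroups", "mortality"}``: stable vs rapid over all
    patients, favorable vs adverse within the stable-size group, and the
    death-vs-survival comparison of FL flow, tortuosity and the tear-margin
    TAWSS statistic over the whole cohort.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    required = {f for _, f, _ in REPORT_ROWS} | {"group", "subgroup", "death", "reintervention"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")

    out: dict[str, pd.DataFrame] = {}
    is_stable = df["group"] == "stable"
    n_s, n_r = int(is_stable.sum()), int((~is_stable).sum())
    groups = _two_group_table(df, is_stable, (f"Stable size (n = {n_s})", f"Rapid growth (n = {n_r})"))
    groups.attrs["header"] = f"n = {n_s} / n = {n_r}"
    out["groups"] = groups

    sub = df[is_stable]
    fav = sub["subgroup"] == "favorable"
    if fav.any() and (~fav).any():
        out["subgroups"] = _two_group_table(
            sub, fav,
            (f"Favorable outcome (n = {int(fav.sum())})", f"Adverse outcome (n = {int((~fav).sum())})"),
        )

    dead = df["death"].astype(bool)
    rows = []
    for field in MORTALITY_ROWS:
        xa = df.loc[dead, field].to_numpy(float)
        xb = df.loc[~dead, field].to_numpy(float)
        try:
            res = compare_groups(xa, xb)
            p, test = res.p, res.test
        except ValueError:
            p, test = float("nan"), "undefined"
        fmt = lambda v: f"{np.mean(v):.2f} ± {np.std(v, ddof=1):.2f}" if len(v) else "-"
        rows.append({
            "variable": field,
            f"Death (n = {int(dead.sum())})": fmt(xa),
            f"Survival (n = {int((~dead).sum())})": fmt(xb),
            "p": p, "test": test,
        })
    out["mortality"] = pd.DataFrame(rows).set_index("variable")
    return out


def report_to_markdown(report: dict[str, pd.DataFrame]) -> str:
    parts = []
    titles = {
        "groups": "Stable size vs rapid growth",
        "subgroups": "Stable-size subgroups: favorable vs adverse outcome",
        "mortality": "Whole cohort: death vs survival",
    }
    for key, df in report.items():
        parts.append(f"## {titles.get(key, key)}")
        header = df.attrs.get("header")
        if header:
            parts.append(f"({header})")
        parts.append(df.to_markdown(floatfmt=".3f"))
        parts.append("")
    return "\n\n".join(parts)
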