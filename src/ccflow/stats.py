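"""Cohort statistics: unpaired t-tests, chi-square, Pearson and partial
correlation, and the grouped report tables.

All tests are two-sided.  The t-test accepts either raw samples or
printed summary triples (n, mean, sd), so the published group tables
can be re-tested without individual-level data.  "Adjusted p" is the
partial-correlation p-value between a 0/1 group indicator and the
metric, controlling for age and sex — the residual-on-residual
operationalization of covariate adjustment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class SummaryStat:
    """Printed group summary: n, mean, sd."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def from_values(cls, values) -> "SummaryStat":
        v = np.asarray(values, dtype=float)
        return cls(n=v.size, mean=float(v.mean()), sd=float(v.std(ddof=1)))


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float


def _as_summary(x) -> SummaryStat:
    return x if isinstance(x, SummaryStat) else SummaryStat.from_values(x)


def ttest_two_sample(a, b, variant: str = "student") -> TestResult:
    """Unpaired two-sample t-test from raw values or summary statistics.

    ``variant='student'`` pools the variances; ``'welch'`` uses the
    Satterthwaite degrees of freedom.  The two input forms agree
    exactly when the summaries are computed from the raw values.
    """
    sa, sb = _as_summary(a), _as_summary(b)
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    va, vb = sa.sd ** 2, sb.sd ** 2
    if va == 0 and vb == 0:
        raise ValueError("t statistic undefined: zero variance in both groups")
    if variant == "student":
        df = sa.n + sb.n - 2
        sp2 = ((sa.n - 1) * va + (sb.n - 1) * vb) / df
        se = np.sqrt(sp2 * (1 / sa.n + 1 / sb.n))
    else:
        se = np.sqrt(va / sa.n + vb / sb.n)
        df = se ** 4 / (
            (va / sa.n) ** 2 / (sa.n - 1) + (vb / sb.n) ** 2 / (sb.n - 1)
        )
    t = (sa.mean - sb.mean) / se
    p = 2 * sps.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=float(df), p_value=float(p))


def chisq_2x2(table, yates: bool = False) -> TestResult:
    """Pearson chi-square on a 2×2 contingency table (1 df).

    No continuity correction by default; set ``yates=True`` for the
    Yates-corrected statistic.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or (obs < 0).any():
        raise ValueError("table must be 2×2 with non-negative counts")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    n = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("chi-square undefined with a zero margin")
    expected = row @ col / n
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0)
    chi2 = float((diff ** 2 / expected).sum())
    return TestResult(statistic=chi2, df=1.0, p_value=float(sps.chi2.sf(chi2, 1)))


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided p via the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired finite values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined: zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    r_ = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r_ * np.sqrt((n - 2) / (1 - r_ ** 2))
    p = float(2 * sps.t.sf(abs(t), n - 2))
    return r, p


def partial_correlation(x, y, covariates=None) -> TestResult:
    """Correlation of x and y after removing the linear effect of covariates.

    Both variables are regressed on [1, covariates] by least squares;
    the Pearson correlation of the residuals carries
    df = n − 2 − n_covariates.  With no covariates this reduces exactly
    to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None:
        z = np.empty((n, 0))
    else:
        z = np.asarray(covariates, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
    if y.size != n or z.shape[0] != n:
        raise ValueError("x, y and covariates must share n")
    k = z.shape[1]
    if n <= k + 2:
        raise ValueError("need n > n_covariates + 2")
    design = np.column_stack([np.ones(n), z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear covariates: design matrix is rank deficient")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    scale = max(np.abs(y).max(), 1.0)
    if rx.std() == 0 or ry.std() / scale < 1e-12:
        raise ValueError("residual is (numerically) zero: correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_ = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r_ * np.sqrt(df / (1 - r_ ** 2))
    p = float(2 * sps.t.sf(abs(t), df))
    return TestResult(statistic=r, df=float(df), p_value=p)


# ---------------------------------------------------------------------------
# grouped report tables

_CONTINUOUS_METRICS = [
    ("age", "Age (yr)"),
    ("axial_length_mm", "Axial length (mm)"),
    ("sfct_um", "SFCT (um)"),
    ("n_voids", "Number of flow voids"),
    ("total_void_area_mm2", "Total flow void area (mm2)"),
    ("mean_void_size_um2", "Average size of the flow voids (um2)"),
]

REQUIRED_COLUMNS = [c for c, _ in _CONTINUOUS_METRICS] + [
    "group", "sex", "pachyvessel_in_3mm", "rpe_vein_distance_um",
]


def _fmt_cell(v: np.ndarray) -> str:
    sd = f"{v.std(ddof=1):.3g}" if v.size > 1 else "-"
    return f"{v.mean():.4g} ± {sd} ({v.min():.4g}–{v.max():.4g})"


def _adjusted_p(metric: np.ndarray, indicator: np.ndarray, age: np.ndarray,
                sex01: np.ndarray) -> float:
    return partial_correlation(indicator, metric, np.column_stack([age, sex01])).p_value


def _two_group_block(df: pd.DataFrame, group_col: str, g1: str, g2: str,
                     metrics: list[tuple[str, str]], ttest_variant: str,
                     adjust: bool, notices: list[str]) -> dict:
    d1, d2 = df[df[group_col] == g1], df[df[group_col] == g2]
    indicator = (df[group_col] == g1).to_numpy(float)
    sex01 = (df["sex"] == "M").to_numpy(float)
    age = df["age"].to_numpy(float)
    rows = {}
    for col, label in metrics:
        v1 = d1[col].dropna().to_numpy(float)
        v2 = d2[col].dropna().to_numpy(float)
        row = {"g1": _fmt_cell(v1) if v1.size else "-",
               "g2": _fmt_cell(v2) if v2.size else "-"}
        if v1.size >= 2 and v2.size >= 2:
            row["p"] = ttest_two_sample(v1, v2, ttest_variant).p_value
            if adjust and col == "age":
                row["p_adj"] = None  # cannot adjust age for itself
            elif adjust:
                ok = df[col].notna().to_numpy()
                try:
                    row["p_adj"] = _adjusted_p(df[col].to_numpy(float)[ok],
                                               indicator[ok], age[ok], sex01[ok])
                except ValueError as exc:
                    notices.append(f"adjusted p unavailable for {col}: {exc}")
                    row["p_adj"] = None
        else:
            notices.append(f"p for {label} not computed: a group is empty or too small")
            row["p"] = None
            row["p_adj"] = None
        rows[col] = row
    return rows


def run_table_reports(
    cohort: pd.DataFrame | str | Path,
    ttest_variant: str = "student",
    adjust: bool = True,
) -> dict:
    """Produce the grouped study tables from a cohort table.

    Emits three blocks: participant characteristics and flow-void
    metrics for PPE vs control (mean ± sd with range, t-test p,
    age/sex-adjusted p, chi-square for the sex ratio), and the
    within-PPE pachyvessel vs non-pachyvessel comparison including the
    RPE-to-choroidal-vein distance.  Returns a JSON-serializable dict;
    :func:`render_report_markdown` renders it deterministically.
    """
    if not isinstance(cohort, pd.DataFrame):
        cohort = pd.read_csv(cohort)
    missing = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {', '.join(missing)}")

    notices: list[str] = []
    report: dict = {"n": {"PPE": int((cohort["group"] == "PPE").sum()),
                          "control": int((cohort["group"] == "control").sum())}}

    both = report["n"]["PPE"] >= 2 and report["n"]["control"] >= 2
    characteristics = _CONTINUOUS_METRICS[:3]
    flowvoid = _CONTINUOUS_METRICS[3:]
    if both:
        report["characteristics"] = _two_group_block(
            cohort, "group", "PPE", "control", characteristics, ttest_variant, adjust, notices)
        report["flow_voids"] = _two_group_block(
            cohort, "group", "PPE", "control", flowvoid, ttest_variant, adjust, notices)
        sex_table = [
            [int(((cohort["group"] == g) & (cohort["sex"] == s)).sum()) for s in ("M", "F")]
            for g in ("PPE", "control")
        ]
        try:
            report["sex"] = {"table": sex_table, "p": chisq_2x2(sex_table).p_value}
        except ValueError as exc:
            notices.append(f"sex-ratio chi-square not computed: {exc}")
            report["sex"] = {"table": sex_table, "p": None}
    else:
        notices.append("only one group present: between-group p-values not computed")
        report["characteristics"] = {}
        report["flow_voids"] = {}

    ppe = cohort[cohort["group"] == "PPE"].copy()
    if ppe["pachyvessel_in_3mm"].nunique() == 2:
        ppe["pv"] = np.where(ppe["pachyvessel_in_3mm"], "pachy", "nonpachy")
        metrics = _CONTINUOUS_METRICS[:1] + flowvoid + [
            ("sfct_um", "SFCT (um)"),
            ("rpe_vein_distance_um", "Distance between RPE and choroidal vein (um)"),
        ]
        report["pachyvessel_split"] = _two_group_block(
            ppe, "pv", "pachy", "nonpachy", metrics, ttest_variant, adjust, notices)
    else:
        report["pachyvessel_split"] = {}
    report["notices"] = notices
    return report


def render_report_markdown(report: dict) -> str:
    """Render the report dict as deterministic Markdown."""
    lines = ["# Cohort report", ""]
    lines.append(f"PPE eyes: n = {report['n']['PPE']}; control eyes: n = {report['n']['control']}")
    lines.append("")

    def block(title: str, rows: dict, g1: str, g2: str) -> None:
        if not rows:
            return
        lines.append(f"## {title}")
        lines.append("")
        lines.append(f"| metric | {g1} | {g2} | p | adjusted p |")
        lines.append("|---|---|---|---|---|")
        for col, row in rows.items():
            p = f"{row['p']:.4g}" if row.get("p") is not None else "-"
            pa = f"{row['p_adj']:.4g}" if row.get("p_adj") is not None else "-"
            lines.append(f"| {col} | {row['g1']} | {row['g2']} | {p} | {pa} |")
        lines.append("")

    block("Participant characteristics (PPE vs control)",
          report.get("characteristics", {}), "PPE", "control")
    if "sex" in report:
        t = report["sex"]["table"]
        p = f"{report['sex']['p']:.4g}" if report["sex"]["p"] is not None else "-"
        lines.append(f"Sex (M/F): PPE {t[0][0]}/{t[0][1]} vs control {t[1][0]}/{t[1][1]}, "
                     f"chi-square p = {p}")
        lines.append("")
    block("Flow-void metrics (PPE vs control)", report.get("flow_voids", {}),
          "PPE", "control")
    block("PPE eyes with vs without pachyvessels in the central 3 mm",
          report.get("pachyvessel_split", {}), "pachyvessel", "no pachyvessel")
    for notice in report.get("notices", []):
        lines.append(f"> note: {notice}")
    return "\n".join(lines) + "\n"


def write_report(report: dict, out_dir: str | Path) -> None:
    """Write the Markdown and JSON forms of a cohort report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.md").write_text(render_report_markdown(report))
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
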