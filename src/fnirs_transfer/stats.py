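"""Group comparison statistics: column means, normality, paired t-test.

Given two subject x epoch-budget accuracy tables (control = fine-tuned,
baseline = trained from scratch), this module computes per-budget group
means, Shapiro-Wilk normality per budget column, normal-quantile (QQ)
points, and a two-tailed paired t-test between the groups at a chosen
budget, pairing subjects by row order.

Reported means are rounded half-up to two decimals (the precision of the
accuracy tables); unrounded values are retained in the report object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps

from .exceptions import ValidationError
from .transfer import AccuracyTable


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), matching table precision."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def column_means(table: AccuracyTable, ndigits: int = 2) -> dict[int, float]:
    """Arithmetic mean of each budget column, rounded half-up.

    Cells are decimal-precision percentages, so the mean is accumulated in
    exact decimal arithmetic before rounding: a column averaging 63.715
    must round to 63.72, which binary-float accumulation (63.71499...)
    would miss.
    """
    vals = table.values()
    if not np.isfinite(vals).all():
        raise ValidationError("accuracy table contains non-finite cells")
    q = Decimal(1).scaleb(-ndigits)
    out = {}
    for b in table.budgets:
        total = sum(Decimal(repr(float(v))) for v in table.column(b))
        mean = total / Decimal(len(table.subjects))
        out[b] = float(mean.quantize(q, rounding=ROUND_HALF_UP))
    return out


def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro-Wilk W and p-value (Royston's approximation) for one sample."""
    x = np.asarray(sample, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValidationError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={len(x)}")
    if np.ptp(x) == 0:
        raise ValidationError("Shapiro-Wilk is undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def qq_points(sample) -> np.ndarray:
    """Normal QQ points: (theoretical quantile, sample order statistic) pairs.

    Theoretical quantiles use Blom's plotting positions
    (i - 0.375) / (n + 0.25) against the standard normal.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    if n < 2:
        raise ValidationError("QQ points require n >= 2")
    positions = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    return np.column_stack([sps.norm.ppf(positions), x])


def paired_t_two_tailed(x, y) -> tuple[float, int, float]:
    """Two-tailed paired t-test on positionally paired samples.

    t = mean(d) / (sd(d) / sqrt(n)) with the n-1 sample standard deviation
    of the differences d = x - y; df = n - 1; p from Student's t.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValidationError("paired t-test needs two equal-length 1-D samples, n >= 2")
    d = x - y
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):  # identical samples: no difference, trivially t = 0
            return 0.0, n - 1, 1.0
        raise ValidationError("paired differences are constant and nonzero; t is undefined")
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), int(df), float(p)


@dataclass
class StatReport:
    """Full comparison of a control and a baseline accuracy table."""

    alpha: float
    test_budget: int
    control_means: dict[int, float]  # rounded, percent
    baseline_means: dict[int, float]
    shapiro: dict[str, dict[int, dict]]  # group -> budget -> {W, p, normal}
    t_value: float
    df: int
    p_value: float
    mean_difference: float  # unrounded mean(control - baseline) at test budget
    control_max: float
    baseline_max: float
    unrounded: dict = field(default_factory=dict, repr=False)

    def all_columns_normal(self) -> bool:
        return all(
            cell["normal"] for cols in self.shapiro.values() for cell in cols.values()
        )

    def to_json(self) -> str:
        def clean(v):
            if isinstance(v, float) and not np.isfinite(v):
                return None
            return v

        doc = {k: clean(v) for k, v in self.__dict__.items() if k != "unrounded"}
        doc["shapiro"] = {
            g: {str(b): cell for b, cell in cols.items()} for g, cols in self.shapiro.items()
        }
        doc["control_means"] = {str(b): m for b, m in self.control_means.items()}
        doc["baseline_means"] = {str(b): m for b, m in self.baseline_means.items()}
        return json.dumps(doc, indent=2)

    def to_text(self) -> str:
        lines = ["Group comparison report", "=" * 23]
        budgets = sorted(self.control_means)
        lines.append("budget:   " + "  ".join(f"{b:>7d}" for b in budgets))
        lines.append("control:  " + "  ".join(f"{self.control_means[b]:>7.2f}" for b in budgets))
        lines.append("baseline: " + "  ".join(f"{self.baseline_means[b]:>7.2f}" for b in budgets))
        lines.append("")
        for g, cols in self.shapiro.items():
            ok = all(c["normal"] for c in cols.values())
            lines.append(
                f"Shapiro-Wilk ({g}): all columns normal at alpha={self.alpha}: {ok}"
            )
        lines.append("")
        if np.isfinite(self.t_value):
            lines.append(
                f"paired t (budget {self.test_budget}): t = {self.t_value:.4f}, "
                f"df = {self.df}, two-tailed p = {self.p_value:.4g}"
            )
        else:
            lines.append("paired t: not computed (needs >= 3 subjects per group)")
        lines.append(f"mean paired difference: {self.mean_difference:.2f}%")
        lines.append(f"max cell: control {self.control_max:.2f}%, baseline {self.baseline_max:.2f}%")
        return "\n".join(lines)


def compare_groups(
    control: AccuracyTable,
    baseline: AccuracyTable,
    test_budget: int = 60,
    alpha: float = 0.05,
) -> StatReport:
    """Run the full statistical comparison between the two groups.

    Subjects are paired by row order, so both tables must have the same
    number of rows and the same budget columns.
    """
    if len(control.subjects) != len(baseline.subjects):
        raise ValidationError(
            f"cannot pair {len(control.subjects)} control with "
            f"{len(baseline.subjects)} baseline subjects"
        )
    if control.budgets != baseline.budgets:
        raise ValidationError("control and baseline tables have different budget columns")
    if test_budget not in control.budgets:
        raise ValidationError(f"test budget {test_budget} not among columns {control.budgets}")

    shapiro_block: dict[str, dict[int, dict]] = {}
    for name, table in (("control", control), ("baseline", baseline)):
        cols = {}
        for b in table.budgets:
            w, p = shapiro_wilk(table.column(b))
            cols[b] = {"W": w, "p": p, "normal": bool(p > alpha)}
        shapiro_block[name] = cols

    x = control.column(test_budget)
    y = baseline.column(test_budget)
    t, df, p = paired_t_two_tailed(x, y)
    ctrl_means_raw = control.values().mean(axis=0)
    base_means_raw = baseline.values().mean(axis=0)
    return StatReport(
        alpha=alpha,
        test_budget=test_budget,
        control_means=column_means(control),
        baseline_means=column_means(baseline),
        shapiro=shapiro_block,
        t_value=t,
        df=df,
        p_value=p,
        mean_difference=float(np.mean(x - y)),
        control_max=control.max_cell(),
        baseline_max=baseline.max_cell(),
        unrounded={
            "control_means": dict(zip(control.budgets, ctrl_means_raw)),
            "baseline_means": dict(zip(baseline.budgets, base_means_raw)),
        },
    )
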