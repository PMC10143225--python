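"""Device-comparison statistics: RMSE, RMSPE, bias, Welch's t, Pearson r.

Errors are signed device-minus-reference DBH differences in centimetres, so
a device that overestimates diameter has positive bias. RMSPE normalises
the RMSE by the mean reference (TLS) DBH of the same stems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import t as t_dist

__all__ = [
    "ComparisonResult",
    "TestResult",
    "rmse",
    "bias",
    "rmspe",
    "welch_t",
    "pearson_r",
    "capture_summary",
    "compare_errors",
    "scatter_report",
]


@dataclass
class ComparisonResult:
    """Per-group DBH error summary (errors in cm, device minus reference)."""

    errors_cm: np.ndarray
    n: int
    rmse_cm: float
    rmspe_pct: float | None
    bias_cm: float
    group: str = ""


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    test: str

    @property
    def df_display(self) -> int:
        """Degrees of freedom as printed in reports (floored integer)."""
        return int(math.floor(self.df))


def rmse(errors) -> float:
    """Root-mean-square of the signed errors."""
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("rmse of an empty error list")
    return float(np.sqrt(np.mean(e ** 2)))


def bias(errors) -> float:
    """Arithmetic mean signed error (device overestimate => positive)."""
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("bias of an empty error list")
    return float(np.mean(e))


def rmspe(rmse_cm: float, mean_reference_dbh_cm: float) -> float:
    """Root-mean-square percentage error: 100 * RMSE / mean reference DBH.

    Reported at one decimal place in tables; the returned value is
    unrounded.
    """
    if mean_reference_dbh_cm <= 0:
        raise ValueError("mean reference DBH must be positive")
    return 100.0 * rmse_cm / mean_reference_dbh_cm


def welch_t(group_a, group_b) -> TestResult:
    """Welch's unequal-variance two-sample t test (two-sided).

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b) with
    Welch-Satterthwaite degrees of freedom.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    for name, g in (("a", a), ("b", b)):
        if g.size < 2:
            raise ValueError(f"group {name} needs at least 2 observations")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            # identical-group degenerate case: no evidence of difference
            return TestResult(0.0, float(a.size + b.size - 2), 1.0, "welch_t")
        raise ValueError("both groups have zero variance")
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (
        sa ** 2 / (a.size - 1) + sb ** 2 / (b.size - 1)
    )
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return TestResult(float(t), float(df), p, "welch_t")


def pearson_r(x, y) -> TestResult:
    """Pearson correlation with df = n - 2 and a two-sided p via the
    t transform r * sqrt(df / (1 - r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input has undefined correlation")
    xm, ym = x - x.mean(), y - y.mean()
    r = float(np.sum(xm * ym) / math.sqrt(np.sum(xm ** 2) * np.sum(ym ** 2)))
    df = x.size - 2
    r_clamped = min(max(r, -1.0), 1.0)
    if abs(r_clamped) >= 1.0:
        p = 0.0
    else:
        t = r_clamped * math.sqrt(df / (1.0 - r_clamped ** 2))
        p = 2.0 * float(t_dist.sf(abs(t), df))
    return TestResult(r, float(df), p, "pearson_r")


def capture_summary(statuses) -> dict:
    """Counts of capture outcomes plus per-cause failure percentages
    (integer-rounded share of all failures)."""
    statuses = list(statuses)
    counts: dict[str, int] = {}
    for s in statuses:
        counts[s] = counts.get(s, 0) + 1
    n_total = len(statuses)
    n_captured = counts.get("captured", 0)
    n_failed = n_total - n_captured
    failure_pct = {}
    for cause, c in counts.items():
        if cause == "captured":
            continue
        failure_pct[cause] = round(100.0 * c / n_failed) if n_failed else 0
    return {
        "n_total": n_total,
        "n_captured": n_captured,
        "n_failed": n_failed,
        "counts": counts,
        "failure_pct": failure_pct,
    }


def compare_errors(
    device_dbh_cm,
    reference_dbh_cm,
    group: str = "",
) -> ComparisonResult:
    """Summarise device-vs-reference DBH agreement for matched stems."""
    dev = np.asarray(device_dbh_cm, dtype=float)
    ref = np.asarray(reference_dbh_cm, dtype=float)
    if dev.size != ref.size:
        raise ValueError("device and reference DBH lists differ in length")
    if dev.size == 0:
        raise ValueError("no matched stems to compare")
    err = dev - ref
    r = rmse(err)
    mean_ref = float(ref.mean())
    return ComparisonResult(
        errors_cm=err,
        n=int(err.size),
        rmse_cm=r,
        rmspe_pct=rmspe(r, mean_ref) if mean_ref > 0 else None,
        bias_cm=bias(err),
        group=group,
    )


def scatter_report(
    comparisons: dict,
    failures: dict | None = None,
    out_dir=".",
    prefix: str = "dbh_scatter",
) -> list:
    """One device-vs-reference DBH scatter panel per (device, approach).

    *comparisons* maps a group label to (device_dbh, reference_dbh) pairs;
    *failures* maps the same labels to reference DBH values of stems the
    device failed to capture, marked on the x-axis. Returns the written
    figure paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for label, (dev, ref) in comparisons.items():
        dev = np.asarray(dev, dtype=float)
        ref = np.asarray(ref, dtype=float)
        fig, ax = plt.subplots(figsize=(4, 4))
        if dev.size == 0:
            ax.text(0.5, 0.5, "no matched stems", ha="center", va="center",
                    transform=ax.transAxes)
        else:
            ax.scatter(ref, dev, s=14, alpha=0.8)
            lim = [0, max(ref.max(), dev.max()) * 1.05]
            ax.plot(lim, lim, color="grey", lw=0.8, label="1:1")
            ax.set_xlim(lim)
            ax.set_ylim(lim)
        if failures and label in failures and len(failures[label]):
            fx = np.asarray(failures[label], dtype=float)
            ax.scatter(fx, np.zeros_like(fx), marker="x", color="red",
                       label="failed capture")
        ax.set_xlabel("reference DBH (cm)")
        ax.set_ylabel("device DBH (cm)")
        ax.set_title(label)
        fig.tight_layout()
        path = out_dir / f"{prefix}_{label.replace(' ', '_').replace('/', '-')}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
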