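"""Paired-device method-agreement statistics.

Quantifies how well smartphone-derived features agree with gold-standard
features across a cohort of paired recordings:

* a t test on the paired values — default is the classical paired t test
  (t = mean(d) / (SD(d)/sqrt(n)), df = n − 1); a Welch two-sample
  unequal-variance mode is selectable;
* Bland–Altman limits of agreement, mean difference ± 1.96 SD of the
  differences (multiplier configurable);
* the fraction of pairs whose absolute difference falls within a tolerance
  (boundary inclusive), e.g. ±1 Hz for frequency features.

Differences are oriented smartphone − gold throughout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sp_stats

from .errors import InsufficientDataError, StreamValidationError

logger = logging.getLogger(__name__)


@dataclass
class PairedFeatureTable:
    """Paired (smartphone, gold) values of one feature for one test."""

    feature_name: str
    test_label: str
    pairs: np.ndarray                   # (n, 2): [:, 0] smartphone, [:, 1] gold
    device_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=float)
        if self.pairs.ndim != 2 or self.pairs.shape[1] != 2:
            raise StreamValidationError("pairs must have shape (n, 2)")

    def clean(self) -> "PairedFeatureTable":
        """Pairwise deletion of rows with undefined (non-finite) values."""
        keep = np.isfinite(self.pairs).all(axis=1)
        dropped = int((~keep).sum())
        if dropped:
            logger.warning(
                "%s/%s: dropped %d pair(s) with undefined values",
                self.feature_name, self.test_label, dropped,
            )
        labels = [l for l, k in zip(self.device_labels, keep) if k] \
            if self.device_labels else []
        return PairedFeatureTable(self.feature_name, self.test_label,
                                  self.pairs[keep], labels)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class TTestResult:
    t_stat: float
    p_value: float
    df: float
    mode: str
    degenerate: bool = False


@dataclass
class AgreementResult:
    """Agreement summary for one feature x test cell."""

    feature_name: str
    test_label: str
    n_pairs: int
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    t_stat: float
    p_value: float
    pct_within_tol: float
    tol: float
    t_mode: str = "paired"
    degenerate: bool = False
    # per-pair quantities for Bland-Altman plotting
    pair_means: np.ndarray = field(default=None, repr=False)
    diffs: np.ndarray = field(default=None, repr=False)

    def as_dict(self) -> dict:
        return {
            "feature": self.feature_name,
            "test": self.test_label,
            "n_pairs": self.n_pairs,
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "t_stat": self.t_stat,
            "p_value": self.p_value,
            "pct_within_tol": self.pct_within_tol,
            "tol": self.tol,
            "t_mode": self.t_mode,
            "degenerate": self.degenerate,
        }


def _as_pairs(pairs) -> np.ndarray:
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise StreamValidationError("pairs must have shape (n, 2)")
    if not np.isfinite(arr).all():
        raise StreamValidationError("pairs must be finite (clean() the table first)")
    return arr


def paired_t_test(pairs, mode: str = "paired") -> TTestResult:
    """t test comparing smartphone and gold values.

    ``mode="paired"``: classical paired t test on the differences.
    ``mode="welch"``: Welch's two-sample test with Welch–Satterthwaite df
    (treats the two columns as independent samples).

    All-zero-variance differences are degenerate: t reported as 0 with
    p = 1 when the mean difference is zero, ±inf with p = 0 otherwise.
    """
    arr = _as_pairs(pairs)
    n = len(arr)
    if n < 2:
        raise InsufficientDataError(f"need at least 2 pairs, got {n}")

    if mode == "paired":
        d = arr[:, 0] - arr[:, 1]
        sd = float(np.std(d, ddof=1))
        df = n - 1
        if sd == 0.0:
            m = float(np.mean(d))
            logger.warning("degenerate paired t test: zero-variance differences")
            if m == 0.0:
                return TTestResult(0.0, 1.0, df, mode, degenerate=True)
            return TTestResult(float(np.sign(m)) * np.inf, 0.0, df, mode,
                               degenerate=True)
        t = float(np.mean(d) / (sd / np.sqrt(n)))
        p = float(2.0 * sp_stats.t.sf(abs(t), df))
        return TTestResult(t, p, df, mode)

    if mode == "welch":
        a, b = arr[:, 0], arr[:, 1]
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        if va == 0.0 and vb == 0.0:
            m = float(np.mean(a) - np.mean(b))
            logger.warning("degenerate Welch t test: both samples zero-variance")
            if m == 0.0:
                return TTestResult(0.0, 1.0, float(n - 1), mode, degenerate=True)
            return TTestResult(float(np.sign(m)) * np.inf, 0.0, float(n - 1),
                               mode, degenerate=True)
        se2 = va / n + vb / n
        t = float((np.mean(a) - np.mean(b)) / np.sqrt(se2))
        df = se2 ** 2 / ((va / n) ** 2 / (n - 1) + (vb / n) ** 2 / (n - 1))
        p = float(2.0 * sp_stats.t.sf(abs(t), df))
        return TTestResult(t, p, float(df), mode)

    raise StreamValidationError(f"unknown t test mode: {mode!r}")


def bland_altman(pairs, loa_multiplier: float = 1.96) -> AgreementResult:
    """Bland–Altman limits of agreement for one paired sample.

    diffs = smartphone − gold; LoA = mean(diffs) ± multiplier · SD(diffs)
    (unbiased SD).  ``pair_means`` and ``diffs`` are attached for plotting.
    """
    arr = _as_pairs(pairs)
    n = len(arr)
    if n < 2:
        raise InsufficientDataError(f"need at least 2 pairs, got {n}")
    d = arr[:, 0] - arr[:, 1]
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    return AgreementResult(
        feature_name="", test_label="", n_pairs=n,
        mean_diff=mean_diff, sd_diff=sd_diff,
        loa_lower=mean_diff - loa_multiplier * sd_diff,
        loa_upper=mean_diff + loa_multiplier * sd_diff,
        t_stat=float("nan"), p_value=float("nan"),
        pct_within_tol=float("nan"), tol=float("nan"),
        pair_means=arr.mean(axis=1), diffs=d,
    )


def pct_within_tolerance(pairs, tol: float) -> float:
    """Percent of pairs with |smartphone − gold| ≤ tol (boundary inclusive)."""
    if tol <= 0:
        raise StreamValidationError("tol must be > 0")
    arr = _as_pairs(pairs)
    n = len(arr)
    if n == 0:
        raise InsufficientDataError("no pairs")
    d = np.abs(arr[:, 0] - arr[:, 1])
    return float(100.0 * np.count_nonzero(d <= tol) / n)


def agreement_for_table(
    table: PairedFeatureTable,
    tol: float = 1.0,
    t_mode: str = "paired",
    loa_multiplier: float = 1.96,
) -> AgreementResult:
    """All agreement statistics for one feature x test table (after clean())."""
    clean = table.clean()
    if clean.n_pairs < 2:
        raise InsufficientDataError(
            f"{table.feature_name}/{table.test_label}: "
            f"{clean.n_pairs} defined pair(s), need >= 2"
        )
    ba = bland_altman(clean.pairs, loa_multiplier)
    tt = paired_t_test(clean.pairs, mode=t_mode)
    pct = pct_within_tolerance(clean.pairs, tol)
    return AgreementResult(
        feature_name=table.feature_name, test_label=table.test_label,
        n_pairs=clean.n_pairs,
        mean_diff=ba.mean_diff, sd_diff=ba.sd_diff,
        loa_lower=ba.loa_lower, loa_upper=ba.loa_upper,
        t_stat=tt.t_stat, p_value=tt.p_value,
        pct_within_tol=pct, tol=tol,
        t_mode=t_mode, degenerate=tt.degenerate,
        pair_means=ba.pair_means, diffs=ba.diffs,
    )


def _bland_altman_plot(res: AgreementResult, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(res.pair_means, res.diffs, s=18, alpha=0.7)
    ax.axhline(res.mean_diff, color="red", ls="--", label="mean difference")
    ax.axhline(res.loa_upper, color="green", ls="--", label="limits of agreement")
    ax.axhline(res.loa_lower, color="green", ls="--")
    ax.set_xlabel("pair mean")
    ax.set_ylabel("smartphone − gold")
    ax.set_title(f"{res.feature_name} — {res.test_label}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def validation_report(
    tables: list[PairedFeatureTable],
    tol: float = 1.0,
    t_mode: str = "paired",
    loa_multiplier: float = 1.96,
    out_dir: str | Path | None = None,
    make_plots: bool = False,
) -> dict:
    """Agreement report over all feature x test tables.

    Returns a machine-readable dict with one row per table (skipping — with
    a logged warning — tables with fewer than 2 defined pairs).  When
    ``out_dir`` is given, writes ``report.json``, a p-value summary CSV and,
    optionally, one Bland–Altman plot image per table.
    """
    if not tables:
        raise InsufficientDataError("no tables supplied")
    rows, skipped = [], []
    results = []
    for table in tables:
        try:
            res = agreement_for_table(table, tol=tol, t_mode=t_mode,
                                      loa_multiplier=loa_multiplier)
        except InsufficientDataError as exc:
            logger.warning("skipping %s/%s: %s",
                           table.feature_name, table.test_label, exc)
            skipped.append({"feature": table.feature_name,
                            "test": table.test_label, "reason": str(exc)})
            continue
        results.append(res)
        rows.append(res.as_dict())
    report = {"tol": tol, "t_mode": t_mode, "loa_multiplier": loa_multiplier,
              "rows": rows, "skipped": skipped}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2)
        import pandas as pd
        pd.DataFrame(rows).to_csv(out / "agreement_table.csv", index=False)
        if make_plots:
            for res in results:
                fname = f"bland_altman_{res.feature_name}_{res.test_label}.png"
                _bland_altman_plot(res, out / fname)
    return report
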