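"""Model/Results interface over the exact tests and the drift model.

``InsertionPatternModel`` holds one labelled marker triplet; ``fit`` runs
the scenario classification and (for multi-directional data) the drift-time
estimation and returns an ``InsertionPatternResults`` with the p-values,
critical boundaries, scenario call and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .exact import classify_scenario
from .markers import MULTI, ONE, MarkerCounts, TestConfig, TestOutcome
from .popmodel import DriftEstimate, estimate_drift_time

__all__ = ["InsertionPatternModel", "InsertionPatternResults"]


def _fmt_p(p: Optional[float], precision: int = 4) -> str:
    if p is None:
        return "-"
    if p < 1e-16:
        return "< 1e-16"
    return f"{p:.{precision}g}"


def _fmt_crit(c: Optional[int]) -> str:
    return "n/a" if c is None else str(c)


class InsertionPatternModel:
    """Three-lineage insertion-marker triplet ready for significance analysis.

    Parameters
    ----------
    counts
        A validated :class:`~retromark.markers.MarkerCounts`.
    alpha
        Type-I error level for scenario calls (default 0.05).
    rate_ratio
        Internal-branch over ancestral insertion-rate ratio n1/n0 used for
        drift-time estimation (default 1: constant insertion rate).
    """

    def __init__(self, counts: MarkerCounts, alpha: float = 0.05, rate_ratio: float = 1.0):
        self.counts = counts
        self.config = TestConfig(alpha=alpha)
        self.rate_ratio = rate_ratio

    @classmethod
    def from_counts(
        cls,
        y_ab: Optional[int],
        y_ac: Optional[int],
        y_bc: Optional[int],
        labels: Sequence[str] = ("A", "B", "C"),
        mode: str = MULTI,
        reference: Optional[str] = None,
        alpha: float = 0.05,
        rate_ratio: float = 1.0,
    ) -> "InsertionPatternModel":
        la, lb, lc = labels
        counts = MarkerCounts(
            y_ab, y_ac, y_bc, label_a=la, label_b=lb, label_c=lc,
            mode=mode, reference_lineage=reference,
        )
        return cls(counts, alpha=alpha, rate_ratio=rate_ratio)

    def fit(
        self, conf_level: float = 0.95, estimate_drift: bool = True
    ) -> "InsertionPatternResults":
        outcome = classify_scenario(self.counts, self.config)
        drift: Optional[DriftEstimate] = None
        if estimate_drift and self.counts.mode == MULTI:
            drift = estimate_drift_time(self.counts, self.rate_ratio, conf_level)
        return InsertionPatternResults(self, outcome, drift)


@dataclass
class InsertionPatternResults:
    """Fitted results: scenario call, p-values, boundaries, drift estimate."""

    model: InsertionPatternModel
    outcome: TestOutcome
    drift: Optional[DriftEstimate] = None

    @property
    def counts(self) -> MarkerCounts:
        return self.model.counts

    @property
    def scenario(self) -> str:
        return self.outcome.scenario

    def scenario_sentence(self) -> str:
        c, o = self.counts, self.outcome
        alpha = self.model.config.alpha
        if o.scenario == "tree":
            a, b = o.supported_pair
            return f"Resolved tree: ({a}, {b}) supported at alpha = {alpha:g}."
        if o.scenario == "polytomy":
            return f"Polytomy cannot be rejected at alpha = {alpha:g}."
        if o.scenario == "hybridization":
            return (
                f"Ancestral hybridization supported: {o.hybrid_lineage} shows "
                f"a hybrid-origin signal at alpha = {alpha:g}."
            )
        if o.scenario == "tree_with_hybridization_signal":
            a, b = o.supported_pair
            return (
                f"Tree with hybridization signal: ({a}, {b}) dominates but "
                f"{o.hybrid_lineage} carries a significant asymmetry."
            )
        if o.supported_pair is not None:
            a, b = o.supported_pair
            return (
                f"One-directional screen: ({a}, {b}) exceeds the alternative at "
                f"alpha = {alpha:g}; bifurcation and hybridization are indistinguishable."
            )
        return "One-directional screen: no significant difference between the observable pairs."

    def test_table(self) -> pd.DataFrame:
        """The web-style five-column report table."""
        o = self.outcome
        c = self.counts
        rows = []
        if c.mode == MULTI:
            ranked = sorted(c.observed_pairs, key=lambda t: t[0], reverse=True)
            rows.append(
                ("bifurcation (largest count vs total)", ranked[0][0], o.p_bifurcation,
                 o.critical_y1_05, o.critical_y1_01)
            )
            rows.append(
                ("hybridization (two smallest counts)",
                 f"{ranked[1][0]}:{ranked[2][0]}", o.p_asymmetry,
                 o.critical_diff_05, o.critical_diff_01)
            )
            rows.append(
                ("top-pair comparison (two largest counts)",
                 f"{ranked[0][0]}:{ranked[1][0]}", o.p_top_pair, None, None)
            )
        else:
            (ya, pa), (yb, pb) = c.observed_pairs
            rows.append(
                ("one-directional comparison", f"{max(ya, yb)}:{min(ya, yb)}",
                 o.p_one_directional, o.critical_y1_05, o.critical_y1_01)
            )
        return pd.DataFrame(
            rows, columns=["test type", "counts", "p_value", "critical_005", "critical_001"]
        )

    def to_dict(self) -> dict:
        """Machine-readable report (validates against schema/report.schema.json)."""
        c, o = self.counts, self.outcome
        out = {
            "labels": {"a": c.label_a, "b": c.label_b, "c": c.label_c},
            "counts": {"ab": c.y_ab, "ac": c.y_ac, "bc": c.y_bc},
            "mode": c.mode,
            "reference_lineage": c.reference_lineage,
            "alpha": self.model.config.alpha,
            "tests": [
                {
                    "test_type": row["test type"],
                    "p_value": None if row["p_value"] is None else float(row["p_value"]),
                    "critical_005": None if pd.isna(row["critical_005"]) else int(row["critical_005"]),
                    "critical_001": None if pd.isna(row["critical_001"]) else int(row["critical_001"]),
                }
                for row in self.test_table().to_dict("records")
            ],
            "scenario": o.scenario,
            "scenario_sentence": self.scenario_sentence(),
            "supported_pair": list(o.supported_pair) if o.supported_pair else None,
            "hybrid_lineage": o.hybrid_lineage,
            "warnings": list(o.warnings),
        }
        if self.drift is not None:
            out["drift_time"] = {
                # infinite bounds become null in strict JSON
                "tau_hat": None if math.isinf(self.drift.tau_hat) else self.drift.tau_hat,
                "ci_low": self.drift.ci_low,
                "ci_high": None if math.isinf(self.drift.ci_high) else self.drift.ci_high,
                "conf_level": self.drift.conf_level,
                "p1_hat": self.drift.p1_hat,
                "rate_ratio": self.model.rate_ratio,
            }
        return out

    def summary(self) -> str:
        """Human-readable report mirroring the web application's layout."""
        c = self.counts
        precision = self.model.config.report_precision
        lines = [
            "Insertion presence/absence pattern analysis",
            "=" * 60,
            f"Lineages : A = {c.label_a}, B = {c.label_b}, C = {c.label_c}",
        ]

        def show(y):
            return "unobserved" if y is None else str(y)

        lines.append(
            f"Counts   : {c.label_a}-{c.label_b} = {show(c.y_ab)}, "
            f"{c.label_a}-{c.label_c} = {show(c.y_ac)}, "
            f"{c.label_b}-{c.label_c} = {show(c.y_bc)}   (n = {c.n})"
        )
        lines.append(f"Mode     : {c.mode}" + (
            f" (reference {c.reference_lineage})" if c.reference_lineage else ""
        ))
        lines.append("-" * 60)
        tab = self.test_table()
        header = f"{'test type':<42}{'counts':>8}{'p':>10}{'5%':>6}{'1%':>6}"
        lines.append(header)
        for _, row in tab.iterrows():
            lines.append(
                f"{row['test type']:<42}{str(row['counts']):>8}"
                f"{_fmt_p(row['p_value'], precision):>10}"
                f"{_fmt_crit(None if pd.isna(row['critical_005']) else int(row['critical_005'])):>6}"
                f"{_fmt_crit(None if pd.isna(row['critical_001']) else int(row['critical_001'])):>6}"
            )
        lines.append("-" * 60)
        lines.append(self.scenario_sentence())
        if self.drift is not None:
            d = self.drift
            hi = "inf" if d.ci_high == float("inf") else f"{d.ci_high:.4g}"
            lines.append(
                f"Drift time tau = {d.tau_hat:.4g} "
                f"[{d.ci_low:.4g}, {hi}] ({d.conf_level:.0%} CI, "
                f"winning fraction {d.p1_hat:.4g})"
            )
        for w in self.outcome.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)
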