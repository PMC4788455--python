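"""Domain containers for three-lineage insertion-marker data.

A *marker* is an orthologous genomic locus at which a retroposon insertion is
present in exactly two of three lineages A, B, C and absent in the third.  The
three phylogenetically informative sharing patterns are

* ``y_ab`` — insertion present in A and B, absent in C,
* ``y_ac`` — insertion present in A and C, absent in B,
* ``y_bc`` — insertion present in B and C, absent in A.

In a *multi-directional* (unbiased) screen all three categories are
observable.  In a *one-directional* screen, where loci are ascertained from
the genome of a single reference lineage, only the two sharing patterns that
involve the reference lineage can be observed; the third is genuinely
missing, not zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

MULTI = "multi_directional"
ONE = "one_directional"


@dataclass(frozen=True)
class MarkerCounts:
    """A labelled triplet of pairwise shared-insertion counts.

    Parameters
    ----------
    y_ab, y_ac, y_bc
        Number of insertion loci shared by each lineage pair to the exclusion
        of the third.  In one-directional mode the count for the pair that
        does not involve ``reference_lineage`` must be ``None`` (unobserved).
    label_a, label_b, label_c
        Free-text lineage names used in reports.
    mode
        ``"multi_directional"`` or ``"one_directional"``.
    reference_lineage
        Required in one-directional mode: the lineage whose genome was used
        for the screen.  Must equal one of the three labels.
    """

    y_ab: Optional[int]
    y_ac: Optional[int]
    y_bc: Optional[int]
    label_a: str = "A"
    label_b: str = "B"
    label_c: str = "C"
    mode: str = MULTI
    reference_lineage: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in (MULTI, ONE):
            raise ValueError(f"unknown mode {self.mode!r}")
        labels = (self.label_a, self.label_b, self.label_c)
        if len(set(labels)) != 3:
            raise ValueError(f"lineage labels must be distinct, got {labels}")
        for name, y in zip(("y_ab", "y_ac", "y_bc"), (self.y_ab, self.y_ac, self.y_bc)):
            if y is None:
                continue
            if int(y) != y or y < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {y!r}")
        if self.mode == MULTI:
            if None in (self.y_ab, self.y_ac, self.y_bc):
                raise ValueError("multi-directional counts require all three categories")
            if self.reference_lineage is not None:
                raise ValueError("reference_lineage is only meaningful in one-directional mode")
        else:
            if self.reference_lineage not in labels:
                raise ValueError(
                    f"one-directional mode requires reference_lineage in {labels}"
                )
            unobserved = self._unobserved_slot()
            observed = {"y_ab", "y_ac", "y_bc"} - {unobserved}
            if getattr(self, unobserved) is not None:
                raise ValueError(
                    f"{unobserved} does not involve reference lineage "
                    f"{self.reference_lineage!r} and must be None (unobserved)"
                )
            if any(getattr(self, slot) is None for slot in observed):
                raise ValueError("both counts involving the reference lineage are required")

    def _unobserved_slot(self) -> str:
        # the pair NOT involving the reference lineage
        if self.reference_lineage == self.label_a:
            return "y_bc"
        if self.reference_lineage == self.label_b:
            return "y_ac"
        return "y_ab"

    @property
    def n(self) -> int:
        """Total number of observed informative markers."""
        return sum(y for y in (self.y_ab, self.y_ac, self.y_bc) if y is not None)

    @property
    def pairs(self) -> list[tuple[Optional[int], tuple[str, str]]]:
        """(count, pair-of-labels) for each sharing category, AB/AC/BC order."""
        return [
            (self.y_ab, (self.label_a, self.label_b)),
            (self.y_ac, (self.label_a, self.label_c)),
            (self.y_bc, (self.label_b, self.label_c)),
        ]

    @property
    def observed_pairs(self) -> list[tuple[int, tuple[str, str]]]:
        return [(y, pair) for y, pair in self.pairs if y is not None]

    @property
    def values(self) -> tuple[int, int, int]:
        """(y_ab, y_ac, y_bc); only valid in multi-directional mode."""
        if self.mode != MULTI:
            raise ValueError("values requires multi-directional counts")
        return (self.y_ab, self.y_ac, self.y_bc)


@dataclass(frozen=True)
class TestConfig:
    """Significance-test settings: type-I error level and report precision."""

    alpha: float = 0.05
    report_precision: int = 4

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.report_precision < 1:
            raise ValueError("report_precision must be >= 1")


# Scenario call vocabulary.
TREE = "tree"
POLYTOMY = "polytomy"
HYBRIDIZATION = "hybridization"
TREE_WITH_HYBRIDIZATION = "tree_with_hybridization_signal"
UNDETERMINED_ONE_DIR = "undetermined_one_directional"


@dataclass
class TestOutcome:
    """Result of the scenario-classification procedure for one triplet.

    ``p_bifurcation`` tests the largest count against the polytomy null
    (success probability 1/3), ``p_asymmetry`` is the two-sided symmetry test
    on the two smallest counts (hybridization signal), and ``p_top_pair``
    compares the two largest counts to separate a dominant topology from a
    genuinely ambiguous (hybrid) one.  One-directional screens only admit the
    pairwise comparison ``p_one_directional``.
    """

    scenario: str
    p_bifurcation: Optional[float] = None
    p_asymmetry: Optional[float] = None
    p_top_pair: Optional[float] = None
    p_one_directional: Optional[float] = None
    supported_pair: Optional[tuple[str, str]] = None
    hybrid_lineage: Optional[str] = None
    critical_y1_05: Optional[int] = None
    critical_y1_01: Optional[int] = None
    critical_diff_05: Optional[int] = None
    critical_diff_01: Optional[int] = None
    warnings: list[str] = field(default_factory=list)

    def p_values(self) -> dict[str, Optional[float]]:
        return {
            "bifurcation": self.p_bifurcation,
            "asymmetry": self.p_asymmetry,
            "top_pair": self.p_top_pair,
            "one_directional": self.p_one_directional,
        }
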