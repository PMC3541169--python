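"""The minimal 3-gene-set rule and diagnostic evaluation against PG status.

An organism that can both synthesize and degrade peptidoglycan needs, at
minimum, one GT28 gene, one GT51 gene and at least one gene from one of five
glycoside-hydrolase families (GH23, GH73, GH102, GH103, GH104).  This module
implements that rule (and arbitrary variants of it, e.g. the single-marker
"GT51 absent" rule), cross-tabulates predictions against the three-valued
literature PG status, and computes diagnostic metrics.

Genomes of unknown PG status are excluded from the cross-tabulation — never
imputed — and the number excluded is always reported.  Metrics with a zero
denominator are ``None`` (an explicit undefined marker), so "no data" is
never confused with a perfect score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .annotation_io import (
    FAMILIES,
    Cohort,
    GenomeRecord,
    PresenceProfile,
    ValidationError,
    binarize,
)

__all__ = [
    "GeneSetRule",
    "ConfusionCounts",
    "DiagnosticMetrics",
    "has_minimal_set",
    "classify_cohort",
    "confusion",
    "metrics",
]

#: The five GH families of the default rule.  GH25 is deliberately not among
#: them: although six GH families act on PG, the minimal-set definition names
#: five; the six-family variant is one ``GeneSetRule`` away.
DEFAULT_REQUIRED_ANY = frozenset({"GH23", "GH73", "GH102", "GH103", "GH104"})
DEFAULT_REQUIRED_ALL = frozenset({"GT28", "GT51"})


class ConfigurationError(ValueError):
    """A rule references unknown families or is internally inconsistent."""


@dataclass(frozen=True)
class GeneSetRule:
    """A conjunctive/disjunctive presence rule over gene families.

    Satisfied iff every family in ``required_all`` is present and at least
    ``min_any`` of the families in ``required_any`` are present.
    """

    required_all: frozenset[str] = DEFAULT_REQUIRED_ALL
    required_any: frozenset[str] = DEFAULT_REQUIRED_ANY
    min_any: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "required_all", frozenset(self.required_all))
        object.__setattr__(self, "required_any", frozenset(self.required_any))
        unknown = (self.required_all | self.required_any) - set(FAMILIES)
        if unknown:
            raise ConfigurationError(f"rule references unknown families: {sorted(unknown)}")
        if self.required_all & self.required_any:
            raise ConfigurationError("required_all and required_any must be disjoint")
        if self.min_any < 1:
            raise ConfigurationError("min_any must be >= 1")


def has_minimal_set(profile: PresenceProfile, rule: GeneSetRule | None = None) -> bool:
    """True iff the presence profile satisfies the gene-set rule."""
    rule = rule or GeneSetRule()
    if not all(profile[f] for f in rule.required_all):
        return False
    return sum(bool(profile[f]) for f in rule.required_any) >= rule.min_any


@dataclass
class ClassificationResult:
    """Per-genome predictions plus per-domain / per-phylum positive counts."""

    predictions: list[bool]
    genome_ids: list[str]
    by_domain: dict[str, tuple[int, int]]  # domain -> (n, n_positive)
    by_phylum: dict[tuple[str, str], tuple[int, int]]  # (domain, phylum) -> (n, n_pos)


def classify_cohort(cohort: Cohort, rule: GeneSetRule | None = None) -> ClassificationResult:
    """Apply the rule to every genome, preserving record order."""
    rule = rule or GeneSetRule()
    preds: list[bool] = []
    by_domain: dict[str, list[int]] = {}
    by_phylum: dict[tuple[str, str], list[int]] = {}
    for rec in cohort:
        p = has_minimal_set(binarize(rec), rule)
        preds.append(p)
        d = by_domain.setdefault(rec.domain, [0, 0])
        d[0] += 1
        d[1] += int(p)
        ph = by_phylum.setdefault((rec.domain, rec.phylum), [0, 0])
        ph[0] += 1
        ph[1] += int(p)
    return ClassificationResult(
        predictions=preds,
        genome_ids=[r.genome_id for r in cohort],
        by_domain={k: (v[0], v[1]) for k, v in by_domain.items()},
        by_phylum={k: (v[0], v[1]) for k, v in by_phylum.items()},
    )


@dataclass(frozen=True)
class ConfusionCounts:
    """A 2x2 cross-tabulation with the unknown-status exclusion count."""

    tp: int
    fp: int
    tn: int
    fn: int
    excluded_unknown: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn", "excluded_unknown"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn + self.excluded_unknown


def confusion(
    predictions: Sequence[bool],
    cohort: Cohort,
    positive_means: str = "pg_present",
) -> ConfusionCounts:
    """Cross-tabulate predictions against literature PG status.

    ``positive_means`` states what a positive prediction asserts about the
    genome: ``"pg_present"`` (e.g. the 3-gene set predicting PG) or
    ``"pg_absent"`` (e.g. GT51 absence predicting PG absence).  Records of
    unknown status are excluded and counted in ``excluded_unknown``.
    """
    if positive_means not in ("pg_present", "pg_absent"):
        raise ValueError("positive_means must be 'pg_present' or 'pg_absent'")
    if len(predictions) != len(cohort):
        raise ValidationError(
            f"{len(predictions)} predictions for {len(cohort)} records"
        )
    truth_positive_status = "present" if positive_means == "pg_present" else "absent"
    tp = fp = tn = fn = unknown = 0
    for pred, rec in zip(predictions, cohort):
        if rec.pg_status == "unknown":
            unknown += 1
            continue
        truth = rec.pg_status == truth_positive_status
        if pred and truth:
            tp += 1
        elif pred and not truth:
            fp += 1
        elif not pred and truth:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, excluded_unknown=unknown)


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity, specificity, PPV and NPV; ``None`` marks a 0/0 metric."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(c: ConfusionCounts) -> DiagnosticMetrics:
    """Diagnostic metrics from a confusion table; never raises on 0/0."""
    return DiagnosticMetrics(
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
    )
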