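"""Per-sample stepwise variant filters.

A call is kept iff it passes all four predicates:

* depth: read depth strictly greater than ``min_depth_exclusive`` (>10x
  by default, so a depth of exactly 10 is excluded);
* vaf: alternate-allele fraction at least ``min_alt_fraction`` (>=30%,
  boundary inclusive);
* popfreq: maximum allele frequency across all population databases at
  most ``max_pop_freq_exclusive`` (variants at *more than* 1% in any
  database are excluded; exactly 1% is retained);
* consequence: the consequence class is not in the excluded set
  (intergenic, UTRs, intronic, synonymous by default), except that any
  variant at a canonical splice site is rescued when ``splice_rescue``
  is on.

The kept/excluded decision is a pure conjunction and order-independent;
the fixed rule order (depth, vaf, popfreq, consequence) matters only for
the ``failed_rules`` report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .models import Consequence, VariantAnnotation, VariantCall, VariantKey

RULE_DEPTH = "depth"
RULE_VAF = "vaf"
RULE_POPFREQ = "popfreq"
RULE_CONSEQUENCE = "consequence"

DEFAULT_EXCLUDED_CONSEQUENCES = frozenset(
    {
        Consequence.INTERGENIC,
        Consequence.UTR5,
        Consequence.UTR3,
        Consequence.INTRONIC,
        Consequence.SYNONYMOUS,
    }
)


@dataclass(frozen=True)
class FilterConfig:
    min_depth_exclusive: int = 10
    min_alt_fraction: float = 0.30
    max_pop_freq_exclusive: float = 0.01
    excluded_consequences: frozenset[Consequence] = DEFAULT_EXCLUDED_CONSEQUENCES
    splice_rescue: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_alt_fraction <= 1.0:
            raise ValueError("min_alt_fraction must be in [0, 1]")
        if not 0.0 <= self.max_pop_freq_exclusive <= 1.0:
            raise ValueError("max_pop_freq_exclusive must be in [0, 1]")

    def replace(self, **kwargs) -> "FilterConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class FilterOutcome:
    call: VariantCall
    kept: bool
    failed_rules: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kept != (len(self.failed_rules) == 0):
            raise ValueError("kept must hold exactly when no rule failed")


class MissingAnnotationError(KeyError):
    pass


def _as_lookup(
    annotations: Mapping[VariantKey, VariantAnnotation] | Iterable[VariantAnnotation],
) -> Mapping[VariantKey, VariantAnnotation]:
    if isinstance(annotations, Mapping):
        return annotations
    return {a.key: a for a in annotations}


def evaluate_call(
    call: VariantCall,
    annotation: VariantAnnotation,
    config: FilterConfig = FilterConfig(),
) -> FilterOutcome:
    """Evaluate the four filter predicates for one call."""
    failed: list[str] = []
    if not call.read_depth > config.min_depth_exclusive:
        failed.append(RULE_DEPTH)
    if not call.alt_fraction >= config.min_alt_fraction:
        failed.append(RULE_VAF)
    if not annotation.max_population_freq <= config.max_pop_freq_exclusive:
        failed.append(RULE_POPFREQ)
    consequence_ok = annotation.consequence not in config.excluded_consequences or (
        config.splice_rescue and annotation.consequence is Consequence.SPLICE_CANONICAL
    )
    if not consequence_ok:
        failed.append(RULE_CONSEQUENCE)
    return FilterOutcome(call=call, kept=not failed, failed_rules=tuple(failed))


def apply_sample_filters(
    calls: Sequence[VariantCall],
    annotations: Mapping[VariantKey, VariantAnnotation] | Iterable[VariantAnnotation],
    config: FilterConfig = FilterConfig(),
) -> list[FilterOutcome]:
    """Apply the stepwise filters to every call.

    Every call must have an annotation for its key.

    Raises
    ------
    MissingAnnotationError
        Naming the first variant key without an annotation.
    """
    lookup = _as_lookup(annotations)
    outcomes = []
    for call in calls:
        ann = lookup.get(call.key)
        if ann is None:
            raise MissingAnnotationError(
                f"no annotation for {call.key.chrom}:{call.key.pos} "
                f"{call.key.ref}>{call.key.alt} (sample {call.sample_id})"
            )
        outcomes.append(evaluate_call(call, ann, config))
    return outcomes


def kept_calls(outcomes: Iterable[FilterOutcome]) -> list[VariantCall]:
    return [o.call for o in outcomes if o.kept]
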