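"""Cohort-level aggregation of per-animal variant calls.

A *carrier* is an animal with at least one alternate allele, regardless of
zygosity.  Variants are retained when carried by at least 2% of the cohort
(for 206 animals the smallest retained count is 5, since 4/206 = 1.94%).
Percentages are rendered at one decimal, half-to-even, with a trailing
``.0`` dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

from .amplicon_caller import VariantCall
from .coding_effects import CodingEffect


@dataclass(frozen=True)
class CohortVariantRecord:
    variant_key: str
    effect: CodingEffect
    exon: str
    carrier_count: int
    cohort_size: int
    domain: str = ""
    interface_class: str = ""
    gene_id: str = ""

    @property
    def percent_carriers(self) -> float:
        return 100.0 * self.carrier_count / self.cohort_size

    @property
    def percent_display(self) -> str:
        return format_percent(self.carrier_count, self.cohort_size)


def aggregate_cohort(call_sets: dict[str, list[VariantCall]],
                     cohort_size: int, annotate=None
                     ) -> list[CohortVariantRecord]:
    """Collapse per-animal call sets into one record per distinct variant.

    ``call_sets`` maps animal id -> calls for one gene.  Carrier counts
    count animals, not alleles.  ``annotate`` is a callable
    ``VariantCall -> (CodingEffect, domain, interface_class)``; when
    omitted, annotation fields stay empty.
    """
    if len(set(call_sets)) != len(call_sets):
        raise ValueError("duplicate animal identifiers")
    carriers: dict[str, set[str]] = {}
    exemplar: dict[str, VariantCall] = {}
    for animal, calls in call_sets.items():
        for call in calls:
            carriers.setdefault(call.genomic_key, set()).add(animal)
            exemplar.setdefault(call.genomic_key, call)

    records = []
    for key in sorted(carriers, key=lambda k: -len(carriers[k])):
        call = exemplar[key]
        if annotate is not None:
            effect, domain, iface = annotate(call)
        else:
            effect, domain, iface = None, "", ""
        records.append(CohortVariantRecord(
            variant_key=key,
            effect=effect,
            exon=call.exon,
            carrier_count=len(carriers[key]),
            cohort_size=cohort_size,
            domain=domain,
            interface_class=iface,
            gene_id=call.gene_id,
        ))
    return records


def filter_min_fraction(records, threshold: float = 0.02):
    """Keep records carried by at least ``threshold`` of the cohort."""
    return [r for r in records
            if r.carrier_count / r.cohort_size >= threshold]


def format_percent(count: int, total: int) -> str:
    """Carrier percentage at one decimal, half-to-even, '.0' dropped."""
    if total <= 0:
        raise ValueError("total must be positive")
    pct = (Decimal(count) * 100 / Decimal(total)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_EVEN)
    if pct == pct.to_integral_value():
        return str(int(pct))
    return str(pct)
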