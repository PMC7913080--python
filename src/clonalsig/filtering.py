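"""Somatic-variant filter cascade for multi-sample patient data.

A variant is retained as high-confidence somatic only if it survives, in
order:

1. ``filter_status`` — the caller's own PASS flag (MuTect2/FilterMutectCalls);
2. ``population_af`` — maximum population allele frequency below a cutoff
   (germline polymorphism exclusion);
3. ``depth`` — total read depth at least ``min_total_depth`` in *every*
   sample, tumor and control;
4. ``alt_reads`` — at least ``min_alt_reads`` variant-supporting reads in at
   least one tumor sample;
5. ``tumor_vaf`` — variant allele frequency at least ``min_vaf`` in at least
   one tumor sample;
6. ``centromere`` — position outside the excluded (centromeric) intervals;
7. ``control_reads`` — at most ``max_control_alt_reads`` variant reads in
   every control sample (somatic status).

Removal is attributed to the *first* failing rule so the report is
reproducible. The alt-read and VAF rules are evaluated over tumor samples
only: a remission control should never qualify a variant as somatic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import IntervalSet, SampleDescriptor, VariantRecord, tumor_samples, control_samples

#: Attribution order of the cascade.
FILTER_RULES = (
    "filter_status",
    "population_af",
    "depth",
    "alt_reads",
    "tumor_vaf",
    "centromere",
    "control_reads",
)


def compute_vaf(ref_count: int, alt_count: int) -> float:
    """Variant allele frequency alt/(ref+alt); 0.0 at zero depth.

    Zero-depth sites are attributed to the depth rule downstream, never the
    VAF rule.
    """
    if ref_count < 0 or alt_count < 0:
        raise ValueError(f"negative read counts ({ref_count}, {alt_count})")
    depth = ref_count + alt_count
    return alt_count / depth if depth > 0 else 0.0


@dataclass
class FilterParams:
    """Thresholds of the somatic filter cascade."""

    max_pop_af: float = 0.01
    min_total_depth: int = 20
    min_alt_reads: int = 3
    min_vaf: float = 0.25
    exclude_intervals: IntervalSet = field(default_factory=IntervalSet)
    max_control_alt_reads: int = 0
    require_pass: bool = True

    def __post_init__(self):
        if not (0 <= self.max_pop_af <= 1 and 0 <= self.min_vaf <= 1):
            raise ValueError("fraction thresholds must lie in [0, 1]")
        if min(self.min_total_depth, self.min_alt_reads, self.max_control_alt_reads) < 0:
            raise ValueError("count thresholds must be >= 0")


@dataclass
class FilterReport:
    """Accounting of the cascade: input = output + sum of per-rule removals."""

    input_count: int
    removed: dict[str, int]
    output_count: int

    def __post_init__(self):
        assert self.input_count == self.output_count + sum(self.removed.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.input_count)]
        rows += [(f"removed_{r}", self.removed[r]) for r in FILTER_RULES]
        rows.append(("output", self.output_count))
        return pd.DataFrame(rows, columns=["stage", "count"])


def failing_rule(
    record: VariantRecord,
    params: FilterParams,
    samples: list[SampleDescriptor],
) -> str | None:
    """Name of the first cascade rule the record fails, or None if it passes."""
    tumors = tumor_samples(samples)
    controls = control_samples(samples)

    if params.require_pass and record.filter_status != "PASS":
        return "filter_status"
    if not record.pop_af_max < params.max_pop_af:
        return "population_af"
    if any(sum(record.counts[s.name]) < params.min_total_depth for s in samples):
        return "depth"
    if not any(record.counts[s.name][1] >= params.min_alt_reads for s in tumors):
        return "alt_reads"
    if not any(compute_vaf(*record.counts[s.name]) >= params.min_vaf for s in tumors):
        return "tumor_vaf"
    if params.exclude_intervals.contains(record.chrom, record.pos):
        return "centromere"
    if any(record.counts[s.name][1] > params.max_control_alt_reads for s in controls):
        return "control_reads"
    return None


def apply_somatic_filters(
    records: list[VariantRecord],
    params: FilterParams,
    sample_descriptors: list[SampleDescriptor],
) -> tuple[list[VariantRecord], FilterReport]:
    """Run the cascade over all records; return survivors and the report."""
    removed = {r: 0 for r in FILTER_RULES}
    passing: list[VariantRecord] = []
    for rec in records:
        rule = failing_rule(rec, params, sample_descriptors)
        if rule is None:
            passing.append(rec)
        else:
            removed[rule] += 1
    report = FilterReport(
        input_count=len(records), removed=removed, output_count=len(passing)
    )
    return passing, report
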