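import numpy as np
import pytest

from clonalsig.io import SampleDescriptor, VariantRecord
from clonalsig.simulate import make_toy_genome, synthetic_signature_catalog


@pytest.fixture(scope="session")
def catalog():
    return synthetic_signature_catalog()


@pytest.fixture(scope="session")
def toy_genome():
    """(GenomeSource, sequences) — 50 kb, GC 0.4, all 32 contexts present."""
    return make_toy_genome(50_000, 0.4, seed=1)


@pytest.fixture(scope="session")
def samples4():
    """Three tumor timepoints plus one remission control."""
    return [
        SampleDescriptor("TUMOR_Dx", "tumor", 0, "Dx"),
        SampleDescriptor("TUMOR_R1", "tumor", 1, "R1"),
        SampleDescriptor("TUMOR_R2", "tumor", 2, "R2"),
        SampleDescriptor("CONTROL_CR", "control"),
    ]


def make_record(
    samples,
    tumor_counts=((40, 40),) * 3,
    control_counts=(80, 0),
    chrom="1",
    pos=5000,
    ref="C",
    alt="T",
    pop_af=0.0,
    filter_status="PASS",
):
    """A VariantRecord with explicit per-role read counts."""
    counts = {}
    t = 0
    for s in samples:
        if s.role == "tumor":
            counts[s.name] = tuple(tumor_counts[t])
            t += 1
        else:
            counts[s.name] = tuple(control_counts)
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, counts=counts,
        pop_af_max=pop_af, filter_status=filter_status,
    )


@pytest.fixture
def engineered_filter_fixture(samples4):
    """Ten records: one failing each of the seven cascade rules (population-AF
    twice), plus two that pass everything. Returns (records, annotations)
    with annotations[i] the intended first-failing rule or None."""
    from clonalsig.io import IntervalSet

    centro = IntervalSet([("1", 10_000, 12_000)])
    recs, notes = [], []

    def add(rule, **kw):
        recs.append(make_record(samples4, **kw))
        notes.append(rule)

    add(None, pos=100)
    add("filter_status", pos=200, filter_status="clustered_events")
    add("population_af", pos=300, pop_af=0.02)
    add("population_af", pos=350, pop_af=0.01)  # boundary: not strictly below
    add("depth", pos=400, control_counts=(19, 0))
    add("alt_reads", pos=500, tumor_counts=((78, 2), (78, 2), (78, 2)))
    add("tumor_vaf", pos=600, tumor_counts=((76, 4), (76, 4), (76, 4)))
    add("centromere", pos=11_000)
    add("control_reads", pos=700, control_counts=(79, 1))
    add(None, pos=800)
    return recs, notes, centro
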