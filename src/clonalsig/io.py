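"""Readers and writers for the pipeline's external formats.

Handles multi-sample VCF (via cyvcf2), reference FASTA (via pyfaidx),
signature catalogs in COSMIC v3 SBS layout, centromere BED files, and the
pipeline's tabular TSV outputs.

Coordinate conventions: variant positions are 1-based (VCF); BED intervals
are half-open 0-based. A 1-based position ``p`` falls inside a BED interval
``(s, e)`` iff ``s < p <= e``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 trinucleotide channels in canonical COSMIC order: substitution
#: class major (C>A, C>G, C>T, T>A, T>C, T>G), then 5' base, then 3' base.
CHANNELS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in BASES
    for three in BASES
)

CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}

_CHANNEL_RE = re.compile(r"^([ACGT])\[([CT])>([ACGT])\]([ACGT])$")


def normalize_chrom(name: str) -> str:
    """Harmonize chromosome naming between VCF, BED and FASTA ('chr1' -> '1')."""
    return name[3:] if name.startswith("chr") else name


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclass(frozen=True)
class SampleDescriptor:
    """One sequenced sample of a patient.

    Tumor samples carry a ``timepoint_index`` defining temporal order
    (0 = diagnosis); controls (remission samples) have no timepoint.
    """

    name: str
    role: str  # "tumor" | "control"
    timepoint_index: int | None = None
    timepoint_label: str = ""

    def __post_init__(self):
        if self.role not in ("tumor", "control"):
            raise ValueError(f"role must be 'tumor' or 'control', got {self.role!r}")
        if self.role == "tumor" and self.timepoint_index is None:
            raise ValueError(f"tumor sample {self.name!r} needs a timepoint_index")


def validate_samples(samples: list[SampleDescriptor]) -> None:
    """Check the descriptor-set invariants: contiguous tumor timepoints from
    0, at least one control."""
    tumors = sorted(
        (s for s in samples if s.role == "tumor"), key=lambda s: s.timepoint_index
    )
    controls = [s for s in samples if s.role == "control"]
    if not controls:
        raise ValueError("at least one control sample is required")
    idx = [s.timepoint_index for s in tumors]
    if idx != list(range(len(tumors))):
        raise ValueError(
            f"tumor timepoint_index values must be unique and contiguous from 0, got {idx}"
        )


def tumor_samples(samples: list[SampleDescriptor]) -> list[SampleDescriptor]:
    return sorted(
        (s for s in samples if s.role == "tumor"), key=lambda s: s.timepoint_index
    )


def control_samples(samples: list[SampleDescriptor]) -> list[SampleDescriptor]:
    return [s for s in samples if s.role == "control"]


@dataclass
class VariantRecord:
    """One somatic single-base substitution with per-sample read support."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    counts: dict[str, tuple[int, int]]  # sample name -> (ref_count, alt_count)
    pop_af_max: float = 0.0
    filter_status: str = "PASS"

    def __post_init__(self):
        if self.ref not in BASES or self.alt not in BASES or self.ref == self.alt:
            raise ValueError(f"not an SBS: {self.ref}>{self.alt}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class SignatureCatalog:
    """A reference set of SBS signatures over the 96 trinucleotide channels.

    ``matrix`` is 96 x S with columns in canonical channel order, each column
    renormalized to sum to 1 on load.
    """

    signature_names: list[str]
    matrix: np.ndarray  # 96 x S

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (96, len(self.signature_names)):
            raise ValueError(
                f"catalog matrix must be 96 x {len(self.signature_names)}, "
                f"got {self.matrix.shape}"
            )
        if (self.matrix < 0).any():
            raise ValueError("signature catalog contains negative entries")
        sums = self.matrix.sum(axis=0)
        if (sums <= 0).any():
            raise ValueError("signature catalog contains an all-zero column")
        self.matrix = self.matrix / sums

    @property
    def n_signatures(self) -> int:
        return len(self.signature_names)

    def column(self, name: str) -> np.ndarray:
        try:
            return self.matrix[:, self.signature_names.index(name)]
        except ValueError:
            raise KeyError(f"unknown signature {name!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=list(CHANNELS_96), columns=self.signature_names
        ).rename_axis("Type")

    def mixture(self, weights: dict[str, float]) -> np.ndarray:
        """Weighted mixture of catalog columns, normalized to sum 1."""
        v = np.zeros(96)
        for name, w in weights.items():
            v += w * self.column(name)
        return v / v.sum()


@dataclass
class IntervalSet:
    """Half-open 0-based genomic intervals (BED convention)."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"invalid interval {chrom}:{start}-{end} (start >= end)")
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.intervals:
            self._by_chrom.setdefault(normalize_chrom(chrom), []).append((start, end))

    def __len__(self) -> int:
        return len(self.intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position: inside (s, e) iff s < pos <= e."""
        for start, end in self._by_chrom.get(normalize_chrom(chrom), ()):
            if start < pos <= end:
                return True
        return False


class GenomeSource:
    """Uppercase sequence access by (chrom, start, end), 1-based inclusive.

    Wraps either a pyfaidx FASTA handle or an in-memory dict of sequences
    (the simulator's toy genomes). Chromosome names are harmonized across
    the 'chr' prefix dialects.
    """

    def __init__(self, sequences: dict[str, str]):
        self._seqs = {normalize_chrom(k): v.upper() for k, v in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSource":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self._seqs.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the sequence [start, end], 1-based inclusive."""
        seq = self._seqs.get(normalize_chrom(chrom))
        if seq is None:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 1 or end > len(seq) or start > end:
            raise IndexError(
                f"query {chrom}:{start}-{end} out of range (length {len(seq)})"
            )
        return seq[start - 1 : end]


def read_multisample_vcf(
    path: str | Path,
    sample_descriptors: list[SampleDescriptor],
    pop_af_fields: tuple[str, ...] = ("POPAF", "GNOMAD_AF", "GONL_AF"),
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Read somatic SBS records from a multi-sample VCF.

    Returns biallelic SBS records only; multiallelic sites are split into one
    record per alt allele; indels/MNVs and records without a per-sample AD
    field are skipped and counted. ``pop_af_max`` is the maximum over the
    population-AF INFO fields present. The FILTER column is preserved
    unchanged (PASS enforcement lives in the filtering module).

    Returns (records, skip_counts) with skip counts keyed by reason.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    names = {s.name for s in sample_descriptors}
    missing = names - set(vcf.samples)
    if missing:
        raise ValueError(
            f"sample(s) {sorted(missing)} not found in VCF columns {vcf.samples}"
        )
    sample_order = [vcf.samples.index(s.name) for s in sample_descriptors]

    records: list[VariantRecord] = []
    skipped = {"non_sbs": 0, "missing_ad": 0}
    for v in vcf:
        ad = v.format("AD")
        pop_af = 0.0
        for key in pop_af_fields:
            val = v.INFO.get(key)
            if val is not None:
                if isinstance(val, (tuple, list)):
                    val = max(val)
                pop_af = max(pop_af, float(val))
        filt = v.FILTER if v.FILTER is not None else "PASS"
        for alt_idx, alt in enumerate(v.ALT, start=1):
            if len(v.REF) != 1 or len(alt) != 1 or v.REF not in BASES or alt not in BASES:
                skipped["non_sbs"] += 1
                continue
            if ad is None or ad.shape[1] <= alt_idx:
                skipped["missing_ad"] += 1
                continue
            counts = {}
            for desc, col in zip(sample_descriptors, sample_order):
                r, a = int(ad[col, 0]), int(ad[col, alt_idx])
                counts[desc.name] = (max(r, 0), max(a, 0))  # cyvcf2 missing -> negative
            records.append(
                VariantRecord(
                    chrom=normalize_chrom(v.CHROM),
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    counts=counts,
                    pop_af_max=pop_af,
                    filter_status=filt,
                )
            )
    if skipped["non_sbs"] or skipped["missing_ad"]:
        logger.info("VCF read: skipped %d non-SBS, %d missing-AD records",
                    skipped["non_sbs"], skipped["missing_ad"])
    return records, skipped


def read_signature_catalog(path: str | Path) -> SignatureCatalog:
    """Load a signature catalog in COSMIC v3 SBS TSV layout.

    The context column (named 'Type' or the first column) must hold exactly
    96 unique COSMIC-style channel strings; rows are reordered into canonical
    channel order and columns renormalized to sum to 1.
    """
    df = pd.read_csv(path, sep="\t")
    ctx_col = "Type" if "Type" in df.columns else df.columns[0]
    contexts = df[ctx_col].astype(str).tolist()
    for c in contexts:
        if not _CHANNEL_RE.match(c):
            raise ValueError(f"unparseable trinucleotide context string {c!r}")
    if len(set(contexts)) != 96 or len(contexts) != 96:
        raise ValueError(f"expected 96 unique contexts, found {len(set(contexts))}")
    df = df.set_index(ctx_col).loc[list(CHANNELS_96)]
    num = df.select_dtypes(include=[np.number])
    if num.shape[1] < 1:
        raise ValueError("no numeric signature columns found")
    if (num.to_numpy() < 0).any():
        raise ValueError("negative entries in signature catalog")
    return SignatureCatalog(signature_names=list(num.columns), matrix=num.to_numpy())


def write_signature_catalog(catalog: SignatureCatalog, path: str | Path) -> None:
    catalog.to_frame().to_csv(path, sep="\t")


def read_centromere_bed(path: str | Path) -> IntervalSet:
    """Read a 3+ column BED of excluded (centromere) intervals."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}: line {lineno}: start >= end ({start} >= {end})")
            intervals.append((chrom, start, end))
    return IntervalSet(intervals)


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_tables(
    outdir: str | Path,
    assignments: pd.DataFrame | None = None,
    count_matrix: pd.DataFrame | None = None,
    similarities: pd.DataFrame | None = None,
    contributions: pd.DataFrame | None = None,
    filter_report: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the pipeline's tabular outputs as TSV into ``outdir``.

    Column order is deterministic and integer count matrices round-trip
    exactly. Returns a map from table name to written path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    tables = {
        "cluster_assignments": (assignments, False),
        "profile_counts_96": (count_matrix, True),
        "signature_similarity": (similarities, True),
        "signature_contributions": (contributions, False),
        "filter_report": (filter_report, False),
    }
    for name, (df, keep_index) in tables.items():
        if df is None:
            continue
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=keep_index)
        written[name] = path
    return written
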