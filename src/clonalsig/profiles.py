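"""96-trinucleotide mutational profiles and cosine similarity scoring.

Every single-base substitution is assigned to one of 96 channels defined by
the pyrimidine-strand substitution (C>A, C>G, C>T, T>A, T>C, T>G) and its
immediate 5' and 3' flanking bases. Purine-reference mutations are
reverse-complemented onto the pyrimidine strand, so the classification is
strand-collapsed by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    CHANNEL_INDEX,
    CHANNELS_96,
    COMPLEMENT,
    GenomeSource,
    SignatureCatalog,
    VariantRecord,
    reverse_complement,
)

logger = logging.getLogger(__name__)


class AmbiguousContextError(ValueError):
    """Raised when the trinucleotide context contains an N base."""


class ReferenceMismatchError(ValueError):
    """Raised when the genome base disagrees with a variant's REF allele
    (usually a genome-build mismatch)."""


@dataclass
class Profile96:
    """Counts of SBS mutations over the 96 channels, canonical order."""

    counts: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (96,):
            raise ValueError("profile must have exactly 96 channels")
        if (self.counts < 0).any():
            raise ValueError("negative channel counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def normalized(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def pyrimidine_context(
    genome: GenomeSource, chrom: str, pos: int, ref: str, alt: str
) -> str:
    """Channel string "X[R>A]Y" for an SBS, collapsed to the pyrimidine strand.

    The genome base at ``pos`` must equal ``ref`` and the position must not
    sit at a chromosome end (incomplete context). Purine refs are folded by
    reverse-complementing both the trinucleotide and the substitution.
    """
    if ref == alt:
        raise ValueError("ref and alt must differ")
    tri = genome.fetch(chrom, pos - 1, pos + 1)  # IndexError at chromosome ends
    if tri[1] != ref:
        raise ReferenceMismatchError(
            f"{chrom}:{pos} genome base {tri[1]!r} != REF {ref!r} "
            f"(genome-build mismatch?)"
        )
    if "N" in tri:
        raise AmbiguousContextError(f"{chrom}:{pos} context {tri} contains N")
    if ref in "AG":
        tri = reverse_complement(tri)
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{tri[0]}[{ref}>{alt}]{tri[2]}"


def count_profile96(
    mutations: list[VariantRecord], genome: GenomeSource, label: str = ""
) -> Profile96:
    """Tally a mutation set into a 96-channel count profile.

    Mutations whose context contains N are excluded with a logged count;
    ``total`` equals the number of counted mutations.
    """
    counts = np.zeros(96, dtype=int)
    excluded = 0
    for m in mutations:
        try:
            channel = pyrimidine_context(genome, m.chrom, m.pos, m.ref, m.alt)
        except AmbiguousContextError:
            excluded += 1
            continue
        counts[CHANNEL_INDEX[channel]] += 1
    if excluded:
        logger.info("profile %s: excluded %d mutation(s) with N context", label, excluded)
    return Profile96(counts=counts, label=label)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two nonnegative 96-vectors, in [0, 1].

    Scale invariant: raw counts and normalized profiles give identical
    values. A value of 1 means identical profiles up to scale.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity of a zero vector is undefined")
    return float(a @ b / (na * nb))


def merged_signature(catalog: SignatureCatalog, members: list[str]) -> np.ndarray:
    """Equal-weight mean of catalog columns, renormalized to sum to 1.

    Used for mechanisms that manifest as two coupled signatures (e.g. the
    APOBEC pair SBS2/SBS13).
    """
    cols = [catalog.column(name) for name in members]  # KeyError on unknown
    v = np.mean(cols, axis=0)
    return v / v.sum()


def catalog_similarity(
    profiles: list[Profile96],
    catalog: SignatureCatalog,
    merge_groups: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Full cluster x signature cosine-similarity matrix.

    ``merge_groups`` ({"SBS2/13": ["SBS2", "SBS13"], ...}) append derived
    columns holding the similarity to the renormalized equal-weight mean of
    the member signatures.
    """
    columns = {name: catalog.column(name) for name in catalog.signature_names}
    for gname, members in (merge_groups or {}).items():
        columns[gname] = merged_signature(catalog, members)
    data = {
        cname: [cosine_similarity(p.counts, col) for p in profiles]
        for cname, col in columns.items()
    }
    return pd.DataFrame(data, index=[p.label for p in profiles])


def report_view(similarity: pd.DataFrame, report_threshold: float = 0.7) -> pd.DataFrame:
    """Mask similarities below the reporting threshold (NaN), keeping only
    signatures that reach the threshold in at least one cluster."""
    masked = similarity.where(similarity >= report_threshold)
    return masked.dropna(axis=1, how="all")


def profiles_to_frame(profiles: list[Profile96]) -> pd.DataFrame:
    """96-count matrix with COSMIC 'Type' strings as row keys, clusters as
    columns — directly comparable to COSMIC-layout files."""
    return pd.DataFrame(
        {p.label: p.counts for p in profiles}, index=list(CHANNELS_96)
    ).rename_axis("Type")


def plot_profile96(profile: Profile96, ax=None):
    """Bar chart of a 96-channel profile, grouped by substitution class."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(12, 3))
    colors = ["#03BCEE", "#010101", "#E32926", "#CAC9C9", "#A1CE63", "#EBC6C4"]
    ax.bar(
        range(96),
        profile.counts,
        color=[colors[i // 16] for i in range(96)],
        width=0.8,
    )
    ax.set_xticks(range(96))
    ax.set_xticklabels(CHANNELS_96, rotation=90, fontsize=4)
    ax.set_ylabel("count")
    ax.set_title(profile.label)
    return ax
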