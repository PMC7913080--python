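"""Ground-truthed simulation of multi-timepoint somatic variant data.

Generates one "patient": a set of clones, each with a cancer-cell-fraction
(CCF) trajectory over serial tumor samples and a mutational-signature
mixture. Every clone mutation draws its 96-channel class from the clone's
mixture, is placed on a toy genome at a site whose trinucleotide context
matches the channel, and receives binomial read counts at Poisson depth
with expected VAF = purity_t x CCF_t / 2 (diploid heterozygous model).
Matched controls receive depth but zero variant reads, except engineered
decoy variants that exercise each somatic-filter rule.

The output — a multi-sample VCF with per-sample AD, a FASTA, a centromere
BED and a truth table — mirrors the structure of clinical serial-sampling
studies (diagnosis + relapses + remission controls) so the whole pipeline
is testable without any controlled-access data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import label_trajectory
from .io import (
    BASES,
    CHANNEL_INDEX,
    CHANNELS_96,
    COMPLEMENT,
    GenomeSource,
    IntervalSet,
    SampleDescriptor,
    SignatureCatalog,
    VariantRecord,
    write_bed,
    write_fasta,
)

_PYRIMIDINE_CONTEXTS = tuple(
    five + mid + three for mid in "CT" for five in BASES for three in BASES
)


def synthetic_signature_catalog() -> SignatureCatalog:
    """A small synthetic stand-in signature catalog.

    Deterministic, stylized approximations of well-known signature *shapes*
    — SBS1 (clock-like C>T at NpCpG), SBS2/SBS13 (APOBEC C>T / C>G at TpC),
    SBS5 (flat), SBS7a (UV-like C>T at dipyrimidines), SBS18 and SBS87 (two
    distinct C>A patterns) — NOT the COSMIC reference signatures. Intended
    for simulation and tests; real analyses should load a real COSMIC v3
    file with :func:`clonalsig.io.read_signature_catalog`.
    """

    def build(peaks: dict[str, float], floor: float) -> np.ndarray:
        v = np.full(96, floor / (96 - len(peaks)))
        for channel, w in peaks.items():
            v[CHANNEL_INDEX[channel]] = w
        return v / v.sum()

    sigs = {
        "SBS1": build(
            {f"{b}[C>T]G": 0.21 for b in BASES}, floor=0.16
        ),
        "SBS2": build(
            {"T[C>T]A": 0.34, "T[C>T]T": 0.33, "T[C>T]C": 0.09, "T[C>T]G": 0.09},
            floor=0.15,
        ),
        "SBS5": None,  # filled below: flat with a mild C>T tilt
        "SBS7a": build(
            {
                "C[C>T]C": 0.24, "C[C>T]T": 0.24, "T[C>T]C": 0.14,
                "C[C>T]A": 0.09, "C[C>T]G": 0.05, "G[C>T]C": 0.05,
            },
            floor=0.19,
        ),
        "SBS13": build(
            {"T[C>G]A": 0.34, "T[C>G]T": 0.33, "T[C>G]C": 0.09, "T[C>G]G": 0.09},
            floor=0.15,
        ),
        "SBS18": build(
            {f"A[C>A]{b}": 0.20 for b in BASES}, floor=0.20
        ),
        "SBS87": build(
            {f"G[C>A]{b}": 0.20 for b in BASES}, floor=0.20
        ),
    }
    flat = np.ones(96)
    flat[[CHANNEL_INDEX[c] for c in CHANNELS_96 if "[C>T]" in c]] = 1.5
    sigs["SBS5"] = flat / flat.sum()
    names = list(sigs)
    return SignatureCatalog(
        signature_names=names, matrix=np.column_stack([sigs[n] for n in names])
    )


def make_toy_genome(
    length: int = 200_000, gc_content: float = 0.4, seed: int = 0
) -> tuple[GenomeSource, dict[str, str]]:
    """Seeded i.i.d. toy genome with all 32 pyrimidine-centered contexts.

    Regenerates (bumping the stream) in the unlikely case a context is
    missing; degenerate GC content is rejected.
    """
    if length < 1000:
        raise ValueError("toy genome length must be >= 1000")
    if not 0 < gc_content < 1:
        raise ValueError("gc_content must lie strictly between 0 and 1")
    p = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    rng = np.random.default_rng(seed)
    for _ in range(10):
        seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
        present = {
            seq[i : i + 3] if seq[i + 1] in "CT"
            else "".join(COMPLEMENT[b] for b in reversed(seq[i : i + 3]))
            for i in range(length - 2)
        }
        if set(_PYRIMIDINE_CONTEXTS) <= present:
            break
    else:  # pragma: no cover - astronomically unlikely at the length floor
        raise RuntimeError("failed to generate a genome containing all 32 contexts")
    seqs = {"chr1": seq}
    return GenomeSource(seqs), seqs


@dataclass
class CloneSpec:
    """One clone: its CCF trajectory, size and signature mixture."""

    name: str
    ccf_per_timepoint: list[float]
    n_mutations: int
    signature_weights: dict[str, float]

    def __post_init__(self):
        w = np.array(list(self.signature_weights.values()))
        if (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError(f"clone {self.name}: weights must be >= 0 and sum to 1")
        if not all(0 <= c <= 1 for c in self.ccf_per_timepoint):
            raise ValueError(f"clone {self.name}: CCFs must lie in [0, 1]")


@dataclass
class SimulationConfig:
    """Study-condition parameters of one simulated patient."""

    timepoint_labels: list[str]
    purity_per_timepoint: list[float]
    clones: list[CloneSpec]
    mean_depth: float = 80.0
    depth_overdispersion: float = 0.0  # >0: gamma-Poisson (negative binomial)
    toy_genome_length: int = 200_000
    gc_content: float = 0.4
    n_controls: int = 1
    n_background_samples: int = 30
    background_mutations_range: tuple[int, int] = (800, 3000)
    background_processes: list[dict[str, float]] = field(default_factory=list)
    decoys_per_rule: int = 2
    germline_contamination_rate: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if len(self.timepoint_labels) < 2:
            raise ValueError("need >= 2 tumor timepoints")
        if len(self.purity_per_timepoint) != len(self.timepoint_labels):
            raise ValueError("purity_per_timepoint length mismatch")
        if not self.clones:
            raise ValueError("need >= 1 clone")
        for c in self.clones:
            if len(c.ccf_per_timepoint) != len(self.timepoint_labels):
                raise ValueError(f"clone {c.name}: CCF trajectory length mismatch")


@dataclass
class GroundTruth:
    """What the simulator planted, keyed the same way the pipeline reports."""

    mutations: pd.DataFrame  # mutation_id, clone, channel, intended_fail
    clone_trajectories: dict[str, str]
    clone_weights: dict[str, dict[str, float]]
    purity: dict[str, float]


@dataclass
class SimulatedPatient:
    sample_descriptors: list[SampleDescriptor]
    records: list[VariantRecord]
    truth: GroundTruth
    sequences: dict[str, str]
    genome: GenomeSource
    centromere: IntervalSet
    background_counts: np.ndarray  # 96 x B
    background_names: list[str]
    filter_decoy_rules: dict[str, str]  # mutation key -> intended failing rule

    def write_vcf(self, path: str | Path) -> Path:
        path = Path(path)
        samples = [s.name for s in self.sample_descriptors]
        lines = [
            "##fileformat=VCFv4.2",
            '##FILTER=<ID=PASS,Description="All filters passed">',
            '##FILTER=<ID=artifact,Description="Failed caller-internal filters">',
            '##INFO=<ID=POPAF,Number=1,Type=Float,Description="Max population allele frequency">',
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        ]
        for chrom, seq in self.sequences.items():
            lines.append(f"##contig=<ID={chrom},length={len(seq)}>")
        lines.append(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
        )
        for rec in sorted(self.records, key=lambda r: (r.chrom, r.pos, r.alt)):
            fields = [
                f"chr{rec.chrom}" if not rec.chrom.startswith("chr") else rec.chrom,
                str(rec.pos), ".", rec.ref, rec.alt, ".",
                rec.filter_status, f"POPAF={rec.pop_af_max:.6g}", "GT:AD:DP",
            ]
            for s in samples:
                r, a = rec.counts[s]
                fields.append(f"0/1:{r},{a}:{r + a}")
            lines.append("\t".join(fields))
        path.write_text("\n".join(lines) + "\n")
        return path

    def write_fasta(self, path: str | Path) -> Path:
        write_fasta(self.sequences, path)
        return Path(path)

    def write_centromere_bed(self, path: str | Path) -> Path:
        write_bed(self.centromere, path)
        return Path(path)

    def write_truth(self, path: str | Path) -> Path:
        self.truth.mutations.to_csv(path, sep="\t", index=False)
        return Path(path)

    def write_background_counts(self, path: str | Path) -> Path:
        pd.DataFrame(
            self.background_counts,
            index=list(CHANNELS_96),
            columns=self.background_names,
        ).rename_axis("Type").to_csv(path, sep="\t")
        return Path(path)


class _SitePicker:
    """Samples genome sites by pyrimidine trinucleotide context, without
    replacement, excluding a forbidden interval set."""

    def __init__(self, seq: str, exclude: IntervalSet, rng: np.random.Generator,
                 invert: bool = False):
        sites: dict[str, list[tuple[int, str]]] = {c: [] for c in _PYRIMIDINE_CONTEXTS}
        for i in range(1, len(seq) - 1):
            pos = i + 1  # 1-based center
            inside = exclude.contains("chr1", pos)
            if inside != invert:
                continue
            tri = seq[i - 1 : i + 2]
            if "N" in tri:
                continue
            if tri[1] in "CT":
                sites[tri].append((pos, "+"))
            else:
                rc = "".join(COMPLEMENT[b] for b in reversed(tri))
                sites[rc].append((pos, "-"))
        self._sites = sites
        self._order = {c: list(rng.permutation(len(v))) for c, v in sites.items()}

    def take(self, context: str) -> tuple[int, str]:
        order = self._order[context]
        if not order:
            raise RuntimeError(
                f"no remaining genome site with context {context}; "
                f"use a longer toy genome"
            )
        return self._sites[context][order.pop()]


def _channel_to_variant(channel: str, strand: str) -> tuple[str, str]:
    """(ref, alt) on the + strand for a channel placed on the given strand."""
    five, sub, three = channel[0], channel[2:5], channel[6]
    ref, alt = sub[0], sub[2]
    if strand == "-":
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return ref, alt


def _draw_depth(rng: np.random.Generator, mean: float, overdispersion: float) -> int:
    if overdispersion > 0:
        lam = rng.gamma(1.0 / overdispersion, mean * overdispersion)
    else:
        lam = mean
    return int(rng.poisson(lam))


def simulate_patient(
    config: SimulationConfig,
    catalog: SignatureCatalog,
    genome: GenomeSource | None = None,
    sequences: dict[str, str] | None = None,
) -> SimulatedPatient:
    """Simulate one patient's multi-sample somatic SBS call set with truth.

    Clone mutations land outside the centromere interval; decoy variants
    engineered to fail exactly one somatic-filter rule each (annotated in
    the truth table) are added on top.
    """
    rng = np.random.default_rng(config.seed)
    if genome is None or sequences is None:
        genome, sequences = make_toy_genome(
            config.toy_genome_length, config.gc_content, seed=config.seed
        )
    seq = sequences["chr1"]
    # toy centromere: the middle 4% of the chromosome
    mid = len(seq) // 2
    half = len(seq) // 50
    centromere = IntervalSet([("chr1", mid - half, mid + half)])

    T = len(config.timepoint_labels)
    tumors = [
        SampleDescriptor(f"TUMOR_{lab}", "tumor", i, lab)
        for i, lab in enumerate(config.timepoint_labels)
    ]
    controls = [
        SampleDescriptor(f"CONTROL_CR{i + 1}", "control") for i in range(config.n_controls)
    ]
    samples = tumors + controls

    picker = _SitePicker(seq, centromere, rng)
    centro_picker = _SitePicker(seq, centromere, rng, invert=True)
    purity = np.asarray(config.purity_per_timepoint, dtype=float)

    records: list[VariantRecord] = []
    truth_rows: list[dict] = []
    decoy_rules: dict[str, str] = {}

    def emit(channel: str, vaf_per_t: np.ndarray, clone: str,
             intended_fail: str = "", pop_af: float = 0.0,
             filter_status: str = "PASS", control_vaf: float = 0.0,
             forced_depth: dict[str, int] | None = None,
             forced_alt: dict[str, int] | None = None,
             in_centromere: bool = False) -> None:
        pos, strand = (centro_picker if in_centromere else picker).take(
            channel[0] + channel[2] + channel[6]
        )
        ref, alt = _channel_to_variant(channel, strand)
        counts: dict[str, tuple[int, int]] = {}
        for s in samples:
            depth = _draw_depth(rng, config.mean_depth, config.depth_overdispersion)
            if forced_depth and s.name in forced_depth:
                depth = forced_depth[s.name]
            vaf = (
                vaf_per_t[s.timepoint_index] if s.role == "tumor" else control_vaf
            )
            a = int(rng.binomial(depth, vaf)) if depth > 0 else 0
            if forced_alt and s.name in forced_alt:
                a = min(forced_alt[s.name], depth)
            counts[s.name] = (depth - a, a)
        rec = VariantRecord(
            chrom="1", pos=pos, ref=ref, alt=alt, counts=counts,
            pop_af_max=pop_af, filter_status=filter_status,
        )
        records.append(rec)
        truth_rows.append(
            {"mutation_id": rec.key, "clone": clone, "channel": channel,
             "intended_fail": intended_fail}
        )
        if intended_fail:
            decoy_rules[rec.key] = intended_fail

    # --- clone mutations -------------------------------------------------
    channel_names = np.array(CHANNELS_96)
    for clone in config.clones:
        mixture = catalog.mixture(clone.signature_weights)
        channels = rng.choice(channel_names, size=clone.n_mutations, p=mixture)
        vaf_per_t = purity * np.asarray(clone.ccf_per_timepoint) / 2.0
        for channel in channels:
            emit(str(channel), vaf_per_t, clone.name)

    # --- decoy variants exercising the filter cascade --------------------
    n_clone = sum(c.n_mutations for c in config.clones)
    flat_channel = "A[C>T]A"
    clonal_vaf = purity / 2.0
    first_control = controls[0].name
    first_tumor = tumors[0].name
    n_germline = max(
        config.decoys_per_rule, int(round(config.germline_contamination_rate * n_clone))
    )
    decoy_plan: list[tuple[str, dict]] = []
    for _ in range(config.decoys_per_rule):
        decoy_plan += [
            ("filter_status", {"filter_status": "artifact"}),
            ("population_af", {"pop_af": 0.05}),
            ("depth", {"forced_depth": {first_control: 10}}),
            ("alt_reads", {"forced_alt": {s.name: 2 for s in tumors}}),
            ("tumor_vaf", {"forced_alt": {s.name: 8 for s in tumors},
                           "forced_depth": {s.name: 80 for s in tumors}}),
            ("centromere", {"in_centromere": True}),
        ]
    for _ in range(n_germline):
        decoy_plan.append(("control_reads", {"control_vaf": 0.5}))
    for rule, kwargs in decoy_plan:
        emit(flat_channel, clonal_vaf, clone="DECOY", intended_fail=rule, **kwargs)

    # --- background 96-count columns (extraction augmentation) -----------
    processes = config.background_processes or [
        {name: 1.0} for name in catalog.signature_names
    ]
    B = config.n_background_samples
    bg = np.zeros((96, B), dtype=int)
    lo, hi = config.background_mutations_range
    for b in range(B):
        expo = rng.dirichlet(np.ones(len(processes)))
        mix = np.zeros(96)
        for w, proc in zip(expo, processes):
            mix += w * catalog.mixture(proc)
        mix /= mix.sum()
        n = int(rng.integers(lo, hi + 1))
        bg[:, b] = rng.multinomial(n, mix)
    bg_names = [f"BG{b + 1}" for b in range(B)]

    clone_traj = {
        c.name: label_trajectory(np.asarray(c.ccf_per_timepoint), 0.1)
        for c in config.clones
    }
    truth = GroundTruth(
        mutations=pd.DataFrame(truth_rows),
        clone_trajectories=clone_traj,
        clone_weights={c.name: dict(c.signature_weights) for c in config.clones},
        purity=dict(zip(config.timepoint_labels, purity.tolist())),
    )
    return SimulatedPatient(
        sample_descriptors=samples,
        records=records,
        truth=truth,
        sequences=sequences,
        genome=genome,
        centromere=centromere,
        background_counts=bg,
        background_names=bg_names,
        filter_decoy_rules=decoy_rules,
    )


def scenario_presets() -> dict[str, SimulationConfig]:
    """Named study-condition presets.

    ``patient1_like``: three tumor timepoints (Dx, R1, R2), six clones —
    a clock-like ancestral clone, a large falling APOBEC-dominated clone,
    two relapse-1 risers (one transient), and two relapse-2 risers, APOBEC
    dominated — with sizes scaled roughly 5x down from the published serial
    relapse case. APOBEC is planted as one coherent process (equal SBS2 and
    SBS13 weights).

    ``patient2_like``: four tumor timepoints with two remission controls,
    UV-like (SBS7a) mutagenesis in the first three clones and a
    thiopurine-like (SBS87) component in the relapse-1 riser.
    """
    apobec = {"SBS2": 0.5, "SBS13": 0.5}

    def mixed(apobec_w: float, rest: dict[str, float]) -> dict[str, float]:
        out = {k: v for k, v in rest.items()}
        out["SBS2"] = apobec_w / 2
        out["SBS13"] = apobec_w / 2
        return out

    patient1 = SimulationConfig(
        timepoint_labels=["Dx", "R1", "R2"],
        purity_per_timepoint=[0.9, 0.9, 0.9],
        clones=[
            CloneSpec("clone1", [1.0, 1.0, 1.0], 150, {"SBS1": 0.8, "SBS5": 0.2}),
            CloneSpec("clone2", [0.95, 0.0, 0.0], 1100, mixed(0.9, {"SBS1": 0.1})),
            CloneSpec("clone3", [0.0, 0.9, 0.85], 110,
                      mixed(0.5, {"SBS1": 0.45, "SBS5": 0.05})),
            CloneSpec("clone4", [0.0, 0.9, 0.0], 40, mixed(0.45, {"SBS1": 0.55})),
            CloneSpec("clone5", [0.0, 0.35, 0.9], 220, mixed(0.95, {"SBS5": 0.05})),
            CloneSpec("clone6", [0.0, 0.0, 0.9], 180, mixed(0.9, {"SBS1": 0.1})),
        ],
        mean_depth=80.0,
        n_controls=1,
        n_background_samples=30,
        background_mutations_range=(800, 3000),
        background_processes=[{"SBS1": 1.0}, apobec, {"SBS5": 1.0}],
        seed=0,
    )
    patient2 = SimulationConfig(
        timepoint_labels=["Dx", "R1", "R2", "R3"],
        purity_per_timepoint=[0.9, 0.9, 0.9, 0.9],
        clones=[
            CloneSpec("clone1", [1.0, 1.0, 1.0, 1.0], 200,
                      {"SBS7a": 0.8, "SBS5": 0.2}),
            CloneSpec("clone2", [0.9, 0.0, 0.0, 0.0], 700,
                      {"SBS7a": 0.9, "SBS5": 0.1}),
            CloneSpec("clone3", [0.0, 0.9, 0.0, 0.0], 450,
                      {"SBS7a": 0.6, "SBS87": 0.4}),
            CloneSpec("clone4", [0.0, 0.0, 0.9, 0.0], 150,
                      {"SBS5": 0.6, "SBS1": 0.4}),
            CloneSpec("clone5", [0.0, 0.0, 0.0, 0.9], 150,
                      {"SBS5": 0.5, "SBS18": 0.5}),
        ],
        mean_depth=80.0,
        n_controls=2,
        n_background_samples=30,
        background_mutations_range=(800, 3000),
        background_processes=[
            {"SBS7a": 1.0}, {"SBS87": 1.0}, {"SBS1": 1.0},
            {"SBS5": 1.0}, {"SBS18": 1.0},
        ],
        seed=0,
    )
    return {"patient1_like": patient1, "patient2_like": patient2}
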