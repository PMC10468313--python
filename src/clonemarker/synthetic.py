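"""Synthetic clonal-cohort generator.

Emulates, at desk scale, the data a resequencing study of vegetatively
propagated clones produces *after* variant calling: a diploid reference, a
background of heterozygous variants shared by every clone (the cultivar's
standing heterozygosity against its haploid reference assembly), per-clone
somatic variants shared by a clone's replicates and absent elsewhere, noisy
per-replicate genotype calls (dropouts, spurious singletons, QUAL scores),
and per-marker amplicon read sets.

Defaults are anchored to the published grapevine numbers where available:
GC 0.345, background heterozygosity ~5 SNV+InDel per kbp, SNV
transition/transversion ratio 2.1, 25.8% of variants InDels, 94% of
clone-specific variants heterozygous, ~1,000 clone-specific variants per
clone. Dropout and false-positive rates are free parameters of the noise
model (the study's own call noise is unobservable); their defaults, 0.05 and
1e-5, are set so every downstream filter has measurable work to do.

All randomness flows from a single integer seed through named
``numpy.random.Generator`` instances; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .errors import CapacityError, InvalidDesignError
from .variant_io import SiteKey, VariantRecord, normalize_variant, write_vcf

BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


@dataclass
class QualModel:
    """Two shifted normal distributions for site QUAL.

    True calls are centered well above the conventional Q>100 filter, false
    calls below it, so the filter removes a tunable share of noise. Draws
    are clipped at 0.
    """

    true_mean: float = 500.0
    true_sd: float = 80.0
    false_mean: float = 60.0
    false_sd: float = 30.0

    def draw(self, rng: np.random.Generator, true_call: bool) -> float:
        mu, sd = (
            (self.true_mean, self.true_sd)
            if true_call
            else (self.false_mean, self.false_sd)
        )
        return float(max(0.0, rng.normal(mu, sd)))


@dataclass
class CohortDesign:
    """Clone/replicate structure plus every simulation parameter.

    ``background_het_rate`` is variants per bp shared (heterozygous) by all
    clones; ``clone_specific_count`` maps each clone to the exact number of
    exclusive variants planted for it.
    """

    clones: list[str]
    replicates_per_clone: dict[str, int]
    genome_length: int = 1_000_000
    n_contigs: int = 2
    gc_fraction: float = 0.345
    background_het_rate: float = 0.005
    clone_specific_count: dict[str, int] = field(default_factory=dict)
    indel_fraction: float = 0.258
    indel_size_range: tuple[int, int] = (1, 15)
    tstv_ratio: float = 2.1
    het_fraction_specific: float = 0.94
    dropout_rate: float = 0.05
    false_positive_rate: float = 1e-5
    qual_model: QualModel = field(default_factory=QualModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.clones)) != len(self.clones):
            raise InvalidDesignError("clone identifiers must be unique")
        if not self.clones:
            raise InvalidDesignError("at least one clone is required")
        for c in self.clones:
            if self.replicates_per_clone.get(c, 0) < 1:
                raise InvalidDesignError(f"clone {c!r} needs >= 1 replicate")
        if self.genome_length < 1_000:
            raise InvalidDesignError("genome_length must be >= 1,000 bp")
        if self.n_contigs < 1:
            raise InvalidDesignError("n_contigs must be positive")
        if not 0 < self.gc_fraction < 1:
            raise InvalidDesignError("gc_fraction must be in (0, 1)")
        for name in (
            "background_het_rate",
            "indel_fraction",
            "het_fraction_specific",
            "dropout_rate",
            "false_positive_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidDesignError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.indel_size_range
        if not 1 <= lo <= hi:
            raise InvalidDesignError("indel_size_range must satisfy 1 <= min <= max")
        if self.tstv_ratio <= 0:
            raise InvalidDesignError("tstv_ratio must be positive")
        self.clone_specific_count = {
            c: int(self.clone_specific_count.get(c, 0)) for c in self.clones
        }
        if any(v < 0 for v in self.clone_specific_count.values()):
            raise InvalidDesignError("clone_specific_count values must be >= 0")

    @property
    def samples(self) -> list[str]:
        return [
            f"{c}_r{i}"
            for c in self.clones
            for i in range(1, self.replicates_per_clone[c] + 1)
        ]

    def sample_to_clone(self) -> dict[str, str]:
        return {
            f"{c}_r{i}": c
            for c in self.clones
            for i in range(1, self.replicates_per_clone[c] + 1)
        }

    def to_dict(self) -> dict:
        return asdict(self)


def make_design(
    n_clones: int = 4,
    replicates: int = 3,
    clone_specific: int = 1000,
    **overrides,
) -> CohortDesign:
    """Convenience constructor for a uniform cohort design."""
    clones = [f"clone{i + 1}" for i in range(n_clones)]
    return CohortDesign(
        clones=clones,
        replicates_per_clone={c: replicates for c in clones},
        clone_specific_count={c: clone_specific for c in clones},
        **overrides,
    )


# ---------------------------------------------------------------------------
# Reference


def generate_reference(
    genome_length: int,
    n_contigs: int = 1,
    gc_fraction: float = 0.345,
    seed: int = 0,
) -> dict[str, str]:
    """Generate an i.i.d. reference with the given GC content.

    Contigs are named ``contig_001`` ... and split the total length evenly,
    remainder on the last contig. Deterministic in ``seed``.
    """
    if genome_length < 1_000 or n_contigs < 1:
        raise InvalidDesignError("need genome_length >= 1,000 and n_contigs >= 1")
    if not 0 < gc_fraction < 1:
        raise InvalidDesignError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array(
        [
            (1 - gc_fraction) / 2,
            gc_fraction / 2,
            gc_fraction / 2,
            (1 - gc_fraction) / 2,
        ]
    )
    base_len = genome_length // n_contigs
    out: dict[str, str] = {}
    for i in range(n_contigs):
        length = base_len if i < n_contigs - 1 else genome_length - base_len * (
            n_contigs - 1
        )
        seq = rng.choice(BASES, size=length, p=p)
        out[f"contig_{i + 1:03d}"] = "".join(seq)
    return out


def write_fasta(reference: Mapping[str, str], path: str, width: int = 70) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in reference.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Truth


@dataclass
class TruthRecord:
    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    origin: str  # "background" or "clone-specific:<clone>"
    clone: str | None
    genotypes: dict[str, int]  # sample -> dosage 0/1/2

    @property
    def key(self) -> SiteKey:
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass
class TruthTable:
    """Planted variants with their true per-sample genotypes."""

    samples: list[str]
    records: list[TruthRecord]
    reference: dict[str, str] | None = None

    def clone_specific_keys(self) -> dict[str, set[SiteKey]]:
        out: dict[str, set[SiteKey]] = {}
        for r in self.records:
            if r.clone is not None:
                out.setdefault(r.clone, set()).add(r.key)
        return out

    def background_keys(self) -> set[SiteKey]:
        return {r.key for r in self.records if r.clone is None}

    def validate(self, sample_to_clone: Mapping[str, str]) -> None:
        """Assert the exclusivity invariant by direct scan."""
        keys = [r.key for r in self.records]
        if len(set(keys)) != len(keys):
            raise InvalidDesignError("duplicate variant keys in truth table")
        for r in self.records:
            if r.clone is None:
                continue
            for s in self.samples:
                d = r.genotypes[s]
                if sample_to_clone[s] == r.clone and d < 1:
                    raise InvalidDesignError(
                        f"{r.key}: focal replicate {s} lacks the variant"
                    )
                if sample_to_clone[s] != r.clone and d != 0:
                    raise InvalidDesignError(
                        f"{r.key}: non-focal sample {s} carries the variant"
                    )

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            cols = ["contig", "pos", "ref", "alt", "origin", "clone"] + self.samples
            fh.write("\t".join(cols) + "\n")
            for r in self.records:
                row = [
                    r.contig,
                    str(r.pos),
                    r.ref,
                    r.alt,
                    r.origin,
                    r.clone or ".",
                ] + [str(r.genotypes[s]) for s in self.samples]
                fh.write("\t".join(row) + "\n")


def _draw_snv_alt(rng: np.random.Generator, ref_base: str, tstv_ratio: float) -> str:
    if rng.random() < tstv_ratio / (tstv_ratio + 1.0):
        return _TRANSITION[ref_base]
    return _TRANSVERSIONS[ref_base][rng.integers(2)]


def plant_cohort(design: CohortDesign, reference: Mapping[str, str]) -> TruthTable:
    """Plant background and clone-specific variants into the reference.

    Background variants are heterozygous in every sample (shared cultivar
    heterozygosity); each clone receives exactly
    ``design.clone_specific_count[clone]`` exclusive variants, heterozygous
    with probability ``het_fraction_specific`` (hom-alt otherwise), carried
    by all of its replicates and by no other sample. Variant positions never
    collide; InDels are planted left-aligned with a VCF anchor base.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0xC0]))
    contigs = list(reference)
    lengths = np.array([len(reference[c]) for c in contigs])
    total = int(lengths.sum())
    samples = design.samples
    s2c = design.sample_to_clone()

    n_background = rng.binomial(total, design.background_het_rate)
    n_specific = sum(design.clone_specific_count.values())
    max_size = design.indel_size_range[1]
    if (n_background + n_specific) * (max_size + 2) > total:
        raise CapacityError(
            f"{n_background + n_specific} variants do not fit in {total} bp"
        )

    occupied: set[tuple[str, int]] = set()
    used_keys: set[SiteKey] = set()
    records: list[TruthRecord] = []
    offsets = np.concatenate([[0], np.cumsum(lengths)])

    def place_one(origin: str, clone: str | None) -> TruthRecord:
        for _ in range(10_000):
            g = int(rng.integers(total))
            ci = int(np.searchsorted(offsets, g, side="right") - 1)
            contig = contigs[ci]
            seq = reference[contig]
            pos = g - int(offsets[ci]) + 1  # 1-based
            is_indel = rng.random() < design.indel_fraction
            lo, hi = design.indel_size_range
            size = int(rng.integers(lo, hi + 1)) if is_indel else 0
            # keep clear of contig edges: room for anchor and deleted span
            if pos < 2 or pos + size + 1 > len(seq):
                continue
            span = range(pos, pos + size + 1) if is_indel else range(pos, pos + 1)
            if any((contig, p) in occupied for p in span):
                continue
            if not is_indel:
                ref = seq[pos - 1]
                alt = _draw_snv_alt(rng, ref, design.tstv_ratio)
            elif rng.random() < 0.5:  # deletion
                ref = seq[pos - 1 : pos + size]
                alt = seq[pos - 1]
            else:  # insertion
                ref = seq[pos - 1]
                alt = ref + "".join(rng.choice(BASES, size=size))
            cand = VariantRecord(contig=contig, pos=pos, ref=ref, alt=alt)
            norm = normalize_variant(cand, reference)
            key = norm.key
            if key in used_keys:
                continue
            if any(
                (norm.contig, p) in occupied
                for p in range(norm.pos, norm.pos + len(norm.ref))
            ):
                continue
            for p in range(norm.pos, norm.pos + max(len(norm.ref), size + 1)):
                occupied.add((norm.contig, p))
            for p in span:
                occupied.add((contig, p))
            used_keys.add(key)
            if clone is None:
                genotypes = {s: 1 for s in samples}
            else:
                dosage = 1 if rng.random() < design.het_fraction_specific else 2
                genotypes = {s: (dosage if s2c[s] == clone else 0) for s in samples}
            return TruthRecord(
                contig=norm.contig,
                pos=norm.pos,
                ref=norm.ref,
                alt=norm.alt,
                origin=origin,
                clone=clone,
                genotypes=genotypes,
            )
        raise CapacityError("could not place variant without collision")

    for _ in range(n_background):
        records.append(place_one("background", None))
    for clone in design.clones:
        for _ in range(design.clone_specific_count[clone]):
            records.append(place_one(f"clone-specific:{clone}", clone))

    records.sort(key=lambda r: (r.contig, r.pos, r.ref, r.alt))
    truth = TruthTable(samples=samples, records=records, reference=dict(reference))
    truth.validate(s2c)
    return truth


# ---------------------------------------------------------------------------
# Noisy calls


def simulate_calls(
    truth: TruthTable,
    design: CohortDesign,
    seed: int | None = None,
) -> tuple[list[str], list[VariantRecord]]:
    """Emulate joint-genotyper output over the truth table.

    Each true variant is dropped from a replicate (genotype set to missing)
    with probability ``dropout_rate``; spurious heterozygous singletons are
    injected at ``false_positive_rate`` per site per replicate with QUAL
    drawn from the low (false-call) component of the QUAL model. A truth
    record observed in no sample at all is not emitted — a caller cannot
    report an allele it never saw.
    """
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCA11]))
    samples = truth.samples
    records: list[VariantRecord] = []
    for t in truth.records:
        genotypes: dict[str, int | None] = {}
        any_present = False
        for s in samples:
            d = t.genotypes[s]
            if d >= 1 and design.dropout_rate > 0 and rng.random() < design.dropout_rate:
                genotypes[s] = None
            else:
                genotypes[s] = d
                any_present = any_present or d >= 1
        if design.dropout_rate > 0 and not any_present:
            continue
        records.append(
            VariantRecord(
                contig=t.contig,
                pos=t.pos,
                ref=t.ref,
                alt=t.alt,
                qual=design.qual_model.draw(rng, true_call=True),
                genotypes=genotypes,
            )
        )

    if design.false_positive_rate > 0:
        reference = truth.reference
        if reference is None:
            raise InvalidDesignError(
                "false-positive injection needs the truth table's reference"
            )
        contigs = list(reference)
        lengths = np.array([len(reference[c]) for c in contigs])
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        total = int(lengths.sum())
        taken = {r.key for r in records} | {t.key for t in truth.records}
        n_fp = rng.binomial(total * len(samples), design.false_positive_rate)
        for _ in range(n_fp):
            for _attempt in range(1000):
                g = int(rng.integers(total))
                ci = int(np.searchsorted(offsets, g, side="right") - 1)
                contig = contigs[ci]
                pos = g - int(offsets[ci]) + 1
                ref = reference[contig][pos - 1]
                alt = _draw_snv_alt(rng, ref, design.tstv_ratio)
                if (contig, pos, ref, alt) in taken:
                    continue
                taken.add((contig, pos, ref, alt))
                victim = samples[int(rng.integers(len(samples)))]
                genotypes = {s: (1 if s == victim else 0) for s in samples}
                records.append(
                    VariantRecord(
                        contig=contig,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        qual=design.qual_model.draw(rng, true_call=False),
                        genotypes=genotypes,
                    )
                )
                break

    records.sort(key=lambda r: (r.contig, r.pos, r.ref, r.alt))
    return samples, records


def write_calls_vcf(
    path: str,
    truth: TruthTable,
    samples: Sequence[str],
    records: Sequence[VariantRecord],
) -> None:
    lengths = (
        {c: len(s) for c, s in truth.reference.items()} if truth.reference else None
    )
    write_vcf(path, samples, records, contig_lengths=lengths)


# ---------------------------------------------------------------------------
# Amplicon reads


@dataclass
class AmpliconReadSet:
    """Simulated reads over one marker plus the allele draws that made them."""

    reads: list[str]
    n_allele_a: int
    n_allele_b: int


def _mutate(rng: np.random.Generator, seq: str, per_base_error: float) -> str:
    if per_base_error <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hits = np.nonzero(rng.random(len(arr)) < per_base_error)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def simulate_amplicon_reads(
    allele_a: str,
    allele_b: str,
    true_genotype: str,
    depth: int,
    allele_bias: float = 0.5,
    per_base_error: float = 0.005,
    seed: int = 0,
) -> AmpliconReadSet:
    """Draw amplicon reads from the two allele sequences of a marker.

    For a heterozygous genotype each read comes from allele A with
    probability ``allele_bias``; homozygous genotypes draw from a single
    allele. Substitution errors are applied per base. The realized draw
    counts are returned alongside the reads as ground truth.
    """
    if depth < 0:
        raise InvalidDesignError("depth must be >= 0")
    if true_genotype not in ("het", "hom_a", "hom_b"):
        raise ValueError(f"unknown genotype {true_genotype!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA3]))
    if true_genotype == "het":
        n_a = int(rng.binomial(depth, allele_bias))
    elif true_genotype == "hom_a":
        n_a = depth
    else:
        n_a = 0
    n_b = depth - n_a
    reads = [_mutate(rng, allele_a, per_base_error) for _ in range(n_a)]
    reads += [_mutate(rng, allele_b, per_base_error) for _ in range(n_b)]
    order = rng.permutation(depth)
    reads = [reads[i] for i in order]
    return AmpliconReadSet(reads=reads, n_allele_a=n_a, n_allele_b=n_b)
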