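"""Variant record I/O, normalization, classification, and genotype matrices.

Variants live in memory as :class:`VariantRecord` objects carrying alt-allele
dosage per sample (0/1/2, ``None`` = missing call). Coordinates are 1-based at
the VCF boundary, as in the format; internal window arithmetic elsewhere in
the package is 0-based half-open and converts at I/O.

VCF reading and writing is delegated to :mod:`pysam`; multi-allelic rows are
split into one record per ALT allele before any downstream comparison, so
site identity is always the full ``(contig, pos, ref, alt)`` tuple.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import (
    ConsistencyError,
    MergeConflictError,
    ReferenceMismatchError,
    VcfParseError,
)

_ALLELE_RE = re.compile(r"^[ACGT]+$")

#: site key: (contig, 1-based position, REF, ALT)
SiteKey = tuple[str, int, str, str]


@dataclass
class VariantRecord:
    """One called variant after multi-allelic splitting.

    ``genotypes`` maps sample name to alt-allele dosage: 0 (hom-ref),
    1 (het), 2 (hom-alt) or ``None`` for a missing call ("./.").
    ``qual`` is the site-level variant quality (VCF QUAL); ``None`` when the
    file stores ".".
    """

    contig: str
    pos: int
    ref: str
    alt: str
    qual: float | None = None
    genotypes: dict[str, int | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not _ALLELE_RE.match(self.ref) or not _ALLELE_RE.match(self.alt):
            raise ValueError(
                f"alleles must be non-empty over ACGT: {self.ref!r}/{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValueError(f"REF and ALT are identical at {self.contig}:{self.pos}")

    @property
    def key(self) -> SiteKey:
        return (self.contig, self.pos, self.ref, self.alt)


def classify_variant(record: VariantRecord) -> str:
    """Classify a record as ``"SNV"``, ``"InDel"`` or ``"other"``.

    Single-base substitutions are SNVs; length-changing variants are InDels;
    equal-length multi-base substitutions fall into "other" and are excluded
    from SNV/InDel tallies.
    """
    if len(record.ref) == 1 and len(record.alt) == 1:
        return "SNV"
    if len(record.ref) != len(record.alt):
        return "InDel"
    return "other"


def indel_size(record: VariantRecord) -> int:
    """Absolute length difference between REF and ALT (0 for substitutions)."""
    return abs(len(record.ref) - len(record.alt))


def quality_filter(
    records: Iterable[VariantRecord], threshold: float = 100.0
) -> list[VariantRecord]:
    """Keep records with QUAL strictly greater than ``threshold``.

    Records with missing quality are dropped: a call without a confidence
    score cannot pass a confidence filter.
    """
    return [r for r in records if r.qual is not None and r.qual > threshold]


def normalize_variant(
    record: VariantRecord, reference: Mapping[str, str]
) -> VariantRecord:
    """Return the minimal, left-aligned representation of ``record``.

    Shared suffix bases are trimmed first, then shared prefix bases; InDels
    are then shifted left through repeat tracts as far as the reference
    allows, VCF-style (an anchor base is kept so neither allele is ever
    empty). The operation is idempotent and preserves the implied alternate
    haplotype.
    """
    if record.contig not in reference:
        raise ReferenceMismatchError(f"contig {record.contig!r} not in reference")
    seq = reference[record.contig]
    pos, ref, alt = record.pos, record.ref, record.alt
    if seq[pos - 1 : pos - 1 + len(ref)] != ref:
        raise ReferenceMismatchError(
            f"REF {ref!r} does not match reference at {record.contig}:{pos}"
        )

    changed = True
    while changed:
        changed = False
        # trim shared suffix
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        # left-align: if both alleles end in the same base we trimmed above,
        # so an indel can only shift when one allele is a prefix-anchored
        # expansion; shift while the last bases agree after prepending.
        while (
            (len(ref) == 1 or len(alt) == 1)
            and len(ref) != len(alt)
            and ref[-1] == alt[-1]
            and pos > 1
        ):
            prev = seq[pos - 2]
            ref, alt = prev + ref[:-1], prev + alt[:-1]
            pos -= 1
            changed = True
        # trim shared prefix
        while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
            changed = True

    return VariantRecord(
        contig=record.contig,
        pos=pos,
        ref=ref,
        alt=alt,
        qual=record.qual,
        genotypes=dict(record.genotypes),
    )


# ---------------------------------------------------------------------------
# VCF I/O


def _dosage_from_gt(gt: tuple | None, allele_index: int) -> int | None:
    if gt is None or all(a is None for a in gt):
        return None
    return sum(1 for a in gt if a == allele_index)


def read_vcf(path: str) -> tuple[list[str], list[VariantRecord]]:
    """Read a VCF file into sample names and split variant records.

    Multi-allelic rows become one record per ALT allele; per-sample dosage is
    the count of that ALT allele in the genotype. ALT alleles that are not
    plain sequence (symbolic, spanning-deletion ``*``) are skipped. Input
    order is preserved. A QUAL of "." parses to missing quality.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"{path}: cannot parse VCF header: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        n_header = str(vf.header).count("\n")
        records: list[VariantRecord] = []
        lineno = n_header
        try:
            for rec in vf.fetch() if vf.index is not None else vf:
                lineno += 1
                if rec.alts is None:
                    continue
                for i, alt in enumerate(rec.alts, start=1):
                    if not _ALLELE_RE.match(alt or "") or not _ALLELE_RE.match(
                        rec.ref or ""
                    ):
                        continue
                    genotypes = {
                        s: _dosage_from_gt(rec.samples[s].get("GT"), i)
                        for s in samples
                    }
                    records.append(
                        VariantRecord(
                            contig=rec.contig,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            qual=rec.qual,
                            genotypes=genotypes,
                        )
                    )
        except (OSError, ValueError) as exc:
            raise VcfParseError(f"{path}: line {lineno + 1}: {exc}") from exc
    return samples, records


_GT_BY_DOSAGE = {0: (0, 0), 1: (0, 1), 2: (1, 1), None: (None, None)}


def write_vcf(
    path: str,
    samples: Sequence[str],
    records: Sequence[VariantRecord],
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write records as a VCF 4.2 file with GT as the only FORMAT field."""
    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                     ("Type", "String"),
                                     ("Description", "Genotype")])
    contigs: dict[str, int] = {}
    for r in records:
        end = r.pos + len(r.ref) - 1
        contigs[r.contig] = max(contigs.get(r.contig, 0), end)
    if contig_lengths:
        for name, length in contig_lengths.items():
            contigs[name] = max(contigs.get(name, 0), length)
    for name in sorted(contigs):
        header.contigs.add(name, length=contigs[name])
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in records:
            rec = out.new_record(
                contig=r.contig, start=r.pos - 1, alleles=(r.ref, r.alt)
            )
            rec.qual = r.qual
            for s in samples:
                rec.samples[s]["GT"] = _GT_BY_DOSAGE[r.genotypes.get(s)]
                rec.samples[s].phased = False
            out.write(rec)


# ---------------------------------------------------------------------------
# Design table


def read_design_table(path: str) -> pd.DataFrame:
    """Read a sample→clone design table.

    TSV with columns ``sample_id``, ``clone_id`` and optionally ``cultivar``
    and ``exclude`` (truthy rows are dropped — the explicit mechanism for
    discarding e.g. an outlier replicate; exclusion is never automatic).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "clone_id"}
    if not required.issubset(df.columns):
        raise ConsistencyError(
            f"{path}: design table needs columns {sorted(required)}"
        )
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ConsistencyError(f"{path}: duplicate sample_id rows: {dups}")
    if "exclude" in df.columns:
        keep = ~df["exclude"].fillna("0").str.lower().isin(
            {"1", "true", "yes"}
        )
        df = df.loc[keep].drop(columns=["exclude"])
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Genotype matrix


class GenotypeMatrix:
    """Samples × variant-sites alt-dosage table with clone labels.

    The underlying frame has one row per site key (sorted by contig then
    position) and one float column per sample; cells are 0/1/2 dosage with
    NaN for missing calls.
    """

    def __init__(self, data: pd.DataFrame, sample_to_clone: Mapping[str, str]):
        missing = [s for s in data.columns if s not in sample_to_clone]
        if missing:
            raise ConsistencyError(f"samples without a clone mapping: {missing}")
        self.data = data
        self.sample_to_clone = dict(sample_to_clone)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def sites(self) -> list[SiteKey]:
        return list(self.data.index)

    @property
    def clones(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.sample_to_clone[s], None)
        return list(seen)

    def clone_samples(self, clone: str) -> list[str]:
        return [s for s in self.samples if self.sample_to_clone[s] == clone]

    def to_tsv(self, path: str) -> None:
        out = self.data.copy()
        out.index = [f"{c}:{p}:{r}:{a}" for c, p, r, a in out.index]
        out.index.name = "site"
        out.to_csv(path, sep="\t", na_rep="NA")


def build_matrix(
    call_sets: Sequence[tuple[Sequence[str], Sequence[VariantRecord]]],
    sample_to_clone: Mapping[str, str],
    absent_as: str = "missing",
) -> GenotypeMatrix:
    """Assemble per-sample or joint call sets into a :class:`GenotypeMatrix`.

    ``call_sets`` is a list of (sample names, records) blocks — one block for
    a jointly genotyped VCF, several for per-sample files. Sites are the
    union across blocks. A site/sample combination never seen in the sample's
    block is recorded as missing (``absent_as="missing"``, the right choice
    when merging per-sample files, where absence is uninformative) or as
    dosage 0 (``absent_as="hom_ref"``, the joint-genotyping convention).

    Raises :class:`MergeConflictError` when two blocks disagree on REF at the
    same (contig, pos, ALT).
    """
    if absent_as not in ("missing", "hom_ref"):
        raise ValueError("absent_as must be 'missing' or 'hom_ref'")
    all_samples: list[str] = []
    for samples, _ in call_sets:
        for s in samples:
            if s in all_samples:
                raise ConsistencyError(f"sample {s!r} appears in two call sets")
            all_samples.append(s)
    for s in all_samples:
        if s not in sample_to_clone:
            raise ConsistencyError(f"sample {s!r} missing from design table")

    ref_at: dict[tuple[str, int, str], str] = {}
    cells: dict[SiteKey, dict[str, float]] = {}
    for samples, records in call_sets:
        for r in records:
            probe = (r.contig, r.pos, r.alt)
            if ref_at.setdefault(probe, r.ref) != r.ref:
                raise MergeConflictError(
                    f"conflicting REF at {r.contig}:{r.pos} ALT {r.alt}: "
                    f"{ref_at[probe]!r} vs {r.ref!r}"
                )
            row = cells.setdefault(r.key, {})
            for s in samples:
                d = r.genotypes.get(s)
                row[s] = np.nan if d is None else float(d)

    keys = sorted(cells)
    fill = np.nan if absent_as == "missing" else 0.0
    data = pd.DataFrame(
        [[cells[k].get(s, fill) for s in all_samples] for k in keys],
        index=pd.Index(keys, tupleize_cols=False),
        columns=all_samples,
        dtype=float,
    )
    return GenotypeMatrix(data, {s: sample_to_clone[s] for s in all_samples})
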