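"""Diagnostic marker selection and marker-table handling.

A marker is a clone-exclusive heterozygous variant packaged with an amplicon
window suitable for PCR amplification and deep sequencing: SNV markers are
read out as the base at the variant site, InDel markers as the two amplicon
allele lengths. Marker tables follow the six-column schema
(cultivar, clone, marker id, variant type, scaffold/position, allele
lengths) used for validated grapevine clone panels.

Primer thermodynamics is deliberately out of scope: candidate windows are
exported (TSV/BED) for external primer design. The traditional visual
inspection of read pileups is replaced by an automatable proxy — a QUAL rank
plus a flank-cleanliness rule (no other variant inside the window).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .discriminate import CloneVariantSets
from .errors import ConsistencyError, MarkerTableError
from .variant_io import GenotypeMatrix, SiteKey, VariantRecord, classify_variant


def canonical_clone_id(clone_id: str) -> str:
    """Canonicalize a clone identifier for matching.

    Nursery catalogs write the same clone as e.g. "c46" or "46"; a leading
    'c'/'C' before an all-digit remainder is stripped so the two spellings
    compare equal.
    """
    s = str(clone_id).strip()
    if len(s) > 1 and s[0] in "cC" and s[1:].isdigit():
        return s[1:]
    return s


@dataclass
class MarkerDefinition:
    """One diagnostic locus.

    ``allele_lengths`` holds one amplicon length for an SNV marker and the
    two distinct allele lengths for an InDel marker. ``amplicon_window`` is
    0-based half-open on the contig, when known. Allele sequences are
    carried when the marker was derived from a reference (needed for
    sequence-level read matching and read simulation); fixture-loaded tables
    carry lengths only.
    """

    cultivar: str
    clone_id: str
    marker_id: str
    variant_type: str  # "SNV" | "InDel"
    contig: str
    position: int  # 1-based variant start
    allele_lengths: tuple[int, ...]
    snv_alleles: tuple[str, str] | None = None
    amplicon_window: tuple[int, int] | None = None
    allele_seq_a: str | None = None
    allele_seq_b: str | None = None
    qual: float | None = None

    def __post_init__(self) -> None:
        if self.variant_type == "SNV":
            if len(self.allele_lengths) != 1:
                raise MarkerTableError(
                    f"{self.marker_id}: SNV marker needs exactly one amplicon length"
                )
        elif self.variant_type == "InDel":
            if len(self.allele_lengths) != 2 or (
                self.allele_lengths[0] == self.allele_lengths[1]
            ):
                raise MarkerTableError(
                    f"{self.marker_id}: InDel marker needs two distinct allele lengths"
                )
        else:
            raise MarkerTableError(
                f"{self.marker_id}: unknown variant type {self.variant_type!r}"
            )

    @property
    def indel_size(self) -> int:
        if self.variant_type != "InDel":
            return 0
        return abs(self.allele_lengths[0] - self.allele_lengths[1])


@dataclass
class MarkerConstraints:
    """Amplicon feasibility window for candidate markers.

    Both allele lengths of every emitted candidate must fall within
    [min_len, max_len]; windows are sized to ``target_len`` (reference
    allele) and centered on the variant. ``min_edge_distance`` keeps the
    variant away from the amplicon ends so short reads still span it.
    """

    min_len: int = 141
    max_len: int = 487
    target_len: int = 200
    min_edge_distance: int = 30


# ---------------------------------------------------------------------------
# Candidate selection


def _apply_variant(window_seq: str, offset: int, ref: str, alt: str) -> str:
    return window_seq[:offset] + alt + window_seq[offset + len(ref):]


def select_candidates(
    exclusive: CloneVariantSets,
    matrix: GenotypeMatrix,
    records: Sequence[VariantRecord],
    reference: Mapping[str, str],
    constraints: MarkerConstraints | None = None,
    cultivar: str = "NA",
    other_variant_keys: Iterable[SiteKey] | None = None,
) -> tuple[list[MarkerDefinition], list[tuple[SiteKey, str]]]:
    """Turn clone-exclusive variants into amplicon marker candidates.

    Only heterozygous exclusive variants qualify (every focal replicate at
    dosage 1): a homozygous readout cannot be distinguished from a reference
    sample by allele balance. Each candidate's window contains the variant,
    lies fully on its contig, has no other known variant inside it, and both
    allele lengths respect the constraints. Candidates are ranked by QUAL
    descending (ties by contig/position) and numbered per clone.

    Returns (markers, skipped) where ``skipped`` pairs each rejected site
    with a reason ("not heterozygous", "edge", "length", "flank").
    """
    constraints = constraints or MarkerConstraints()
    by_key = {r.key: r for r in records}
    all_keys = set(by_key)
    if other_variant_keys is not None:
        all_keys |= set(other_variant_keys)

    markers: list[MarkerDefinition] = []
    skipped: list[tuple[SiteKey, str]] = []
    half = constraints.target_len // 2

    for clone in matrix.clones:
        focal = matrix.clone_samples(clone)
        ranked = sorted(
            exclusive.exclusive.get(clone, ()),
            key=lambda k: (
                -(by_key[k].qual if k in by_key and by_key[k].qual is not None else 0.0),
                k[0],
                k[1],
            ),
        )
        accepted: list[MarkerDefinition] = []
        for key in ranked:
            contig, pos, ref, alt = key
            dosages = matrix.data.loc[[key], focal].iloc[0]
            if not (dosages == 1).all():
                skipped.append((key, "not heterozygous"))
                continue
            seq = reference.get(contig)
            if seq is None:
                skipped.append((key, "edge"))
                continue
            start0 = pos - 1 - half  # window start, 0-based
            end0 = start0 + constraints.target_len
            if start0 < 0 or end0 > len(seq):
                skipped.append((key, "edge"))
                continue
            var_start0 = pos - 1
            var_end0 = var_start0 + len(ref)
            if (
                var_start0 - start0 < constraints.min_edge_distance
                or end0 - var_end0 < constraints.min_edge_distance
            ):
                skipped.append((key, "edge"))
                continue
            len_ref_allele = constraints.target_len
            len_alt_allele = constraints.target_len + (len(alt) - len(ref))
            if not (
                constraints.min_len <= len_ref_allele <= constraints.max_len
                and constraints.min_len <= len_alt_allele <= constraints.max_len
            ):
                skipped.append((key, "length"))
                continue
            inside = any(
                k != key and k[0] == contig and start0 < k[1] - 1 < end0
                for k in all_keys
            )
            if inside:
                skipped.append((key, "flank"))
                continue
            window_seq = seq[start0:end0]
            alt_seq = _apply_variant(window_seq, var_start0 - start0, ref, alt)
            kind = classify_variant(by_key[key]) if key in by_key else (
                "SNV" if len(ref) == len(alt) == 1 else "InDel"
            )
            if kind == "other":
                skipped.append((key, "length"))
                continue
            marker = MarkerDefinition(
                cultivar=cultivar,
                clone_id=str(clone),
                marker_id=f"{clone}_{len(accepted) + 1}",
                variant_type=kind,
                contig=contig,
                position=pos,
                allele_lengths=(
                    (len_ref_allele,)
                    if kind == "SNV"
                    else (len_ref_allele, len_alt_allele)
                ),
                snv_alleles=(ref, alt) if kind == "SNV" else None,
                amplicon_window=(start0, end0),
                allele_seq_a=window_seq,
                allele_seq_b=alt_seq,
                qual=by_key[key].qual if key in by_key else None,
            )
            accepted.append(marker)
        markers.extend(accepted)
    return markers, skipped


# ---------------------------------------------------------------------------
# Table 5-schema I/O

_TABLE_COLUMNS = [
    "Cultivar",
    "Clone ID",
    "Marker ID",
    "DNA variant",
    "Scaffold/start position (bp)",
    "Allele length (bp)",
]

_SNV_RE = re.compile(r"^SNV\s+([ACGT])/([ACGT])$")


def _parse_int(text: str) -> int:
    return int(str(text).replace(",", "").strip())


def load_marker_table(path: str) -> list[MarkerDefinition]:
    """Read a marker table in the six-column validated-panel schema.

    The "DNA variant" field is either ``InDel`` or ``SNV X/Y``; the locus
    field is ``scaffold/position`` with tolerated thousands separators; the
    allele-length field holds two slash-separated lengths for InDels and a
    single length for SNVs.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise MarkerTableError(f"{path}: missing columns {missing}")
    markers: list[MarkerDefinition] = []
    for _, row in df.iterrows():
        marker_id = str(row["Marker ID"]).strip()
        variant = str(row["DNA variant"]).strip()
        try:
            locus = str(row["Scaffold/start position (bp)"]).strip()
            contig, _, pos_text = locus.rpartition("/")
            if not contig:
                raise ValueError(f"locus field {locus!r} lacks a '/'")
            lengths_text = str(row["Allele length (bp)"]).strip()
            if variant == "InDel":
                parts = [
                    _parse_int(p) for p in lengths_text.split("/")
                ]
                if len(parts) != 2:
                    raise ValueError(f"InDel needs two lengths, got {lengths_text!r}")
                kind, alleles, lengths = "InDel", None, tuple(parts)
            else:
                m = _SNV_RE.match(variant)
                if not m:
                    raise ValueError(f"unrecognized DNA variant {variant!r}")
                kind = "SNV"
                alleles = (m.group(1), m.group(2))
                lengths = (_parse_int(lengths_text),)
            markers.append(
                MarkerDefinition(
                    cultivar=str(row["Cultivar"]).strip(),
                    clone_id=str(row["Clone ID"]).strip(),
                    marker_id=marker_id,
                    variant_type=kind,
                    contig=contig,
                    position=_parse_int(pos_text),
                    allele_lengths=lengths,
                    snv_alleles=alleles,
                )
            )
        except (ValueError, MarkerTableError) as exc:
            raise MarkerTableError(f"marker {marker_id!r}: {exc}") from exc
    return markers


def write_marker_table(markers: Sequence[MarkerDefinition], path: str) -> None:
    """Write markers in the same six-column schema ``load_marker_table`` reads."""
    rows = []
    for m in markers:
        variant = (
            "InDel" if m.variant_type == "InDel" else f"SNV {m.snv_alleles[0]}/{m.snv_alleles[1]}"
        )
        lengths = "/".join(str(x) for x in m.allele_lengths)
        rows.append(
            (m.cultivar, m.clone_id, m.marker_id, variant,
             f"{m.contig}/{m.position}", lengths)
        )
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_candidates_bed(markers: Sequence[MarkerDefinition], path: str) -> None:
    """Export candidate amplicon windows as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for m in markers:
            if m.amplicon_window is None:
                continue
            start, end = m.amplicon_window
            fh.write(f"{m.contig}\t{start}\t{end}\t{m.marker_id}\n")


# ---------------------------------------------------------------------------
# Panel summary


def _truncate1(x: float) -> float:
    return int(x * 10) / 10.0


@dataclass
class PanelSummary:
    """Direct tallies over a marker panel against an evaluated-clone roster."""

    n_markers: int
    n_snv: int
    n_indel: int
    by_cultivar: dict[str, int]
    by_clone: dict[tuple[str, str], int]
    n_clones_with_markers: int
    n_evaluated_clones: int
    clone_coverage_pct: float  # truncated to one decimal
    min_allele_length: int | None
    max_allele_length: int | None
    mean_allele_length: float | None
    mean_indel_size: float | None
    mean_markers_per_covered_clone: float | None
    mean_markers_per_covered_clone_rounded: int | None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("total_markers", self.n_markers),
            ("snv_markers", self.n_snv),
            ("indel_markers", self.n_indel),
            ("clones_with_markers", self.n_clones_with_markers),
            ("evaluated_clones", self.n_evaluated_clones),
            ("clone_coverage_pct", self.clone_coverage_pct),
            ("min_allele_length_bp", self.min_allele_length),
            ("max_allele_length_bp", self.max_allele_length),
            ("mean_allele_length_bp", self.mean_allele_length),
            ("mean_indel_size_bp", self.mean_indel_size),
        ]
        rows += [(f"markers_{c}", n) for c, n in sorted(self.by_cultivar.items())]
        df = pd.DataFrame({"statistic": [k for k, _ in rows]})
        df["value"] = pd.array([v for _, v in rows], dtype=object)
        return df


def load_roster(path: str) -> pd.DataFrame:
    """Read an evaluated-clone roster: TSV with cultivar, clone_id and
    optionally n_replicates."""
    df = pd.read_csv(path, sep="\t", dtype={"cultivar": str, "clone_id": str})
    if not {"cultivar", "clone_id"}.issubset(df.columns):
        raise ConsistencyError(f"{path}: roster needs cultivar and clone_id columns")
    return df


def summarize_panel(
    markers: Sequence[MarkerDefinition], roster: pd.DataFrame
) -> PanelSummary:
    """Tally a marker panel against the roster of evaluated clones.

    Clone coverage is 100 × clones-with-≥1-marker / roster size, truncated
    (not rounded) to one decimal. The headline markers-per-clone figure is
    the mean over covered clones, reported both unrounded and rounded to the
    nearest integer. Raises :class:`ConsistencyError` for a marker whose
    clone is not on the roster.
    """
    roster_keys = {
        (str(c), canonical_clone_id(k))
        for c, k in zip(roster["cultivar"], roster["clone_id"])
    }
    by_cultivar: dict[str, int] = {}
    by_clone: dict[tuple[str, str], int] = {}
    n_snv = n_indel = 0
    lengths: list[int] = []
    indel_sizes: list[int] = []
    for m in markers:
        key = (m.cultivar, canonical_clone_id(m.clone_id))
        if key not in roster_keys:
            raise ConsistencyError(
                f"marker {m.marker_id}: clone {m.cultivar}/{m.clone_id} "
                "absent from the evaluated roster"
            )
        by_cultivar[m.cultivar] = by_cultivar.get(m.cultivar, 0) + 1
        by_clone[key] = by_clone.get(key, 0) + 1
        if m.variant_type == "SNV":
            n_snv += 1
        else:
            n_indel += 1
            indel_sizes.append(m.indel_size)
        lengths.extend(m.allele_lengths)
    n_covered = len(by_clone)
    n_roster = len(roster_keys)
    coverage = _truncate1(100.0 * n_covered / n_roster) if n_roster else 0.0
    per_clone = (len(markers) / n_covered) if n_covered else None
    return PanelSummary(
        n_markers=len(markers),
        n_snv=n_snv,
        n_indel=n_indel,
        by_cultivar=by_cultivar,
        by_clone=by_clone,
        n_clones_with_markers=n_covered,
        n_evaluated_clones=n_roster,
        clone_coverage_pct=coverage,
        min_allele_length=min(lengths) if lengths else None,
        max_allele_length=max(lengths) if lengths else None,
        mean_allele_length=(sum(lengths) / len(lengths)) if lengths else None,
        mean_indel_size=(sum(indel_sizes) / len(indel_sizes)) if indel_sizes else None,
        mean_markers_per_covered_clone=per_clone,
        mean_markers_per_covered_clone_rounded=(
            round(per_clone) if per_clone is not None else None
        ),
    )


# ---------------------------------------------------------------------------
# Packaged fixtures


def packaged_marker_table() -> list[MarkerDefinition]:
    """The packaged 46-row validated grapevine marker panel."""
    from importlib.resources import files

    return load_marker_table(str(files("clonemarker.data") / "table5_markers.tsv"))


def packaged_design_table() -> pd.DataFrame:
    """The packaged 18-clone evaluated roster with replicate counts."""
    from importlib.resources import files

    return load_roster(str(files("clonemarker.data") / "table1_design.tsv"))
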