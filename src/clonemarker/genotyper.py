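"""Amplicon read counting, genotype calling, and clone identification.

The decision procedure mirrors how a validated clone panel is used in
practice: every sample is sequenced over every marker of its cultivar's
panel; reads are assigned to the marker's two alleles; allele counts become
genotype calls; and a sample is identified as a clone when it shows the
expected heterozygous call at one or more of that clone's markers and at no
other clone's markers — one positive marker suffices, and conflicting
evidence is reported rather than tie-broken.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import edlib
import pandas as pd

from .errors import ConfigurationError, ConsistencyError
from .panel import MarkerDefinition


@dataclass
class AlleleCounts:
    """Per-marker read tallies for one sample."""

    marker_id: str
    count_a: int
    count_b: int
    count_unassigned: int = 0

    def __post_init__(self) -> None:
        if min(self.count_a, self.count_b, self.count_unassigned) < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def total_depth(self) -> int:
        return self.count_a + self.count_b + self.count_unassigned

    @property
    def assigned_depth(self) -> int:
        return self.count_a + self.count_b

    @property
    def minor_fraction(self) -> float | None:
        if self.assigned_depth == 0:
            return None
        return min(self.count_a, self.count_b) / self.assigned_depth

    @property
    def allele_fraction(self) -> float | None:
        """Fraction of assigned reads supporting allele B (the alt allele)."""
        if self.assigned_depth == 0:
            return None
        return self.count_b / self.assigned_depth


class GenotypeCall(str, Enum):
    HOM_A = "hom_a"
    HET = "het"
    HOM_B = "hom_b"
    NO_CALL = "no_call"


# ---------------------------------------------------------------------------
# Read → allele assignment


def _edit_distance(read: str, allele: str) -> int:
    mode = "HW" if len(read) < len(allele) else "NW"
    return edlib.align(read, allele, mode=mode)["editDistance"]


def count_alleles(
    reads: Iterable[str],
    marker: MarkerDefinition,
    max_mismatches: int = 4,
) -> AlleleCounts:
    """Assign each read to the marker allele it matches best.

    With allele sequences available, assignment is by edit distance (ties or
    distances above ``max_mismatches`` go to unassigned). A fixture-style
    InDel marker that carries only its two allele lengths falls back to
    length matching with the same tolerance. An SNV marker without allele
    sequences cannot discriminate reads and raises
    :class:`ConfigurationError`.
    """
    has_seqs = marker.allele_seq_a is not None and marker.allele_seq_b is not None
    if not has_seqs and marker.variant_type == "SNV":
        raise ConfigurationError(
            f"marker {marker.marker_id}: SNV matching needs allele sequences"
        )
    n_a = n_b = n_un = 0
    if has_seqs:
        for read in reads:
            d_a = _edit_distance(read, marker.allele_seq_a)
            d_b = _edit_distance(read, marker.allele_seq_b)
            if d_a == d_b or min(d_a, d_b) > max_mismatches:
                n_un += 1
            elif d_a < d_b:
                n_a += 1
            else:
                n_b += 1
    else:
        len_a, len_b = marker.allele_lengths
        for read in reads:
            d_a = abs(len(read) - len_a)
            d_b = abs(len(read) - len_b)
            if d_a == d_b or min(d_a, d_b) > max_mismatches:
                n_un += 1
            elif d_a < d_b:
                n_a += 1
            else:
                n_b += 1
    return AlleleCounts(
        marker_id=marker.marker_id, count_a=n_a, count_b=n_b, count_unassigned=n_un
    )


# ---------------------------------------------------------------------------
# Counts → genotype


@dataclass
class GenotypeThresholds:
    """Allele-balance thresholds with an explicit ambiguous zone.

    ``min_depth`` is the minimum assigned depth for any call; minor-allele
    fractions at or above ``min_minor_fraction`` call heterozygous; at or
    below ``max_minor_for_hom`` call homozygous for the major allele;
    fractions between the two are a no-call rather than a guess.
    """

    min_depth: int = 20
    min_minor_fraction: float = 0.20
    max_minor_for_hom: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.max_minor_for_hom < self.min_minor_fraction <= 0.5:
            raise ConfigurationError(
                "need 0 <= max_minor_for_hom < min_minor_fraction <= 0.5"
            )


def call_genotype(
    counts: AlleleCounts, thresholds: GenotypeThresholds | None = None
) -> GenotypeCall:
    """Call a genotype from allele counts; symmetric in the two alleles."""
    t = thresholds or GenotypeThresholds()
    depth = counts.assigned_depth
    if depth < t.min_depth:
        return GenotypeCall.NO_CALL
    minor = counts.minor_fraction
    if minor >= t.min_minor_fraction:
        return GenotypeCall.HET
    if minor <= t.max_minor_for_hom:
        return GenotypeCall.HOM_A if counts.count_a > counts.count_b else GenotypeCall.HOM_B
    return GenotypeCall.NO_CALL


# ---------------------------------------------------------------------------
# Calls → clone identification


@dataclass
class MarkerEvidence:
    marker_id: str
    clone_id: str
    call: GenotypeCall
    allele_fraction: float | None


@dataclass
class IdentificationResult:
    """Per-sample clone assignment with supporting evidence.

    ``assigned_clone`` is a clone name only when positive markers point to
    exactly one clone; otherwise "unassigned" (no positives) or "ambiguous"
    (positives for two or more clones, all listed in ``conflicts``).
    """

    sample_id: str
    assigned_clone: str
    evidence: list[MarkerEvidence] = field(default_factory=list)
    conflicts: list[MarkerEvidence] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "assigned_clone": self.assigned_clone,
            "n_positive_markers": len(self.evidence),
            "evidence": [
                {
                    "marker_id": e.marker_id,
                    "clone_id": e.clone_id,
                    "call": e.call.value,
                    "allele_fraction": e.allele_fraction,
                }
                for e in self.evidence
            ],
            "conflicts": [
                {
                    "marker_id": e.marker_id,
                    "clone_id": e.clone_id,
                    "call": e.call.value,
                    "allele_fraction": e.allele_fraction,
                }
                for e in self.conflicts
            ],
        }


def identify_clone(
    sample_id: str,
    counts: Sequence[AlleleCounts],
    panel: Sequence[MarkerDefinition],
    thresholds: GenotypeThresholds | None = None,
) -> IdentificationResult:
    """Assign a sample to a clone from its per-marker allele counts.

    A marker is *positive* when the sample's call is heterozygous — the
    expected genotype of every validated clonal marker, since a somatic
    mutation appears on one haplotype of an otherwise shared genome.
    Positives for exactly one clone assign that clone; one marker suffices.
    """
    by_id = {m.marker_id: m for m in panel}
    positives: list[MarkerEvidence] = []
    for c in counts:
        marker = by_id.get(c.marker_id)
        if marker is None:
            raise ConsistencyError(
                f"sample {sample_id}: counts reference unknown marker {c.marker_id!r}"
            )
        call = call_genotype(c, thresholds)
        if call is GenotypeCall.HET:
            positives.append(
                MarkerEvidence(
                    marker_id=c.marker_id,
                    clone_id=marker.clone_id,
                    call=call,
                    allele_fraction=c.allele_fraction,
                )
            )
    clones = sorted({e.clone_id for e in positives})
    if not clones:
        return IdentificationResult(sample_id=sample_id, assigned_clone="unassigned")
    if len(clones) == 1:
        return IdentificationResult(
            sample_id=sample_id, assigned_clone=clones[0], evidence=positives
        )
    counts_per_clone = {c: sum(e.clone_id == c for e in positives) for c in clones}
    top = max(clones, key=lambda c: counts_per_clone[c])
    return IdentificationResult(
        sample_id=sample_id,
        assigned_clone="ambiguous",
        evidence=[e for e in positives if e.clone_id == top],
        conflicts=[e for e in positives if e.clone_id != top],
    )


# ---------------------------------------------------------------------------
# Counts-table I/O and reports


def read_counts_table(path: str) -> dict[str, list[AlleleCounts]]:
    """Read a per-sample, per-marker allele-count TSV.

    Columns: sample_id, marker_id, count_a, count_b and optionally
    unassigned. Duplicate (sample, marker) rows are a consistency error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "marker_id": str})
    required = {"sample_id", "marker_id", "count_a", "count_b"}
    if not required.issubset(df.columns):
        raise ConsistencyError(f"{path}: counts table needs columns {sorted(required)}")
    dup = df.duplicated(subset=["sample_id", "marker_id"])
    if dup.any():
        rows = df.loc[dup, ["sample_id", "marker_id"]].to_records(index=False)
        raise ConsistencyError(f"{path}: duplicate sample/marker rows: {list(rows)}")
    out: dict[str, list[AlleleCounts]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["sample_id"]), []).append(
            AlleleCounts(
                marker_id=str(row["marker_id"]),
                count_a=int(row["count_a"]),
                count_b=int(row["count_b"]),
                count_unassigned=int(row.get("unassigned", 0) or 0),
            )
        )
    return out


def write_counts_table(
    counts: Mapping[str, Sequence[AlleleCounts]], path: str
) -> None:
    rows = [
        (s, c.marker_id, c.count_a, c.count_b, c.count_unassigned)
        for s, cs in counts.items()
        for c in cs
    ]
    pd.DataFrame(
        rows, columns=["sample_id", "marker_id", "count_a", "count_b", "unassigned"]
    ).to_csv(path, sep="\t", index=False)


def write_report(
    results: Sequence[IdentificationResult], tsv_path: str, json_path: str | None = None
) -> None:
    """Write the identification report as TSV (one row per sample) and
    optionally as structured JSON."""
    rows = []
    for r in results:
        rows.append(
            (
                r.sample_id,
                r.assigned_clone,
                len(r.evidence),
                ";".join(e.marker_id for e in r.evidence),
                ";".join(e.marker_id for e in r.conflicts),
            )
        )
    pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "assigned_clone",
            "n_positive_markers",
            "evidence",
            "conflicts",
        ],
    ).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump([r.to_dict() for r in results], fh, indent=2)
            fh.write("\n")
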