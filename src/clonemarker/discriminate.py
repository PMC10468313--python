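"""Replicate-concordance filtering, clone-exclusive variant extraction,
summary statistics and PCA over a genotype matrix.

The central definitions, applied to a cohort of vegetatively propagated
clones with biological replicates:

* a variant is *consistent* for clone ``c`` when every replicate of ``c``
  carries it (alt dosage >= 1; a missing call counts as not-present);
* a variant is *exclusive* to clone ``c`` when it is consistent for ``c``
  and absent from every sample of every other clone.

Exclusive variants are the somatic mutations private to one clonal lineage —
the raw material for diagnostic markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import InvalidDesignError
from .variant_io import GenotypeMatrix, SiteKey, VariantRecord, classify_variant

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class CloneVariantSets:
    """Per-clone consistent and exclusive site-key sets.

    Invariants: ``exclusive[c] ⊆ consistent[c]`` and exclusive sets are
    pairwise disjoint.
    """

    consistent: dict[str, set[SiteKey]]
    exclusive: dict[str, set[SiteKey]]


def replicate_consistent(matrix: GenotypeMatrix) -> dict[str, set[SiteKey]]:
    """Sites carried by every replicate of each clone.

    A single-replicate clone's consistent set is simply that sample's
    presence set — replication tightens the filter but is not required.
    """
    out: dict[str, set[SiteKey]] = {}
    for clone in matrix.clones:
        cols = matrix.clone_samples(clone)
        if not cols:
            raise InvalidDesignError(f"clone {clone!r} has no samples")
        sub = matrix.data[cols]
        present_all = (sub >= 1).all(axis=1)  # NaN >= 1 is False: missing = absent
        out[clone] = set(sub.index[present_all])
    return out


def clone_exclusive(
    matrix: GenotypeMatrix, strict_missing: bool = False
) -> CloneVariantSets:
    """Extract variants present in all replicates of one clone and absent
    from every other sample.

    ``strict_missing=False`` (default) treats a missing call in a non-focal
    sample as absence, matching joint-genotyping output where every sample is
    genotyped at every emitted site. ``strict_missing=True`` treats missing
    as potentially-present and drops the site — the conservative choice when
    merging independently called per-sample files.
    """
    consistent = replicate_consistent(matrix)
    exclusive: dict[str, set[SiteKey]] = {}
    data = matrix.data
    for clone in matrix.clones:
        other_cols = [s for s in matrix.samples if matrix.sample_to_clone[s] != clone]
        sub = data[other_cols]
        if strict_missing:
            clean = ((sub == 0).all(axis=1)) & (~sub.isna().any(axis=1))
        else:
            clean = ((sub == 0) | sub.isna()).all(axis=1)
        clean_sites = set(sub.index[clean])
        exclusive[clone] = consistent[clone] & clean_sites
    return CloneVariantSets(consistent=consistent, exclusive=exclusive)


# ---------------------------------------------------------------------------
# Summary statistics


@dataclass
class SummaryStats:
    """Cultivar-level variant summary in the conventional reporting units."""

    n_snv: int
    n_indel: int
    n_other: int
    het_fraction_pct: float | None  # 100 * het / called; None if nothing called
    snv_per_kbp: float
    indel_per_kbp: float
    tstv_ratio: float | None  # None when no transversions were observed
    window_densities: pd.DataFrame = field(repr=False, default=None)


def is_transition(record: VariantRecord) -> bool:
    return (record.ref, record.alt) in TRANSITIONS


def _record_called_het(record: VariantRecord, sample: str | None) -> tuple[bool, bool]:
    """(called, het) status of a record, per sample or by consensus."""
    if sample is not None:
        d = record.genotypes.get(sample)
        return (d is not None and d >= 1, d == 1)
    dosages = [d for d in record.genotypes.values() if d is not None and d >= 1]
    if not dosages:
        # no genotype columns at all: treat the record itself as one call
        return (not record.genotypes, False) if not record.genotypes else (False, False)
    return True, max(dosages) == 1


def summarize(
    records: Iterable[VariantRecord],
    genome_length: int,
    window: int = 100_000,
    sample: str | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> SummaryStats:
    """Tally SNV/InDel counts, heterozygous fraction, per-kbp densities,
    transition/transversion ratio, and windowed densities.

    When ``sample`` is given, "called" and "het" refer to that sample's
    genotype; otherwise a record counts as called when any sample carries the
    alt allele and het when the maximum observed dosage is 1. Window
    densities are reported in 0-based half-open coordinates; the final window
    of a contig may be partial.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    recs = list(records)
    n_snv = n_indel = n_other = 0
    n_called = n_het = 0
    n_ts = n_tv = 0
    win_counts: dict[tuple[str, int], list[int]] = {}
    for r in recs:
        kind = classify_variant(r)
        called, het = _record_called_het(r, sample)
        if sample is not None and not called:
            continue
        if kind == "SNV":
            n_snv += 1
            if is_transition(r):
                n_ts += 1
            else:
                n_tv += 1
        elif kind == "InDel":
            n_indel += 1
        else:
            n_other += 1
        if called:
            n_called += 1
            n_het += int(het)
        w = (r.pos - 1) // window
        key = (r.contig, w)
        win_counts.setdefault(key, [0, 0])[0 if kind == "SNV" else 1] += int(
            kind != "other"
        )

    rows = []
    for (contig, w), (snv, ind) in sorted(win_counts.items()):
        start = w * window
        end = start + window
        if contig_lengths and contig in contig_lengths:
            end = min(end, contig_lengths[contig])
        rows.append((contig, start, end, snv, ind))
    dens = pd.DataFrame(
        rows, columns=["contig", "start", "end", "snv_count", "indel_count"]
    )
    return SummaryStats(
        n_snv=n_snv,
        n_indel=n_indel,
        n_other=n_other,
        het_fraction_pct=(100.0 * n_het / n_called) if n_called else None,
        snv_per_kbp=n_snv * 1_000.0 / genome_length,
        indel_per_kbp=n_indel * 1_000.0 / genome_length,
        tstv_ratio=(n_ts / n_tv) if n_tv else None,
        window_densities=dens,
    )


# ---------------------------------------------------------------------------
# PCA


def pca_clones(
    matrix: GenotypeMatrix,
    sites: Sequence[SiteKey] | None = None,
    n_components: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the samples over alt-dosage genotypes.

    Dosage is encoded 0/1/2 with missing cells imputed to the site mean and
    no variance scaling; the decomposition is a plain SVD of the centered
    matrix. ``sites`` restricts the analysis (typically to the union of
    replicate-consistent sets). Component signs are canonicalized so the
    largest-magnitude coordinate on each axis is positive, making the output
    deterministic. Returns (coordinates indexed by sample, explained-variance
    fractions).
    """
    if len(matrix.samples) < 2:
        raise InvalidDesignError("PCA needs at least 2 samples")
    data = matrix.data if sites is None else matrix.data.loc[list(sites)]
    X = data.to_numpy(dtype=float).T  # samples × sites
    if X.shape[1] == 0:
        coords = pd.DataFrame(
            np.zeros((X.shape[0], n_components)),
            index=matrix.samples,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        )
        return coords, np.zeros(n_components)
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]

    k = min(n_components, X.shape[0], X.shape[1])
    if np.allclose(X, X[0]):  # identical samples: zero variance everywhere
        coords = pd.DataFrame(
            np.zeros((X.shape[0], n_components)),
            index=matrix.samples,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        )
        return coords, np.zeros(n_components)
    pca = PCA(n_components=k, svd_solver="full")
    Y = pca.fit_transform(X)
    for j in range(Y.shape[1]):  # sign canonicalization
        i = int(np.argmax(np.abs(Y[:, j])))
        if Y[i, j] < 0:
            Y[:, j] = -Y[:, j]
    if Y.shape[1] < n_components:
        Y = np.pad(Y, ((0, 0), (0, n_components - Y.shape[1])))
    ratios = np.zeros(n_components)
    ratios[: len(pca.explained_variance_ratio_)] = pca.explained_variance_ratio_
    coords = pd.DataFrame(
        Y[:, :n_components],
        index=matrix.samples,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return coords, ratios
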