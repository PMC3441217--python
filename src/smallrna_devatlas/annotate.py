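"""Hierarchical annotation of unique tags and TPM quantification.

Each tag is tested against reference classes in a fixed priority order and
assigned to the first class that matches; matching is exact substring search
(no mismatches), so mismatched tags fall through the whole cascade and are
later examined by the editing detector.

Priority: miRNA (exact substring of a precursor, or an isomiR-window match to
a mature, including a short non-templated 3' tail) > rRNA > tRNA > snRNA >
snoRNA > scRNA > srpRNA > piRNA > repeat > exon > intron > genome_only (exact
substring of the genome, either strand) > unannotated.  Within a class,
references are scanned in file order and the first hit wins.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .io import CLASS_ORDER, NON_MIRNA_CLASSES, ReferenceSet, UniqueTag
from .isomir import DEFAULT_MAX_NTA, DEFAULT_OFFSET_WINDOW, classify_isomir

__all__ = [
    "AnnotationRecord",
    "annotate_tags",
    "compute_tpm",
    "class_abundance_profile",
    "mirna_expression_matrix",
    "ALL_CLASSES",
]

ALL_CLASSES = tuple(CLASS_ORDER) + ("genome_only", "unannotated")


@dataclass(frozen=True)
class AnnotationRecord:
    tag: UniqueTag
    assigned_class: str
    matched_reference_id: str | None
    match_offset: int | None


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


class _ClassIndex:
    """Concatenated-library substring index preserving file order.

    References are joined with ``#`` separators so a single ``str.find`` scans
    the whole class in file order; the hit position maps back to the reference
    id and the offset within it.
    """

    def __init__(self, library: dict[str, str]):
        self.ids: list[str] = []
        self.starts: list[int] = []
        parts = []
        pos = 0
        for rid, seq in library.items():
            self.ids.append(rid)
            self.starts.append(pos)
            parts.append(seq)
            pos += len(seq) + 1
        self.text = "#".join(parts)

    def find(self, seq: str) -> tuple[str, int] | None:
        i = self.text.find(seq)
        if i == -1:
            return None
        # locate the containing reference (bisect over starts)
        import bisect

        k = bisect.bisect_right(self.starts, i) - 1
        return self.ids[k], i - self.starts[k]


def annotate_tags(
    tags: list[UniqueTag],
    refset: ReferenceSet,
    isomir_window: int = DEFAULT_OFFSET_WINDOW,
    max_nta: int = DEFAULT_MAX_NTA,
) -> list[AnnotationRecord]:
    """Assign every tag to exactly one class via the priority cascade."""
    prec_index = _ClassIndex(refset.precursors)
    class_indexes = {
        cls: _ClassIndex(lib)
        for cls, lib in refset.class_libraries.items()
        if lib
    }
    genome_fwd = _ClassIndex(refset.genome)
    genome_rev = _ClassIndex(
        {cid: _revcomp(seq) for cid, seq in refset.genome.items()}
    )

    out: list[AnnotationRecord] = []
    for tag in tags:
        seq = tag.sequence
        hit = prec_index.find(seq)
        if hit is not None:
            out.append(AnnotationRecord(tag, "miRNA", hit[0], hit[1]))
            continue
        iso = classify_isomir(tag, refset, window=isomir_window, max_nta=max_nta)
        if iso is not None:
            out.append(AnnotationRecord(tag, "miRNA", iso.mature_id, None))
            continue
        assigned = False
        for cls in NON_MIRNA_CLASSES:
            idx = class_indexes.get(cls)
            if idx is None:
                continue
            hit = idx.find(seq)
            if hit is not None:
                out.append(AnnotationRecord(tag, cls, hit[0], hit[1]))
                assigned = True
                break
        if assigned:
            continue
        hit = genome_fwd.find(seq) or genome_rev.find(seq)
        if hit is not None:
            out.append(AnnotationRecord(tag, "genome_only", None, None))
        else:
            out.append(AnnotationRecord(tag, "unannotated", None, None))
    return out


def compute_tpm(tags: list[UniqueTag]) -> list[UniqueTag]:
    """Normalize tag counts to transcripts per million of the sample total.

    ``tpm = count_mean / sum(count_mean) * 1e6``; the TPM column sums to 1e6.
    """
    total = sum(t.count_mean for t in tags)
    if total <= 0:
        raise ValueError("cannot compute TPM: sample has zero total count")
    return [replace(t, tpm=t.count_mean / total * 1e6) for t in tags]


def class_abundance_profile(
    records_per_stage: dict[str, list[AnnotationRecord]],
    include_unmatched: bool = True,
) -> pd.DataFrame:
    """Class x stage TPM matrix (columns sum to 1e6 when all classes included)."""
    classes = list(ALL_CLASSES if include_unmatched else CLASS_ORDER)
    data = {}
    for stage, records in records_per_stage.items():
        col = dict.fromkeys(classes, 0.0)
        for r in records:
            if r.assigned_class in col:
                col[r.assigned_class] += r.tag.tpm
        data[stage] = col
    return pd.DataFrame(data).reindex(classes)


def mirna_expression_matrix(
    records_per_stage: dict[str, list[AnnotationRecord]],
    refset: ReferenceSet,
    aggregate_isomirs: bool = False,
    isomir_window: int = DEFAULT_OFFSET_WINDOW,
    max_nta: int = DEFAULT_MAX_NTA,
) -> pd.DataFrame:
    """Mature-miRNA x stage TPM matrix.

    By default a mature's TPM is the canonical tag only (tag sequence equal to
    the mature).  With ``aggregate_isomirs=True`` the TPM of every tag that
    classifies as one of the 8 isomiR categories of that mature is added.
    Matures never detected in any stage are omitted; missing cells are 0.
    """
    seq_to_mid = {seq: mid for mid, seq in refset.mature.items()}
    data: dict[str, dict[str, float]] = {}
    for stage, records in records_per_stage.items():
        col: dict[str, float] = {}
        for r in records:
            if r.assigned_class != "miRNA":
                continue
            mid = seq_to_mid.get(r.tag.sequence)
            if mid is not None:
                col[mid] = col.get(mid, 0.0) + r.tag.tpm
            elif aggregate_isomirs:
                iso = classify_isomir(
                    r.tag, refset, window=isomir_window, max_nta=max_nta
                )
                if iso is not None and iso.category != "canonical":
                    col[iso.mature_id] = col.get(iso.mature_id, 0.0) + r.tag.tpm
        data[stage] = col
    df = pd.DataFrame(data).fillna(0.0)
    return df.sort_index()
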