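"""Reading, writing and collapsing of small-RNA sequence data.

The pipeline operates on *unique tags*: distinct 18-30 nt sequences with
per-replicate read counts.  This module collapses raw reads into tags,
applies the clean-read length gate, intersects technical replicates, and
round-trips the reference libraries (mature miRNAs, precursors, per-class
decoy libraries, genome, SNP table) used by the annotation cascade.

All sequences are stored in the DNA alphabet; U is mapped to T on input,
matching the space in which sequencers report reads.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "UniqueTag",
    "ReferenceSet",
    "collapse_reads",
    "length_filter",
    "drop_n_tags",
    "clean_tags",
    "replicate_concordance",
    "read_fasta",
    "write_fasta",
    "read_tag_fasta",
    "write_tag_fasta",
    "read_snp_table",
    "write_snp_table",
    "read_reference_set",
    "write_reference_set",
    "normalize_sequence",
]

_VALID_RE = re.compile(r"^[ACGTN]*$")

# Fixed, ordered vocabulary of annotation classes (cascade priority order).
CLASS_ORDER = (
    "miRNA",
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "scRNA",
    "srpRNA",
    "piRNA",
    "repeat",
    "exon",
    "intron",
)
NON_MIRNA_CLASSES = CLASS_ORDER[1:]


def normalize_sequence(seq: str, where: str = "sequence") -> str:
    """Uppercase, map U->T, and validate the alphabet (ACGTN)."""
    s = str(seq).strip().upper().replace("U", "T")
    if not _VALID_RE.match(s):
        bad = sorted(set(s) - set("ACGTN"))
        raise ValueError(f"invalid character(s) {bad} in {where}")
    return s


@dataclass(frozen=True)
class UniqueTag:
    """A distinct small-RNA sequence with per-replicate counts.

    ``count_mean`` is the arithmetic mean of the replicate counts (kept as a
    rational; never rounded before TPM).  ``tpm`` is filled by
    :func:`smallrna_devatlas.annotate.compute_tpm`.
    """

    sequence: str
    count_rep1: int
    count_rep2: int = 0
    count_mean: float = 0.0
    tpm: float = 0.0

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


@dataclass
class ReferenceSet:
    """Reference libraries for the annotation cascade.

    ``mature_offsets`` maps precursor id -> list of (mature_id, 0-based
    offset of the mature within the precursor).
    """

    mature: dict[str, str]
    precursors: dict[str, str]
    mature_offsets: dict[str, list[tuple[str, int]]]
    class_libraries: dict[str, dict[str, str]]
    genome: dict[str, str]
    snp_table: set[tuple[str, int]] = field(default_factory=set)

    def validate(self) -> None:
        """Check that every precursor contains its matures at the recorded offsets."""
        bad = []
        for pid, pairs in self.mature_offsets.items():
            pseq = self.precursors.get(pid)
            if pseq is None:
                bad.append(pid)
                continue
            for mid, off in pairs:
                mseq = self.mature.get(mid)
                if mseq is None or pseq[off : off + len(mseq)] != mseq:
                    bad.append(pid)
        if bad:
            raise ValueError(
                "precursor(s) lacking the annotated mature at the recorded "
                f"offset: {sorted(set(bad))}"
            )


# ---------------------------------------------------------------------------
# tag operations
# ---------------------------------------------------------------------------

def collapse_reads(reads: list[str]) -> list[UniqueTag]:
    """Collapse raw reads into unique tags with counts.

    Output is sorted by descending count, ties broken lexicographically by
    sequence, so collapsing is a stable, reproducible operation.  Total counts
    equal the number of input reads.
    """
    counts: Counter[str] = Counter()
    for i, r in enumerate(reads):
        counts[normalize_sequence(r, where=f"read #{i + 1}")] += 1
    return [
        UniqueTag(sequence=s, count_rep1=c, count_mean=float(c))
        for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def length_filter(
    tags: list[UniqueTag], min_nt: int = 18, max_nt: int = 30
) -> list[UniqueTag]:
    """Keep tags whose length lies in [min_nt, max_nt] (inclusive)."""
    if min_nt > max_nt:
        raise ValueError("min_nt must be <= max_nt")
    return [t for t in tags if min_nt <= len(t.sequence) <= max_nt]


def drop_n_tags(tags: list[UniqueTag]) -> tuple[list[UniqueTag], int]:
    """Drop tags containing N; returns (kept, number dropped)."""
    kept = [t for t in tags if "N" not in t.sequence]
    return kept, len(tags) - len(kept)


def clean_tags(
    tags: list[UniqueTag], min_nt: int = 18, max_nt: int = 30
) -> tuple[list[UniqueTag], int]:
    """The clean-read gate: drop N-containing tags, then apply the length gate.

    Returns (clean tags, number of N tags dropped).
    """
    no_n, n_dropped = drop_n_tags(tags)
    return length_filter(no_n, min_nt, max_nt), n_dropped


def replicate_concordance(
    rep1: list[UniqueTag], rep2: list[UniqueTag]
) -> list[UniqueTag]:
    """Keep tags detected in both technical replicates; average their counts.

    A tag must have count >= 1 in both replicates to be retained; its
    ``count_mean`` is the arithmetic mean of the two counts (possibly a
    half-integer).  Output sorted by descending mean, ties lexicographic.
    """
    c1 = {t.sequence: t.count_rep1 for t in rep1}
    c2 = {t.sequence: t.count_rep1 for t in rep2}
    shared = set(c1) & set(c2)
    out = [
        UniqueTag(
            sequence=s,
            count_rep1=c1[s],
            count_rep2=c2[s],
            count_mean=(c1[s] + c2[s]) / 2.0,
        )
        for s in shared
    ]
    out.sort(key=lambda t: (-t.count_mean, t.sequence))
    return out


# ---------------------------------------------------------------------------
# FASTA / TSV round trips
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-FASTA into an ordered id -> DNA sequence mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = normalize_sequence(str(rec.seq), where=f"record {rec.id!r}")
    return out


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


_TAG_HEADER_RE = re.compile(r"_x(\d+)$")


def read_tag_fasta(path: str | Path) -> list[UniqueTag]:
    """Read collapsed-tag FASTA (``>tag{N}_x{count}``); plain FASTA counts 1 per record."""
    counts: Counter[str] = Counter()
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _TAG_HEADER_RE.search(rec.id)
        n = int(m.group(1)) if m else 1
        counts[normalize_sequence(str(rec.seq), where=f"record {rec.id!r}")] += n
    return [
        UniqueTag(sequence=s, count_rep1=c, count_mean=float(c))
        for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def write_tag_fasta(tags: list[UniqueTag], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, t in enumerate(tags, start=1):
            fh.write(f">tag{i}_x{t.count_rep1}\n{t.sequence}\n")


def read_snp_table(path: str | Path) -> set[tuple[str, int]]:
    """Read a TSV of (miRNA_id, position_1based) SNP positions."""
    out: set[tuple[str, int]] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("miRNA_id"):
                continue
            mid, pos = line.split("\t")[:2]
            out.add((mid, int(pos)))
    return out


def write_snp_table(snps: set[tuple[str, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("miRNA_id\tposition_1based\n")
        for mid, pos in sorted(snps):
            fh.write(f"{mid}\t{pos}\n")


def write_reference_set(refset: ReferenceSet, outdir: str | Path) -> None:
    """Write a ReferenceSet as plain FASTA/TSV files under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(refset.mature, outdir / "mature.fa")
    write_fasta(refset.precursors, outdir / "precursors.fa")
    with open(outdir / "mature_offsets.tsv", "w") as fh:
        fh.write("precursor_id\tmature_id\toffset_0based\n")
        for pid in refset.precursors:
            for mid, off in refset.mature_offsets.get(pid, []):
                fh.write(f"{pid}\t{mid}\t{off}\n")
    for cls, lib in refset.class_libraries.items():
        write_fasta(lib, outdir / f"class_{cls}.fa")
    write_fasta(refset.genome, outdir / "genome.fa")
    write_snp_table(refset.snp_table, outdir / "snp_table.tsv")


def read_reference_set(refdir: str | Path) -> ReferenceSet:
    """Load a ReferenceSet written by :func:`write_reference_set`; validates containment."""
    refdir = Path(refdir)
    offsets: dict[str, list[tuple[str, int]]] = {}
    with open(refdir / "mature_offsets.tsv") as fh:
        next(fh)
        for line in fh:
            pid, mid, off = line.rstrip("\n").split("\t")
            offsets.setdefault(pid, []).append((mid, int(off)))
    class_libraries = {}
    for cls in NON_MIRNA_CLASSES:
        p = refdir / f"class_{cls}.fa"
        if p.exists():
            class_libraries[cls] = read_fasta(p)
    refset = ReferenceSet(
        mature=read_fasta(refdir / "mature.fa"),
        precursors=read_fasta(refdir / "precursors.fa"),
        mature_offsets=offsets,
        class_libraries=class_libraries,
        genome=read_fasta(refdir / "genome.fa"),
        snp_table=read_snp_table(refdir / "snp_table.tsv"),
    )
    refset.validate()
    return refset
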