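"""IsomiR taxonomy: classify miRNA tags by their 5'/3' end offsets.

A tag assigned to the miRNA class is aligned exactly within a precursor and
its end offsets are computed against the annotated mature:

* ``d5`` = tag 5' end minus mature 5' end.  Negative means the tag starts
  upstream of the mature (a 5' **addition**); positive means 5' trimming.
* ``d3`` = tag 3' end minus mature 3' end.  Positive means 3' **addition**;
  negative means 3' trimming.

The sign pattern maps onto an 8-category scheme (category texts in
:data:`CATEGORY_DESCRIPTIONS`), with (0, 0) being the canonical mature:

=========  =========  =========
category   5' end     3' end
=========  =========  =========
1          addition   addition
2          addition   unchanged
3          unchanged  addition
4          addition   trimming
5          trimming   unchanged
6          trimming   trimming
7          unchanged  trimming
8          trimming   addition
=========  =========  =========

5' additions must be templated (present in the precursor).  3' additions may
be templated or non-templated: a tag whose body aligns exactly but whose last
1-2 nt disagree with the precursor is treated as carrying a non-templated 3'
tail (``templated_3p=False``), the dominant tailing mode in vivo.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import ReferenceSet, UniqueTag

__all__ = [
    "IsomiRRecord",
    "classify_isomir",
    "category_from_offsets",
    "isomir_spectrum",
    "CATEGORY_DESCRIPTIONS",
]

CATEGORY_DESCRIPTIONS: dict[int, str] = {
    1: "addition of nucleotides at both 3' and 5' ends",
    2: "addition of nucleotides at 5' end",
    3: "addition of nucleotides at 3' end",
    4: "addition at 5' end and trimming of nucleotides at 3' end",
    5: "trimming at 5' end",
    6: "trimming at both 3' and 5' ends",
    7: "trimming at 3' end",
    8: "trimming at 5' end and addition at 3' end",
}

#: largest |d5| / |d3| still considered an isomiR of a given mature
DEFAULT_OFFSET_WINDOW = 5
#: longest non-templated 3' tail recognized
DEFAULT_MAX_NTA = 2


@dataclass(frozen=True)
class IsomiRRecord:
    tag: UniqueTag
    mature_id: str
    d5: int
    d3: int
    category: int | str  # 1..8 or "canonical"
    templated_3p: bool


def category_from_offsets(d5: int, d3: int) -> int | str:
    """Map signed end offsets to the 8-category scheme (or ``"canonical"``)."""
    if d5 == 0 and d3 == 0:
        return "canonical"
    add5, trim5 = d5 < 0, d5 > 0
    add3, trim3 = d3 > 0, d3 < 0
    if add5 and add3:
        return 1
    if add5 and d3 == 0:
        return 2
    if d5 == 0 and add3:
        return 3
    if add5 and trim3:
        return 4
    if trim5 and d3 == 0:
        return 5
    if trim5 and trim3:
        return 6
    if d5 == 0 and trim3:
        return 7
    assert trim5 and add3
    return 8


def _alignments(
    seq: str,
    refset: ReferenceSet,
    window: int,
    max_nta: int,
):
    """Yield (|d5|+|d3|, precursor_id, start, mature_id, d5, d3, templated_3p)."""
    for pid, pseq in refset.precursors.items():
        pairs = refset.mature_offsets.get(pid)
        if not pairs:
            raise ValueError(f"precursor {pid!r} has no recorded mature offsets")
        for nta in range(0, max_nta + 1):
            core = seq[: len(seq) - nta] if nta else seq
            if not core:
                continue
            start = pseq.find(core)
            while start != -1:
                end = start + len(core)
                # a non-templated tail must actually disagree with the precursor
                if nta == 0 or pseq[end : end + nta] != seq[len(core) :]:
                    for mid, moff in pairs:
                        mlen = len(refset.mature[mid])
                        d5 = start - moff
                        d3 = (end + nta) - (moff + mlen)
                        if abs(d5) <= window and abs(d3) <= window:
                            yield (
                                abs(d5) + abs(d3),
                                pid,
                                start,
                                mid,
                                d5,
                                d3,
                                nta == 0,
                            )
                start = pseq.find(core, start + 1)


def classify_isomir(
    tag: UniqueTag,
    refset: ReferenceSet,
    window: int = DEFAULT_OFFSET_WINDOW,
    max_nta: int = DEFAULT_MAX_NTA,
) -> IsomiRRecord | None:
    """Classify a miRNA-class tag against the precursor/mature references.

    The tag (or the tag minus a <=``max_nta`` nt non-templated 3' tail) must
    align exactly within a precursor with both end offsets inside the window.
    Among admissible placements the one with the smallest ``|d5| + |d3|`` wins
    (ties: first precursor by id order, then 5'-most placement).  Returns
    ``None`` if no placement exists.
    """
    best = None
    for cand in _alignments(tag.sequence, refset, window, max_nta):
        key = (cand[0], cand[1], cand[2])
        if best is None or key < (best[0], best[1], best[2]):
            best = cand
    if best is None:
        return None
    _, _, _, mid, d5, d3, templated = best
    return IsomiRRecord(
        tag=tag,
        mature_id=mid,
        d5=d5,
        d3=d3,
        category=category_from_offsets(d5, d3),
        templated_3p=templated,
    )


def isomir_spectrum(records: list[IsomiRRecord]):
    """Per-category tag count, summed TPM and TPM fraction (canonical excluded).

    Fractions are over the 8 isomiR categories and sum to 1 when any isomiR
    exists; with no isomiRs all fractions are 0 and ``empty`` is flagged.
    """
    import pandas as pd

    rows = []
    iso = [r for r in records if r.category != "canonical"]
    total_tpm = sum(r.tag.tpm for r in iso)
    for cat in range(1, 9):
        sub = [r for r in iso if r.category == cat]
        tpm = sum(r.tag.tpm for r in sub)
        rows.append(
            {
                "category": cat,
                "description": CATEGORY_DESCRIPTIONS[cat],
                "tag_count": len(sub),
                "tpm": tpm,
                "fraction": (tpm / total_tpm) if total_tpm > 0 else 0.0,
            }
        )
    df = pd.DataFrame(rows).set_index("category")
    df.attrs["empty"] = total_tpm == 0
    return df
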