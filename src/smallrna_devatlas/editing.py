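"""Single-nucleotide miRNA editing detection with SNP filtering.

Tags that survive no exact-match annotation are compared to every mature
miRNA of the same length; a Hamming distance of exactly 1 (no indels) yields
a candidate editing event at the mismatched position.  Events at known SNP
positions are removed, and the survivors are profiled by position (seed =
mature positions 2-8, flank = 12-15), by stage, and against the TPM > 50
high-confidence gate.  A->G events correspond to A-to-I editing as read by
sequencers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import UniqueTag

__all__ = [
    "EditingEvent",
    "region_of_position",
    "detect_edits",
    "filter_snp",
    "positional_profile",
    "editing_summary",
    "wt_vs_edited_series",
    "SEED_POSITIONS",
    "FLANK_POSITIONS",
]

SEED_POSITIONS = range(2, 9)  # mature positions 2-8 inclusive
FLANK_POSITIONS = range(12, 16)  # mature positions 12-15 inclusive
DEFAULT_HIGH_TPM = 50.0


def region_of_position(position: int) -> str:
    if position in SEED_POSITIONS:
        return "seed"
    if position in FLANK_POSITIONS:
        return "flank"
    return "other"


@dataclass(frozen=True)
class EditingEvent:
    mature_id: str
    position: int  # 1-based from the mature 5' end
    ref_base: str
    alt_base: str
    tpm: float
    region: str
    tag_sequence: str
    multi_hit: bool = False
    end_ambiguous: bool = False  # position 1 or terminal: indistinguishable
    # from non-templated end modification

    @property
    def label(self) -> str:
        """Display convention ``(ref/alt: position)``, e.g. ``(A/G: 6)``."""
        return f"({self.ref_base}/{self.alt_base}: {self.position})"


def _hamming1_position(a: str, b: str) -> int | None:
    """0-based index of the single mismatch, or None if distance != 1."""
    pos = -1
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            if pos >= 0:
                return None
            pos = i
    return pos if pos >= 0 else None


def detect_edits(
    unannotated_tags: list[UniqueTag],
    matures: dict[str, str],
    split_multi_tpm: bool = False,
) -> list[EditingEvent]:
    """One event per (tag, mature) pair at Hamming distance exactly 1.

    Only equal-length comparisons are made (no indels).  A tag at distance 1
    from several matures yields one event per mature, each flagged
    ``multi_hit``.  Position-1 and terminal-position events are flagged
    ``end_ambiguous``.  Event TPM is the tag's TPM; with
    ``split_multi_tpm=True`` a multi-hit tag's TPM is divided equally among
    its parent matures instead of counted in full for each.
    """
    by_len: dict[int, list[tuple[str, str]]] = {}
    for mid, mseq in matures.items():
        by_len.setdefault(len(mseq), []).append((mid, mseq))
    events: list[EditingEvent] = []
    for tag in unannotated_tags:
        hits = []
        for mid, mseq in by_len.get(len(tag.sequence), []):
            p = _hamming1_position(tag.sequence, mseq)
            if p is not None:
                hits.append((mid, mseq, p))
        share = tag.tpm / len(hits) if (split_multi_tpm and hits) else tag.tpm
        for mid, mseq, p in hits:
            pos1 = p + 1
            events.append(
                EditingEvent(
                    mature_id=mid,
                    position=pos1,
                    ref_base=mseq[p],
                    alt_base=tag.sequence[p],
                    tpm=share,
                    region=region_of_position(pos1),
                    tag_sequence=tag.sequence,
                    multi_hit=len(hits) > 1,
                    end_ambiguous=pos1 == 1 or pos1 == len(mseq),
                )
            )
    return events


def error_model_filter(
    events: list[EditingEvent],
    canonical_tpm: dict[str, float],
    total_reads: int,
    per_base_error_rate: float,
    alpha: float = 0.01,
) -> list[EditingEvent]:
    """Optional statistical gate: reject events explainable by base errors.

    Under a uniform error model, reads of the canonical tag of mature *m*
    produce a specific (position, alt) neighbor at rate ``e / 3`` per read.
    An event is kept when its observed read count is improbable under a
    Poisson with that expectation (one-sided p < ``alpha``).  This is an
    alternative to the plain TPM gate, not a default.
    """
    from scipy import stats as _stats

    if per_base_error_rate < 0 or not 0 < alpha < 1:
        raise ValueError("need per_base_error_rate >= 0 and 0 < alpha < 1")
    kept = []
    for e in events:
        lam = (
            canonical_tpm.get(e.mature_id, 0.0)
            / 1e6
            * total_reads
            * per_base_error_rate
            / 3.0
        )
        observed = e.tpm / 1e6 * total_reads
        # P(Poisson(lam) >= observed), with lam = 0 meaning errors impossible
        p = _stats.poisson.sf(max(observed, 1.0) - 1.0, lam) if lam > 0 else 0.0
        if p < alpha:
            kept.append(e)
    return kept


def filter_snp(
    events: list[EditingEvent], snp_table: set[tuple[str, int]]
) -> list[EditingEvent]:
    """Drop events whose (mature_id, position) is a known SNP position."""
    return [e for e in events if (e.mature_id, e.position) not in snp_table]


def positional_profile(
    events_per_stage: dict[str, list[EditingEvent]],
    max_position: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Cumulative editing TPM at each mature position, per stage.

    Returns ``(position x stage TPM matrix, region x stage sums, enrichment)``
    where enrichment is the mean per-position TPM inside seed (2-8) plus
    flank (12-15) divided by the mean per-position TPM elsewhere (over all
    stages).  With no events the ratio is undefined and returned as NaN; with
    no TPM outside seed/flank it is ``inf``.
    """
    all_events = [e for evs in events_per_stage.values() for e in evs]
    if max_position is None:
        max_position = max((e.position for e in all_events), default=0)
    positions = list(range(1, max_position + 1))
    mat = pd.DataFrame(
        0.0, index=positions, columns=list(events_per_stage.keys())
    )
    mat.index.name = "position"
    for stage, evs in events_per_stage.items():
        for e in evs:
            mat.loc[e.position, stage] += e.tpm
    regions = pd.DataFrame(
        0.0, index=["seed", "flank", "other"], columns=mat.columns
    )
    for pos in positions:
        regions.loc[region_of_position(pos)] += mat.loc[pos]
    if not all_events or not positions:
        return mat, regions, float("nan")
    inside = [p for p in positions if region_of_position(p) != "other"]
    outside = [p for p in positions if region_of_position(p) == "other"]
    mean_in = mat.loc[inside].to_numpy().sum() / max(len(inside), 1)
    mean_out = (
        mat.loc[outside].to_numpy().sum() / len(outside) if outside else 0.0
    )
    ratio = float("inf") if mean_out == 0 else float(mean_in / mean_out)
    return mat, regions, ratio


def editing_summary(
    events_per_stage: dict[str, list[EditingEvent]],
    mirna_tpm_per_stage: dict[str, float],
    high_tpm_threshold: float = DEFAULT_HIGH_TPM,
) -> pd.DataFrame:
    """Per-stage editing summary.

    Columns: number of distinct edited miRNAs, distinct edited (miRNA,
    position) pairs, events above the high-TPM gate (strict inequality), and
    the edited-read fraction = event TPM / (event TPM + miRNA-class TPM).
    Multi-hit events are counted once per (mature, position, alt).
    """
    if high_tpm_threshold < 0:
        raise ValueError("high_tpm_threshold must be >= 0")
    rows = []
    for stage, evs in events_per_stage.items():
        uniq = {}
        for e in evs:
            key = (e.mature_id, e.position, e.alt_base)
            uniq[key] = uniq.get(key, 0.0) + e.tpm
        edited_tpm = sum(
            e.tpm for e in {(ev.tag_sequence): ev for ev in evs}.values()
        )
        mirna_tpm = mirna_tpm_per_stage.get(stage, 0.0)
        denom = edited_tpm + mirna_tpm
        rows.append(
            {
                "stage": stage,
                "edited_mirnas": len({k[0] for k in uniq}),
                "edited_positions": len({k[:2] for k in uniq}),
                "high_editing_events": sum(
                    1 for v in uniq.values() if v > high_tpm_threshold
                ),
                "edited_read_fraction": (edited_tpm / denom) if denom > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("stage")


def wt_vs_edited_series(
    mature_id: str,
    position: int,
    alt_base: str,
    events_per_stage: dict[str, list[EditingEvent]],
    wt_tpm_per_stage: dict[str, float],
) -> tuple[np.ndarray, np.ndarray, int | None]:
    """Developmental trajectory of the wild-type vs the edited form.

    Stages are taken in the order of ``events_per_stage``.  The crossing stage
    is the first index where edited TPM > WT TPM and the edited form remains
    >= WT at every later stage; ``None`` if that never happens.
    """
    stages = list(events_per_stage.keys())
    found = any(
        e.mature_id == mature_id and e.position == position and e.alt_base == alt_base
        for evs in events_per_stage.values()
        for e in evs
    )
    if not found:
        raise ValueError(
            f"no editing event ({mature_id}, {position}, {alt_base}) in any stage"
        )
    wt = np.array([wt_tpm_per_stage.get(s, 0.0) for s in stages], dtype=float)
    ed = np.array(
        [
            sum(
                e.tpm
                for e in events_per_stage[s]
                if e.mature_id == mature_id
                and e.position == position
                and e.alt_base == alt_base
            )
            for s in stages
        ],
        dtype=float,
    )
    crossing = None
    for k in range(len(stages)):
        if ed[k] > wt[k] and all(ed[j] >= wt[j] for j in range(k + 1, len(stages))):
            crossing = k
            break
    return wt, ed, crossing
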