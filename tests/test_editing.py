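"""Single-mismatch editing detection, SNP filtering and stage profiles."""

from __future__ import annotations

import random

import numpy as np
import pytest

from smallrna_devatlas.editing import (
    EditingEvent,
    detect_edits,
    editing_summary,
    filter_snp,
    positional_profile,
    region_of_position,
    wt_vs_edited_series,
)
from smallrna_devatlas.io import UniqueTag


def _tag(seq: str, tpm: float = 10.0) -> UniqueTag:
    return UniqueTag(sequence=seq, count_rep1=1, count_mean=1.0, tpm=tpm)


def _event(mid="mirX", pos=6, ref="A", alt="G", tpm=10.0) -> EditingEvent:
    return EditingEvent(
        mature_id=mid, position=pos, ref_base=ref, alt_base=alt, tpm=tpm,
        region=region_of_position(pos), tag_sequence="A" * 20,
    )


class TestDetection:
    MATURE = "AAACCCGGGTTTAAACCCGG"

    def test_single_mismatch_yields_positioned_event(self):
        events = detect_edits(
            [_tag("AAACCTGGGTTTAAACCCGG")], {"m1": self.MATURE}
        )
        assert len(events) == 1
        e = events[0]
        assert (e.position, e.ref_base, e.alt_base) == (6, "C", "T")
        assert e.region == "seed"
        assert e.label == "(C/T: 6)"

    def test_exact_match_yields_nothing(self):
        assert detect_edits([_tag(self.MATURE)], {"m1": self.MATURE}) == []

    def test_two_mismatches_yield_nothing(self):
        assert (
            detect_edits([_tag("TAACCTGGGTTTAAACCCGG")], {"m1": self.MATURE})
            == []
        )

    def test_length_mismatch_never_compared(self):
        assert detect_edits([_tag(self.MATURE[:-1])], {"m1": self.MATURE}) == []

    def test_terminal_positions_flagged_end_ambiguous(self):
        t1 = "T" + self.MATURE[1:]
        t2 = self.MATURE[:-1] + "A"
        events = detect_edits([_tag(t1), _tag(t2)], {"m1": self.MATURE})
        assert all(e.end_ambiguous for e in events)
        assert {e.position for e in events} == {1, len(self.MATURE)}

    def test_multi_hit_flagged_once_per_mature(self):
        m1 = "AAACCCGGGTTTAAACCCGG"
        m2 = "AAACCAGGGTTTAAACCCGG"  # distance 1 from the tag below too
        tag = _tag("AAACCTGGGTTTAAACCCGG")
        events = detect_edits([tag], {"m1": m1, "m2": m2})
        assert len(events) == 2
        assert all(e.multi_hit for e in events)

    def test_multi_hit_tpm_split_option(self):
        m1 = "AAACCCGGGTTTAAACCCGG"
        m2 = "AAACCAGGGTTTAAACCCGG"
        tag = UniqueTag("AAACCTGGGTTTAAACCCGG", 1, 0, 1.0, tpm=90.0)
        full = detect_edits([tag], {"m1": m1, "m2": m2})
        assert [e.tpm for e in full] == [90.0, 90.0]
        split = detect_edits([tag], {"m1": m1, "m2": m2}, split_multi_tpm=True)
        assert [e.tpm for e in split] == [45.0, 45.0]

    def test_matches_hamming1_neighborhood_enumeration(self):
        """Detector output equals brute-force neighborhood enumeration."""
        rng = random.Random(23)
        matures = {
            f"m{i}": "".join(rng.choice("ACGT") for _ in range(rng.randint(20, 23)))
            for i in range(50)
        }
        tags = []
        for mseq in list(matures.values())[::2]:
            p = rng.randrange(len(mseq))
            alt = rng.choice([b for b in "ACGT" if b != mseq[p]])
            tags.append(_tag(mseq[:p] + alt + mseq[p + 1 :]))
        tags += [
            _tag("".join(rng.choice("ACGT") for _ in range(21)))
            for _ in range(40)
        ]
        got = {
            (e.tag_sequence, e.mature_id, e.position, e.alt_base)
            for e in detect_edits(tags, matures)
        }
        expected = set()
        tag_seqs = {t.sequence for t in tags}
        for mid, mseq in matures.items():
            for p in range(len(mseq)):
                for alt in "ACGT":
                    if alt == mseq[p]:
                        continue
                    neighbor = mseq[:p] + alt + mseq[p + 1 :]
                    if neighbor in tag_seqs:
                        expected.add((neighbor, mid, p + 1, alt))
        assert got == expected


class TestSnpFilter:
    def test_event_at_snp_position_removed(self):
        events = [_event(pos=7), _event(pos=9)]
        kept = filter_snp(events, {("mirX", 7)})
        assert [e.position for e in kept] == [9]

    def test_empty_table_is_identity(self):
        events = [_event(pos=7)]
        assert filter_snp(events, set()) == events

    def test_no_event_survives_at_any_snp_position(self):
        rng = random.Random(1)
        events = [
            _event(pos=rng.randint(1, 20), alt=rng.choice("CGT"))
            for _ in range(200)
        ]
        snps = {("mirX", p) for p in range(1, 11)}
        kept = filter_snp(events, snps)
        assert all((e.mature_id, e.position) not in snps for e in kept)
        assert len(kept) == sum(e.position > 10 for e in events)


class TestErrorModelFilter:
    def test_abundant_event_survives_error_explainable_removed(self):
        from smallrna_devatlas.editing import error_model_filter

        # canonical parent at 50,000 TPM, depth 10,000 reads, e = 1e-3:
        # expected error reads at one specific neighbor ~ 0.17
        strong = _event(tpm=2000.0)
        weak = _event(pos=9, tpm=100.0)  # one read pair: plausible error? no:
        events = error_model_filter(
            [strong, weak],
            canonical_tpm={"mirX": 50_000.0},
            total_reads=10_000,
            per_base_error_rate=1e-3,
        )
        assert strong in events
        # at a much higher error rate the weak event becomes explainable
        events_hi = error_model_filter(
            [strong, weak],
            canonical_tpm={"mirX": 50_000.0},
            total_reads=10_000,
            per_base_error_rate=0.05,
        )
        assert weak not in events_hi

    def test_orphan_event_always_kept(self):
        from smallrna_devatlas.editing import error_model_filter

        ev = _event(tpm=100.0)
        out = error_model_filter(
            [ev], canonical_tpm={}, total_reads=10_000,
            per_base_error_rate=1e-3,
        )
        assert out == [ev]


class TestRegions:
    @pytest.mark.parametrize(
        "pos,region",
        [(1, "other"), (2, "seed"), (8, "seed"), (9, "other"),
         (11, "other"), (12, "flank"), (15, "flank"), (16, "other")],
    )
    def test_seed_and_flank_boundaries(self, pos, region):
        assert region_of_position(pos) == region


class TestPositionalProfile:
    def test_single_position_profile(self):
        mat, regions, ratio = positional_profile(
            {"P0": [_event(pos=6, tpm=5.0), _event(pos=6, tpm=7.0)]}
        )
        assert mat.loc[6, "P0"] == 12.0
        assert (mat.drop(index=6) == 0).all().all()
        assert regions.loc["seed", "P0"] == 12.0

    def test_no_events_ratio_undefined(self):
        mat, _, ratio = positional_profile({"P0": []})
        assert mat.size == 0 or (mat == 0).all().all()
        assert np.isnan(ratio)

    def test_seed_flank_enrichment_ratio(self):
        evs = {
            "P0": [_event(pos=4, tpm=50.0), _event(pos=13, tpm=50.0),
                   _event(pos=10, tpm=1.0)],
        }
        _, _, ratio = positional_profile(evs, max_position=20)
        assert ratio > 1


class TestSummary:
    def test_high_gate_is_strict(self):
        summary = editing_summary(
            {"P0": [_event(pos=3, tpm=60.0), _event(pos=5, tpm=50.0)]},
            {"P0": 1000.0},
            high_tpm_threshold=50.0,
        )
        assert summary.loc["P0", "high_editing_events"] == 1
        assert summary.loc["P0", "edited_mirnas"] == 1
        assert summary.loc["P0", "edited_positions"] == 2

    def test_no_events(self):
        summary = editing_summary({"P0": []}, {"P0": 1000.0})
        assert (summary.loc["P0"] == 0).all()

    def test_edited_read_fraction_definition(self):
        summary = editing_summary(
            {"P0": [_event(tpm=100.0)]}, {"P0": 900.0}
        )
        assert summary.loc["P0", "edited_read_fraction"] == pytest.approx(0.1)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            editing_summary({"P0": []}, {}, high_tpm_threshold=-1)


class TestWtVsEdited:
    def _events(self, ed_series):
        return {
            f"s{i}": [_event(tpm=v)] if v > 0 else []
            for i, v in enumerate(ed_series)
        }

    def test_crossing_detected_at_defined_stage(self):
        wt = {f"s{i}": v for i, v in enumerate([100.0, 80.0, 60.0, 40.0])}
        evs = self._events([10.0, 30.0, 70.0, 90.0])
        _, _, crossing = wt_vs_edited_series("mirX", 6, "G", evs, wt)
        assert crossing == 2

    def test_never_crossing_is_none(self):
        wt = {f"s{i}": v for i, v in enumerate([100.0, 100.0, 100.0])}
        evs = self._events([10.0, 20.0, 30.0])
        _, _, crossing = wt_vs_edited_series("mirX", 6, "G", evs, wt)
        assert crossing is None

    def test_transient_crossing_not_reported(self):
        wt = {f"s{i}": v for i, v in enumerate([10.0, 100.0, 10.0])}
        evs = self._events([20.0, 20.0, 20.0])
        _, _, crossing = wt_vs_edited_series("mirX", 6, "G", evs, wt)
        assert crossing == 2  # stage 0 crossing is not sustained

    def test_unknown_event_rejected(self):
        with pytest.raises(ValueError, match="no editing event"):
            wt_vs_edited_series("mirZ", 3, "G", self._events([5.0]), {"s0": 1.0})
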