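"""The priority annotation cascade, TPM normalization and derived matrices."""

from __future__ import annotations

import random

import pytest

from smallrna_devatlas.annotate import (
    annotate_tags,
    class_abundance_profile,
    compute_tpm,
    mirna_expression_matrix,
)
from smallrna_devatlas.io import (
    CLASS_ORDER,
    NON_MIRNA_CLASSES,
    ReferenceSet,
    UniqueTag,
    collapse_reads,
)
from smallrna_devatlas.isomir import classify_isomir
from tests.conftest import MIR_A, MIR_B


def _tag(seq: str, count: int = 1) -> UniqueTag:
    return UniqueTag(sequence=seq, count_rep1=count, count_mean=float(count))


class TestCascade:
    def test_mature_sequence_assigned_mirna(self, tiny_refset):
        (rec,) = annotate_tags([_tag(MIR_A)], tiny_refset)
        assert rec.assigned_class == "miRNA"

    def test_rrna_substring_assigned_rrna(self, tiny_refset):
        seq = tiny_refset.class_libraries["rRNA"]["rRNA-1"][10:32]
        (rec,) = annotate_tags([_tag(seq)], tiny_refset)
        assert rec.assigned_class == "rRNA"
        assert rec.matched_reference_id == "rRNA-1"
        assert rec.match_offset == 10

    def test_mirna_wins_over_rrna_on_double_match(self, tiny_refset):
        """A tag matching both a precursor and an rRNA reference is miRNA:
        matures/precursors are aligned before any other class."""
        seq = tiny_refset.precursors["pre-mirA"][2:24]
        tiny_refset.class_libraries["rRNA"]["rRNA-2"] = "CCTT" + seq + "GGAA"
        (rec,) = annotate_tags([_tag(seq)], tiny_refset)
        assert rec.assigned_class == "miRNA"

    def test_genome_only_and_unannotated(self, tiny_refset):
        in_genome = tiny_refset.genome["chr1"][:20]
        nowhere = "ATATATATATGCGCGCGCTT"
        recs = annotate_tags([_tag(in_genome), _tag(nowhere)], tiny_refset)
        assert [r.assigned_class for r in recs] == ["genome_only", "unannotated"]
        assert all(r.matched_reference_id is None for r in recs)

    def test_minus_strand_tag_is_genome_only(self, tiny_refset):
        from tests.conftest import revcomp

        seq = revcomp(tiny_refset.genome["chr1"][:20])
        (rec,) = annotate_tags([_tag(seq)], tiny_refset)
        assert rec.assigned_class == "genome_only"

    def test_every_tag_gets_exactly_one_class(self, small_refset, small_sim_config):
        from smallrna_devatlas.simulate import generate_stage_reads

        r1, _, _ = generate_stage_reads(small_refset, small_sim_config, 0)
        tags = collapse_reads(r1)
        recs = annotate_tags(tags, small_refset)
        assert len(recs) == len(tags)
        valid = set(CLASS_ORDER) | {"genome_only", "unannotated"}
        assert all(r.assigned_class in valid for r in recs)

    def test_priority_monotone_under_lower_class_additions(self, tiny_refset):
        tags = [
            _tag(MIR_A),
            _tag(tiny_refset.class_libraries["rRNA"]["rRNA-1"][5:27]),
        ]
        before = [r.assigned_class for r in annotate_tags(tags, tiny_refset)]
        tiny_refset.class_libraries.setdefault("intron", {})["intron-1"] = (
            "AA" + tags[0].sequence + tags[1].sequence + "TT"
        )
        after = [r.assigned_class for r in annotate_tags(tags, tiny_refset)]
        assert before == after == ["miRNA", "rRNA"]

    def test_matches_bruteforce_prioritized_search(self, small_refset):
        """On a small instance the indexed cascade equals an all-pairs scan."""
        rng = random.Random(13)
        seqs = []
        for lib in (
            [small_refset.precursors]
            + [small_refset.class_libraries[c] for c in NON_MIRNA_CLASSES]
        ):
            for ref in lib.values():
                start = rng.randrange(0, max(1, len(ref) - 20))
                seqs.append(ref[start : start + 20])
        seqs += ["".join(rng.choice("ACGT") for _ in range(20)) for _ in range(30)]
        tags = [_tag(s) for s in seqs[:200]]
        recs = annotate_tags(tags, small_refset)

        def brute(seq: str) -> str:
            for pseq in small_refset.precursors.values():
                if seq in pseq:
                    return "miRNA"
            if classify_isomir(_tag(seq), small_refset) is not None:
                return "miRNA"
            for cls in NON_MIRNA_CLASSES:
                for ref in small_refset.class_libraries.get(cls, {}).values():
                    if seq in ref:
                        return cls
            from tests.conftest import revcomp

            for contig in small_refset.genome.values():
                if seq in contig or seq in revcomp(contig):
                    return "genome_only"
            return "unannotated"

        for tag, rec in zip(tags, recs):
            assert rec.assigned_class == brute(tag.sequence)


class TestTPM:
    def test_forced_arithmetic(self):
        tags = compute_tpm([_tag("A" * 20, 10), _tag("C" * 20, 90)])
        assert [t.tpm for t in tags] == [100_000.0, 900_000.0]

    def test_single_tag_is_one_million(self):
        (t,) = compute_tpm([_tag("A" * 20, 7)])
        assert t.tpm == 1e6

    def test_total_is_one_million(self):
        rng = random.Random(1)
        tags = [_tag("".join(rng.choice("ACGT") for _ in range(20)), rng.randint(1, 99))
                for _ in range(50)]
        total = sum(t.tpm for t in compute_tpm(tags))
        assert abs(total - 1e6) <= 1e6 * 1e-6

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            compute_tpm([])


class TestProfilesAndMatrix:
    def test_all_mirna_stage_profile(self, tiny_refset):
        tags = compute_tpm([_tag(MIR_A, 5), _tag(MIR_B, 5)])
        recs = annotate_tags(tags, tiny_refset)
        profile = class_abundance_profile({"P0": recs})
        assert profile.loc["miRNA", "P0"] == 1e6
        assert profile.drop(index="miRNA")["P0"].sum() == 0
        assert abs(profile["P0"].sum() - 1e6) < 1e-6

    def test_rrna_spike_stage_is_maximal(self):
        """A 3x rRNA proportion planted at one stage dominates its row."""
        from smallrna_devatlas.annotate import annotate_tags as ann
        from smallrna_devatlas.simulate import (
            SimulationConfig,
            generate_reference_set,
            generate_stage_reads,
        )

        cfg = SimulationConfig(
            rng_seed=3, mirna_count=15, reads_per_replicate=3000,
            rrna_spike_stage=1,
        )
        refset = generate_reference_set(cfg)
        per_stage = {}
        for s in range(cfg.n_stages):
            r1, _, _ = generate_stage_reads(refset, cfg, s)
            tags = compute_tpm(collapse_reads(r1))
            per_stage[f"s{s}"] = ann(tags, refset)
        profile = class_abundance_profile(per_stage)
        assert profile.loc["rRNA"].idxmax() == "s1"

    def test_matrix_counts_canonical_only_by_default(self, tiny_refset):
        iso = MIR_A[:-2]  # 3'-trimmed isomiR
        tags = compute_tpm([_tag(MIR_A, 6), _tag(iso, 4)])
        recs = annotate_tags(tags, tiny_refset)
        default = mirna_expression_matrix({"P0": recs}, tiny_refset)
        assert default.loc["mirA", "P0"] == pytest.approx(600_000.0)
        both = mirna_expression_matrix(
            {"P0": recs}, tiny_refset, aggregate_isomirs=True
        )
        assert both.loc["mirA", "P0"] == pytest.approx(1e6)

    def test_absent_mirna_is_zero(self, tiny_refset):
        tags = compute_tpm([_tag(MIR_A, 1)])
        recs = annotate_tags(tags, tiny_refset)
        m = mirna_expression_matrix({"a": recs, "b": []}, tiny_refset)
        assert m.loc["mirA", "b"] == 0.0

    def test_planted_abundance_tiers_recovered(self):
        """Strict >300 / >1000 TPM filters reproduce the planted split."""
        from smallrna_devatlas.profiling import abundance_tiers
        from smallrna_devatlas.simulate import (
            SimulationConfig,
            expected_mirna_tpm_matrix,
            generate_reference_set,
            generate_stage_reads,
        )

        overrides = (
            {f"mir-{i}": 30.0 for i in range(1, 6)}
            | {f"mir-{i}": 0.12 for i in range(6, 11)}
            | {f"mir-{i}": 0.002 for i in range(11, 31)}
        )
        cfg = SimulationConfig(
            rng_seed=17, mirna_count=30, reads_per_replicate=30_000,
            weight_overrides=overrides, edit_plan=[], snp_plan=[],
            seq_error_rate=0.0, rrna_spike_stage=None,
            replicate_jitter_sigma=0.05,
        )
        refset = generate_reference_set(cfg)
        expected = expected_mirna_tpm_matrix(cfg)
        measured = expected * 0.0
        for s, label in enumerate(cfg.labels()):
            _, _, truth = generate_stage_reads(refset, cfg, s)
            counts = truth.reads[
                truth.reads.class_label == "miRNA"
            ].source_id.value_counts()
            col = counts.reindex(expected.index, fill_value=0)
            measured[label] = col / (2 * cfg.reads_per_replicate) * 1e6
        t_exp = abundance_tiers(expected)
        t_meas = abundance_tiers(measured)
        for thr in (300.0, 1000.0):
            assert t_exp["per_stage"][thr].equals(t_meas["per_stage"][thr])
        assert (
            t_exp["gt_first_threshold_multi_stage"]
            == t_meas["gt_first_threshold_multi_stage"]
        )
        assert (
            t_exp["lt_first_threshold_all_stages"]
            == t_meas["lt_first_threshold_all_stages"]
        )
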