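"""End-to-end orchestration: collapse -> concordance -> annotate -> isomiR ->
editing -> novel hairpins -> stage profiling, from a single config.

Each stage consumes and produces plain files (FASTA / TSV / JSON), so stages
are independently re-runnable and a rerun with an identical config produces
byte-identical manifest-tracked outputs.  ``simulate_and_run`` additionally
generates a synthetic dataset, runs the pipeline on it, and scores every
recoverable piece of planted ground truth into one scorecard.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import (
    AnnotationRecord,
    annotate_tags,
    class_abundance_profile,
    compute_tpm,
    mirna_expression_matrix,
)
from .editing import (
    EditingEvent,
    detect_edits,
    editing_summary,
    filter_snp,
    positional_profile,
)
from .hairpin import HairpinConfig, call_candidates
from .io import (
    ReferenceSet,
    UniqueTag,
    clean_tags,
    read_reference_set,
    read_tag_fasta,
    replicate_concordance,
    write_reference_set,
    write_tag_fasta,
)
from .isomir import IsomiRRecord, classify_isomir, isomir_spectrum
from .profiling import (
    abundance_tiers,
    categorize_matrix,
    complete_linkage_cluster,
    replicate_correlation,
    zscore_matrix,
)
from .simulate import SimulationConfig, build_model, generate_stage_reads

__all__ = ["StageInput", "RunConfig", "run_pipeline", "simulate_and_run"]


@dataclass
class StageInput:
    label: str
    rep1_fasta: str
    rep2_fasta: str


@dataclass
class RunConfig:
    stages: list[StageInput]
    refdir: str
    outdir: str
    seed: int = 0
    min_len: int = 18
    max_len: int = 30
    isomir_window: int = 5
    max_nta: int = 2
    editing_high_tpm: float = 50.0
    aggregate_isomirs: bool = False
    clustering_metric: str = "euclidean"
    hairpin: HairpinConfig = field(default_factory=HairpinConfig)
    enable_isomir: bool = True
    enable_editing: bool = True
    enable_novel: bool = True
    enable_profile: bool = True

    _KNOWN = {
        "stages", "refdir", "outdir", "seed", "min_len", "max_len",
        "isomir_window", "max_nta", "editing_high_tpm", "aggregate_isomirs",
        "clustering_metric", "hairpin", "enable_isomir", "enable_editing",
        "enable_novel", "enable_profile",
    }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        unknown = set(raw) - cls._KNOWN
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw["stages"] = [StageInput(**s) for s in raw["stages"]]
        if "hairpin" in raw:
            raw["hairpin"] = HairpinConfig(**raw["hairpin"])
        return cls(**raw)

    def validate(self) -> None:
        if not self.stages:
            raise ValueError("no stages configured")
        for s in self.stages:
            for p in (s.rep1_fasta, s.rep2_fasta):
                if not Path(p).exists():
                    raise FileNotFoundError(f"stage {s.label}: missing {p}")
        if not Path(self.refdir).exists():
            raise FileNotFoundError(f"reference directory {self.refdir} missing")

    def to_manifest_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hairpin"] = dataclasses.asdict(self.hairpin)
        return d


def _tag_frame(tags: list[UniqueTag]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sequence": [t.sequence for t in tags],
            "count_rep1": [t.count_rep1 for t in tags],
            "count_rep2": [t.count_rep2 for t in tags],
            "count_mean": [t.count_mean for t in tags],
            "tpm": [t.tpm for t in tags],
        }
    )


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6f")


def run_pipeline(config: RunConfig) -> dict:
    """Run every enabled stage; returns the in-memory result bundle.

    All outputs land under ``config.outdir`` together with a ``manifest.json``
    recording inputs, parameters, software version, seed and per-stage record
    counts.  Any stage failure aborts with the failing stage named; the
    manifest then marks it failed.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_manifest_dict(),
        "stages": {},
        "modules": {},
    }
    bundle: dict = {"manifest": manifest}
    current = "load_references"
    try:
        refset = read_reference_set(config.refdir)
        bundle["refset"] = refset

        tags_per_stage: dict[str, list[UniqueTag]] = {}
        records_per_stage: dict[str, list[AnnotationRecord]] = {}
        for stage in config.stages:
            current = f"annotate[{stage.label}]"
            rep1 = read_tag_fasta(stage.rep1_fasta)
            rep2 = read_tag_fasta(stage.rep2_fasta)
            n_reads = (
                sum(t.count_rep1 for t in rep1),
                sum(t.count_rep1 for t in rep2),
            )
            rep1, n_drop1 = clean_tags(rep1, config.min_len, config.max_len)
            rep2, n_drop2 = clean_tags(rep2, config.min_len, config.max_len)
            tags = replicate_concordance(rep1, rep2)
            tags = compute_tpm(tags)
            records = annotate_tags(
                tags, refset,
                isomir_window=config.isomir_window, max_nta=config.max_nta,
            )
            tags_per_stage[stage.label] = tags
            records_per_stage[stage.label] = records
            frame = _tag_frame(tags)
            frame["assigned_class"] = [r.assigned_class for r in records]
            frame["matched_reference_id"] = [
                r.matched_reference_id or "" for r in records
            ]
            _write_tsv(frame, outdir / f"annotation_{stage.label}.tsv")
            manifest["stages"][stage.label] = {
                "reads_in": n_reads,
                "tags_rep1": len(rep1),
                "tags_rep2": len(rep2),
                "n_dropped_N": n_drop1 + n_drop2,
                "tags_concordant": len(tags),
                "status": "done",
            }

        current = "class_profile"
        profile = class_abundance_profile(records_per_stage)
        _write_tsv(profile, outdir / "class_profile.tsv", index=True)
        matrix = mirna_expression_matrix(
            records_per_stage, refset, aggregate_isomirs=config.aggregate_isomirs
        )
        _write_tsv(matrix, outdir / "mirna_tpm_matrix.tsv", index=True)
        bundle["class_profile"] = profile
        bundle["mirna_matrix"] = matrix
        bundle["tags_per_stage"] = tags_per_stage
        bundle["records_per_stage"] = records_per_stage

        isomir_per_stage: dict[str, list[IsomiRRecord]] = {}
        if config.enable_isomir:
            current = "isomir"
            rows = []
            for label, records in records_per_stage.items():
                recs = []
                for r in records:
                    if r.assigned_class != "miRNA":
                        continue
                    iso = classify_isomir(
                        r.tag, refset,
                        window=config.isomir_window, max_nta=config.max_nta,
                    )
                    if iso is not None:
                        recs.append(iso)
                        rows.append(
                            {
                                "stage": label,
                                "sequence": iso.tag.sequence,
                                "mature_id": iso.mature_id,
                                "d5": iso.d5,
                                "d3": iso.d3,
                                "category": iso.category,
                                "templated_3p": iso.templated_3p,
                                "tpm": iso.tag.tpm,
                            }
                        )
                isomir_per_stage[label] = recs
                spectrum = isomir_spectrum(recs)
                _write_tsv(
                    spectrum, outdir / f"isomir_spectrum_{label}.tsv", index=True
                )
            _write_tsv(pd.DataFrame(rows), outdir / "isomir_records.tsv")
            bundle["isomir_per_stage"] = isomir_per_stage
            manifest["modules"]["isomir"] = {
                "status": "done",
                "records": sum(len(v) for v in isomir_per_stage.values()),
            }
        else:
            manifest["modules"]["isomir"] = {"status": "skipped"}

        events_per_stage: dict[str, list[EditingEvent]] = {}
        if config.enable_editing:
            current = "editing"
            rows = []
            for label, records in records_per_stage.items():
                unannotated = [
                    r.tag
                    for r in records
                    if r.assigned_class in ("unannotated", "genome_only")
                ]
                events = filter_snp(
                    detect_edits(unannotated, refset.mature), refset.snp_table
                )
                events_per_stage[label] = events
                for e in events:
                    rows.append(
                        {
                            "stage": label,
                            "mature_id": e.mature_id,
                            "position": e.position,
                            "ref_base": e.ref_base,
                            "alt_base": e.alt_base,
                            "region": e.region,
                            "tpm": e.tpm,
                            "multi_hit": e.multi_hit,
                            "end_ambiguous": e.end_ambiguous,
                        }
                    )
            _write_tsv(pd.DataFrame(rows), outdir / "editing_events.tsv")
            pos_profile, region_sums, enrichment = positional_profile(
                events_per_stage
            )
            _write_tsv(pos_profile, outdir / "editing_positional.tsv", index=True)
            mirna_tpm = {
                label: sum(
                    r.tag.tpm for r in records if r.assigned_class == "miRNA"
                )
                for label, records in records_per_stage.items()
            }
            summary = editing_summary(
                events_per_stage, mirna_tpm, config.editing_high_tpm
            )
            _write_tsv(summary, outdir / "editing_summary.tsv", index=True)
            bundle["events_per_stage"] = events_per_stage
            bundle["editing_summary"] = summary
            bundle["editing_enrichment"] = enrichment
            manifest["modules"]["editing"] = {
                "status": "done",
                "events": sum(len(v) for v in events_per_stage.values()),
                "seed_flank_enrichment": (
                    None if np.isnan(enrichment) else float(enrichment)
                ) if enrichment != float("inf") else "inf",
            }
        else:
            manifest["modules"]["editing"] = {"status": "skipped"}

        if config.enable_novel:
            current = "novel"
            seen: dict[str, UniqueTag] = {}
            for label, records in records_per_stage.items():
                for r in records:
                    if r.assigned_class == "genome_only":
                        prev = seen.get(r.tag.sequence)
                        if prev is None or r.tag.tpm > prev.tpm:
                            seen[r.tag.sequence] = r.tag
            candidates = call_candidates(
                list(seen.values()), refset.genome, config.hairpin
            )
            rows = []
            with open(outdir / "novel_precursors.fa", "w") as fa, open(
                outdir / "novel_structures.txt", "w"
            ) as st, open(outdir / "novel_windows.bed", "w") as bed:
                for i, c in enumerate(candidates):
                    if not c.accepted:
                        continue
                    name = f"candidate-{i + 1}"
                    fa.write(f">{name}\n{c.window_seq}\n")
                    st.write(f">{name}\n{c.structure}\n")
                    bed.write(
                        f"{c.contig}\t{c.start}\t{c.end}\t{name}\t0\t{c.strand}\n"
                    )
            for i, c in enumerate(candidates):
                rows.append(
                    {
                        "contig": c.contig,
                        "start": c.start,
                        "end": c.end,
                        "strand": c.strand,
                        "sequence": c.mature_tag.sequence,
                        "energy": c.energy,
                        "duplex_pairs": c.duplex_pairs,
                        "loop_span": c.loop_span,
                        "accepted": c.accepted,
                        **{f"pass_{k}": v for k, v in c.passed.items()},
                    }
                )
            _write_tsv(pd.DataFrame(rows), outdir / "novel_candidates.tsv")
            bundle["novel_candidates"] = candidates
            manifest["modules"]["novel"] = {
                "status": "done",
                "candidates": len(candidates),
                "accepted": sum(c.accepted for c in candidates),
            }
        else:
            manifest["modules"]["novel"] = {"status": "skipped"}

        if config.enable_profile:
            current = "profile"
            z = zscore_matrix(matrix) if matrix.shape[1] >= 2 else matrix * 0.0
            _write_tsv(z, outdir / "zscores.tsv", index=True)
            if z.shape[0] >= 2:
                linkage, order = complete_linkage_cluster(
                    z, metric=config.clustering_metric
                )
                _write_tsv(
                    pd.DataFrame(
                        linkage, columns=["a", "b", "height", "size"]
                    ),
                    outdir / "linkage.tsv",
                )
                pd.Series(
                    [matrix.index[i] for i in order], name="mirna"
                ).to_csv(outdir / "cluster_order.tsv", sep="\t", index=False)
                bundle["linkage"] = linkage
                bundle["cluster_order"] = order
            tiers = abundance_tiers(matrix)
            tier_frame = pd.DataFrame(
                {f"gt_{int(t)}": s for t, s in tiers["per_stage"].items()}
            )
            _write_tsv(tier_frame, outdir / "tiers.tsv", index=True)
            corr_rows = []
            seq_to_mid = {s: m for m, s in refset.mature.items()}
            for label, tags in tags_per_stage.items():
                c1: dict[str, float] = {}
                c2: dict[str, float] = {}
                for t in tags:
                    mid = seq_to_mid.get(t.sequence)
                    if mid is not None:
                        c1[mid] = c1.get(mid, 0) + t.count_rep1
                        c2[mid] = c2.get(mid, 0) + t.count_rep2
                r = replicate_correlation(c1, c2) if len(c1) >= 3 else float("nan")
                corr_rows.append({"stage": label, "pearson_r_log10": r})
            corr = pd.DataFrame(corr_rows)
            _write_tsv(corr, outdir / "replicate_correlation.tsv")
            patterns = None
            if matrix.shape[1] >= 4 and matrix.shape[0] > 0:
                patterns = categorize_matrix(matrix)
                patterns.rename_axis("mirna").to_frame().to_csv(
                    outdir / "patterns.tsv", sep="\t"
                )
            bundle["zscores"] = z
            bundle["tiers"] = tiers
            bundle["replicate_correlation"] = corr
            bundle["patterns"] = patterns
            manifest["modules"]["profile"] = {"status": "done"}
        else:
            manifest["modules"]["profile"] = {"status": "skipped"}
    except Exception:
        manifest["stages"].setdefault(current, {})
        manifest["failed_stage"] = current
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise RuntimeError(f"pipeline stage {current!r} failed") from None
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return bundle


# ---------------------------------------------------------------------------
# simulate + run + score
# ---------------------------------------------------------------------------

def _write_simulated_inputs(
    sim_config: SimulationConfig, datadir: Path
) -> tuple[RunConfig, dict]:
    """Generate references and per-stage replicate read files under datadir."""
    from .io import collapse_reads
    from .simulate import generate_reference_set

    refset = generate_reference_set(sim_config)
    refdir = datadir / "references"
    write_reference_set(refset, refdir)
    truths = {}
    stages = []
    for s, label in enumerate(sim_config.labels()):
        rep1, rep2, truth = generate_stage_reads(refset, sim_config, s)
        truths[label] = truth
        p1 = datadir / f"reads_{label}_rep1.fa"
        p2 = datadir / f"reads_{label}_rep2.fa"
        write_tag_fasta(collapse_reads(rep1), p1)
        write_tag_fasta(collapse_reads(rep2), p2)
        stages.append(
            StageInput(label=label, rep1_fasta=str(p1), rep2_fasta=str(p2))
        )
    run_config = RunConfig(
        stages=stages,
        refdir=str(refdir),
        outdir=str(datadir / "out"),
        seed=sim_config.rng_seed,
    )
    return run_config, truths


def _score_classes(truths, records_per_stage) -> tuple[float, float]:
    """Read-weighted class accuracy over reads whose tag survived concordance.

    Ground-truth 'novel' reads are expected to annotate as genome_only, and
    planted edited/SNP-alt reads as unannotated (they carry a deliberate
    mismatch so that they reach the editing detector).  Reads hit by a
    sequencing error have no recoverable expectation and are excluded.
    Returns (accuracy, fraction of reads scored)."""
    expected_map = {"novel": "genome_only"}
    n_ok = n_scored = n_total = 0
    for label, truth in truths.items():
        assigned = {
            r.tag.sequence: r.assigned_class for r in records_per_stage[label]
        }
        for _, row in truth.reads.iterrows():
            n_total += 1
            if row.has_error:
                continue
            cls = assigned.get(row.sequence)
            if cls is None:
                continue
            n_scored += 1
            if row.edit_label or row.snp_alt:
                want = "unannotated"
            else:
                want = expected_map.get(row.class_label, row.class_label)
            if cls == want:
                n_ok += 1
    return (n_ok / n_scored if n_scored else float("nan"),
            n_scored / n_total if n_total else 0.0)


def _score_isomirs(truths, isomir_per_stage) -> float:
    """Category accuracy among unmodified, error-free planted miRNA reads."""
    n_ok = n_scored = 0
    for label, truth in truths.items():
        cat_map = {
            r.tag.sequence: str(r.category) for r in isomir_per_stage[label]
        }
        sub = truth.reads
        sub = sub[
            (sub.class_label == "miRNA")
            & (~sub.has_error)
            & (sub.edit_label == "")
            & (~sub.snp_alt)
        ]
        for _, row in sub.iterrows():
            got = cat_map.get(row.sequence)
            if got is None:
                continue
            n_scored += 1
            if got == row.isomir_category:
                n_ok += 1
    return n_ok / n_scored if n_scored else float("nan")


def _score_editing(truths, events_per_stage, gate: float = 50.0) -> dict:
    planted_all = set()
    recovered = 0
    expected = 0
    for label, truth in truths.items():
        detected = {
            (e.mature_id, e.position, e.alt_base) for e in events_per_stage[label]
        }
        for _, row in truth.planted_edits.iterrows():
            key = (row.mature_id, int(row.position), row.alt_base)
            planted_all.add(key)
            if row.expected_tpm >= gate:
                expected += 1
                if key in detected:
                    recovered += 1
    false_high = 0
    for label, truth in truths.items():
        agg: dict[tuple, float] = {}
        for e in events_per_stage[label]:
            k = (e.mature_id, e.position, e.alt_base)
            agg[k] = agg.get(k, 0.0) + e.tpm
        for k, tpm in agg.items():
            if k not in planted_all and tpm >= gate:
                false_high += 1
    return {
        "recall": recovered / expected if expected else float("nan"),
        "n_expected": expected,
        "false_high_events": false_high,
    }


def simulate_and_run(
    sim_config: SimulationConfig, workdir: str | Path
) -> tuple[dict, pd.DataFrame]:
    """Generate synthetic data, run the pipeline, score planted truth.

    Returns (pipeline bundle, scorecard).  The scorecard TSV is written next
    to the pipeline outputs.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    run_config, truths = _write_simulated_inputs(sim_config, workdir)
    bundle = run_pipeline(run_config)
    records_per_stage = bundle["records_per_stage"]

    class_acc, scored_frac = _score_classes(truths, records_per_stage)
    iso_acc = _score_isomirs(truths, bundle.get("isomir_per_stage", {}))
    edit_scores = _score_editing(
        truths, bundle.get("events_per_stage", {}), gate=50.0
    )
    snp_surviving = sum(
        1
        for evs in bundle.get("events_per_stage", {}).values()
        for e in evs
        if (e.mature_id, e.position) in bundle["refset"].snp_table
    )
    model = build_model(sim_config)
    planted_tags = [
        UniqueTag(sequence=s, count_rep1=1, count_mean=1.0)
        for s in model.matures.values()
    ]
    cands = call_candidates(planted_tags, bundle["refset"].genome)
    accepted_seqs = {c.mature_tag.sequence for c in cands if c.accepted}
    hairpin_acc = len(accepted_seqs) / len(planted_tags)
    corr = bundle["replicate_correlation"]["pearson_r_log10"].tolist()
    summary = bundle.get("editing_summary")
    fractions = (
        summary["edited_read_fraction"].tolist() if summary is not None else []
    )
    spectrum_top = {}
    for label, recs in bundle.get("isomir_per_stage", {}).items():
        spec = isomir_spectrum(recs)
        spectrum_top[label] = int(spec["fraction"].idxmax())

    # wild-type vs edited trajectory for the planted frequency-ramp event
    crossing_planted = crossing_detected = None
    ramp = next(
        (e for e in sim_config.resolved_edit_plan() if max(e.freq_per_stage) > 0.5),
        None,
    )
    if ramp is not None and bundle.get("events_per_stage"):
        from .editing import wt_vs_edited_series

        p_canonical = 1.0 - sum(sim_config.isomir_rates.values())
        exp_wt = np.array([(1 - f) * p_canonical for f in ramp.freq_per_stage])
        exp_ed = np.array(ramp.freq_per_stage)
        for k in range(len(exp_ed)):
            if exp_ed[k] > exp_wt[k] and np.all(exp_ed[k + 1 :] >= exp_wt[k + 1 :]):
                crossing_planted = k
                break
        matrix = bundle["mirna_matrix"]
        wt_per_stage = {
            label: float(matrix.loc[ramp.mirna_id, label])
            if ramp.mirna_id in matrix.index and label in matrix.columns
            else 0.0
            for label in bundle["events_per_stage"]
        }
        try:
            _, _, crossing_detected = wt_vs_edited_series(
                ramp.mirna_id, ramp.position, ramp.alt_base,
                bundle["events_per_stage"], wt_per_stage,
            )
        except ValueError:
            crossing_detected = None

    rows = [
        ("class_accuracy", class_acc),
        ("class_scored_read_fraction", scored_frac),
        ("isomir_category_accuracy", iso_acc),
        ("editing_recall_tpm50", edit_scores["recall"]),
        ("editing_false_high_events", edit_scores["false_high_events"]),
        ("snp_surviving_events", snp_surviving),
        ("hairpin_planted_acceptance", hairpin_acc),
        ("editing_enrichment_ratio", bundle.get("editing_enrichment")),
        ("replicate_r_min", min(corr) if corr else float("nan")),
        ("replicate_r_max", max(corr) if corr else float("nan")),
        (
            "edited_fraction_monotone",
            float(all(b > a for a, b in zip(fractions, fractions[1:])))
            if fractions
            else float("nan"),
        ),
        (
            "isomir_top_category_always_7",
            float(all(v == 7 for v in spectrum_top.values()))
            if spectrum_top
            else float("nan"),
        ),
        (
            "crossing_stage_planted",
            float(crossing_planted) if crossing_planted is not None else float("nan"),
        ),
        (
            "crossing_stage_detected",
            float(crossing_detected)
            if crossing_detected is not None
            else float("nan"),
        ),
    ]
    scorecard = pd.DataFrame(rows, columns=["metric", "value"])
    scorecard.to_csv(
        Path(run_config.outdir) / "scorecard.tsv", sep="\t", index=False
    )
    return bundle, scorecard
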