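"""Synthetic small-RNA read sets with fully known planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: multi-stage read sets of 18-30 nt dominated by a ~22 nt miRNA
fraction, a declared class-composition mixture, isomiRs in all 8 end-offset
categories with 3' trimming dominant, single-base editing events planted at
seed (2-8) and flank (12-15) positions with stage-increasing frequencies,
heterozygous-like SNP positions, residual sequencing-error noise, and paired
technical replicates drawn from a shared tag-abundance law.

Abundance model: per-miRNA base weights are log-normal; a small set of
*anchor* miRNAs (those carrying planted edits or SNPs) get a fixed elevated
weight so that planted events are comfortably detectable at the simulated
depth.  Stage profiles multiply the base weight by an archetype shape
(increasing / decreasing / mid-peak / mid-trough / flat, assigned
round-robin); each technical replicate additionally re-draws a small
log-normal perturbation of every weight before multinomial sampling, which
reproduces the high-but-imperfect replicate correlation seen in real
technical replicates.

Everything is deterministic given the configuration (including its seed):
two calls with the same ``SimulationConfig`` produce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import NON_MIRNA_CLASSES, ReferenceSet

__all__ = [
    "EditSpec",
    "SimulationConfig",
    "GroundTruth",
    "SimModel",
    "build_model",
    "generate_reference_set",
    "generate_stage_reads",
    "expected_mirna_tpm_matrix",
    "default_class_mixture",
    "default_isomir_rates",
    "default_edit_plan",
    "default_snp_plan",
]

_BASES = "ACGT"
_ARCHETYPES = ("increasing", "decreasing", "mid_peak", "mid_trough", "flat")
# alt base used for planted SNP positions, by reference base
_SNP_ALT = {"A": "G", "C": "T", "G": "A", "T": "C"}


def default_class_mixture() -> dict[str, float]:
    return {
        "miRNA": 0.68,
        "novel": 0.02,
        "rRNA": 0.08,
        "tRNA": 0.05,
        "snRNA": 0.03,
        "snoRNA": 0.03,
        "scRNA": 0.02,
        "srpRNA": 0.02,
        "piRNA": 0.03,
        "repeat": 0.02,
        "exon": 0.01,
        "intron": 0.01,
    }


def default_isomir_rates() -> dict[int, float]:
    """Per-miRNA-read isomiR category probabilities (remainder = canonical).

    3' trimming (category 7) is weighted highest, matching the dominant mode
    in small-RNA libraries; all 8 categories are producible.
    """
    return {1: 0.01, 2: 0.015, 3: 0.04, 4: 0.015, 5: 0.03, 6: 0.03, 7: 0.15, 8: 0.02}


@dataclass(frozen=True)
class EditSpec:
    """A planted single-base editing event on one mature miRNA."""

    mirna_id: str
    position: int  # 1-based from the mature 5' end
    ref_base: str
    alt_base: str
    freq_per_stage: tuple[float, ...]  # fraction of that miRNA's reads edited


def _ramp(f0: float, n_stages: int, growth: float = 2.0, cap: float = 0.85):
    return tuple(min(cap, f0 * growth**s) for s in range(n_stages))


def default_edit_plan(n_stages: int) -> list[EditSpec]:
    """Six A->G events on anchor miRNAs: four in the seed, two in the flank.

    Frequencies increase with stage; the mir-3 event follows a linear ramp
    from 0.2 to 0.8 so the edited form overtakes the wild type mid-course.
    """
    crossing = tuple(np.linspace(0.2, 0.8, n_stages))
    return [
        EditSpec("mir-1", 3, "A", "G", _ramp(0.10, n_stages)),
        EditSpec("mir-2", 5, "A", "G", _ramp(0.15, n_stages)),
        EditSpec("mir-3", 6, "A", "G", crossing),
        EditSpec("mir-4", 8, "A", "G", _ramp(0.20, n_stages)),
        EditSpec("mir-5", 13, "A", "G", _ramp(0.12, n_stages)),
        EditSpec("mir-6", 14, "A", "G", _ramp(0.25, n_stages)),
    ]


def default_snp_plan() -> list[tuple[str, int]]:
    return [("mir-7", 10), ("mir-8", 10), ("mir-9", 11)]


@dataclass
class SimulationConfig:
    rng_seed: int = 1
    n_stages: int = 3
    reads_per_replicate: int = 10_000
    class_mixture: dict[str, float] = field(default_factory=default_class_mixture)
    mirna_count: int = 60
    mature_length_range: tuple[int, int] = (20, 24)
    isomir_rates: dict[int, float] = field(default_factory=default_isomir_rates)
    edit_plan: list[EditSpec] | None = None  # None -> default_edit_plan(n_stages)
    snp_plan: list[tuple[str, int]] | None = None  # None -> default_snp_plan()
    # residual per-base error rate of the clean-read set.  Dual-replicate
    # concordance at this depth promotes any duplicated error tag above the
    # 50-TPM editing gate, so the clean-read residual must be very small;
    # see the methods note for the derivation of the feasible range.
    seq_error_rate: float = 1e-5
    # log-normal spread of per-miRNA base weights
    abundance_sigma: float = 1.2
    # per-replicate technical log-normal jitter of tag weights
    replicate_jitter_sigma: float = 0.25
    # fixed weight given to anchor (edit/SNP-carrying) miRNAs
    anchor_weight: float = 4.0
    # explicit per-miRNA weight overrides (id -> weight); overrides anchors too
    weight_overrides: dict[str, float] = field(default_factory=dict)
    # heterozygous-like alt fraction at planted SNP positions
    snp_alt_fraction: float = 0.5
    # stage whose rRNA proportion is tripled (early-development rRNA peak);
    # None disables the spike
    rrna_spike_stage: int | None = 0
    novel_mirna_count: int = 2
    decoys_per_class: int = 8
    decoy_length_range: tuple[int, int] = (60, 200)
    precursor_arm_ext: int = 5  # templated nt kept on each side of the mature
    precursor_loop_len: int = 8
    genome_spacer: int = 50
    stage_labels: list[str] | None = None

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in __import__("dataclasses").fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        if "edit_plan" in raw and raw["edit_plan"] is not None:
            raw["edit_plan"] = [
                EditSpec(
                    e["mirna_id"], e["position"], e["ref_base"], e["alt_base"],
                    tuple(e["freq_per_stage"]),
                )
                for e in raw["edit_plan"]
            ]
        if "snp_plan" in raw and raw["snp_plan"] is not None:
            raw["snp_plan"] = [tuple(x) for x in raw["snp_plan"]]
        for key in ("mature_length_range", "decoy_length_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def resolved_edit_plan(self) -> list[EditSpec]:
        return (
            default_edit_plan(self.n_stages)
            if self.edit_plan is None
            else self.edit_plan
        )

    def resolved_snp_plan(self) -> list[tuple[str, int]]:
        return default_snp_plan() if self.snp_plan is None else self.snp_plan

    def labels(self) -> list[str]:
        if self.stage_labels is not None:
            return list(self.stage_labels)
        return [f"stage{i}" for i in range(self.n_stages)]

    def validate(self) -> None:
        probs = list(self.class_mixture.values())
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("class_mixture must be non-negative and sum to 1")
        lo, hi = self.mature_length_range
        if lo < 18 or hi > 30 or lo > hi:
            raise ValueError(
                "mature_length_range must lie within [18, 30] "
                "(tags outside it are removed by the clean-read gate)"
            )
        if self.mirna_count < 1:
            raise ValueError("mirna_count must be >= 1")
        if any(not (0 <= r <= 1) for r in self.isomir_rates.values()) or sum(
            self.isomir_rates.values()
        ) > 1:
            raise ValueError("isomir_rates must be probabilities summing to <= 1")
        if not set(self.isomir_rates) <= set(range(1, 9)):
            raise ValueError("isomir_rates keys must be categories 1..8")
        edit_positions: dict[str, set[int]] = {}
        for e in self.resolved_edit_plan():
            if len(e.freq_per_stage) != self.n_stages:
                raise ValueError(f"edit {e.mirna_id}: needs {self.n_stages} frequencies")
            if not (1 <= e.position <= lo):
                raise ValueError(
                    f"edit {e.mirna_id}: position {e.position} outside mature"
                )
            edit_positions.setdefault(e.mirna_id, set()).add(e.position)
        for mid, pos in self.resolved_snp_plan():
            if pos in edit_positions.get(mid, set()):
                raise ValueError(
                    f"SNP and edit positions overlap for {mid} at {pos}"
                )
        if not (0 <= self.seq_error_rate < 0.1):
            raise ValueError("seq_error_rate must be a small probability")
        if "novel" in self.class_mixture and self.class_mixture["novel"] > 0:
            if self.novel_mirna_count < 1:
                raise ValueError("novel reads requested but novel_mirna_count < 1")


@dataclass
class SimModel:
    """Deterministic realization of the planted world for one configuration."""

    config: SimulationConfig
    matures: dict[str, str]
    precursors: dict[str, str]
    mature_offsets: dict[str, list[tuple[str, int]]]
    novel_matures: dict[str, str]
    novel_precursors: dict[str, str]
    class_libraries: dict[str, dict[str, str]]
    genome: dict[str, str]
    snp_table: set[tuple[str, int]]
    base_weights: np.ndarray  # per-miRNA, stage-independent
    modulation: np.ndarray  # (mirna_count, n_stages) archetype factors
    archetypes: dict[str, str]
    edit_by_mirna: dict[str, list[EditSpec]]
    snp_by_mirna: dict[str, list[int]]

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.matures.keys())

    def stage_weights(self, stage_index: int) -> np.ndarray:
        w = self.base_weights * self.modulation[:, stage_index]
        return w / w.sum()

    def stage_mixture(self, stage_index: int) -> dict[str, float]:
        mix = dict(self.config.class_mixture)
        if (
            self.config.rrna_spike_stage == stage_index
            and mix.get("rRNA", 0) > 0
        ):
            mix["rRNA"] *= 3.0
            total = sum(mix.values())
            mix = {k: v / total for k, v in mix.items()}
        return mix


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _make_precursor(
    mature: str, rng: np.random.Generator, ext: int, loop_len: int
) -> tuple[str, int]:
    """Arm + loop + reverse-complement arm; the mature sits on the 5' arm.

    The arm keeps ``ext`` templated nt on each side of the mature so that
    templated 5'/3' isomiR additions are realizable; the fold-back complement
    guarantees a deep stem by construction.  Returns (precursor, mature
    offset).
    """
    arm = _random_seq(rng, ext) + mature + _random_seq(rng, ext)
    loop = _random_seq(rng, loop_len)
    return arm + loop + _revcomp(arm), ext


def _archetype_factors(label: str, n_stages: int) -> np.ndarray:
    s = np.arange(n_stages)
    if label == "increasing":
        return np.geomspace(1.0, 8.0, n_stages)
    if label == "decreasing":
        return np.geomspace(8.0, 1.0, n_stages)
    mid = (n_stages - 1) / 2.0
    # triangular in log space between 1 at the ends and 8 (or 1/8) mid-course
    shape = 1.0 - np.abs(s - mid) / mid if n_stages > 1 else np.ones(1)
    if label == "mid_peak":
        return 8.0**shape
    if label == "mid_trough":
        return 8.0 ** (-shape)
    return np.ones(n_stages)


def build_model(config: SimulationConfig) -> SimModel:
    """Materialize references, abundance law and planted truth for a config."""
    config.validate()
    rng = np.random.default_rng([config.rng_seed % 2**31, 11])
    lo, hi = config.mature_length_range
    edit_by_mirna: dict[str, list[EditSpec]] = {}
    for e in config.resolved_edit_plan():
        edit_by_mirna.setdefault(e.mirna_id, []).append(e)
    snp_by_mirna: dict[str, list[int]] = {}
    for mid, pos in config.resolved_snp_plan():
        snp_by_mirna.setdefault(mid, []).append(pos)

    matures: dict[str, str] = {}
    precursors: dict[str, str] = {}
    offsets: dict[str, list[tuple[str, int]]] = {}
    for i in range(config.mirna_count):
        mid = f"mir-{i + 1}"
        length = int(rng.integers(lo, hi + 1))
        seq = list(_random_seq(rng, length))
        for e in edit_by_mirna.get(mid, []):
            if e.position > length:
                raise ValueError(
                    f"edit position {e.position} exceeds mature length {length}"
                )
            seq[e.position - 1] = e.ref_base
        mseq = "".join(seq)
        matures[mid] = mseq
        pid = f"pre-{mid}"
        pseq, off = _make_precursor(
            mseq, rng, config.precursor_arm_ext, config.precursor_loop_len
        )
        precursors[pid] = pseq
        offsets[pid] = [(mid, off)]

    novel_matures: dict[str, str] = {}
    novel_precursors: dict[str, str] = {}
    for i in range(config.novel_mirna_count):
        nid = f"novel-{i + 1}"
        mseq = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        novel_matures[nid] = mseq
        pseq, _ = _make_precursor(
            mseq, rng, config.precursor_arm_ext, config.precursor_loop_len
        )
        novel_precursors[f"pre-{nid}"] = pseq

    class_libraries: dict[str, dict[str, str]] = {}
    dlo, dhi = config.decoy_length_range
    for cls in NON_MIRNA_CLASSES:
        lib = {}
        for k in range(config.decoys_per_class):
            lib[f"{cls}-{k + 1}"] = _random_seq(
                rng, int(rng.integers(dlo, dhi + 1))
            )
        class_libraries[cls] = lib

    spacer = config.genome_spacer
    parts = []
    for pseq in list(precursors.values()) + list(novel_precursors.values()):
        parts.append(_random_seq(rng, spacer))
        parts.append(pseq)
    parts.append(_random_seq(rng, spacer))
    genome = {"chr1": "".join(parts)}

    snp_table = {(mid, pos) for mid, pos in config.resolved_snp_plan()}

    anchors = set(edit_by_mirna) | set(snp_by_mirna)
    base_weights = rng.lognormal(0.0, config.abundance_sigma, config.mirna_count)
    ids = list(matures.keys())
    archetypes: dict[str, str] = {}
    arch_cycle = 0
    for i, mid in enumerate(ids):
        if mid in config.weight_overrides:
            base_weights[i] = config.weight_overrides[mid]
            archetypes[mid] = "flat"
        elif mid in anchors:
            base_weights[i] = config.anchor_weight
            archetypes[mid] = "flat"
        else:
            archetypes[mid] = _ARCHETYPES[arch_cycle % len(_ARCHETYPES)]
            arch_cycle += 1
    modulation = np.column_stack(
        [
            _archetype_factors(archetypes[mid], config.n_stages)
            for mid in ids
        ]
    ).T

    return SimModel(
        config=config,
        matures=matures,
        precursors=precursors,
        mature_offsets=offsets,
        novel_matures=novel_matures,
        novel_precursors=novel_precursors,
        class_libraries=class_libraries,
        genome=genome,
        snp_table=snp_table,
        base_weights=base_weights,
        modulation=modulation,
        archetypes=archetypes,
        edit_by_mirna=edit_by_mirna,
        snp_by_mirna=snp_by_mirna,
    )


def generate_reference_set(config: SimulationConfig) -> ReferenceSet:
    """Reference libraries realizing the configuration's planted world.

    Novel precursors are present in the genome but deliberately absent from
    the mature/precursor libraries, so their reads annotate as genome_only
    and exercise the hairpin caller.
    """
    model = build_model(config)
    refset = ReferenceSet(
        mature=model.matures,
        precursors=model.precursors,
        mature_offsets=model.mature_offsets,
        class_libraries=model.class_libraries,
        genome=model.genome,
        snp_table=model.snp_table,
    )
    refset.validate()
    return refset


@dataclass
class GroundTruth:
    """Planted truth for one stage (both replicates)."""

    stage_index: int
    stage_label: str
    reads: pd.DataFrame  # replicate, sequence, class_label, source_id,
    # isomir_category, edit_label, snp_alt, has_error
    expected_mirna_tpm: pd.Series  # per mature, this stage (all isoforms)
    planted_edits: pd.DataFrame  # mature_id, position, ref, alt, frequency,
    # expected_tpm


def expected_mirna_tpm_matrix(config: SimulationConfig) -> pd.DataFrame:
    """Expected TPM of each mature miRNA at each stage under the model."""
    model = build_model(config)
    mix_mirna = [
        model.stage_mixture(s).get("miRNA", 0.0) for s in range(config.n_stages)
    ]
    cols = {}
    for s, label in enumerate(config.labels()):
        cols[label] = model.stage_weights(s) * mix_mirna[s] * 1e6
    return pd.DataFrame(cols, index=model.mirna_ids)


def _apply_isomir(
    mature: str,
    prec: str,
    moff: int,
    category: int,
    rng: np.random.Generator,
) -> str:
    """Realize an isomiR of the given category from its precursor context."""
    add5 = category in (1, 2, 4)
    trim5 = category in (5, 6, 8)
    add3 = category in (1, 3, 8)
    trim3 = category in (4, 6, 7)
    d5 = 0
    if add5:
        d5 = -int(rng.integers(1, 3))
    elif trim5:
        d5 = int(rng.integers(1, 3))
    d3 = 0
    if add3:
        d3 = int(rng.integers(1, 3))
    elif trim3:
        d3 = -1 if rng.random() < 0.7 else -2
    start = moff + d5
    end = moff + len(mature) + min(d3, 0)
    core = prec[start:end]
    if d3 > 0:
        if rng.random() < 0.5:  # templated 3' extension
            core = prec[start : end + d3]
        else:  # non-templated tail: must disagree with the template
            tail = []
            for k in range(d3):
                templ = prec[end + k] if end + k < len(prec) else "A"
                choices = [b for b in _BASES if b != templ]
                tail.append(choices[int(rng.integers(3))])
            core = core + "".join(tail)
    return core


def generate_stage_reads(
    refset: ReferenceSet,
    config: SimulationConfig,
    stage_index: int,
) -> tuple[list[str], list[str], GroundTruth]:
    """Two technical-replicate read sets plus the planted truth for a stage."""
    if stage_index >= config.n_stages:
        raise ValueError("stage_index out of range")
    model = build_model(config)
    for cls in config.class_mixture:
        if cls in ("miRNA", "novel"):
            continue
        if cls not in refset.class_libraries or not refset.class_libraries[cls]:
            raise ValueError(f"class_mixture names {cls!r} but no library exists")

    mixture = model.stage_mixture(stage_index)
    classes = list(mixture.keys())
    probs = np.array([mixture[c] for c in classes])
    ids = model.mirna_ids
    novel_ids = list(model.novel_matures.keys())
    mlen_mean = sum(len(s) for s in model.matures.values()) / len(model.matures)
    iso_cats = sorted(config.isomir_rates)
    iso_probs = [config.isomir_rates[c] for c in iso_cats]
    p_canonical = 1.0 - sum(iso_probs)

    replicate_frames = []
    for rep in (1, 2):
        rng = np.random.default_rng(
            [config.rng_seed % 2**31, 23, stage_index, rep]
        )
        class_counts = rng.multinomial(config.reads_per_replicate, probs)
        w = model.stage_weights(stage_index)
        w = w * rng.lognormal(0.0, config.replicate_jitter_sigma, len(w))
        w = w / w.sum()
        rows = []
        for cls, n_reads in zip(classes, class_counts):
            if n_reads == 0:
                continue
            if cls == "miRNA":
                picks = rng.choice(len(ids), size=n_reads, p=w)
                u_edit = rng.random(n_reads)
                u_snp = rng.random(n_reads)
                u_cat = rng.random(n_reads)
                for r in range(n_reads):
                    mid = ids[picks[r]]
                    mature = model.matures[mid]
                    pid = f"pre-{mid}"
                    prec = model.precursors[pid]
                    moff = model.mature_offsets[pid][0][1]
                    edit_label = ""
                    snp_alt = False
                    category: int | str = "canonical"
                    seq = mature
                    edits = model.edit_by_mirna.get(mid, [])
                    fired = None
                    acc = 0.0
                    for e in edits:
                        acc += e.freq_per_stage[stage_index]
                        if u_edit[r] < acc:
                            fired = e
                            break
                    if fired is not None:
                        seq = (
                            mature[: fired.position - 1]
                            + fired.alt_base
                            + mature[fired.position :]
                        )
                        edit_label = (
                            f"{mid}:{fired.position}:"
                            f"{fired.ref_base}>{fired.alt_base}"
                        )
                    elif (
                        mid in model.snp_by_mirna
                        and u_snp[r] < config.snp_alt_fraction
                    ):
                        pos = model.snp_by_mirna[mid][0]
                        alt = _SNP_ALT[mature[pos - 1]]
                        seq = mature[: pos - 1] + alt + mature[pos:]
                        snp_alt = True
                    else:
                        uc = u_cat[r]
                        acc = p_canonical
                        if uc >= acc:
                            for cat, pr in zip(iso_cats, iso_probs):
                                acc += pr
                                if uc < acc:
                                    category = cat
                                    break
                            seq = _apply_isomir(mature, prec, moff, category, rng)
                    rows.append((cls, mid, category, edit_label, snp_alt, seq))
            elif cls == "novel":
                picks = rng.integers(0, len(novel_ids), size=n_reads)
                for r in range(n_reads):
                    nid = novel_ids[picks[r]]
                    rows.append((cls, nid, "", "", False, model.novel_matures[nid]))
            else:
                lib = model.class_libraries[cls]
                lib_ids = list(lib.keys())
                picks = rng.integers(0, len(lib_ids), size=n_reads)
                lens = rng.integers(18, 31, size=n_reads)
                for r in range(n_reads):
                    rid = lib_ids[picks[r]]
                    ref = lib[rid]
                    L = min(int(lens[r]), len(ref))
                    start = int(rng.integers(0, len(ref) - L + 1))
                    rows.append((cls, rid, "", "", False, ref[start : start + L]))
        # residual sequencing errors, independent per replicate
        seqs = [r[5] for r in rows]
        has_error = np.zeros(len(rows), dtype=bool)
        if config.seq_error_rate > 0:
            p_read = np.array(
                [1.0 - (1.0 - config.seq_error_rate) ** len(s) for s in seqs]
            )
            hit = rng.random(len(rows)) < p_read
            for r in np.flatnonzero(hit):
                s = seqs[r]
                pos = int(rng.integers(len(s)))
                alt = _BASES[
                    ("ACGT".index(s[pos]) + 1 + int(rng.integers(3))) % 4
                ]
                seqs[r] = s[:pos] + alt + s[pos + 1 :]
                has_error[r] = True
        frame = pd.DataFrame(
            {
                "replicate": rep,
                "class_label": [r[0] for r in rows],
                "source_id": [r[1] for r in rows],
                "isomir_category": [str(r[2]) for r in rows],
                "edit_label": [r[3] for r in rows],
                "snp_alt": [r[4] for r in rows],
                "has_error": has_error,
                "sequence": seqs,
            }
        )
        replicate_frames.append(frame)

    reads_df = pd.concat(replicate_frames, ignore_index=True)
    w_expected = model.stage_weights(stage_index)
    expected_tpm = pd.Series(
        w_expected * mixture.get("miRNA", 0.0) * 1e6, index=ids
    )
    edit_rows = []
    for mid, especs in model.edit_by_mirna.items():
        for e in especs:
            f = e.freq_per_stage[stage_index]
            edit_rows.append(
                {
                    "mature_id": mid,
                    "position": e.position,
                    "ref_base": e.ref_base,
                    "alt_base": e.alt_base,
                    "frequency": f,
                    "expected_tpm": float(expected_tpm.get(mid, 0.0)) * f,
                }
            )
    planted_edits = pd.DataFrame(
        edit_rows,
        columns=[
            "mature_id",
            "position",
            "ref_base",
            "alt_base",
            "frequency",
            "expected_tpm",
        ],
    )
    truth = GroundTruth(
        stage_index=stage_index,
        stage_label=config.labels()[stage_index],
        reads=reads_df,
        expected_mirna_tpm=expected_tpm,
        planted_edits=planted_edits,
    )
    rep1 = reads_df.loc[reads_df.replicate == 1, "sequence"].tolist()
    rep2 = reads_df.loc[reads_df.replicate == 2, "sequence"].tolist()
    return rep1, rep2, truth
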