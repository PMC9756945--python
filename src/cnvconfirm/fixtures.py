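"""Synthetic cohort generator: every pipeline stage testable without data.

The simulator emulates the statistical structure the method assumes of real
exome cohorts: per-target read depth follows a negative binomial around a
mean shaped by a smooth unimodal GC-bias curve, a shared per-target capture
efficiency and a per-sample sequencing-depth scale; families are trios whose
children carry rare CNVs that are inherited from one parent with high
probability (true de novo events are rare); heterozygous deletions and
duplications scale the depth mean by 0.5x / 1.5x over 2-40 contiguous
targets; artifacts are localized depth wobbles (0.7-0.8x or 1.2-1.3x over
2-5 targets) that get reported as calls but have no underlying CNV.  A
WGS-style standard set contains exactly the simulated truth, and a caller
emulator reports each truth CNV through 1-3 callers with jittered
breakpoints while artifacts stay single-caller.

Cohort frequencies are drawn, not counted: the simulated cohort stands in
for the rare-variant regime of a much larger population, so truth and
artifact calls carry frequencies well below 1% while dedicated decoy calls
exercise the frequency, target-count, segmental-duplication and autosome
filters.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .calls import CNVCall, write_calls_tsv
from .depthio import RAW, CaptureTarget, DepthMatrix
from .errors import ValidationError
from .evaluation import StandardSet
from .imaging import RenderStyle, encode_cnv_image
from .references import select_references
from .trio_labeling import ARTIFACT, RARE_DEL, RARE_DUP, Pedigree, RegionScores

_CALLERS = ("xhmm", "canoes", "clamms")


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic cohort (all rates per sample)."""

    n_families: int = 50
    n_targets: int = 1200
    n_chromosomes: int = 22
    target_length_range: tuple[int, int] = (120, 300)
    target_gap_range: tuple[int, int] = (500, 30000)
    gc_beta: tuple[float, float] = (2.5, 2.5)  # over [0.2, 0.8]
    depth_mean: float = 100.0
    nb_size: float = 33.3  # NB dispersion: CV ~= 0.2 at mean 100
    gc_bias_base: float = 0.8
    gc_bias_amplitude: float = 0.4
    gc_bias_center: float = 0.45
    gc_bias_width: float = 0.15
    target_efficiency_sigma: float = 0.15
    sample_scale_sigma: float = 0.10
    cnv_rate: float = 2.0  # expected CNVs per child
    cnv_size_range: tuple[int, int] = (2, 40)
    del_multiplier: float = 0.5
    dup_multiplier: float = 1.5
    inheritance_probability: float = 0.95
    parent_miss_rate: float = 0.05  # inherited CNV absent from parent's calls
    artifact_rate: float = 1.0
    artifact_size_range: tuple[int, int] = (2, 5)
    artifact_low: tuple[float, float] = (0.7, 0.8)
    artifact_high: tuple[float, float] = (1.2, 1.3)
    decoy_rate: float = 0.5  # filter-exercising junk calls per child
    n_segdups: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.del_multiplier <= 0 or self.dup_multiplier <= 0:
            raise ValidationError("copy-number multipliers must be > 0")
        if not 0 <= self.inheritance_probability <= 1:
            raise ValidationError("inheritance_probability outside [0, 1]")
        if self.cnv_size_range[1] > self.n_targets // self.n_chromosomes:
            raise ValidationError(
                "largest CNV exceeds the number of targets per chromosome"
            )


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    targets: list[CaptureTarget]
    matrix: DepthMatrix  # raw depth
    pedigree: Pedigree
    truth_calls: list[CNVCall]  # one record per carrier sample
    artifact_calls: list[CNVCall]
    standard: StandardSet
    parent_nq: dict[str, RegionScores]
    segdups: list[tuple[str, int, int]]
    decoy_calls: list[CNVCall] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.sample_ids)


def gc_bias_curve(gc: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Smooth unimodal multiplicative bias as a function of GC fraction."""
    return config.gc_bias_base + config.gc_bias_amplitude * np.exp(
        -((gc - config.gc_bias_center) ** 2) / (2 * config.gc_bias_width**2)
    )


def _make_targets(config: SimulationConfig, rng: np.random.Generator) -> list[CaptureTarget]:
    per_chrom = np.full(config.n_chromosomes, config.n_targets // config.n_chromosomes)
    per_chrom[: config.n_targets % config.n_chromosomes] += 1
    targets: list[CaptureTarget] = []
    for ci, n in enumerate(per_chrom, start=1):
        pos = 1_000_000
        for _ in range(n):
            length = int(rng.integers(*config.target_length_range))
            gc = 0.2 + 0.6 * rng.beta(*config.gc_beta)
            targets.append(CaptureTarget(f"chr{ci}", pos, pos + length, float(gc)))
            pos += length + int(rng.integers(*config.target_gap_range))
    return targets


def _chrom_runs(targets: list[CaptureTarget]) -> dict[str, tuple[int, int]]:
    """chrom -> (first index, last index + 1) in the target list."""
    runs: dict[str, tuple[int, int]] = {}
    for i, t in enumerate(targets):
        lo, _ = runs.get(t.chrom, (i, i))
        runs[t.chrom] = (lo, i + 1)
    return runs


def _place_region(
    rng: np.random.Generator,
    runs: dict[str, tuple[int, int]],
    size: int,
    occupied: set[int],
    max_tries: int = 30,
) -> tuple[str, int, int] | None:
    """A contiguous target-index run of ``size`` avoiding ``occupied``."""
    chroms = sorted(runs)
    for _ in range(max_tries):
        chrom = chroms[int(rng.integers(len(chroms)))]
        lo, hi = runs[chrom]
        if hi - lo < size:
            continue
        i0 = int(rng.integers(lo, hi - size + 1))
        idx = range(i0, i0 + size)
        if occupied.isdisjoint(idx):
            return chrom, i0, i0 + size
    return None


def simulate_cohort(config: SimulationConfig | None = None) -> SimulatedCohort:
    """Draw a full synthetic trio cohort from the configured conditions."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    targets = _make_targets(config, rng)
    runs = _chrom_runs(targets)
    n_targets = len(targets)

    samples: list[str] = []
    trios: list[tuple[str, str, str]] = []
    for f in range(config.n_families):
        fa, mo, ch = (f"fam{f:03d}_{r}" for r in ("fa", "mo", "ch"))
        samples += [fa, mo, ch]
        trios.append((ch, fa, mo))
    pedigree = Pedigree(trios=trios)

    mult = {s: np.ones(n_targets) for s in samples}
    occupied = {s: set() for s in samples}
    truth_calls: list[CNVCall] = []
    artifact_calls: list[CNVCall] = []
    rare_freq = lambda: float(rng.uniform(0.0005, 0.008))

    def add_cnv(sample: str, chrom: str, i0: int, i1: int, cnv_type: str, freq: float):
        m = config.del_multiplier if cnv_type == "DEL" else config.dup_multiplier
        mult[sample][i0:i1] *= m
        occupied[sample].update(range(i0, i1))
        truth_calls.append(
            CNVCall(
                sample_id=sample,
                chrom=chrom,
                start=targets[i0].start,
                end=targets[i1 - 1].end,
                cnv_type=cnv_type,
                num_targets=i1 - i0,
                cohort_frequency=freq,
            )
        )

    # rare CNVs: drawn per child, copied into one parent when inherited
    for ch, fa, mo in trios:
        for _ in range(rng.poisson(config.cnv_rate)):
            size = int(rng.integers(config.cnv_size_range[0], config.cnv_size_range[1] + 1))
            carriers = [ch]
            if rng.random() < config.inheritance_probability:
                carriers.append(fa if rng.random() < 0.5 else mo)
            occ = set().union(*(occupied[s] for s in carriers))
            region = _place_region(rng, runs, size, occ)
            if region is None:
                continue
            chrom, i0, i1 = region
            cnv_type = "DEL" if rng.random() < 0.5 else "DUP"
            freq = rare_freq()
            for s in carriers:
                add_cnv(s, chrom, i0, i1, cnv_type, freq)

    # artifacts: localized depth wobble emitted as a false call, any sample
    for s in samples:
        for _ in range(rng.poisson(config.artifact_rate)):
            size = int(rng.integers(config.artifact_size_range[0], config.artifact_size_range[1] + 1))
            region = _place_region(rng, runs, size, occupied[s])
            if region is None:
                continue
            chrom, i0, i1 = region
            if rng.random() < 0.5:
                m = float(rng.uniform(*config.artifact_low))
                cnv_type = "DEL"
            else:
                m = float(rng.uniform(*config.artifact_high))
                cnv_type = "DUP"
            mult[s][i0:i1] *= m
            occupied[s].update(range(i0, i1))
            artifact_calls.append(
                CNVCall(
                    sample_id=s,
                    chrom=chrom,
                    start=targets[i0].start,
                    end=targets[i1 - 1].end,
                    cnv_type=cnv_type,
                    num_targets=i1 - i0,
                    cohort_frequency=rare_freq(),
                )
            )

    # depth draw: NB around mu * gc_bias * target efficiency * sample scale
    gc = np.array([t.gc_fraction for t in targets])
    eff = rng.lognormal(0.0, config.target_efficiency_sigma, size=n_targets)
    base_mean = config.depth_mean * gc_bias_curve(gc, config) * eff
    scale = rng.lognormal(0.0, config.sample_scale_sigma, size=len(samples))
    values = np.empty((len(samples), n_targets))
    for i, s in enumerate(samples):
        mean = np.maximum(base_mean * scale[i] * mult[s], 1e-6)
        p = config.nb_size / (config.nb_size + mean)
        values[i] = rng.negative_binomial(config.nb_size, p)
    matrix = DepthMatrix(samples, targets, values, state=RAW)

    # WGS-style standard: exactly the simulated truth
    std: dict[str, list[tuple[str, int, int, str]]] = {s: [] for s in samples}
    for c in truth_calls:
        std[c.sample_id].append((c.chrom, c.start, c.end, c.cnv_type))
    standard = StandardSet(std, source="union")

    # parental no-CNV scores: low wherever the parent truly carries a CNV
    parent_nq: dict[str, RegionScores] = {}
    for s in samples:
        low = [
            (c.chrom, c.start, c.end, float(rng.uniform(0, 20)))
            for c in truth_calls
            if c.sample_id == s
        ]
        parent_nq[s] = RegionScores(low, default=95.0)

    # segmental-duplication track (random, unrelated to the CNVs)
    segdups: list[tuple[str, int, int]] = []
    for _ in range(config.n_segdups):
        region = _place_region(rng, runs, 3, set())
        if region is None:
            continue
        chrom, i0, i1 = region
        segdups.append((chrom, targets[i0].start - 50, targets[i1 - 1].end + 50))
    segdups.sort()

    cohort = SimulatedCohort(
        config=config,
        targets=targets,
        matrix=matrix,
        pedigree=pedigree,
        truth_calls=truth_calls,
        artifact_calls=artifact_calls,
        standard=standard,
        parent_nq=parent_nq,
        segdups=segdups,
    )
    cohort.decoy_calls = _make_decoys(cohort, rng)
    return cohort


def _make_decoys(cohort: SimulatedCohort, rng: np.random.Generator) -> list[CNVCall]:
    """Junk calls that each violate exactly one candidate filter."""
    config = cohort.config
    runs = _chrom_runs(cohort.targets)
    decoys: list[CNVCall] = []
    kinds = ("common", "single_target", "chrx", "segdup")
    for ch, _fa, _mo in cohort.pedigree.trios:
        for _ in range(rng.poisson(config.decoy_rate)):
            kind = kinds[int(rng.integers(len(kinds)))]
            if kind == "chrx":
                decoys.append(
                    CNVCall(ch, "chrX", 1_000_000, 1_050_000, "DEL", num_targets=3,
                            cohort_frequency=float(rng.uniform(0.0005, 0.008)))
                )
                continue
            if kind == "segdup" and cohort.segdups:
                chrom, s, e = cohort.segdups[int(rng.integers(len(cohort.segdups)))]
                decoys.append(
                    CNVCall(ch, chrom, s + 10, e - 10, "DUP", num_targets=3,
                            cohort_frequency=float(rng.uniform(0.0005, 0.008)))
                )
                continue
            size = 1 if kind == "single_target" else 3
            region = _place_region(rng, runs, size, set())
            if region is None:
                continue
            chrom, i0, i1 = region
            freq = float(rng.uniform(0.02, 0.2)) if kind == "common" else float(
                rng.uniform(0.0005, 0.008)
            )
            decoys.append(
                CNVCall(
                    ch,
                    chrom,
                    cohort.targets[i0].start,
                    cohort.targets[i1 - 1].end,
                    "DEL" if rng.random() < 0.5 else "DUP",
                    num_targets=i1 - i0,
                    cohort_frequency=freq,
                )
            )
    return decoys


def emit_caller_calls(
    cohort: SimulatedCohort,
    jitter: int = 1,
    caller_names: tuple[str, ...] = _CALLERS,
    seed: int | None = None,
) -> dict[str, list[CNVCall]]:
    """Emulate multi-caller output over the simulated truth.

    Each truth CNV is reported by 1-3 callers (an inherited CNV missed in the
    parent with probability ``parent_miss_rate``), with breakpoints jittered
    by up to ``jitter`` targets per side and caller; each artifact and decoy
    is reported by exactly one caller.  SQ is high for truth calls, lower for
    artifacts; NQ on a call mirrors the carrier's regional no-CNV score.
    """
    if jitter < 0:
        raise ValidationError("jitter must be >= 0")
    config = cohort.config
    rng = np.random.default_rng(cohort.config.seed + 7919 if seed is None else seed)
    targets = cohort.targets
    runs = _chrom_runs(targets)
    starts = np.array([t.start for t in targets])
    ends = np.array([t.end for t in targets])
    children = {ch for ch, _f, _m in cohort.pedigree.trios}

    def jittered(call: CNVCall) -> tuple[int, int, int]:
        lo, hi = runs[call.chrom]
        i0 = lo + int(np.searchsorted(starts[lo:hi], call.start))
        i1 = lo + int(np.searchsorted(ends[lo:hi], call.end, side="left")) + 1
        if jitter:
            i0 += int(rng.integers(-jitter, jitter + 1))
            i1 += int(rng.integers(-jitter, jitter + 1))
        i0 = max(lo, min(i0, hi - 2))
        i1 = max(i0 + 2, min(i1, hi))  # keep >= 2 targets
        return targets[i0].start, targets[i1 - 1].end, i1 - i0

    out: dict[str, list[CNVCall]] = {c: [] for c in caller_names}
    for call in cohort.truth_calls:
        inherited_parent = call.sample_id not in children
        if inherited_parent and rng.random() < config.parent_miss_rate:
            continue  # parental false negative
        n = int(rng.integers(1, len(caller_names) + 1))
        chosen = rng.choice(len(caller_names), size=n, replace=False)
        for ci in sorted(chosen):
            s, e, nt = jittered(call)
            out[caller_names[ci]].append(
                call.with_(
                    start=s,
                    end=e,
                    num_targets=nt,
                    callers=frozenset({caller_names[ci]}),
                    quality={"SQ": float(rng.uniform(60, 99))},
                )
            )
    for call in cohort.artifact_calls + cohort.decoy_calls:
        ci = int(rng.integers(len(caller_names)))
        out[caller_names[ci]].append(
            call.with_(
                callers=frozenset({caller_names[ci]}),
                quality={"SQ": float(rng.uniform(20, 60))},
            )
        )
    for calls in out.values():
        calls.sort(key=lambda c: (c.sample_id, c.chrom, c.start, c.end))
    return out


def calls_by_sample(calls_by_caller: dict[str, list[CNVCall]]) -> dict[str, list[CNVCall]]:
    by_sample: dict[str, list[CNVCall]] = {}
    for calls in calls_by_caller.values():
        for c in calls:
            by_sample.setdefault(c.sample_id, []).append(c)
    return by_sample


def truth_image_pairs(cohort: SimulatedCohort) -> list[tuple[CNVCall, str]]:
    """(call, class) pairs straight from simulation truth, for training-set
    construction with known labels: every truth carrier yields a rare-CNV
    image, every artifact an artifact image."""
    label = {"DEL": RARE_DEL, "DUP": RARE_DUP}
    pairs = [(c, label[c.cnv_type]) for c in cohort.truth_calls]
    pairs += [(c, ARTIFACT) for c in cohort.artifact_calls]
    return pairs


def render_image_set(
    pairs: list[tuple[CNVCall, str]],
    matrix: DepthMatrix,
    pedigree: Pedigree,
    k_references: int = 100,
    flank_targets: int | None = None,
    style: RenderStyle | None = None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Encode each (call, label) pair; returns (images, labels, cnv keys).

    Reference panels exclude the carrier's family members so inherited CNVs
    keep their depth contrast.
    """
    images, labels, keys = [], [], []
    panel_cache: dict[str, object] = {}
    for call, label in pairs:
        if call.sample_id not in panel_cache:
            panel_cache[call.sample_id] = select_references(
                matrix,
                call.sample_id,
                k=k_references,
                exclude=pedigree.family_members(call.sample_id),
            )
        img = encode_cnv_image(
            call, matrix, panel_cache[call.sample_id], flank_targets, style
        )
        images.append(img.pixels)
        labels.append(label)
        keys.append(call.key)
    return np.stack(images), labels, keys


def write_cohort(
    cohort: SimulatedCohort,
    calls_by_caller: dict[str, list[CNVCall]],
    outdir: str,
) -> None:
    """Write every standard format the pipeline reads."""
    os.makedirs(os.path.join(outdir, "depth"), exist_ok=True)
    with open(os.path.join(outdir, "targets.bed"), "w") as fh:
        for t in cohort.targets:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.gc_fraction:.4f}\n")
    for i, sample in enumerate(cohort.matrix.sample_ids):
        with open(os.path.join(outdir, "depth", f"{sample}.regions.bed"), "w") as fh:
            for t, d in zip(cohort.targets, cohort.matrix.values[i]):
                fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{d:.4g}\n")
    cohort.pedigree.to_ped(os.path.join(outdir, "cohort.ped"))
    for caller, calls in calls_by_caller.items():
        write_calls_tsv(calls, os.path.join(outdir, f"calls_{caller}.tsv"))
    cohort.standard.to_tsv(os.path.join(outdir, "standard.tsv"))
    with open(os.path.join(outdir, "segdup.bed"), "w") as fh:
        for chrom, s, e in cohort.segdups:
            fh.write(f"{chrom}\t{s}\t{e}\n")
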