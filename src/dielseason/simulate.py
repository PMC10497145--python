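"""Synthetic photoperiod time-course data with known ground truth.

The generator emulates a three-photoperiod diel RNA-seq design: short day
(SD, 8 h light), equinox (EQ, 12 h) and long day (LD, 16 h), sampled every
4 h over one cycle with three replicates.  Per-gene mean traces are built
from a small set of interpretable waveform components:

* a smooth *light gate* (logistic edges at dawn and dusk) for light-induced
  genes, and its complement for dark-induced genes;
* a *post-dusk pulse* — rapid rise after lights-off followed by exponential
  decay, anchored to the photoperiod's dusk time;
* a *dawn pulse* — wrapped Gaussian centred on ZT0;
* a *clock-like cosine* whose peak phase is an affine function of daylength
  (intercept + slope x hours-of-light), modelling phase-delaying genes;
* a multiplicative *trough* (e.g. a long-day-specific mid-day dip).

Counts are drawn from a negative binomial parameterized by mean ``m`` and
dispersion ``phi`` (variance ``m + phi*m**2``); ``phi = 0`` degrades to
Poisson.  Spike-in rows have constant mean across all libraries.  The
module also plants promoter motifs into a synthetic genome, and builds
gene-set (GMT) and pathway-catalog fixtures, all with a recorded truth
table for recovery testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .experiment import DEFAULT_TIMEPOINTS, PHOTOPERIOD_HOURS, TimeCourseExperiment

__all__ = [
    "DesignSpec", "ArchetypeSpec", "SyntheticTruth", "SyntheticGenome",
    "mean_trace", "simulate_counts", "plant_promoters", "archetype",
    "make_gene_population", "make_gene_sets", "make_catalog",
    "ARCHETYPE_NAMES", "study_scale_design",
]


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignSpec:
    """Experimental design: photoperiods x time points x replicates."""

    photoperiods: tuple[tuple[str, int], ...] = (("SD", 8), ("EQ", 12), ("LD", 16))
    timepoints_zt: tuple[float, ...] = DEFAULT_TIMEPOINTS
    replicates: int = 3
    library_size_range: tuple[float, float] = (0.75, 1.25)
    seed: int = 0

    def __post_init__(self) -> None:
        ts = self.timepoints_zt
        if any(t2 <= t1 for t1, t2 in zip(ts, ts[1:])):
            raise ValueError("time points must be strictly increasing")
        if any(not (0 <= t < 24) for t in ts):
            raise ValueError("time points must lie in [0, 24)")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library size range must be positive")
        for label, hours in self.photoperiods:
            if not (0 <= hours <= 24):
                raise ValueError(f"photoperiod {label}: light hours outside [0, 24]")

    def library_table(self) -> pd.DataFrame:
        rows = []
        for label, _hours in self.photoperiods:
            for zt in self.timepoints_zt:
                for rep in range(1, self.replicates + 1):
                    lib = f"{label}_ZT{int(zt):02d}_R{rep}"
                    rows.append((lib, label, float(zt), rep))
        return pd.DataFrame(rows, columns=["library_id", "photoperiod", "zt",
                                           "replicate"]).set_index("library_id")

    @property
    def hours_of_light(self) -> dict[str, int]:
        return dict(self.photoperiods)


def study_scale_design(seed: int = 0) -> DesignSpec:
    """The default SD/EQ/LD, 6-time-point, triplicate design."""
    return DesignSpec(seed=seed)


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

_DEFAULT_WAVEFORM = dict(
    light_amp=0.0,        # amplitude of the smooth light gate
    dark_amp=0.0,         # amplitude of the gate complement (dark elevation)
    dusk_amp=0.0,         # post-dusk pulse amplitude
    dusk_decay=0.5,       # pulse decay rate, 1/h
    dusk_rise=0.5,        # pulse rise time constant, h (keeps the trace continuous)
    dawn_amp=0.0,         # dawn pulse amplitude
    dawn_width=2.0,       # dawn pulse Gaussian sigma, h
    clock_amp=0.0,        # cosine amplitude
    clock_phase_intercept=0.0,   # cosine peak phase at zero daylength, h
    clock_phase_slope=0.0,       # phase shift per hour of light, h/h
    trough_depth=0.0,     # fractional depth of the multiplicative trough (< 1)
    trough_time=8.0,      # trough centre, ZT h
    trough_width=2.0,     # trough Gaussian sigma, h
    gate_width=0.5,       # logistic edge width of the light gate, h
)


@dataclass(frozen=True)
class ArchetypeSpec:
    """A named expression pattern with waveform parameters and gains."""

    name: str
    baseline_mean: float = 200.0
    waveform_params: Mapping[str, float] = field(default_factory=dict)
    photoperiod_gain: Mapping[str, float] = field(default_factory=dict)
    #: per-photoperiod trough depths override the scalar ``trough_depth``
    trough_photoperiods: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in self.waveform_params:
            if key not in _DEFAULT_WAVEFORM:
                raise ValueError(f"unknown waveform parameter {key!r}")
        for key in ("light_amp", "dark_amp", "dusk_amp", "dawn_amp", "clock_amp"):
            if self.waveform_params.get(key, 0.0) < 0:
                raise ValueError(f"{key} must be non-negative")

    def param(self, key: str) -> float:
        return float(self.waveform_params.get(key, _DEFAULT_WAVEFORM[key]))

    def gain(self, photoperiod: str) -> float:
        return float(self.photoperiod_gain.get(photoperiod, 1.0))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))


def _circdist(t: np.ndarray, t0: float) -> np.ndarray:
    d = np.abs((t - t0) % 24.0)
    return np.minimum(d, 24.0 - d)


def mean_trace(arch: ArchetypeSpec, hours_of_light: float,
               t: float | np.ndarray, photoperiod: str | None = None) -> np.ndarray:
    """Noiseless expression mean of an archetype at time ``t`` (ZT hours).

    ``photoperiod`` is the design label (``SD``/``EQ``/``LD``) used to look
    up per-photoperiod gains and trough depths; when omitted it is inferred
    from ``hours_of_light`` via the standard preset.
    """
    t = np.asarray(t, dtype=float)
    if np.any((t < 0) | (t >= 24)):
        raise ValueError("t must lie in [0, 24)")
    if photoperiod is None:
        lookup = {v: k for k, v in PHOTOPERIOD_HOURS.items()}
        photoperiod = lookup.get(int(hours_of_light), "EQ")
    L = float(hours_of_light)
    p = arch.param

    gate = _sigmoid(t / p("gate_width")) * _sigmoid((L - t) / p("gate_width"))
    dark = 1.0 - gate

    tau = (t - L) % 24.0
    dusk = (1.0 - np.exp(-tau / p("dusk_rise"))) * np.exp(-p("dusk_decay") * tau)

    dawn = np.exp(-_circdist(t, 0.0) ** 2 / (2.0 * p("dawn_width") ** 2))

    phase = p("clock_phase_intercept") + p("clock_phase_slope") * L
    clock = 0.5 * (1.0 + np.cos(2.0 * np.pi * (t - phase) / 24.0))

    shape = (1.0
             + p("light_amp") * gate
             + p("dark_amp") * dark
             + p("dusk_amp") * dusk
             + p("dawn_amp") * dawn
             + p("clock_amp") * clock)

    depth = float(arch.trough_photoperiods.get(photoperiod, p("trough_depth")))
    trough = 1.0 - depth * np.exp(-_circdist(t, p("trough_time")) ** 2
                                  / (2.0 * p("trough_width") ** 2))

    out = arch.baseline_mean * arch.gain(photoperiod) * shape * trough
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# archetype presets
# ---------------------------------------------------------------------------

def _preset(name, baseline=200.0, gains=(1.0, 1.0, 1.0), troughs=None, **wave):
    return ArchetypeSpec(
        name=name, baseline_mean=baseline, waveform_params=wave,
        photoperiod_gain={"SD": gains[0], "EQ": gains[1], "LD": gains[2]},
        trough_photoperiods=troughs or {},
    )


# 19 presets named after the major co-expression subgroups, plus "constant"
# for spike-ins.  Parameter values are fixtures chosen to reproduce the
# qualitative shapes (light-induced, post-dusk, dawn-phased, phase-delaying,
# LD-trough, EQ-specific, ...), not fits to any real data set.
_ARCHETYPES: dict[str, ArchetypeSpec] = {a.name: a for a in [
    _preset("constant"),
    _preset("2C", gains=(0.8, 1.0, 1.3), clock_amp=3.0, clock_phase_intercept=4.0,
            dawn_width=1.5),
    _preset("3G", gains=(0.6, 1.0, 1.5), light_amp=2.5),
    _preset("3I-LD-trough", gains=(0.9, 1.0, 1.2), light_amp=2.5,
            troughs={"LD": 0.7}, trough_time=8.0, trough_width=2.0),
    _preset("3M-light-doublepeak", gains=(0.6, 1.0, 1.5), light_amp=1.5,
            dawn_amp=2.5, dawn_width=1.5, clock_amp=2.0, clock_phase_intercept=10.0),
    _preset("3N-clock-phase-delay", gains=(0.9, 1.0, 1.1), clock_amp=3.0,
            clock_phase_intercept=2.0, clock_phase_slope=0.5),
    _preset("3O", gains=(0.6, 1.0, 1.6), light_amp=1.0, clock_amp=3.0,
            clock_phase_intercept=9.0, clock_phase_slope=0.25),
    _preset("3P", gains=(0.5, 1.0, 1.6), light_amp=1.2, dawn_amp=2.0, dawn_width=3.5),
    _preset("3R", gains=(0.8, 1.0, 1.25), light_amp=3.0,
            trough_depth=0.5, trough_time=0.0, trough_width=1.5),
    _preset("3Y-SD-daypeak", gains=(1.8, 1.0, 0.7), clock_amp=3.0,
            clock_phase_intercept=4.0, light_amp=0.5),
    _preset("4D-EQ-peak", gains=(0.7, 1.6, 0.7), clock_amp=2.5,
            clock_phase_intercept=8.0),
    _preset("4I", gains=(0.8, 1.2, 1.0), clock_amp=2.0, clock_phase_intercept=12.0,
            trough_depth=0.3, trough_time=2.0, trough_width=2.0),
    _preset("4J", gains=(1.3, 1.0, 0.9), clock_amp=2.5,
            clock_phase_intercept=15.0, clock_phase_slope=0.25),
    _preset("6F", gains=(0.7, 1.0, 1.4), dusk_amp=2.5, dusk_decay=0.6),
    _preset("6G", gains=(0.6, 1.0, 1.5), dusk_amp=3.0, dusk_decay=0.12,
            dark_amp=0.5),
    _preset("11J-dawn", gains=(1.3, 1.0, 0.8), dawn_amp=3.5, dawn_width=1.2),
    _preset("11L", gains=(1.2, 1.0, 0.9), dark_amp=1.5),
    _preset("11Oa-postdusk", gains=(1.8, 1.2, 0.8), dusk_amp=3.0, dusk_decay=0.5,
            dawn_amp=1.5, dawn_width=2.5, dark_amp=0.7),
    _preset("11Ob-dawn", gains=(1.7, 1.1, 0.9), dusk_amp=1.5, dusk_decay=0.5,
            dawn_amp=2.8, dawn_width=2.5, dark_amp=0.8),
    _preset("11P", gains=(1.8, 1.2, 0.7), dark_amp=1.5, dusk_amp=2.5,
            dusk_decay=0.08),
    _preset("11X", gains=(1.2, 1.0, 0.9), dark_amp=1.0, dawn_amp=1.5,
            dawn_width=4.0, trough_depth=0.4, trough_time=10.0, trough_width=3.0),
]}

ARCHETYPE_NAMES: tuple[str, ...] = tuple(n for n in _ARCHETYPES if n != "constant")


def archetype(name: str) -> ArchetypeSpec:
    """Look up a shipped archetype preset by name."""
    try:
        return _ARCHETYPES[name]
    except KeyError:
        raise ValueError(f"unknown archetype {name!r}; known: "
                         f"{sorted(_ARCHETYPES)}") from None


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Planted ground truth: archetype, phase, DEI, dispersion, motifs."""

    genes: pd.DataFrame                       # indexed by gene id
    motifs: pd.DataFrame | None = None        # one row per planted instance

    def archetype_labels(self, gene_ids: Sequence[str] | None = None) -> pd.Series:
        labels = self.genes["archetype"]
        return labels if gene_ids is None else labels.loc[list(gene_ids)]


def _true_phase(arch: ArchetypeSpec, hours: float, photoperiod: str) -> float:
    grid = np.arange(0.0, 24.0, 0.05)
    vals = mean_trace(arch, hours, grid, photoperiod)
    if np.ptp(vals) < 1e-9:
        return float("nan")
    return float(grid[int(np.argmax(vals))])


def _true_dei(arch: ArchetypeSpec, hours: float, photoperiod: str) -> float:
    grid = np.linspace(0.0, 24.0, 2401) % 24.0
    vals = mean_trace(arch, hours, grid, photoperiod)
    return float(np.trapezoid(vals, np.linspace(0.0, 24.0, 2401)))


def simulate_counts(design: DesignSpec, genes: Sequence[ArchetypeSpec],
                    dispersion: float = 0.05, n_spikeins: int = 0,
                    spikein_mean: float = 500.0,
                    gene_ids: Sequence[str] | None = None,
                    ) -> tuple[TimeCourseExperiment, SyntheticTruth]:
    """Draw NB counts for every gene x library of the design.

    Library depth factors are drawn once per library from
    ``design.library_size_range``; the count for gene *g* in library *l* is
    NB with mean ``s_l * mu(g, photoperiod_l, ZT_l)`` and variance
    ``mean + dispersion * mean**2``.  Reproducible under a fixed
    ``design.seed``.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(design.seed)
    table = design.library_table()
    hours = design.hours_of_light

    if gene_ids is None:
        gene_ids = [f"G{i + 1:05d}" for i in range(len(genes))]
    if len(gene_ids) != len(genes):
        raise ValueError("gene_ids and genes must have equal length")
    spike_ids = [f"SPIKE{i + 1:03d}" for i in range(n_spikeins)]

    size_factors = rng.uniform(*design.library_size_range, size=len(table))

    means = np.empty((len(genes) + n_spikeins, len(table)))
    for j, (lib, row) in enumerate(table.iterrows()):
        pp, zt = row["photoperiod"], row["zt"]
        col = np.array([mean_trace(g, hours[pp], zt, pp) for g in genes])
        means[:len(genes), j] = col * size_factors[j]
    means[len(genes):, :] = spikein_mean * size_factors[np.newaxis, :]

    if np.any(means < 0):
        raise ValueError("negative simulated mean; check archetype parameters")

    if dispersion == 0:
        counts = rng.poisson(means)
    else:
        r = 1.0 / dispersion
        p = r / (r + np.maximum(means, 1e-12))
        counts = np.where(means > 0, rng.negative_binomial(r, p), 0)

    all_ids = list(gene_ids) + spike_ids
    exp = TimeCourseExperiment(
        counts=pd.DataFrame(counts, index=all_ids, columns=table.index),
        design=table,
        spikein=pd.Series([False] * len(genes) + [True] * n_spikeins, index=all_ids),
    )

    rows = []
    for gid, g in zip(gene_ids, genes):
        row = {"archetype": g.name, "dispersion": dispersion,
               "baseline_mean": g.baseline_mean}
        for pp, h in hours.items():
            row[f"true_phase_{pp}"] = _true_phase(g, h, pp)
            row[f"true_dei_{pp}"] = _true_dei(g, h, pp)
        rows.append(row)
    for sid in spike_ids:
        row = {"archetype": "constant", "dispersion": dispersion,
               "baseline_mean": spikein_mean}
        for pp, h in hours.items():
            row[f"true_phase_{pp}"] = float("nan")
            row[f"true_dei_{pp}"] = 24.0 * spikein_mean
        rows.append(row)
    truth = SyntheticTruth(genes=pd.DataFrame(rows, index=all_ids))
    return exp, truth


def make_gene_population(archetype_counts: Mapping[str, int], seed: int = 0,
                         baseline_cv: float = 0.3, amp_jitter: float = 0.15,
                         gain_jitter: float = 0.12,
                         ) -> tuple[list[ArchetypeSpec], list[str]]:
    """Expand per-archetype gene counts into jittered per-gene specs.

    Each gene keeps its archetype's waveform shape but receives a log-normal
    baseline, mild multiplicative jitter on its component amplitudes, and
    log-normal jitter on its per-photoperiod gains, so that genes of one
    archetype are strongly but not perfectly correlated and their rDEI
    values scatter around the archetype's designed preference — the regime
    in which clustering and group-level rDEI testing are actually exercised.
    """
    rng = np.random.default_rng(seed)
    specs: list[ArchetypeSpec] = []
    labels: list[str] = []
    amp_keys = ("light_amp", "dark_amp", "dusk_amp", "dawn_amp", "clock_amp")
    for name, count in archetype_counts.items():
        base = archetype(name)
        for _ in range(count):
            wave = dict(base.waveform_params)
            for key in amp_keys:
                if wave.get(key, 0.0) > 0:
                    wave[key] = wave[key] * rng.lognormal(0.0, amp_jitter)
            gains = {pp: base.gain(pp) * rng.lognormal(0.0, gain_jitter)
                     for pp in ("SD", "EQ", "LD")}
            if name == "constant":
                gains = {}              # background stays flat by definition
            spec = replace(
                base,
                baseline_mean=base.baseline_mean * rng.lognormal(0.0, baseline_cv),
                waveform_params=wave,
                photoperiod_gain=gains,
            )
            specs.append(spec)
            labels.append(name)
    return specs, labels


def study_scale_population(seed: int = 0, genes_per_subgroup: int = 50,
                          n_background: int = 2000,
                          oversize_postdusk: bool = True,
                          ) -> tuple[list[ArchetypeSpec], list[str]]:
    """The standard study-scale population: all 19 archetypes plus a
    non-photoperiodic background.

    The background ("constant" archetype) anchors TMM normalization the way
    the stable majority of a real transcriptome does; without it the
    composition bias of a tiny all-regulated gene set distorts CPMs.  The
    two post-dusk/dawn dark-induced subgroups are oversized by default,
    mirroring their dominance among short-day-induced genes.
    """
    counts = {name: genes_per_subgroup for name in ARCHETYPE_NAMES}
    if oversize_postdusk:
        counts["11Oa-postdusk"] = int(genes_per_subgroup * 1.6)
        counts["11Ob-dawn"] = int(genes_per_subgroup * 1.6)
    counts["constant"] = n_background
    return make_gene_population(counts, seed=seed)


# ---------------------------------------------------------------------------
# promoter planting
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SyntheticGenome:
    """Synthetic chromosome sequences plus gene annotation and motif truth."""

    sequences: dict[str, str]
    genes: pd.DataFrame          # chrom, start, end, strand per gene id
    truth: pd.DataFrame          # gene_id, motif_id, offset, strand, instance

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for gid, row in self.genes.iterrows():
                base = (f"{row.chrom}\tdielseason\t{{feat}}\t{row.start}\t{row.end}"
                        f"\t.\t{row.strand}\t.\t")
                fh.write(base.format(feat="gene") + f"ID={gid}\n")
                fh.write(base.format(feat="mRNA")
                         + f"ID={gid}.1;Parent={gid}\n")


@dataclass(frozen=True)
class MotifPlacement:
    motif_id: str
    offset: int       # instance start relative to TSS, promoter orientation
    strand: str       # '+': same strand as the gene, '-': opposite


def _draw_instance(motif, rng: np.random.Generator) -> str:
    """A sequence drawn from a PFM (4 x w, rows A,C,G,T) or a literal string."""
    if isinstance(motif, str):
        return motif.upper()
    mat = np.asarray(motif, dtype=float)
    if mat.shape[0] != 4:
        raise ValueError("PFM must have 4 rows (A, C, G, T)")
    cols = mat / mat.sum(axis=0, keepdims=True)
    bases = "ACGT"
    return "".join(bases[rng.choice(4, p=cols[:, i])] for i in range(mat.shape[1]))


def plant_promoters(gene_ids: Sequence[str],
                    motif_assignments: Mapping[str, Sequence[MotifPlacement]],
                    motifs: Mapping[str, object],
                    upstream: int = 1500, downstream: int = 500,
                    seed: int = 0, gene_length: int = 2000,
                    spacing: int = 6000, genes_per_chrom: int = 50,
                    ) -> SyntheticGenome:
    """Build a synthetic genome with motif instances planted in promoters.

    Background sequence is i.i.d. uniform over A/C/G/T.  A placement at
    offset ``o`` (relative to the TSS, in the transcription direction)
    occupies promoter window positions ``o .. o+w-1``; minus-strand genes
    receive the reverse complement in genomic coordinates.  Offsets must lie
    inside the ``[-upstream, downstream)`` window that promoter extraction
    will use downstream.
    """
    rng = np.random.default_rng(seed)
    sequences: dict[str, list[str]] = {}
    gene_rows = []
    truth_rows = []

    chrom_len = spacing * min(genes_per_chrom, len(gene_ids)) + spacing
    for ci in range(math.ceil(len(gene_ids) / genes_per_chrom)):
        chrom = f"chr{ci + 1}"
        n_here = min(genes_per_chrom, len(gene_ids) - ci * genes_per_chrom)
        sequences[chrom] = list("".join(
            rng.choice(list("ACGT"), size=spacing * n_here + spacing)))

    for i, gid in enumerate(gene_ids):
        ci, slot = divmod(i, genes_per_chrom)
        chrom = f"chr{ci + 1}"
        slot_start = slot * spacing + 1          # 1-based genomic coordinate
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            tss = slot_start + upstream + 100
            start, end = tss, tss + gene_length - 1
        else:
            start = slot_start + 100
            end = start + gene_length - 1
            tss = end
        gene_rows.append((gid, chrom, start, end, strand))

        for place in motif_assignments.get(gid, ()):
            inst = _draw_instance(motifs[place.motif_id], rng)
            w = len(inst)
            if not (-upstream <= place.offset <= downstream - w):
                raise ValueError(
                    f"{gid}: offset {place.offset} outside promoter window "
                    f"[-{upstream}, {downstream - w}]")
            oriented = inst if place.strand == "+" else _revcomp(inst)
            if strand == "+":
                g0 = tss + place.offset - 1          # 0-based genomic index
                sequences[chrom][g0:g0 + w] = list(oriented)
            else:
                g0 = tss - place.offset - w          # 0-based genomic index
                sequences[chrom][g0:g0 + w] = list(_revcomp(oriented))
            truth_rows.append((gid, place.motif_id, place.offset,
                               place.strand, inst))

    genome = SyntheticGenome(
        sequences={c: "".join(s) for c, s in sequences.items()},
        genes=pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start",
                                               "end", "strand"]
                           ).set_index("gene_id"),
        truth=pd.DataFrame(truth_rows, columns=["gene_id", "motif_id", "offset",
                                                "strand", "instance"]),
    )
    return genome


# ---------------------------------------------------------------------------
# gene sets and catalog fixtures
# ---------------------------------------------------------------------------

def make_gene_sets(truth: SyntheticTruth, seed: int = 0, n_random: int = 20,
                   random_size: tuple[int, int] = (25, 80)) -> dict[str, list[str]]:
    """Gene sets from planted archetypes plus size-matched random sets."""
    rng = np.random.default_rng(seed)
    genes = truth.genes[truth.genes["archetype"] != "constant"]
    universe = list(genes.index)
    sets: dict[str, list[str]] = {}
    for name, members in genes.groupby("archetype").groups.items():
        if len(members) >= 10:
            sets[f"ARCHETYPE_{name}"] = sorted(members)
    for i in range(n_random):
        size = min(int(rng.integers(*random_size)), len(universe))
        sets[f"RANDOM_{i + 1:02d}"] = sorted(
            rng.choice(universe, size=size, replace=False))
    return sets


def make_catalog(truth: SyntheticTruth, seed: int = 0,
                 flavonoid_archetypes: Sequence[str] = ("3G", "3M-light-doublepeak"),
                 lignin_archetypes: Sequence[str] = ("4D-EQ-peak",),
                 n_per_branch: int = 30) -> pd.DataFrame:
    """A pathway-catalog fixture with an LD-induced flavonoid branch.

    Flavonoid-branch genes are drawn from LD-gain archetypes and
    lignin-branch genes from photoperiod-neutral ones, mirroring the
    qualitative contrast the catalog scoring stage is designed to detect.
    """
    rng = np.random.default_rng(seed)
    genes = truth.genes
    rows = []
    for branch, pool_names in (("flavonoid", flavonoid_archetypes),
                               ("lignin", lignin_archetypes)):
        pool = list(genes.index[genes["archetype"].isin(pool_names)])
        take = rng.choice(pool, size=min(n_per_branch, len(pool)), replace=False)
        for j, gid in enumerate(take):
            rows.append((gid, "positive", "enzyme", branch,
                         f"{branch.upper()[:3]}{j // 3 + 1}"))
    return pd.DataFrame(rows, columns=["gene_id", "effect", "function",
                                       "branch", "step_label"])
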