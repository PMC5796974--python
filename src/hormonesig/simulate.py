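"""Synthetic-data generation with planted ground truth.

Every input the pipeline consumes can be simulated here with known
structure: two overlapping-but-distinct cistromes with an exact Venn triple,
an estrogen-receptor cistrome remodeled (retained / lost / gained) by a
second factor, read tracks with enriched sites over uniform background,
treatment-group expression matrices whose samples cluster by condition,
two-bait spectral-count tables with IgG background, and survival cohorts
whose hazard depends on a signature score. Each generator returns a
:class:`TruthManifest` recording the planted quantities so downstream stages
can be tested for exact or statistical recovery.

All randomness flows through ``numpy.random.default_rng`` seeded explicitly;
a fixed seed gives byte-identical outputs. Stage-level child seeds are
derived from one global seed by stage index (:func:`stage_seed`).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import CapacityError, ConfigError
from .intervals import GenomicInterval, IntervalSet
from .matrix import FeatureMatrix
from .survival import SurvivalCohort

# stage indices for child-seed derivation
STAGES = (
    "genome",
    "cistromes",
    "remodeling",
    "reads",
    "expression",
    "spectral",
    "cohort",
)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed from one global seed."""
    idx = STAGES.index(stage)
    return int(
        np.random.SeedSequence(seed, spawn_key=(idx,)).generate_state(1)[0] % (2**31)
    )


@dataclass
class GenomeLayout:
    """Chromosome names and lengths of a synthetic genome."""

    names: list[str]
    lengths: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ConfigError("chromosome names must be unique")
        for name in self.names:
            if self.lengths.get(name, 0) <= 0:
                raise ConfigError(f"chromosome {name!r} must have positive length")

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())


@dataclass
class TruthManifest:
    """Machine-readable record of planted simulation parameters."""

    data: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True, default=str)

    @classmethod
    def read(cls, path) -> "TruthManifest":
        with open(path) as fh:
            return cls(json.load(fh))


@dataclass
class ReadTracks:
    """Single-position read placements per sample, with recorded totals."""

    reads: dict[str, list[tuple[str, int]]]
    library_sizes: dict[str, int]

    def write_bed(self, sample: str, path) -> None:
        with open(path, "w") as fh:
            for chrom, pos in self.reads[sample]:
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\n")


def generate_genome(
    chrom_lengths: Mapping[str, int], seed: int
) -> tuple[GenomeLayout, str]:
    """Uniform-random A/C/G/T genome of the declared chromosome lengths.

    Returns the layout and the FASTA text (60-column wrapping).
    """
    if not chrom_lengths:
        raise ConfigError("at least one chromosome is required")
    layout = GenomeLayout(list(chrom_lengths.keys()), dict(chrom_lengths))
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    buf = io.StringIO()
    for name in layout.names:
        seq = bases[rng.integers(0, 4, size=layout.lengths[name])].tobytes().decode()
        buf.write(f">{name}\n")
        for i in range(0, len(seq), 60):
            buf.write(seq[i : i + 60] + "\n")
    return layout, buf.getvalue()


def fasta_to_dict(fasta_text: str) -> dict[str, str]:
    """Parse FASTA text into {name: sequence}."""
    seqs: dict[str, list[str]] = {}
    name = None
    for line in fasta_text.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = []
        elif name is not None:
            seqs[name].append(line.strip())
    return {n: "".join(parts) for n, parts in seqs.items()}


def _site_slots(layout: GenomeLayout, width: int) -> list[tuple[str, int]]:
    """Candidate start positions spaced 3*width apart (>= 2*width gaps)."""
    slots = []
    for name in layout.names:
        pos = width  # margin from the chromosome start
        while pos + width <= layout.lengths[name] - width:
            slots.append((name, pos))
            pos += 3 * width
    return slots


def _place_sites(
    layout: GenomeLayout, n: int, width: int, rng: np.random.Generator
) -> list[GenomicInterval]:
    slots = _site_slots(layout, width)
    if n > len(slots):
        raise CapacityError(
            f"genome holds only {len(slots)} disjoint {width}-bp sites, "
            f"requested {n}"
        )
    chosen = rng.permutation(len(slots))[:n]
    return [
        GenomicInterval(slots[i][0], slots[i][1], slots[i][1] + width)
        for i in sorted(chosen)
    ]


def generate_isoform_cistromes(
    layout: GenomeLayout,
    n_common: int,
    n_unique_a: int,
    n_unique_b: int,
    width: int,
    seed: int,
) -> tuple[IntervalSet, IntervalSet, TruthManifest]:
    """Two cistromes sharing exactly ``n_common`` sites.

    Sites are placed >= 2*width apart so the planted Venn triple
    (common, unique-A, unique-B) is recovered exactly by interval
    intersection.
    """
    rng = np.random.default_rng(seed)
    total = n_common + n_unique_a + n_unique_b
    sites = _place_sites(layout, total, width, rng)
    perm = rng.permutation(total)
    common = [sites[i] for i in perm[:n_common]]
    uniq_a = [sites[i] for i in perm[n_common : n_common + n_unique_a]]
    uniq_b = [sites[i] for i in perm[n_common + n_unique_a :]]
    set_a = IntervalSet(sorted(common + uniq_a), label="cistrome_A")
    set_b = IntervalSet(sorted(common + uniq_b), label="cistrome_B")
    manifest = TruthManifest(
        {
            "n_common": n_common,
            "n_unique_a": n_unique_a,
            "n_unique_b": n_unique_b,
            "width": width,
        }
    )
    return set_a, set_b, manifest


def generate_er_remodeling(
    layout: GenomeLayout,
    n_pre: int,
    retained_fraction: float,
    n_gained: int,
    seed: int,
    width: int = 200,
) -> tuple[IntervalSet, IntervalSet, TruthManifest]:
    """A binding-site set and its remodeled counterpart.

    Exactly round(retained_fraction * n_pre) pre sites persist at identical
    coordinates; ``n_gained`` new sites appear elsewhere. The planted percent
    inhibition 100 * (1 - (retained + gained) / n_pre) is recovered exactly
    by the remodeling summary.
    """
    if not 0 <= retained_fraction <= 1:
        raise ConfigError("retained_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_retained = int(round(retained_fraction * n_pre))
    sites = _place_sites(layout, n_pre + n_gained, width, rng)
    perm = rng.permutation(n_pre + n_gained)
    pre = sorted(sites[i] for i in perm[:n_pre])
    retained = [pre[i] for i in sorted(rng.permutation(n_pre)[:n_retained])]
    gained = sorted(sites[i] for i in perm[n_pre:])
    post = IntervalSet(sorted(retained + gained), label="post")
    manifest = TruthManifest(
        {
            "n_pre": n_pre,
            "n_retained": n_retained,
            "n_lost": n_pre - n_retained,
            "n_gained": n_gained,
            "percent_inhibition": (
                100.0 * (1.0 - (n_retained + n_gained) / n_pre) if n_pre else None
            ),
        }
    )
    return IntervalSet(pre, label="pre"), post, manifest


def _neg_binomial(
    rng: np.random.Generator, mean, dispersion: float, size=None
) -> np.ndarray:
    """Counts with variance mean + dispersion * mean^2 (gamma-Poisson)."""
    mean = np.broadcast_to(
        np.asarray(mean, dtype=float), np.shape(mean) if size is None else size
    )
    if dispersion <= 0:
        return np.asarray(rng.poisson(mean))
    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mean)
    return np.asarray(rng.poisson(lam))


def generate_read_placements(
    layout: GenomeLayout,
    sites: IntervalSet,
    n_samples: int,
    enrichment: float,
    background_rate: float,
    seed: int,
    dispersion: float = 0.1,
    sample_prefix: str = "sample",
) -> ReadTracks:
    """Single-position read tracks: enriched sites over uniform background.

    Per sample, each true site receives a negative-binomial read count with
    the given mean and dispersion, placed uniformly within the site;
    background reads arrive at ``background_rate`` per kb, uniformly on the
    genome. Each track's total read count is recorded as its library size.
    """
    if enrichment > 0 and sites.intervals:
        per_site_bg = background_rate * max(iv.length for iv in sites) / 1000.0
        if enrichment <= per_site_bg:
            raise ConfigError(
                "site enrichment must exceed the background expectation per site"
            )
    rng = np.random.default_rng(seed)
    chroms = layout.names
    cum = np.cumsum([layout.lengths[c] for c in chroms])
    reads: dict[str, list[tuple[str, int]]] = {}
    sizes: dict[str, int] = {}
    for s in range(n_samples):
        label = f"{sample_prefix}{s + 1}"
        track: list[tuple[str, int]] = []
        for iv in sites:
            k = int(_neg_binomial(rng, enrichment, dispersion)) if enrichment > 0 else 0
            if k:
                track.extend(
                    (iv.chrom, int(p))
                    for p in rng.integers(iv.start, iv.end, size=k)
                )
        n_bg = rng.poisson(background_rate * layout.total_length / 1000.0)
        if n_bg:
            flat = rng.integers(0, layout.total_length, size=n_bg)
            idx = np.searchsorted(cum, flat, side="right")
            offset = flat - np.concatenate([[0], cum])[idx]
            track.extend((chroms[i], int(o)) for i, o in zip(idx, offset))
        reads[label] = track
        sizes[label] = len(track)
    return ReadTracks(reads, sizes)


def generate_background_intervals(
    layout: GenomeLayout, n: int, width: int, seed: int
) -> IntervalSet:
    """Random fixed-width intervals for motif-enrichment background."""
    rng = np.random.default_rng(seed)
    chroms = layout.names
    weights = np.array([layout.lengths[c] - width for c in chroms], dtype=float)
    if (weights <= 0).any():
        raise CapacityError(f"chromosomes shorter than {width} bp")
    picks = rng.choice(len(chroms), size=n, p=weights / weights.sum())
    ivs = []
    for c_idx in picks:
        chrom = chroms[c_idx]
        start = int(rng.integers(0, layout.lengths[chrom] - width))
        ivs.append(GenomicInterval(chrom, start, start + width))
    return IntervalSet(sorted(ivs), label="background")


def plant_motif_instances(
    genome: dict[str, str],
    sites: IntervalSet,
    consensus: str,
    fraction: float,
    seed: int,
) -> dict[str, str]:
    """Write a motif consensus into the centre of a fraction of the sites.

    Returns a new genome dict; used to make motif enrichment at simulated
    binding sites a planted positive rather than a null.
    """
    rng = np.random.default_rng(seed)
    editable = {c: bytearray(s, "ascii") for c, s in genome.items()}
    L = len(consensus)
    for iv in sites:
        if rng.random() >= fraction:
            continue
        mid = (iv.start + iv.end) // 2 - L // 2
        if mid < 0 or mid + L > len(editable[iv.chrom]):
            continue
        editable[iv.chrom][mid : mid + L] = consensus.encode()
    return {c: bytes(b).decode() for c, b in editable.items()}


def generate_expression_matrix(
    design: Mapping[str, str],
    n_genes: int,
    programs: Mapping[str, Mapping[str, float]],
    seed: int,
    dispersion: float = 0.1,
    baseline_log_mean: float = np.log(100.0),
    baseline_log_sd: float = 1.0,
) -> tuple[FeatureMatrix, TruthManifest]:
    """Count matrix with condition-specific regulated gene programs.

    ``design`` maps sample label -> condition; ``programs`` maps condition ->
    {gene: log2 fold change vs baseline}. Baseline means are log-normal and
    counts negative binomial around the condition-specific means.
    """
    conditions = sorted(set(design.values()))
    for cond, samples in _group_by_condition(design).items():
        if len(samples) < 2:
            raise ConfigError(f"condition {cond!r} has < 2 samples")
    genes = [f"g{i + 1:05d}" for i in range(n_genes)]
    gene_set = set(genes)
    for cond, prog in programs.items():
        bad = set(prog) - gene_set
        if bad:
            raise ConfigError(f"program for {cond!r} names unknown genes: {sorted(bad)[:3]}")
    rng = np.random.default_rng(seed)
    baseline = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, size=n_genes))
    samples = sorted(design)
    counts = np.zeros((n_genes, len(samples)))
    gene_idx = {g: i for i, g in enumerate(genes)}
    for j, sample in enumerate(samples):
        mean = baseline.copy()
        for g, lfc in programs.get(design[sample], {}).items():
            mean[gene_idx[g]] *= 2.0**lfc
        counts[:, j] = _neg_binomial(rng, mean, dispersion)
    data = pd.DataFrame(counts, index=genes, columns=samples)
    lengths = pd.Series(1000.0, index=genes)  # nominal 1-kb genes
    classes = {
        cond: {g: ("up" if lfc > 0 else "down") for g, lfc in programs.get(cond, {}).items()}
        for cond in conditions
    }
    manifest = TruthManifest(
        {
            "design": dict(design),
            "programs": {c: dict(p) for c, p in programs.items()},
            "classes": classes,
            "dispersion": dispersion,
        }
    )
    return FeatureMatrix(data, lengths, kind="counts"), manifest


def _group_by_condition(design: Mapping[str, str]) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for sample, cond in design.items():
        groups.setdefault(cond, []).append(sample)
    return groups


def generate_two_group_expression(
    seed: int,
    n_genes: int = 2000,
    n_regulated: int = 200,
    lfc: float = 2.0,
    n_per_group: int = 4,
    dispersion: float = 0.1,
    conditions: tuple[str, str] = ("agonist", "antagonist"),
) -> tuple[FeatureMatrix, TruthManifest]:
    """Two treatment groups separated by a planted regulated program.

    Condition 2 carries ``n_regulated`` genes shifted by +/- ``lfc`` log2
    units (half up, half down) relative to condition 1 — the structure the
    clustering stage is expected to segregate perfectly at the defaults.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:05d}" for i in range(n_genes)]
    regulated = [genes[i] for i in sorted(rng.permutation(n_genes)[:n_regulated])]
    signs = rng.choice([-1.0, 1.0], size=n_regulated)
    program = {g: float(s * lfc) for g, s in zip(regulated, signs)}
    design = {}
    for cond_i, cond in enumerate(conditions):
        for r in range(n_per_group):
            design[f"{cond}_{r + 1}"] = cond
    matrix, manifest = generate_expression_matrix(
        design,
        n_genes,
        {conditions[1]: program},
        seed=stage_seed(seed, "expression"),
        dispersion=dispersion,
    )
    manifest.data["group_labels"] = {s: c for s, c in design.items()}
    return matrix, manifest


def generate_isoform_expression(
    seed: int,
    n_genes: int = 2000,
    n_regulated: int = 500,
    p_a_stronger: float = 0.8,
    lfc_strong: float = -2.5,
    lfc_weak: float = -1.0,
    n_per_group: int = 4,
    dispersion: float = 0.1,
) -> tuple[FeatureMatrix, TruthManifest]:
    """Vehicle / isoform-A / isoform-B design with asymmetric repression.

    Each regulated gene is repressed by both isoforms; with probability
    ``p_a_stronger`` isoform A carries the strong effect, else isoform B.
    The manifest records each gene's stronger isoform for recovery tests of
    the differential-repression comparison.
    """
    if not 0 <= p_a_stronger <= 1:
        raise ConfigError("p_a_stronger must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:05d}" for i in range(n_genes)]
    regulated = [genes[i] for i in sorted(rng.permutation(n_genes)[:n_regulated])]
    a_stronger = rng.random(n_regulated) < p_a_stronger
    prog_a = {
        g: (lfc_strong if strong else lfc_weak)
        for g, strong in zip(regulated, a_stronger)
    }
    prog_b = {
        g: (lfc_weak if strong else lfc_strong)
        for g, strong in zip(regulated, a_stronger)
    }
    design = {}
    for cond in ("vehicle", "isoA", "isoB"):
        for r in range(n_per_group):
            design[f"{cond}_{r + 1}"] = cond
    matrix, manifest = generate_expression_matrix(
        design,
        n_genes,
        {"isoA": prog_a, "isoB": prog_b},
        seed=stage_seed(seed, "expression"),
        dispersion=dispersion,
    )
    manifest.data["stronger_isoform"] = {
        g: ("A" if strong else "B") for g, strong in zip(regulated, a_stronger)
    }
    manifest.data["p_a_stronger"] = p_a_stronger
    return matrix, manifest


def generate_spectral_table(
    seed: int,
    n_proteins: int = 400,
    f_pref_a: float = 0.25,
    f_pref_b: float = 0.25,
    f_shared: float = 0.25,
    mean_count: float = 30.0,
    igg_mean: float = 1.0,
    n_reps: int = 2,
):
    """Two-bait spectral-count table with IgG background runs.

    Proteins fall into four planted classes: A-preferential (Poisson
    ``mean_count`` in bait-A runs, ``igg_mean`` elsewhere), B-preferential
    (mirrored), shared (``mean_count`` in both baits) and background-only
    (``igg_mean`` everywhere). IgG runs always draw at ``igg_mean``.
    """
    from .interactome import SpectralCountTable

    if n_reps < 1:
        raise ConfigError("need >= 1 replicate per bait")
    if f_pref_a + f_pref_b + f_shared > 1 + 1e-9:
        raise ConfigError("class fractions must sum to <= 1")
    rng = np.random.default_rng(seed)
    n_a = int(round(f_pref_a * n_proteins))
    n_b = int(round(f_pref_b * n_proteins))
    n_sh = int(round(f_shared * n_proteins))
    classes = (
        ["A-preferential"] * n_a
        + ["B-preferential"] * n_b
        + ["shared"] * n_sh
        + ["background"] * (n_proteins - n_a - n_b - n_sh)
    )
    proteins = [f"P{i + 1:04d}" for i in range(n_proteins)]
    runs = [f"{bait}_rep{r + 1}" for bait in ("A", "B", "IgG") for r in range(n_reps)]
    baits = {run: run.split("_")[0] for run in runs}
    means = np.full((n_proteins, len(runs)), igg_mean)
    for i, cls in enumerate(classes):
        for j, run in enumerate(runs):
            bait = baits[run]
            if (
                (cls == "A-preferential" and bait == "A")
                or (cls == "B-preferential" and bait == "B")
                or (cls == "shared" and bait in ("A", "B"))
            ):
                means[i, j] = mean_count
    counts = pd.DataFrame(rng.poisson(means), index=proteins, columns=runs)
    table = SpectralCountTable(counts, baits)
    manifest = TruthManifest(
        {
            "classes": dict(zip(proteins, classes)),
            "mean_count": mean_count,
            "igg_mean": igg_mean,
            "n_reps": n_reps,
        }
    )
    return table, manifest


def generate_cohort(
    seed: int,
    n_patients: int = 300,
    signature_genes: Optional[Sequence[str]] = None,
    beta: Optional[float] = None,
    baseline_hazard: float = 0.1,
    censor_rate: float = 0.04,
    noise_sd: float = 1.0,
    n_background_genes: int = 100,
    loading: float = 0.2,
):
    """Survival cohort with a planted score -> hazard link.

    Each patient draws a standard-normal score s; signature-gene expression
    scales linearly with s (relative amplitude ``loading``, per-gene noise
    ``noise_sd`` times that amplitude); the event hazard is
    baseline_hazard * exp(beta * s) and censoring is exponential at
    ``censor_rate`` (0 = no censoring).
    """
    if beta is None:
        raise ConfigError("the log hazard ratio beta must be specified")
    if n_patients < 8:
        raise ConfigError("need >= 8 patients for quartile stratification")
    if signature_genes is None:
        signature_genes = [f"sig{i + 1:03d}" for i in range(50)]
    rng = np.random.default_rng(seed)
    patients = [f"pt{i + 1:04d}" for i in range(n_patients)]
    s = rng.standard_normal(n_patients)

    genes = list(signature_genes) + [f"bg{i + 1:04d}" for i in range(n_background_genes)]
    baseline = rng.uniform(50.0, 150.0, size=len(genes))
    expr = np.empty((len(genes), n_patients))
    for i, g in enumerate(genes):
        noise = rng.standard_normal(n_patients) * noise_sd * loading
        signal = loading * s if i < len(signature_genes) else 0.0
        expr[i] = np.maximum(baseline[i] * (1.0 + signal + noise), 0.0)
    matrix = FeatureMatrix(
        pd.DataFrame(expr, index=genes, columns=patients),
        pd.Series(1000.0, index=genes),
        kind="counts",
    )

    hazard = baseline_hazard * np.exp(beta * s)
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        t_censor = rng.exponential(1.0 / censor_rate, size=n_patients)
    else:
        t_censor = np.full(n_patients, np.inf)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    cohort = SurvivalCohort(patients, time, event)
    manifest = TruthManifest(
        {
            "beta": beta,
            "baseline_hazard": baseline_hazard,
            "censor_rate": censor_rate,
            "noise_sd": noise_sd,
            "scores": {p: float(v) for p, v in zip(patients, s)},
            "signature_genes": list(signature_genes),
        }
    )
    return cohort, matrix, manifest
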