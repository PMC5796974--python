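"""Config-driven end-to-end orchestration.

Runs the stages in dependency order — simulate, cistrome, motif, cluster,
differential expression, interactome, survival — from a single YAML config
with one global seed, writing every artifact plus a deterministic run
manifest of SHA-256 digests. Per-stage wall-clock timings go to a separate
timings file so the manifest itself is byte-identical across reruns of the
same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__, diffexpr, interactome, matrix, motifs, simulate, survival
from .errors import ConfigError, DataError
from .intervals import IntervalSet, intersect, read_bed, remodel, write_bed

log = logging.getLogger("hormonesig")

STAGE_ORDER = ("simulate", "cistrome", "motif", "cluster", "de", "interactome", "survival")

DEFAULT_CONFIG = {
    "seed": 1,
    "genome": {"chromosomes": {"chr1": 500_000, "chr2": 500_000}},
    "cistromes": {"n_common": 50, "n_unique_a": 100, "n_unique_b": 75, "width": 200},
    "remodeling": {"n_pre": 500, "retained_fraction": 0.3, "n_gained": 0, "width": 200},
    "reads": {"n_samples": 4, "enrichment": 50.0, "background_rate": 0.05, "dispersion": 0.1},
    "motif": {
        "consensus": "AGAACAGAATGTTCT",
        "plant_fraction": 0.6,
        "threshold_fraction": 0.8,
        "n_background": 200,
    },
    "expression": {
        "n_genes": 2000,
        "n_regulated": 200,
        "lfc": 2.0,
        "n_per_group": 4,
        "dispersion": 0.1,
        "k": 2,
    },
    "repression": {
        "n_genes": 2000,
        "n_regulated": 500,
        "p_a_stronger": 0.8,
        "lfc_strong": -2.5,
        "lfc_weak": -1.0,
        "n_per_group": 4,
        "delta": 0.25,
        "signature_n": 100,
    },
    "interactome": {
        "n_proteins": 400,
        "f_pref_a": 0.25,
        "f_pref_b": 0.25,
        "f_shared": 0.25,
        "mean_count": 30.0,
        "igg_mean": 1.0,
        "n_reps": 2,
        "fold_min": 2.0,
        "count_min": 2.0,
        "si_cut": 0.33,
    },
    "survival": {
        "n_patients": 300,
        "beta": float(np.log(2.5)),
        "baseline_hazard": 0.1,
        "censor_rate": 0.04,
        "noise_sd": 1.0,
        "n_signature": 50,
    },
}


def _validate(config: dict, template: dict, path: str = "") -> None:
    for key, value in config.items():
        where = f"{path}.{key}" if path else key
        if key not in template:
            raise ConfigError(f"unknown config key: {where}")
        if isinstance(template[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config key {where} must be a mapping")
            _validate(value, template[key], where)


def load_config(path: Optional[str] = None, seed: Optional[int] = None) -> dict:
    """Load and validate a YAML config, merged over the defaults."""
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _validate(user, DEFAULT_CONFIG)
        for key, value in user.items():
            if isinstance(value, dict):
                config[key].update(value)
            else:
                config[key] = value
    if seed is not None:
        config["seed"] = int(seed)
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)


class PipelineRun:
    """One orchestrated run over a validated config."""

    def __init__(self, config: dict, outdir: Path):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.seed = int(config["seed"])
        self.timings: dict[str, float] = {}

    def path(self, name: str) -> Path:
        return self.outdir / name

    # ----- stages -------------------------------------------------------

    def stage_simulate(self) -> None:
        cfg = self.config
        layout, fasta = simulate.generate_genome(
            cfg["genome"]["chromosomes"], simulate.stage_seed(self.seed, "genome")
        )
        cis = cfg["cistromes"]
        set_a, set_b, truth_cis = simulate.generate_isoform_cistromes(
            layout, cis["n_common"], cis["n_unique_a"], cis["n_unique_b"],
            cis["width"], simulate.stage_seed(self.seed, "cistromes"),
        )
        rem = cfg["remodeling"]
        pre, post, truth_rem = simulate.generate_er_remodeling(
            layout, rem["n_pre"], rem["retained_fraction"], rem["n_gained"],
            simulate.stage_seed(self.seed, "remodeling"), width=rem["width"],
        )
        mot = cfg["motif"]
        genome = simulate.fasta_to_dict(fasta)
        genome = simulate.plant_motif_instances(
            genome, set_a, mot["consensus"], mot["plant_fraction"],
            simulate.stage_seed(self.seed, "genome"),
        )
        with open(self.path("genome.fa"), "w") as fh:
            for name in layout.names:
                fh.write(f">{name}\n")
                seq = genome[name]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        write_bed(set_a, self.path("cistrome_A.bed"))
        write_bed(set_b, self.path("cistrome_B.bed"))
        write_bed(pre, self.path("er_pre.bed"))
        write_bed(post, self.path("er_post.bed"))
        rd = cfg["reads"]
        sizes: dict[str, int] = {}
        for cond, sites in (("A", set_a), ("B", set_b)):
            tracks = simulate.generate_read_placements(
                layout, sites, rd["n_samples"], rd["enrichment"],
                rd["background_rate"],
                seed=simulate.stage_seed(self.seed, "reads") + (cond == "B"),
                dispersion=rd["dispersion"], sample_prefix=f"chip{cond}_",
            )
            for sample in tracks.reads:
                tracks.write_bed(sample, self.path(f"reads_{sample}.bed"))
            sizes.update(tracks.library_sizes)
        _write_json(sizes, self.path("library_sizes.json"))
        truth_cis.write(self.path("truth_cistromes.json"))
        truth_rem.write(self.path("truth_remodeling.json"))
        _write_json(
            {"chromosomes": {c: layout.lengths[c] for c in layout.names}},
            self.path("genome_layout.json"),
        )

    def stage_cistrome(self) -> None:
        set_a = read_bed(self.path("cistrome_A.bed"), "A")
        set_b = read_bed(self.path("cistrome_B.bed"), "B")
        summary = intersect(set_a, set_b)
        _write_json(summary.as_dict(), self.path("overlap_summary.json"))
        pre = read_bed(self.path("er_pre.bed"), "pre")
        post = read_bed(self.path("er_post.bed"), "post")
        _write_json(remodel(pre, post).as_dict(), self.path("remodeling_summary.json"))

    def stage_motif(self) -> None:
        mot = self.config["motif"]
        with open(self.path("genome.fa")) as fh:
            genome = simulate.fasta_to_dict(fh.read())
        layout = simulate.GenomeLayout(
            list(genome), {c: len(s) for c, s in genome.items()}
        )
        fg = read_bed(self.path("cistrome_A.bed"), "A")
        width = fg.intervals[0].length if fg.intervals else 200
        bg = simulate.generate_background_intervals(
            layout, mot["n_background"], width, simulate.stage_seed(self.seed, "genome")
        )
        pwm = motifs.PositionWeightMatrix.from_sequences(
            "planted", [mot["consensus"]] * 10
        )
        result = motifs.enrich(fg, bg, genome, pwm, mot["threshold_fraction"])
        _write_json(result.as_dict(), self.path("motif_enrichment.json"))

    def stage_cluster(self) -> None:
        # ChIP arm: read counts at union peaks -> RPKM -> quantile -> r -> tree
        set_a = read_bed(self.path("cistrome_A.bed"), "A")
        set_b = read_bed(self.path("cistrome_B.bed"), "B")
        union = matrix.build_union_features([set_a, set_b])
        with open(self.path("library_sizes.json")) as fh:
            library_sizes = json.load(fh)
        tracks = {
            sample: [(iv.chrom, iv.start) for iv in read_bed(self.path(f"reads_{sample}.bed"))]
            for sample in sorted(library_sizes)
        }
        counts = matrix.count_reads(union, tracks)
        counts.to_tsv(self.path("chip_counts.tsv"))
        chip_norm = matrix.quantile_normalize(matrix.rpkm(counts, library_sizes))
        chip_corr = matrix.correlation(chip_norm)
        chip_corr.data.to_csv(self.path("chip_correlation.tsv"), sep="\t")
        _write_json(
            matrix.hcluster(chip_corr, k=2).as_dict(), self.path("chip_clustering.json")
        )

        cfg = self.config["expression"]
        fm, truth = simulate.generate_two_group_expression(
            seed=simulate.stage_seed(self.seed, "expression"),
            n_genes=cfg["n_genes"],
            n_regulated=cfg["n_regulated"],
            lfc=cfg["lfc"],
            n_per_group=cfg["n_per_group"],
            dispersion=cfg["dispersion"],
        )
        fm.to_tsv(self.path("expression_counts.tsv"))
        truth.write(self.path("truth_expression.json"))
        sizes = fm.data.sum(axis=0).to_dict()
        normalized = matrix.quantile_normalize(matrix.rpkm(fm, sizes))
        corr = matrix.correlation(normalized)
        corr.data.to_csv(self.path("sample_correlation.tsv"), sep="\t")
        clustering = matrix.hcluster(corr, k=cfg["k"])
        _write_json(clustering.as_dict(), self.path("clustering.json"))

    def stage_de(self) -> None:
        cfg = self.config["repression"]
        fm, truth = simulate.generate_isoform_expression(
            seed=simulate.stage_seed(self.seed, "expression") + 1,
            n_genes=cfg["n_genes"],
            n_regulated=cfg["n_regulated"],
            p_a_stronger=cfg["p_a_stronger"],
            lfc_strong=cfg["lfc_strong"],
            lfc_weak=cfg["lfc_weak"],
            n_per_group=cfg["n_per_group"],
        )
        fm.to_tsv(self.path("isoform_counts.tsv"))
        truth.write(self.path("truth_isoform.json"))
        design = truth.data["design"]
        groups = {c: sorted(s for s, cc in design.items() if cc == c) for c in set(design.values())}
        res_a = diffexpr.differential(fm, groups["isoA"], groups["vehicle"])
        res_b = diffexpr.differential(fm, groups["isoB"], groups["vehicle"])
        res_a.to_csv(self.path("de_isoA.tsv"), sep="\t")
        res_b.to_csv(self.path("de_isoB.tsv"), sep="\t")
        union = diffexpr.regulated_set(res_a) | diffexpr.regulated_set(res_b)
        comparison = diffexpr.compare_repression(res_a, res_b, union, delta=cfg["delta"])
        _write_json(comparison.as_dict(), self.path("repression_comparison.json"))
        sig = diffexpr.top_n(res_a, cfg["signature_n"], origin="isoA_vs_vehicle")
        sig.write(self.path("signature_isoA.txt"))

    def stage_interactome(self) -> None:
        cfg = self.config["interactome"]
        table, truth = simulate.generate_spectral_table(
            seed=simulate.stage_seed(self.seed, "spectral"),
            n_proteins=cfg["n_proteins"],
            f_pref_a=cfg["f_pref_a"],
            f_pref_b=cfg["f_pref_b"],
            f_shared=cfg["f_shared"],
            mean_count=cfg["mean_count"],
            igg_mean=cfg["igg_mean"],
            n_reps=cfg["n_reps"],
        )
        table.to_tsv(self.path("spectral_counts.tsv"))
        truth.write(self.path("truth_interactome.json"))
        retained = interactome.filter_background(
            table, fold_min=cfg["fold_min"], count_min=cfg["count_min"]
        )
        results = interactome.spectral_index(table, retained)
        results["class"] = interactome.classify(results, si_cut=cfg["si_cut"])
        results.to_csv(self.path("spectral_index.tsv"), sep="\t")

    def stage_survival(self) -> None:
        cfg = self.config["survival"]
        genes = [f"sig{i + 1:03d}" for i in range(cfg["n_signature"])]
        cohort, expr, truth = simulate.generate_cohort(
            seed=simulate.stage_seed(self.seed, "cohort"),
            n_patients=cfg["n_patients"],
            signature_genes=genes,
            beta=cfg["beta"],
            baseline_hazard=cfg["baseline_hazard"],
            censor_rate=cfg["censor_rate"],
            noise_sd=cfg["noise_sd"],
        )
        cohort.to_tsv(self.path("cohort.tsv"))
        truth.write(self.path("truth_cohort.json"))
        signature = diffexpr.GeneSignature(genes, {g: 1 for g in genes}, origin="planted")
        report = survival.run_survival(cohort, expr, signature)
        report.curve_high.to_frame().to_csv(self.path("km_high.tsv"), sep="\t", index=False)
        report.curve_low.to_frame().to_csv(self.path("km_low.tsv"), sep="\t", index=False)
        _write_json(
            {
                "log_rank": report.test.as_dict(),
                "n_high": len(report.groups.high),
                "n_low": len(report.groups.low),
                "cut_low": report.groups.cut_low,
                "cut_high": report.groups.cut_high,
                "median_high": report.curve_high.median(),
                "median_low": report.curve_low.median(),
            },
            self.path("survival_report.json"),
        )

    # ----- orchestration ------------------------------------------------

    def run(self, skip: tuple[str, ...] = ()) -> dict:
        unknown = set(skip) - set(STAGE_ORDER)
        if unknown:
            raise ConfigError(f"unknown stages to skip: {sorted(unknown)}")
        for stage in STAGE_ORDER:
            if stage in skip:
                log.info("stage=%s skipped", stage)
                continue
            fn = getattr(self, f"stage_{stage}")
            t0 = time.perf_counter()
            try:
                fn()
            except (ConfigError, DataError) as exc:
                raise type(exc)(f"stage {stage}: {exc}") from exc
            self.timings[stage] = time.perf_counter() - t0
            log.info("stage=%s done in %.2fs", stage, self.timings[stage])
        return self.write_manifest()

    def write_manifest(self) -> dict:
        digests = {
            p.name: _sha256(p)
            for p in sorted(self.outdir.iterdir())
            if p.is_file() and p.name not in ("run_manifest.json", "timings.json")
        }
        manifest = {
            "version": __version__,
            "seed": self.seed,
            "config_sha256": hashlib.sha256(
                json.dumps(self.config, sort_keys=True).encode()
            ).hexdigest(),
            "files": digests,
        }
        _write_json(manifest, self.path("run_manifest.json"))
        _write_json(self.timings, self.path("timings.json"))
        return manifest


def run_all(
    config_path: Optional[str],
    outdir,
    seed: Optional[int] = None,
    skip: tuple[str, ...] = (),
) -> dict:
    """Validate the config, run all stages and return the run manifest."""
    config = load_config(config_path, seed=seed)
    return PipelineRun(config, Path(outdir)).run(skip=skip)
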