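"""End-to-end pipeline: simulate → search → cluster → partition → trees →
annotation summaries → CRISPR scan → report.

Each stage writes its outputs under the run directory and later stages can
restart from those files, so a run is re-entrant from any checkpoint.  A
single integer seed drives every stochastic stage; re-running a config with
the same seed reproduces the report byte for byte.
"""

from __future__ import annotations

import argparse
import json
import logging
import sys
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from sklearn.metrics import adjusted_rand_score

from . import annotation as anno
from . import clustering, crispr, pangenome, phylo, similarity, simulate
from .records import strain_of

log = logging.getLogger("panveil")

STAGES = ("simulate", "allvall", "cluster", "pangenome", "trees", "annotate", "crispr", "report")


class ConfigError(ValueError):
    pass


class DataError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Flat stage-block configuration with defaults mirroring each module."""

    outdir: str = "panveil_run"
    seed: int = 0
    stages: tuple = STAGES
    simulate: dict = field(default_factory=dict)
    similarity: dict = field(default_factory=lambda: {"evalue_cutoff": 1e-5, "prefilter_k": 5})
    mcl: dict = field(default_factory=lambda: {"inflation": 1.5})
    curves: dict = field(default_factory=lambda: {"n_permutations": 1000})
    trees: dict = field(default_factory=lambda: {"correction": "poisson", "method": "nj", "bootstrap": 100})
    annotate: dict = field(default_factory=lambda: {"label_rate": 0.3, "rule": "majority"})
    crispr: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        bad = set(cfg.stages) - set(STAGES)
        if bad:
            raise ConfigError(f"unknown stage(s): {sorted(bad)}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(data)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DataError(f"stage '{stage}' needs missing input {path}")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return (and write) the run report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(config.stages)
    report: dict = {"seed": config.seed, "stages": list(stages)}

    sim_config = None
    proteomes = truth = None
    hits = cluster_set = matrix = partition = None
    genomes: dict[str, str] = {}

    if "simulate" in stages:
        log.info("simulating strain set")
        sim_config = simulate.SimulationConfig(**{**config.simulate, "seed": config.seed})
        rng = np.random.default_rng(config.seed)
        proteomes, truth = simulate.simulate_pangenome(sim_config, rng=rng)
        simulate.write_proteomes(proteomes, out / "proteomes")
        n_specs = len(sim_config.array_specs)
        for strain in sim_config.strain_ids:
            k = int(rng.integers(2, n_specs + 1)) if n_specs > 2 else n_specs
            chosen = [sim_config.array_specs[i] for i in sorted(rng.choice(n_specs, size=k, replace=False))]
            strain_cfg = simulate.SimulationConfig(**{
                **config.simulate, "seed": config.seed, "array_specs": chosen,
            })
            genome, arrays = simulate.simulate_genome_with_arrays(strain_cfg, rng=rng, genome_id=strain)
            genomes[strain] = genome
            truth.planted_arrays[strain] = arrays
            simulate.write_genome_fasta(strain, genome, out / "proteomes" / f"{strain}.fna")
        simulate.write_truth_tables(truth, out)

    if truth is None and (out / "truth_clusters.tsv").exists():
        truth = simulate.read_truth_tables(out)

    if "allvall" in stages:
        if proteomes is None:
            paths = sorted((out / "proteomes").glob("*.faa"))
            if not paths:
                raise DataError("stage 'allvall' needs proteome FASTA files")
            proteomes = simulate.read_proteomes(paths)
        log.info("all-vs-all similarity search over %d proteomes", len(proteomes))
        hits = similarity.all_vs_all(proteomes, **config.similarity)
        similarity.write_hits_tsv(hits, out / "hits.tsv")

    if "cluster" in stages:
        if hits is None:
            hits = similarity.read_hits_tsv(_require(out / "hits.tsv", "cluster"))
        log.info("clustering %d hits", len(hits))
        graph = clustering.classify_edges(hits)
        cluster_set = clustering.mcl(graph, **config.mcl)
        clustering.write_groups(cluster_set, out / "groups.txt")
        clustering.write_singletons(cluster_set, out / "singletons.txt")

    if "pangenome" in stages:
        if cluster_set is None:
            cluster_set = clustering.read_groups(
                _require(out / "groups.txt", "pangenome"), out / "singletons.txt"
            )
        matrix = pangenome.build_presence_matrix(cluster_set)
        partition = pangenome.partition_clusters(matrix)
        curve = pangenome.accumulation_curves(matrix, seed=config.seed, **config.curves)
        heaps = pangenome.fit_heaps(curve)
        pangenome.write_presence_matrix(matrix, out / "presence_matrix.tsv")
        pangenome.write_partition(partition, matrix, out / "partition.tsv")
        pangenome.write_curves(curve, out / "curves.tsv")
        report["pangenome"] = {
            "n_clusters": len(matrix.columns),
            **{f"n_{k}": v for k, v in partition.counts.items()},
            "n_single_copy_core": len(partition.single_copy_core),
            "heaps_alpha": round(heaps.alpha, 4),
            "heaps_gamma": round(heaps.gamma, 4),
            "openness_verdict": heaps.openness_verdict,
        }

    if "trees" in stages:
        if matrix is None:
            matrix = pangenome.read_presence_matrix(_require(out / "presence_matrix.tsv", "trees"))
            partition = pangenome.partition_clusters(matrix)
        if cluster_set is None:
            cluster_set = clustering.read_groups(_require(out / "groups.txt", "trees"), out / "singletons.txt")
        if proteomes is None:
            paths = sorted((out / "proteomes").glob("*.faa"))
            if not paths:
                raise DataError("stage 'trees' needs proteome FASTA files")
            proteomes = simulate.read_proteomes(paths)
        seq_of = {rec.protein_id: rec.sequence for prot in proteomes for rec in prot}
        strain_order = sorted(matrix.index)
        family_seqs = []
        for cid in sorted(partition.single_copy_core):
            members = cluster_set.clusters[cid]
            family_seqs.append({strain_of(p): seq_of[p] for p in members})
        n_boot = int(config.trees.get("bootstrap", 100))
        tree_opts = {k: v for k, v in config.trees.items() if k not in ("bootstrap",)}
        log.info("building single-copy-core tree from %d families", len(family_seqs))
        core_tree, concat = phylo.core_genome_tree(family_seqs, strain_order, **tree_opts)
        if n_boot:
            method = config.trees.get("method", "nj")
            correction = config.trees.get("correction", "poisson")

            def builder(aln):
                dist = phylo.protein_distance(aln, correction=correction)
                return phylo.neighbor_joining(dist) if method == "nj" else phylo.upgma(dist)

            core_tree = phylo.bootstrap_support(concat, builder, n_replicates=n_boot, seed=config.seed)
        pan_tree = phylo.manhattan_tree(matrix)
        if n_boot:
            pan_tree = phylo.bootstrap_support(matrix, phylo.manhattan_tree, n_replicates=n_boot, seed=config.seed)
        core_tree.write(str(out / "core_tree.nwk"))
        pan_tree.write(str(out / "pan_tree.nwk"))
        report["trees"] = {
            "n_single_copy_core_families": len(family_seqs),
            "core_alignment_columns": concat.length,
        }
        if truth is not None and truth.strain_tree is not None:
            report["trees"]["rf_core_vs_truth"] = phylo.rf_distance(core_tree, truth.strain_tree)

    if "annotate" in stages:
        if cluster_set is None:
            cluster_set = clustering.read_groups(_require(out / "groups.txt", "annotate"), out / "singletons.txt")
        if matrix is None or partition is None:
            matrix = pangenome.build_presence_matrix(cluster_set)
            partition = pangenome.partition_clusters(matrix)
        table_path = config.annotate.get("table")
        if table_path:
            table = anno.read_annotation_tsv(table_path)
        elif truth is not None:
            table = simulate.simulate_annotation_labels(
                truth, label_rate=config.annotate.get("label_rate", 0.3), seed=config.seed
            )
            table.to_csv(out / "annotations.tsv", sep="\t", index=False)
        else:
            raise DataError("stage 'annotate' needs an annotation table or simulated truth")
        rule = config.annotate.get("rule", "majority")
        report["annotation"] = {}
        for ns in sorted(table["namespace"].unique()):
            sub = table[table["namespace"] == ns]
            protein_labels = dict(zip(sub["protein_id"], sub["label"]))
            lifted = anno.lift_to_clusters(cluster_set, protein_labels, rule=rule)
            summary = anno.partition_counts(lifted, partition, matrix)
            anno.write_partition_summary(summary, out / f"annotation_{ns}")
            report["annotation"][ns] = {
                "n_annotated_clusters": len(lifted.labels),
                "n_labels": len(summary.stratum_label_counts.index),
            }

    if "crispr" in stages:
        if not genomes:
            for path in sorted(out.glob("proteomes/*.fna")):
                from Bio import SeqIO

                rec = next(SeqIO.parse(str(path), "fasta"))
                genomes[path.stem] = str(rec.seq)
        if not genomes:
            raise DataError("stage 'crispr' needs genome FASTA files")
        params = crispr.CrisprParams(**config.crispr)
        counts = {}
        all_arrays = []
        for strain in sorted(genomes):
            arrays = crispr.scan_genome(genomes[strain], params, genome_id=strain)
            counts[strain] = len(arrays)
            all_arrays.extend(arrays)
        crispr.write_arrays_tsv(all_arrays, out / "crispr_arrays.tsv")
        crispr.write_arrays_gff3(all_arrays, out / "crispr_arrays.gff3")
        crispr.write_flanks_fasta(all_arrays, out / "crispr_flanks.fasta")
        report["crispr"] = {"arrays_per_strain": counts}

    if "report" in stages:
        if proteomes is not None:
            table, total = pangenome.proteome_summary(proteomes)
            report["proteins"] = {
                "per_strain": {s: int(n) for s, n in table["n_proteins"].items()},
                "total": total,
            }
        if truth is not None and cluster_set is not None:
            pids = sorted(truth.cluster_assignment)
            inferred = {}
            for cid, members in cluster_set.clusters.items():
                for p in members:
                    inferred[p] = cid
            for i, p in enumerate(cluster_set.singletons):
                inferred[p] = f"singleton{i}"
            report["clustering_ari_vs_truth"] = round(
                float(
                    adjusted_rand_score(
                        [truth.cluster_assignment[p] for p in pids],
                        [inferred.get(p, "missing") for p in pids],
                    )
                ),
                6,
            )
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(
        prog="panveil",
        description="Pan-genome pipeline on simulated or provided strain sets",
    )
    parser.add_argument("--config", help="YAML run configuration")
    parser.add_argument("--outdir", help="output directory (overrides config)")
    parser.add_argument("--seed", type=int, help="master random seed (overrides config)")
    parser.add_argument("--stages", help="comma-separated stage subset")
    parser.add_argument("--log-level", default="INFO")
    args = parser.parse_args(argv)
    logging.basicConfig(level=args.log_level, stream=sys.stderr, format="%(levelname)s %(message)s")
    try:
        config = RunConfig.from_yaml(args.config) if args.config else RunConfig()
        if args.outdir:
            config.outdir = args.outdir
        if args.seed is not None:
            config.seed = args.seed
        if args.stages:
            config = RunConfig.from_dict({**config.__dict__, "stages": tuple(args.stages.split(","))})
    except (ConfigError, OSError) as exc:
        log.error("config error: %s", exc)
        return 2
    try:
        report = run_pipeline(config)
    except DataError as exc:
        log.error("data error: %s", exc)
        return 3
    json.dump(report, sys.stdout, indent=2, sort_keys=True)
    print()
    return 0


if __name__ == "__main__":
    sys.exit(main())
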