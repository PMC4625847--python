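"""End-to-end orchestration of the MLST analysis workflow.

Runs typing -> clonal complexes -> minimum spanning tree -> diversity ->
linkage -> NJ tree -> split decomposition from either a directory of
per-locus FASTA files (plus metadata TSV) or a simulation block, writing
every standard output plus a run manifest.  Results go only to files;
structured logs go to standard error.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field
from importlib import metadata as _im

import yaml

from . import allele_typing, clonal_structure, diversity_stats, linkage_stats
from . import phylogeny, seqdata_io, synthetic_data

logger = logging.getLogger("mlstpop.pipeline")

STAGE_EXIT_CODES = {
    "load": 2, "type": 3, "eburst": 4, "mst": 5, "diversity": 6,
    "linkage": 7, "tree": 8, "splits": 9,
}


class StageError(seqdata_io.MLSTError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.exit_code = STAGE_EXIT_CODES.get(stage, 1)
        self.cause = cause


@dataclass
class RunConfig:
    """Flat configuration of one pipeline run.

    Exactly one of ``input_dir`` (per-locus FASTAs named ``<locus>.fasta``
    plus ``metadata.tsv``) or ``simulate`` must be given.
    """

    outdir: str
    input_dir: str | None = None
    loci: list[str] | None = None           # locus names; inferred if None
    simulate: synthetic_data.SimConfig | None = None
    unit: str = "isolates"
    h_bias: str = "unbiased"
    dnds_correction: str = "jukes_cantor"
    permutations: int = 1000
    bootstrap_reps: int = 100
    eburst_threshold: int | None = None
    trim_mode: str = "strict"
    splits_max_taxa: int = 20
    seed: int | None = None

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.simulate is None):
            raise ValueError("exactly one of input_dir / simulate must be set")
        stochastic = self.permutations > 0 or self.bootstrap_reps > 0 or self.simulate
        if stochastic and self.seed is None:
            raise ValueError("seed required when any stochastic stage is enabled")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        if sim is not None:
            loci = sim.pop("loci", None)
            if loci is not None:
                sim["loci"] = [
                    seqdata_io.LocusDef(
                        l["name"], l["fragment_length"],
                        l.get("frame_offset", 0), l.get("coding", True),
                    )
                    for l in loci
                ]
            sim = synthetic_data.SimConfig(**sim)
        return cls(simulate=sim, **raw)

    def to_dict(self) -> dict:
        out = {
            k: v for k, v in self.__dict__.items() if k != "simulate"
        }
        if self.simulate is not None:
            sim = dict(self.simulate.__dict__)
            sim["loci"] = [
                {
                    "name": l.name, "fragment_length": l.fragment_length,
                    "frame_offset": l.frame_offset, "coding": l.coding,
                }
                for l in self.simulate.loci
            ]
            out["simulate"] = sim
        return out


def _load_dataset(cfg: RunConfig):
    if cfg.simulate is not None:
        dataset, truth = synthetic_data.simulate_population(cfg.simulate)
        synthetic_data.write_simulated(
            os.path.join(cfg.outdir, "simulated_input"), dataset, truth
        )
        return dataset
    loci = cfg.loci
    if loci is None:
        loci = sorted(
            f[: -len(".fasta")]
            for f in os.listdir(cfg.input_dir)
            if f.endswith(".fasta")
        )
    per_locus = {}
    for name in loci:
        records = seqdata_io.read_locus_fasta(
            os.path.join(cfg.input_dir, f"{name}.fasta"), name
        )
        if cfg.trim_mode == "trim_to_shortest":
            lengths = {len(r.sequence) for r in records}
            locus_def = seqdata_io.LocusDef(name, min(lengths))
            records, _ = seqdata_io.validate_and_trim(
                records, seqdata_io.LocusDef(name, max(lengths)), "trim_to_shortest"
            )
        per_locus[name] = records
    meta_path = os.path.join(cfg.input_dir, "metadata.tsv")
    meta = seqdata_io.read_metadata_tsv(meta_path) if os.path.exists(meta_path) else []
    dataset, rejected = seqdata_io.build_dataset(per_locus, meta)
    if rejected:
        logger.warning("rejected isolates: %s", ", ".join(rejected))
    return dataset


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns a summary dict (also written to disk)."""
    os.makedirs(cfg.outdir, exist_ok=True)
    timings: dict[str, float] = {}
    summary: dict = {"seed": cfg.seed}

    def stage(name: str):
        class _Ctx:
            def __enter__(self_inner):
                logger.info("stage %s: start", name)
                self_inner.t0 = time.perf_counter()

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    logger.error("stage %s: failed: %s", name, exc)
                    raise StageError(name, exc) from exc
                timings[name] = round(time.perf_counter() - self_inner.t0, 3)
                logger.info("stage %s: done (%.3fs)", name, timings[name])

        return _Ctx()

    with stage("load"):
        dataset = _load_dataset(cfg)
        with open(os.path.join(cfg.outdir, "dataset_summary.tsv"), "w") as fh:
            fh.write(dataset.summary())
        summary["n_isolates"] = dataset.n_isolates
        summary["n_loci"] = len(dataset.loci)

    with stage("type"):
        table = allele_typing.assign_profiles(dataset)
        allele_typing.export_profiles(table, os.path.join(cfg.outdir, "profiles"))
        summary["n_sts"] = table.n_sts
        summary["largest_st_size"] = max(table.st_size(st) for st in table.st_profiles)

    with stage("eburst"):
        complexes, singletons = clonal_structure.find_clonal_complexes(
            table, cfg.eburst_threshold
        )
        clonal_structure.write_cc_table(
            os.path.join(cfg.outdir, "clonal_complexes.tsv"), complexes, singletons
        )
        summary["n_ccs"] = len(complexes)
        summary["n_singletons"] = len(singletons)
        if complexes:
            summary["cc1_n_sts"] = len(complexes[0].member_sts)
            summary["cc1_n_isolates"] = complexes[0].n_isolates
            summary["cc1_founder_slv"] = complexes[0].slv_counts[
                complexes[0].founder_st
            ]

    with stage("mst"):
        mst = clonal_structure.build_mst(table)
        clonal_structure.write_mst_graphml(os.path.join(cfg.outdir, "mst.graphml"), mst)
        clonal_structure.write_mst_dot(os.path.join(cfg.outdir, "mst.dot"), mst)
        summary["mst_total_weight"] = mst.total_weight

    with stage("diversity"):
        rows = diversity_stats.diversity_report(
            dataset, table, unit=cfg.unit, dnds_correction=cfg.dnds_correction
        )
        diversity_stats.write_report_tsv(
            os.path.join(cfg.outdir, "diversity.tsv"), rows
        )
        concat_row = rows[-1]
        summary["polymorphic_sites"] = concat_row.n_polymorphic_sites
        summary["pi_concatenated"] = concat_row.pi
        summary["gc_concatenated"] = concat_row.gc_percent

    with stage("linkage"):
        unit = cfg.unit if cfg.unit != "sts" else "unique_sts"
        try:
            if cfg.permutations > 0:
                stats = linkage_stats.permutation_test(
                    table, n_perm=cfg.permutations, seed=cfg.seed,
                    unit=unit, h_bias=cfg.h_bias,
                )
            else:
                stats = linkage_stats.index_of_association(
                    table, unit=unit, h_bias=cfg.h_bias
                )
            payload = stats.to_dict()
        except linkage_stats.UndefinedLinkageError as exc:
            logger.warning("linkage statistics undefined: %s", exc)
            payload = {"undefined": str(exc)}
            stats = None
        with open(os.path.join(cfg.outdir, "linkage.json"), "w") as fh:
            json.dump(payload, fh, indent=1)
        summary["i_a"] = stats.i_a if stats else None
        summary["i_a_s"] = stats.i_a_s if stats else None
        summary["p_value_ia"] = stats.p_value_ia if stats else None

    with stage("tree"):
        concat = seqdata_io.concatenate(dataset, "per_st", table)
        concat.write_fasta(os.path.join(cfg.outdir, "concatenated_sts.fasta"))
        dm = phylogeny.k2p_matrix(concat)
        dm.write_phylip(os.path.join(cfg.outdir, "k2p_distances.phy"))
        if len(concat.ids) < 2:
            logger.warning("single ST: writing trivial tree")
            with open(os.path.join(cfg.outdir, "nj_tree.nwk"), "w") as fh:
                fh.write(f"({concat.ids[0]});\n")
        else:
            if cfg.bootstrap_reps > 0 and len(concat.ids) >= 4:
                tree = phylogeny.bootstrap_support(
                    concat, n_reps=cfg.bootstrap_reps, seed=cfg.seed
                )
            else:
                tree = phylogeny.neighbour_joining(dm)
            tree.write_newick(
                os.path.join(cfg.outdir, "nj_tree.nwk"),
                include_support=cfg.bootstrap_reps > 0,
            )
        summary["n_tree_leaves"] = len(concat.ids)

    with stage("splits"):
        if len(concat.ids) < 2:
            dm_splits = None
        elif len(concat.ids) > cfg.splits_max_taxa:
            # restrict to the most populous STs for tractability
            picked = sorted(
                table.st_profiles,
                key=lambda st: (-table.st_size(st), st),
            )[: cfg.splits_max_taxa]
            keep = {f"ST{st}" for st in picked}
            ids = [i for i in concat.ids if i in keep]
            seqs = [s for i, s in zip(concat.ids, concat.matrix) if i in keep]
            dm_splits = phylogeny.k2p_matrix((ids, seqs))
        else:
            dm_splits = dm
        if dm_splits is None:
            system = phylogeny.SplitSystem(list(concat.ids), [])
        else:
            system = phylogeny.split_decomposition(dm_splits)
        system.write_nexus(os.path.join(cfg.outdir, "splits.nex"))
        summary["n_splits"] = len(system.splits)
        summary["n_incompatible_splits"] = _n_incompatible(system)
        summary["splits_fit"] = system.fit

    manifest = {
        "config": cfg.to_dict(),
        "package_version": _package_version(),
        "seed": cfg.seed,
        "stage_seconds": timings,
    }
    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    with open(os.path.join(cfg.outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary


def _n_incompatible(system) -> int:
    """Number of pairwise-crossing (box-forming) split pairs."""
    nt = system.nontrivial()
    taxa = set(system.taxa)
    count = 0
    for i in range(len(nt)):
        for j in range(i + 1, len(nt)):
            a, b = set(nt[i][0]), set(nt[j][0])
            quadrants = [a & b, a - b, b - a, taxa - a - b]
            if all(quadrants):
                count += 1
    return count


def _package_version() -> str:
    try:
        return _im.version("mlstpop")
    except _im.PackageNotFoundError:
        return "unknown"
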