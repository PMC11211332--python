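"""Pipeline orchestration: simulate/read -> filter -> expansion -> sharing ->
trajectories -> specificity, from a single declarative config.

Every stage reads and writes only declared files, so the pipeline is
restartable per stage from prior outputs; identical config + seed yields
byte-identical outputs (tables are sorted and written with a fixed float
format, the manifest with sorted keys, and the run log carries no
timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clonotype, io, sharing, specificity, trajectories
from .simulate import SimConfig, generate_cohort, write_fixtures

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "read_paired", "read_assignments"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Declarative configuration of a full run.

    Exactly one of ``sim`` (a :class:`~tcrlineage.simulate.SimConfig`) or
    ``inputs`` (paths to contig CSV / metadata TSV / optional specificity
    TSV) must be provided.
    """

    out_dir: str | Path = "tcrlineage_out"
    seed: int = 0
    chain: str = "TRA"
    sim: SimConfig | None = None
    inputs: dict = field(default_factory=dict)
    precursor_clusters: frozenset = frozenset({4})
    pd1_clusters: frozenset = frozenset({7})
    cd57_clusters: frozenset = frozenset({5, 6, 8})
    nonex_clusters: frozenset = frozenset({1, 2, 3})
    expansion_scope: str = "donor_cluster"

    def validate(self) -> None:
        if (self.sim is None) == (not self.inputs):
            raise PipelineError("config: provide exactly one of a simulate block or input paths")
        roles = [self.precursor_clusters, self.pd1_clusters, self.cd57_clusters, self.nonex_clusters]
        seen = set()
        for r in roles:
            if seen & set(r):
                raise PipelineError("config: cluster role sets must be pairwise disjoint")
            seen |= set(r)
        if self.chain not in ("TRA", "TRB"):
            raise PipelineError(f"config: chain must be TRA or TRB, got {self.chain!r}")

    @property
    def tex_clusters(self) -> frozenset:
        return frozenset(self.pd1_clusters | self.cd57_clusters)

    @property
    def reference_clusters(self) -> frozenset:
        """Non-exhausted comparison group: precursor plus non-Tex clusters."""
        return frozenset(self.precursor_clusters | self.nonex_clusters)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key in ("out_dir", "seed", "chain", "expansion_scope"):
            if key in raw:
                kwargs[key] = raw[key]
        roles = raw.get("roles", {})
        for short, long in (
            ("precursor", "precursor_clusters"),
            ("pd1", "pd1_clusters"),
            ("cd57", "cd57_clusters"),
            ("nonex", "nonex_clusters"),
        ):
            if short in roles:
                kwargs[long] = frozenset(roles[short])
        if "simulate" in raw:
            sim_kwargs = dict(raw["simulate"] or {})
            for k in ("precursor_clusters", "pd1_clusters", "cd57_clusters", "nonex_clusters"):
                if k in sim_kwargs:
                    sim_kwargs[k] = frozenset(sim_kwargs[k])
            if "cluster_ids" in sim_kwargs:
                sim_kwargs["cluster_ids"] = tuple(sim_kwargs["cluster_ids"])
            if "trajectory_mixture" in sim_kwargs:
                sim_kwargs["trajectory_mixture"] = tuple(sim_kwargs["trajectory_mixture"])
            sim_kwargs.setdefault("seed", kwargs.get("seed", 0))
            kwargs["sim"] = SimConfig(**sim_kwargs)
        if "inputs" in raw:
            kwargs["inputs"] = dict(raw["inputs"] or {})
        return cls(**kwargs)


def _serialize_clusters(clusters) -> str:
    return ",".join(str(c) for c in sorted(clusters, key=str))


def read_paired(path: str | Path) -> pd.DataFrame:
    """Read back a paired-cell TSV written by the filter stage."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df["cluster"] = df["cluster"].map(io.coerce_cluster)
    return df


def read_assignments(path: str | Path) -> pd.DataFrame:
    """Read back a per-clone trajectory-assignment TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df["n_cells"] = df["n_cells"].astype(int)
    return df


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest.

    The manifest lists every output table with its row count and SHA-256,
    plus the headline statistics of each analysis stage.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("tcrlineage")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    manifest: dict = {"outputs": {}, "stats": {}, "seed": config.seed, "chain": config.chain}

    def emit(name: str, df: pd.DataFrame, fname: str) -> None:
        path = io.write_table(df, out_dir / fname)
        manifest["outputs"][name] = {
            "path": fname,
            "n_rows": int(len(df)),
            "sha256": _sha256(path),
        }

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                logger.info("stage %s: start", name)

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                logger.info("stage %s: done", name)

        return _Stage()

    try:
        with stage("inputs"):
            if config.sim is not None:
                cohort = generate_cohort(config.sim)
                fixture_dir = out_dir / "inputs"
                paths = write_fixtures(cohort, fixture_dir)
                for key, p in paths.items():
                    manifest["outputs"][f"input_{key}"] = {
                        "path": str(p.relative_to(out_dir)),
                        "n_rows": int(sum(1 for _ in open(p)) - 1),
                        "sha256": _sha256(p),
                    }
                contig_path, meta_path = paths["contigs"], paths["metadata"]
                spec_path = paths["specificity"]
            else:
                contig_path = config.inputs["contigs"]
                meta_path = config.inputs["metadata"]
                spec_path = config.inputs.get("specificity")

        with stage("read"):
            contigs = io.read_contig_annotations(contig_path)
            metadata = io.read_cell_metadata(meta_path)
            spec_db = io.read_vdjdb(spec_path) if spec_path else None
            manifest["stats"]["read"] = {
                "contigs": contigs.attrs["read_report"],
                "metadata": metadata.attrs["read_report"],
            }

        with stage("filter"):
            paired = clonotype.filter_single_pair_cells(contigs, metadata)
            emit("paired_cells", paired, "paired_cells.tsv")
            manifest["stats"]["filter"] = paired.attrs["filter_report"]

        with stage("expansion"):
            comparison = clonotype.compare_expansion(
                paired,
                tex_clusters=config.tex_clusters,
                nonex_clusters=config.reference_clusters,
                chain=config.chain,
                scope=config.expansion_scope,
            )
            emit("expansion_per_donor", comparison.per_donor, "expansion_per_donor.tsv")
            emit("expansion_test", comparison.summary(), "expansion_test.tsv")
            manifest["stats"]["expansion"] = {
                "statistic": comparison.statistic,
                "pvalue": comparison.pvalue,
                "group_means": comparison.group_means,
            }

        with stage("sharing"):
            reps = sharing.build_repertoires(paired, chain=config.chain, scope="pooled")
            mat = sharing.jaccard_matrix(reps)
            emit("sharing_matrix", mat.to_long(), "sharing_matrix.tsv")
            net = sharing.sharing_network(paired, chain=config.chain)
            nodes, edges, loops = sharing.network_tables(net)
            emit("network_nodes", nodes, "network_nodes.tsv")
            emit("network_edges", edges, "network_edges.tsv")
            emit("network_self_loops", loops, "network_self_loops.tsv")
            prec = sharing.precursor_sharing(
                paired,
                tex_clusters=config.tex_clusters,
                candidate_precursors=sorted(config.reference_clusters, key=str),
                chain=config.chain,
            )
            emit("precursor_per_donor", prec.per_donor, "precursor_per_donor.tsv")
            emit("precursor_test", prec.summary(), "precursor_test.tsv")
            manifest["stats"]["precursor"] = {
                "statistic": prec.statistic,
                "pvalue": prec.pvalue,
                "medians": {str(k): v for k, v in prec.medians.items()},
            }

        with stage("trajectories"):
            sigs = trajectories.build_signatures(paired, chain=config.chain)
            assigned = trajectories.classify_all(
                sigs,
                precursor=config.precursor_clusters,
                pd1=config.pd1_clusters,
                cd57=config.cd57_clusters,
            )
            out_assign = assigned.assign(
                clusters=assigned["clusters"].map(_serialize_clusters)
            )[["clone_key", "donor", "clusters", "n_cells", "label", "extended"]]
            out_assign = out_assign.sort_values(["donor", "clone_key"]).reset_index(drop=True)
            emit("trajectory_assignments", out_assign, "trajectory_assignments.tsv")

            combos = trajectories.decompose_combinations(sigs)
            combos_out = combos.assign(combination=combos["combination"].map(_serialize_clusters))
            emit("combination_counts", combos_out, "combination_counts.tsv")

            div = trajectories.diversity_table(assigned)
            emit("diversity_per_donor", div, "diversity_per_donor.tsv")
            div_cmp = trajectories.diversity_comparison(div)
            emit("diversity_test", div_cmp.summary(), "diversity_test.tsv")
            manifest["stats"]["trajectories"] = {
                "label_counts": assigned["label"].value_counts().sort_index().to_dict(),
                "diversity_pvalue": div_cmp.pvalue,
            }

        if spec_db is not None:
            with stage("specificity"):
                annotations = specificity.match_specificity(paired, spec_db, chain=config.chain)
                emit("specificity_annotations", annotations, "specificity_annotations.tsv")
                summary, per_donor = specificity.specificity_by_trajectory(annotations, assigned)
                emit("specificity_summary", summary, "specificity_summary.tsv")
                emit("specificity_per_donor", per_donor, "specificity_per_donor.tsv")
                manifest["stats"]["specificity"] = {
                    "n_annotated_clones": int(
                        annotations[["clone_key", "donor"]].drop_duplicates().shape[0]
                    )
                    if len(annotations)
                    else 0
                }

        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return manifest
    finally:
        root.removeHandler(handler)
        handler.close()
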