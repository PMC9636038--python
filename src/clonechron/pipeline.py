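"""End-to-end orchestration: simulate -> ccf -> presence -> cluster -> tree
-> time -> spectrum, with a JSON run manifest.

A single global seed deterministically derives a per-stage seed (CRC32 of
the stage name), so any stochastic stage can be rerun in isolation and a
rerun of the whole pipeline with the same configuration is bit-identical
(manifests differ only in their timestamp).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import ccf_engine, clock_timing, dirichlet_clustering, phylogeny_builder
from . import presence_filter, sim_evolution, spectra, variant_io

logger = logging.getLogger(__name__)

STAGES = ["simulate", "ccf", "presence", "cluster", "tree", "time", "spectrum"]


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31)


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "clonechron_run"
    inputs: dict | None = None  # variants/segments/meta/panel paths; None = simulate
    sim: dict = dataclasses.field(default_factory=dict)
    presence: dict = dataclasses.field(default_factory=dict)
    clustering: dict = dataclasses.field(default_factory=dict)
    tree: dict = dataclasses.field(default_factory=dict)
    timing: dict = dataclasses.field(default_factory=dict)
    spectrum: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; return (and write) the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.inputs is not None:
        for key in ("variants", "segments", "meta", "panel"):
            p = config.inputs.get(key)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"input file for '{key}' missing or not found: {p}")

    manifest: dict = {"seed": config.seed, "version": __version__, "stages": {}}
    state: dict = {}

    def record(stage: str, outputs: list[Path], **counts):
        manifest["stages"][stage] = {
            "outputs": [p.name for p in outputs],
            "sha256": {p.name: _sha256(p) for p in outputs},
            **counts,
        }
        logger.info("stage %s: %s", stage, counts)

    def run_stage(stage: str, fn):
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    # ------------------------------------------------------------------ simulate
    def _simulate():
        if config.inputs is None:
            sim_cfg = sim_evolution.config_from_dict(
                {"seed": stage_seed(config.seed, "simulate"), **config.sim}
            )
            result = sim_evolution.simulate_tumor(sim_cfg)
            panel = sim_evolution.simulate_panel(sim_cfg, result.variants)
            state["truth"] = result.truth
        else:
            result = None
        if result is not None:
            variant_io.write_variants(result.variants, outdir / "variants.tsv")
            variant_io.write_segments(result.segments, outdir / "segments.tsv")
            variant_io.write_sample_meta(result.meta, outdir / "meta.tsv")
            panel.to_csv(outdir / "panel.tsv", sep="\t", index=False)
            with open(outdir / "truth.json", "w") as fh:
                json.dump(
                    {
                        "event_truth": result.truth.event_truth,
                        "cluster_truth": result.truth.cluster_truth.to_dict("records"),
                    },
                    fh, indent=2,
                )
            state["paths"] = {
                "variants": outdir / "variants.tsv",
                "segments": outdir / "segments.tsv",
                "meta": outdir / "meta.tsv",
                "panel": outdir / "panel.tsv",
            }
            outputs = list(state["paths"].values()) + [outdir / "truth.json"]
        else:
            state["paths"] = {k: Path(v) for k, v in config.inputs.items()}
            outputs = []
        state["variants"] = variant_io.read_variants(state["paths"]["variants"])
        state["segments"] = variant_io.read_segments(state["paths"]["segments"])
        state["meta"] = variant_io.read_sample_meta(state["paths"]["meta"])
        state["panel"] = pd.read_csv(state["paths"]["panel"], sep="\t")
        record("simulate", outputs, n_variants=len(state["variants"]),
               n_samples=len(state["meta"]))

    # ----------------------------------------------------------------------- ccf
    def _ccf():
        ann = ccf_engine.annotate(state["variants"], state["segments"], state["meta"])
        ann.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
        state["annotations"] = ann
        record("ccf", [outdir / "annotations.tsv"],
               n_annotations=len(ann), n_excluded=int(ann["excluded"].sum()))

    # ------------------------------------------------------------------ presence
    def _presence():
        models = presence_filter.estimate_error_rates(
            state["panel"], pseudocount=config.presence.get("pseudocount", 0.5)
        )
        calls = presence_filter.call_presence(
            state["variants"], models,
            alpha=config.presence.get("alpha", presence_filter.DEFAULT_ALPHA),
            method=config.presence.get("method", "bh"),
        )
        calls.to_csv(outdir / "presence_calls.tsv", sep="\t", index=False)
        present_ids = set(calls.loc[calls["present"], "mutation_id"])
        state["calls"] = calls
        state["present_ids"] = present_ids
        state["annotations_kept"] = state["annotations"][
            state["annotations"]["mutation_id"].isin(present_ids)
        ]
        record("presence", [outdir / "presence_calls.tsv"],
               n_tests=len(calls), n_mutations_present=len(present_ids))

    # ------------------------------------------------------------------- cluster
    def _cluster():
        cl_cfg = dirichlet_clustering.ClusteringConfig(
            seed=stage_seed(config.seed, "cluster"), **config.clustering
        )
        result = dirichlet_clustering.cluster_mutations(state["annotations_kept"], cl_cfg)
        state["clustering"] = result
        rows = [
            {"cluster_id": c.cluster_id, "n_mutations": c.n_mutations,
             **{f"ccf_{s}": v for s, v in c.ccf_center.items()}}
            for c in result.clusters
        ]
        pd.DataFrame(rows).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        result.assignments.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
        mean_sub, frac_sub = dirichlet_clustering.subclonal_fraction_summary(result.clusters)
        state["subclonal_summary"] = {"mean_ccf_subclonal": mean_sub,
                                      "fraction_subclonal": frac_sub}
        record("cluster", [outdir / "clusters.tsv", outdir / "assignments.tsv"],
               n_clusters=len(result.clusters), **state["subclonal_summary"])

    # ---------------------------------------------------------------------- tree
    def _tree():
        tree = phylogeny_builder.build_tree(
            state["clustering"].clusters,
            tolerance=config.tree.get("tolerance", phylogeny_builder.DEFAULT_TOLERANCE),
        )
        variant_io.write_tree(tree, outdir / "tree.nwk", format="newick")
        variant_io.write_tree(tree, outdir / "tree.json", format="json")
        state["tree"] = tree
        stats = phylogeny_builder.tree_stats(tree)
        record("tree", [outdir / "tree.nwk", outdir / "tree.json"],
               n_terminal_branches=stats.n_terminal_branches,
               truncal_burden=stats.truncal_burden)

    # ---------------------------------------------------------------------- time
    def _time():
        tree = state["tree"]
        truncal = tree.clusters[tree.root]
        truncal_ids = set(truncal.members)
        donor = state["meta"][0].donor

        if "rate_per_year" in config.timing:
            rate_model = clock_timing.RateModel(
                rate_per_year=float(config.timing["rate_per_year"]),
                se_rate=float(config.timing.get("se_rate", 0.0)),
                sigma2=float("nan"), tau2=float("nan"), method="fixed",
            )
        else:
            # burden per sample = mutations passing presence; for donors with
            # multiple regions the post-clustering union replaces it
            calls = state["calls"]
            per_sample = calls[calls["present"]].groupby("sample")["mutation_id"].nunique()
            donor_of = {m.sample: m.donor for m in state["meta"]}
            age_of = {m.sample: m.age_years for m in state["meta"]}
            n_regions = len(state["meta"])
            clustered_union = len(state["clustering"].assignments)
            rows = []
            for s in per_sample.index:
                n = clustered_union if n_regions > 1 else int(per_sample[s])
                rows.append({"donor": donor_of[s], "age_years": age_of[s],
                             "n_substitutions": n})
            rate_model = clock_timing.fit_rate_model(pd.DataFrame(rows))

        arm_fraction = clock_timing.arm_fraction_from_segments(
            state["segments"],
            callable_genome_bp=config.timing.get(
                "callable_genome_bp", clock_timing.DEFAULT_CALLABLE_GENOME_BP
            ),
        )
        n_dup, n_nondup = clock_timing.classify_duplication(
            state["annotations_kept"], truncal_ids
        )
        n_boot = int(config.timing.get("n_boot", 1000))
        tseed = stage_seed(config.seed, "time")
        gain = clock_timing.time_gain(
            n_dup, rate_model, arm_fraction, n_boot=n_boot, seed=tseed,
            min_dup=int(config.timing.get("min_dup", clock_timing.DEFAULT_MIN_DUP)),
            donor=donor,
        )
        mrca = clock_timing.time_mrca(
            truncal.n_mutations, rate_model, n_boot=n_boot, seed=tseed + 1, donor=donor
        )
        rows = [
            {"event": e.event, "t_years": e.t_years, "ci_low": e.ci_low,
             "ci_high": e.ci_high, "n_mutations": e.n_mutations,
             "rate_per_year": e.rate_per_year, "arm_fraction": e.arm_fraction,
             "status": e.status, "rate_source": e.rate_source}
            for e in (gain, mrca)
        ]
        pd.DataFrame(rows).to_csv(outdir / "timing.tsv", sep="\t", index=False)
        state["timing"] = {"gain": gain, "mrca": mrca}
        record("time", [outdir / "timing.tsv"], n_dup=n_dup, n_nondup=n_nondup,
               t_gain=gain.t_years, t_mrca=mrca.t_years,
               rate_per_year=rate_model.rate_per_year)

    # ------------------------------------------------------------------ spectrum
    def _spectrum():
        tree = state["tree"]
        truncal_ids = set(tree.clusters[tree.root].members)
        assigned = set(state["clustering"].assignments["mutation_id"])
        ann = state["annotations_kept"]
        clonal = spectra.build_spectrum(ann, subset_ids=truncal_ids)
        sub = spectra.build_spectrum(ann, subset_ids=assigned - truncal_ids)
        out = pd.DataFrame({"channel": spectra.CHANNELS,
                            "clonal": clonal.counts, "subclonal": sub.counts})
        out.to_csv(outdir / "spectra.tsv", sep="\t", index=False)
        counts: dict = {"n_clonal": clonal.total, "n_subclonal": sub.total}
        if clonal.total > 0 and sub.total > 0:
            counts["cosine"] = spectra.compare_spectra(clonal, sub)
            counts["cosine_p"] = spectra.bootstrap_cosine_pvalue(
                clonal, sub, n_boot=int(config.spectrum.get("n_boot", 1000)),
                seed=stage_seed(config.seed, "spectrum"),
            )
        record("spectrum", [outdir / "spectra.tsv"], **counts)

    for stage, fn in zip(STAGES, [_simulate, _ccf, _presence, _cluster, _tree,
                                  _time, _spectrum]):
        run_stage(stage, fn)

    manifest["timestamp"] = datetime.now(timezone.utc).isoformat()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
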