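"""End-to-end orchestration: simulate/load -> rarefy -> analyses -> bundle.

A :class:`RunConfig` fully determines a run.  Every stochastic stage derives
its own child seed from the master seed by stable hashing of the stage name,
so adding or removing a stage never perturbs the randomness of the others,
and re-running the same config reproduces every output byte for byte.  Each
stage writes plain TSV/JSON files into the output directory; a provenance
manifest records parameters, child seeds, and SHA-256 hashes of all outputs.
Stage failures are isolated: the failing stage is recorded in the manifest
and independent downstream stages still run.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .alpha import alpha_diversity
from .beta import Anosim, Permanova, bray_curtis
from .biomarkers import LefseScreen, aggregate_lineages
from .neutral import SloanNCM
from .niche import NicheBreadth
from .partition import detect_sets, headline_fractions, venn_regions
from .phylosignal import PhylogeneticSignal
from .simulate import SimSpec, expand_replicates, make_host_tree, simulate_community
from .stochasticity import StochasticityRatio
from .tables import (CountTable, GroupDesign, rarefy, read_count_table,
                     read_design, read_taxonomy, read_tree, write_count_table,
                     write_design)

__all__ = ["RunConfig", "run_pipeline", "child_seed"]


def child_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the master seed."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) % (2**31)


@dataclass
class RunConfig:
    """Inputs, per-stage parameters, and the master seed of one run."""

    output_dir: str
    seed: int = 0
    # either a simulation spec ...
    simulate: SimSpec | None = None
    # ... or paths to real inputs
    table_path: str | None = None
    table_dialect: str = "tsv_wide"
    design_path: str | None = None
    taxonomy_path: str | None = None
    tree_path: str | None = None
    # stage parameters
    rarefy_depth: int | None = None
    n_permutations: int = 999        # PERMANOVA/ANOSIM/phylosignal
    niche_permutations: int = 1000   # quasiswap nulls
    mst_nulls: int = 1000
    ncm_bootstraps: int = 1000
    lda_bootstraps: int = 30
    lda_threshold: float = 2.0
    kw_alpha: float = 0.05
    min_reps: int = 1
    stages: list[str] = field(default_factory=lambda: [
        "alpha", "beta", "niche", "mst", "ncm", "phylosignal",
        "biomarkers", "partition",
    ])

    def validate(self) -> None:
        if (self.simulate is None) == (self.table_path is None):
            raise ValueError("provide exactly one of simulate= or table_path=")
        if self.table_path is not None:
            for name, p in (("table", self.table_path),
                            ("design", self.design_path)):
                if p is None:
                    raise ValueError(f"{name}_path is required with table inputs")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name} file not found: {p}")
            for p in (self.taxonomy_path, self.tree_path):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"input file not found: {p}")


def _synthetic_taxonomy(taxon_ids: list[str], seed: int,
                        n_phyla: int = 8, n_classes: int = 3) -> dict[str, str]:
    """Deterministic toy lineages so rank aggregation has something to chew on."""
    rng = np.random.default_rng(seed)
    tax = {}
    for t in taxon_ids:
        p = rng.integers(1, n_phyla + 1)
        c = rng.integers(1, n_classes + 1)
        tax[t] = f"Phylum{p};Class{p}_{c}"
    return tax


def run_pipeline(config: RunConfig) -> dict:
    """Execute all requested stages; returns the provenance manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "master_seed": config.seed,
        "config": _jsonable(asdict(config)),
        "child_seeds": {},
        "stages": {},
        "errors": {},
        "outputs": {},
    }
    results: dict = {}

    def stage(name: str, func) -> None:
        if name not in ("data", "rarefy") and name not in config.stages:
            return
        seed = child_seed(config.seed, name)
        manifest["child_seeds"][name] = seed
        t0 = time.perf_counter()
        try:
            func(seed)
            status = "ok"
        except Exception as exc:  # isolate the failing stage
            status = "failed"
            manifest["errors"][name] = f"{type(exc).__name__}: {exc}"
        wall = time.perf_counter() - t0
        manifest["stages"][name] = status
        print(f"[assemblage] stage={name} status={status} seed={seed} "
              f"wall={wall:.2f}s", file=sys.stderr)

    # ---- data -----------------------------------------------------------
    def _data(seed: int) -> None:
        if config.simulate is not None:
            table, design, truth = simulate_community(config.simulate)
            tree = make_host_tree(config.simulate.n_categories,
                                  seed=child_seed(config.seed, "host_tree"))
            species = [lf.taxon.label for lf in tree.leaf_node_iter()]
            tree = expand_replicates(tree, config.simulate.n_samples_per_category)
            # replicate tips spK_rJ -> sample ids catK_sJ
            for lf in tree.leaf_node_iter():
                sp, rep = lf.taxon.label.rsplit("_r", 1)
                cat = design.categories[species.index(sp)]
                lf.taxon.label = f"{cat}_s{rep}"
            taxonomy = _synthetic_taxonomy(
                table.taxon_ids, child_seed(config.seed, "taxonomy"))
            write_count_table(table, out / "table.tsv", taxonomy=taxonomy)
            write_design(design, out / "design.tsv")
            tree.write(path=str(out / "host_tree.nwk"), schema="newick")
            if truth:
                (out / "truth_labels.tsv").write_text(
                    "otu_id\tlabel\n" +
                    "".join(f"{k}\t{v}\n" for k, v in sorted(truth.items())))
            results.update(table=table, design=design, taxonomy=taxonomy,
                           tree=tree, truth=truth)
        else:
            table, taxonomy = read_count_table(config.table_path,
                                               config.table_dialect)
            design = read_design(config.design_path)
            if config.taxonomy_path:
                taxonomy = read_taxonomy(config.taxonomy_path)
            tree = read_tree(config.tree_path) if config.tree_path else None
            results.update(table=table, design=design, taxonomy=taxonomy,
                           tree=tree, truth={})

    def _rarefy(seed: int) -> None:
        if config.rarefy_depth is None:
            return
        results["table"] = rarefy(results["table"], config.rarefy_depth, seed)
        write_count_table(results["table"], out / "table_rarefied.tsv")

    def _alpha(seed: int) -> None:
        res = alpha_diversity(results["table"], results["design"])
        res.per_sample.to_csv(out / "alpha_per_sample.tsv", sep="\t")
        res.per_category.to_csv(out / "alpha_per_category.tsv", sep="\t")
        results["alpha"] = res

    def _beta(seed: int) -> None:
        dm = bray_curtis(results["table"])
        dm.to_data_frame().to_csv(out / "bray_curtis.tsv", sep="\t")
        perma = Permanova(dm, results["design"]).fit(config.n_permutations, seed)
        anos = Anosim(dm, results["design"]).fit(config.n_permutations, seed)
        (out / "beta_tests.json").write_text(json.dumps(
            {"permanova": _jsonable(asdict(perma)),
             "anosim": _jsonable(asdict(anos))}, indent=2))
        results["beta"] = {"dm": dm, "permanova": perma, "anosim": anos}

    def _niche(seed: int) -> None:
        res = NicheBreadth(results["table"], results["design"]).fit(
            config.niche_permutations, seed)
        res.classification.to_csv(out / "niche_classification.tsv", sep="\t")
        results["niche"] = res

    def _mst(seed: int) -> None:
        res = StochasticityRatio(results["table"], results["design"]).fit(
            config.mst_nulls, seed)
        res.pairwise.to_csv(out / "mst_pairwise.tsv", sep="\t", index=False)
        (out / "mst_summary.json").write_text(json.dumps(
            {"per_category": res.per_category.to_dict(orient="index"),
             "null_model": res.null_model, "n_null": res.n_null}, indent=2))
        results["mst"] = res

    def _ncm(seed: int) -> None:
        res = SloanNCM(results["table"]).fit(config.ncm_bootstraps, seed)
        res.per_taxon.to_csv(out / "ncm_per_taxon.tsv", sep="\t")
        (out / "ncm_fit.json").write_text(json.dumps(_jsonable({
            "m": res.m, "Nm": res.Nm, "N": res.N, "R2": res.r2,
            "R2_binom": res.r2_binom, "R2_pois": res.r2_pois,
            "boot_m_ci": res.boot_m_ci, "fit_ok": res.fit_ok,
            "good_fit": res.good_fit}), indent=2))
        results["ncm"] = res

    def _phylosignal(seed: int) -> None:
        tree = results.get("tree")
        if tree is None:
            raise ValueError("phylosignal stage requires a host tree")
        if "alpha" not in results:
            raise ValueError("phylosignal stage requires the alpha stage")
        tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
        payload = {}
        for metric in ("shannon", "inv_simpson"):
            trait = results["alpha"].per_sample[metric]
            trait = {s: float(v) for s, v in trait.items() if s in tips}
            res = PhylogeneticSignal(tree, trait, trait_name=metric).fit(
                config.n_permutations, seed)
            payload[metric] = _jsonable(asdict(res))
            results[f"phylosignal_{metric}"] = res
        (out / "phylosignal.json").write_text(json.dumps(payload, indent=2))

    def _biomarkers(seed: int) -> None:
        if not results.get("taxonomy"):
            raise ValueError("biomarkers stage requires a taxonomy")
        feats = aggregate_lineages(results["table"], results["taxonomy"])
        df = LefseScreen(feats, results["design"], config.kw_alpha).fit(
            config.lda_bootstraps, seed=seed, threshold=config.lda_threshold)
        df.to_csv(out / "biomarkers.tsv", sep="\t", index=False)
        results["biomarkers"] = df

    def _partition(seed: int) -> None:
        sets = detect_sets(results["table"], results["design"], config.min_reps)
        summary = venn_regions(sets)
        fractions = headline_fractions(summary)
        payload = {
            "regions": {"+".join(sorted(k)): v
                        for k, v in (summary.regions or {}).items()},
            "core_size": len(summary.core),
            "exclusive_sizes": {c: len(s) for c, s in summary.exclusives.items()},
            "detected_sizes": {c: len(s) for c, s in summary.sets.items()},
            "fractions": fractions,
        }
        (out / "partition.json").write_text(json.dumps(payload, indent=2))
        results["partition"] = summary

    stage("data", _data)
    if "table" not in results:
        raise RuntimeError(f"data stage failed: {manifest['errors'].get('data')}")
    stage("rarefy", _rarefy)
    for name, func in (("alpha", _alpha), ("beta", _beta), ("niche", _niche),
                       ("mst", _mst), ("ncm", _ncm),
                       ("phylosignal", _phylosignal),
                       ("biomarkers", _biomarkers), ("partition", _partition)):
        stage(name, func)

    for path in sorted(out.glob("*")):
        if path.name == "manifest.json" or path.is_dir():
            continue
        manifest["outputs"][path.name] = hashlib.sha256(
            path.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    results["manifest"] = manifest
    return results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
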