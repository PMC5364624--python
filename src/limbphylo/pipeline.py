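"""End-to-end pipeline: simulate/load -> normalize -> orthologs -> ages ->
conservation -> clustering -> TAI/VTAI -> divergence -> overlaps.

Driven by one declarative config mapping (typically YAML).  A single global
seed fans out to per-stage seeds through a fixed counter-based derivation,
so re-running any stage with the same config is deterministic and two full
runs with identical config produce byte-identical result bundles.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, agemetrics, conservation, divergence, homology, io
from . import normalize as norm
from . import synth
from .normalize import LIMBS, STAGES

log = logging.getLogger("limbphylo")

STAGE_ORDER = [
    "simulate",
    "normalize",
    "orthologs",
    "ages",
    "conservation",
    "clustering",
    "tai",
    "divergence",
]

_REQUIRES = {
    "normalize": ["simulate"],
    "orthologs": ["simulate"],
    "ages": ["simulate"],
    "conservation": ["normalize", "orthologs"],
    "clustering": ["normalize", "orthologs"],
    "tai": ["normalize", "ages"],
    "divergence": ["normalize", "orthologs"],
}

#: per-stage seed offsets; the global seed fans out as seed * 1000 + offset
_SEED_OFFSETS = {name: i for i, name in enumerate(STAGE_ORDER)}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(seed: int, stage: str) -> int:
    return seed * 1000 + _SEED_OFFSETS[stage]


def _default_config() -> dict:
    return {
        "seed": 0,
        "reference": None,  # default: first tree leaf
        "e_max_core": homology.CORE_E_MAX,
        "e_max_ps": homology.PS_E_MAX,
        "intensities": [0.5, 0.6, 0.7, 0.8, 0.9, 1.0],
        "n_draws": 200,
        "n_boot": 200,
        "scales": list(conservation.DEFAULT_SCALES),
        "n_perm": 1000,
        "percentile": 75.0,
        "au_cutoff": conservation.AU_SIGNIFICANT,
        "stages": STAGE_ORDER,
    }


def run_all(config: dict, out_dir: str | Path) -> dict:
    """Run the configured stages in dependency order; returns the manifest.

    ``config`` must contain either a ``simulate`` block (a
    :class:`~limbphylo.synth.SimConfig` mapping) or an ``inputs`` directory
    holding a dataset written by :func:`limbphylo.synth.write_dataset`.
    """
    cfg = _default_config()
    cfg.update(config)
    stages = [s for s in STAGE_ORDER if s in cfg["stages"]]
    for s in stages:
        for dep in _REQUIRES.get(s, []):
            if dep not in stages:
                raise ValueError(f"stage {s!r} requires stage {dep!r}")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {"version": __version__, "seed": seed, "stages": {}, "files": []}
    state: dict = {}

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["files"].append(name)

    for stage in stages:
        marker = out / f"{stage}.partial"
        marker.write_text("")
        try:
            _run_stage(stage, cfg, state, out, emit, seed)
        except Exception as exc:  # noqa: BLE001 - abort with failing stage named
            raise PipelineError(stage, exc) from exc
        marker.unlink()
        manifest["stages"][stage] = {"seed": stage_seed(seed, stage)}
        log.info("stage %s done", stage)

    manifest["files"].sort()
    io.write_json(manifest, out / "run_manifest.json")
    return manifest


def _run_stage(stage, cfg, state, out, emit, seed):  # noqa: C901
    if stage == "simulate":
        if "simulate" in cfg:
            sim_cfg = dict(cfg["simulate"])
            sim_cfg.setdefault("seed", stage_seed(seed, "simulate"))
            ds = synth.generate_dataset(synth.SimConfig(**sim_cfg))
            synth.write_dataset(ds, out / "dataset")
        elif "inputs" in cfg:
            ds = synth.read_dataset(cfg["inputs"])
        else:
            raise ValueError("config needs a 'simulate' block or an 'inputs' dir")
        state["ds"] = ds

    elif stage == "normalize":
        ds = state["ds"]
        profiles = {}
        for sp in ds.species:
            expr = norm.compute_fpkm(ds.counts[sp], ds.lengths[sp])
            factors = norm.size_factors(ds.counts[sp])
            expr = norm.apply_size_factors(expr, factors)
            prof = norm.average_replicates(expr, ds.samples)
            profiles[sp] = prof
            emit(
                f"profiles_{sp}.tsv",
                lambda p, v=prof.values: io.write_matrix(v, p),
            )
        state["profiles"] = profiles

    elif stage == "orthologs":
        ds = state["ds"]
        reference = cfg.get("reference") or ds.species[0]
        core = homology.build_core_orthologs(
            ds.homology, ds.species, reference, e_max=float(cfg["e_max_core"])
        )
        state["core"] = core
        emit(
            "ortholog_core.tsv",
            lambda p: core.to_csv(p, sep="\t", index_label="group"),
        )
        clust = homology.homolog_count_clustering(
            ds.homology, ds.tree_newick, e_max=float(cfg["e_max_ps"])
        )
        emit(
            "homolog_clustering.json",
            lambda p: io.write_json(
                {
                    "newick": clust.newick,
                    "rf_distance": clust.rf_distance,
                    "matches_tree": clust.matches_tree,
                },
                p,
            ),
        )

    elif stage == "ages":
        ds = state["ds"]
        ps_maps = {}
        for sp in ds.species:
            genes = list(ds.counts[sp].index)
            ps_maps[sp] = homology.assign_phylostrata(
                ds.homology,
                ds.tree_newick,
                sp,
                genes=genes,
                e_max=float(cfg["e_max_ps"]),
            )
            emit(
                f"ps_{sp}.tsv",
                lambda p, v=ps_maps[sp]: v.to_csv(p, sep="\t", index_label="gene"),
            )
        state["ps"] = ps_maps

    elif stage == "conservation":
        results = _conservation_stage(cfg, state, seed)
        emit("conservation.json", lambda p: io.write_json(results, p))

    elif stage == "clustering":
        results = _clustering_stage(cfg, state, seed)
        emit("clustering.json", lambda p: io.write_json(results, p))

    elif stage == "tai":
        results = _tai_stage(cfg, state, seed)
        emit("tai.json", lambda p: io.write_json(results, p))

    elif stage == "divergence":
        results = _divergence_stage(cfg, state)
        emit("divergence.json", lambda p: io.write_json(results, p))

    else:  # pragma: no cover
        raise ValueError(f"unknown stage {stage!r}")


def _core_profiles(state: dict, limb: str, stage: str) -> pd.DataFrame:
    """Cross-species profile set over the ortholog core, indexed by group."""
    core = state["core"]
    cols = {}
    for sp in state["ds"].species:
        prof = state["profiles"][sp].values[norm.condition_label(sp, limb, stage)]
        cols[sp] = prof.loc[core[sp]].values
    return pd.DataFrame(cols, index=core.index)


def _conservation_stage(cfg, state, seed) -> dict:
    out: dict = {}
    for limb in LIMBS:
        per_stage = {}
        for st in STAGES:
            profiles = _core_profiles(state, limb, st)
            per_stage[st] = conservation.subsample_conservation(
                profiles,
                intensities=[float(f) for f in cfg["intensities"]],
                n_draws=int(cfg["n_draws"]),
                seed=stage_seed(seed, "conservation"),
            )
        flags = {}
        for f in cfg["intensities"]:
            pairs = conservation.compare_stages(per_stage, float(f))
            flags[str(f)] = {f"{a}|{b}": bool(v) for (a, b), v in pairs.items()}
        out[limb] = {
            "c": {st: r.c for st, r in per_stage.items()},
            "ci": {
                st: {str(f): list(ci) for f, ci in r.ci.items()}
                for st, r in per_stage.items()
            },
            "disjoint_ci": flags,
        }
    return out


def _clustering_stage(cfg, state, seed) -> dict:
    out: dict = {"within": {}, "among": {}}
    ds = state["ds"]
    scales = tuple(float(s) for s in cfg["scales"])
    n_boot = int(cfg["n_boot"])
    for sp in ds.species:
        prof = state["profiles"][sp].values
        sig = conservation.significant_clustering(
            prof, n_boot=n_boot, scales=scales,
            seed=stage_seed(seed, "clustering"),
        )
        out["within"][sp] = {
            "newick": sig.to_newick(),
            "significant": [
                sorted(nd.members) for nd in sig.nodes if nd.significant
            ],
        }
    for limb in LIMBS:
        cols = {}
        for st in STAGES:
            block = _core_profiles(state, limb, st)
            for sp in ds.species:
                cols[norm.condition_label(sp, limb, st)] = block[sp].values
        profiles = pd.DataFrame(cols, index=state["core"].index)
        sig = conservation.significant_clustering(
            profiles, n_boot=n_boot, scales=scales,
            seed=stage_seed(seed, "clustering"),
        )
        out["among"][limb] = {
            "newick": sig.to_newick(),
            "significant": [
                sorted(nd.members) for nd in sig.nodes if nd.significant
            ],
        }
    return out


def _tai_stage(cfg, state, seed) -> dict:
    ds = state["ds"]
    out: dict = {}
    for sp in ds.species:
        out[sp] = {}
        for limb in LIMBS:
            stage_expr = {
                st: state["profiles"][sp].values[norm.condition_label(sp, limb, st)]
                for st in STAGES
            }
            profile = agemetrics.tai_profile(
                stage_expr, state["ps"][sp], species=sp, limb=limb
            )
            test = agemetrics.vtai_test(
                stage_expr,
                state["ps"][sp],
                n_perm=int(cfg["n_perm"]),
                seed=stage_seed(seed, "tai"),
            )
            rec = test.to_dict()
            rec.pop("seed")
            out[sp][limb] = {
                "tai": profile.values,
                "shape": profile.shape,
                "test": rec,
            }
    return out


def _divergence_stage(cfg, state) -> dict:
    ds = state["ds"]
    core = state["core"]
    pct = float(cfg["percentile"])
    annotation = divergence.load_limb_gene_list()
    out: dict = {"within": {}, "among": {}, "overlap": {}}

    within_sets: dict[str, dict[str, set[str]]] = {st: {} for st in STAGES}
    for st in STAGES:
        for sp in ds.species:
            profiles = _core_profiles_by_limb(state, sp, st)
            sc = divergence.score_within(
                profiles["fore"], profiles["hind"], species=sp, stage=st
            )
            sc.percentile = pct
            within_sets[st][sp] = sc.divergent
            out["within"].setdefault(st, {})[sp] = {
                "threshold": sc.threshold,
                "n_divergent": len(sc.divergent),
            }

    among_sets: dict[str, dict[str, set[str]]] = {}
    for limb in LIMBS:
        among_sets[limb] = {}
        for st in STAGES:
            expr = {
                sp: state["profiles"][sp].values[norm.condition_label(sp, limb, st)]
                for sp in ds.species
            }
            sc = divergence.score_among(expr, core, limb=limb, stage=st)
            sc.percentile = pct
            among_sets[limb][st] = sc.divergent
            out["among"].setdefault(limb, {})[st] = {
                "threshold": sc.threshold,
                "n_divergent": len(sc.divergent),
            }

    universe = len(core)
    for st in STAGES:
        rep = divergence.overlap_report(
            within_sets[st], universe_size=universe, annotation=annotation
        )
        out["overlap"][f"within_all_species_{st}"] = rep.to_dict()
    return out


def _core_profiles_by_limb(state: dict, sp: str, stage: str) -> dict[str, pd.Series]:
    """Fore/hind profiles for one species restricted to core groups."""
    core = state["core"]
    prof = state["profiles"][sp].values
    out = {}
    for limb in LIMBS:
        col = prof[norm.condition_label(sp, limb, stage)]
        out[limb] = pd.Series(col.loc[core[sp]].values, index=core.index)
    return out
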