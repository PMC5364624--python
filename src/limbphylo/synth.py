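"""Synthetic multi-species limb-development expression datasets.

Generates, from a rooted species tree, per-species fragment-count and FPKM
matrices over a 2-limb x 3-stage x replicate design, with a planted,
parameterized structure: a shared ortholog core, clade- and species-specific
genes (phylostratum classes), stage-dependent cross-species divergence,
fore/hind-divergent genes, and configurable age-index trend shapes.  A truth
record accompanies every dataset so downstream inference can be validated
without external data.

Expression is log2-normal around ancestral means; counts are Poisson with
mean proportional to FPKM x length x depth.  Homology hits are emitted at a
fixed E-value of 1e-30 for every true homolog pair; alignment statistics are
not simulated.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, trees
from .normalize import LIMBS, STAGES, ExpressionMatrix

TAI_SHAPES = ("hourglass", "reverse_hourglass", "monotone_decreasing", "flat")

#: log2-boost applied to oldest-phylostratum genes per stage, scaled by
#: ``tai_effect_size``.
_SHAPE_WEIGHTS = {
    "hourglass": {"ridge": 0.0, "bud": 1.0, "paddle": 0.0},
    "reverse_hourglass": {"ridge": 1.0, "bud": 0.0, "paddle": 1.0},
    "monotone_decreasing": {"ridge": 1.0, "bud": 0.5, "paddle": 0.0},
    "flat": {"ridge": 0.0, "bud": 0.0, "paddle": 0.0},
}

HOMOLOG_EVALUE = 1e-30


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset.

    ``species_tree`` is a rooted Newick string; stages are fixed to
    ridge/bud/paddle.  ``stage_divergence_sd`` controls how far each
    species' log2 expression drifts from the shared ancestral profile at
    each stage, which is what the conservation statistics downstream
    measure.
    """

    species_tree: str
    n_core_orthologs: int = 200
    n_specific_per_species: dict[str, int] | int = 20
    n_specific_per_clade: int = 0
    stage_divergence_sd: dict[str, float] = field(
        default_factory=lambda: {"ridge": 0.2, "bud": 0.4, "paddle": 0.6}
    )
    limb_effect_genes: int = 0
    limb_effect_size: float = 0.0
    tai_shape: str = "flat"
    tai_effect_size: float = 0.0
    noise_sd: float = 0.1
    n_replicates: int = 2
    seq_depth: int = 1_000_000
    seed: int = 0

    def validate(self) -> None:
        if self.tai_shape not in TAI_SHAPES:
            raise ConfigError(f"unknown tai_shape {self.tai_shape!r}")
        if set(self.stage_divergence_sd) != set(STAGES):
            raise ConfigError(
                f"stage_divergence_sd must cover exactly {set(STAGES)}"
            )
        if self.seq_depth <= 0:
            raise ConfigError("seq_depth must be positive")
        if self.n_core_orthologs < 0:
            raise ConfigError("n_core_orthologs must be >= 0")
        if self.n_replicates <= 0:
            raise ConfigError("n_replicates must be positive")
        for sd in list(self.stage_divergence_sd.values()) + [self.noise_sd]:
            if sd < 0:
                raise ConfigError("standard deviations must be >= 0")
        if self.tai_effect_size < 0:
            raise ConfigError("tai_effect_size must be >= 0")
        if self.limb_effect_genes < 0 or self.limb_effect_genes > self.n_core_orthologs:
            raise ConfigError("limb_effect_genes must be in [0, n_core_orthologs]")
        # parse to surface tree errors early
        trees.load_tree(self.species_tree)

    def specific_counts(self, species: list[str]) -> dict[str, int]:
        if isinstance(self.n_specific_per_species, int):
            counts = {sp: self.n_specific_per_species for sp in species}
        else:
            counts = dict(self.n_specific_per_species)
            if set(counts) != set(species):
                raise ConfigError(
                    "n_specific_per_species keys must equal tree leaves"
                )
        if any(v < 0 for v in counts.values()):
            raise ConfigError("n_specific_per_species must be >= 0")
        return counts


@dataclass
class SimDataset:
    """One generated dataset plus its ground truth."""

    species: list[str]
    tree_newick: str
    counts: dict[str, pd.DataFrame]
    lengths: dict[str, pd.Series]
    fpkm: dict[str, ExpressionMatrix]
    samples: pd.DataFrame
    homology: pd.DataFrame
    truth: dict

    def core_groups(self) -> pd.DataFrame:
        """Ortholog core groups as a species-columned DataFrame."""
        groups = self.truth["core_groups"]
        return pd.DataFrame.from_dict(groups, orient="index")[self.species]


def _gene_universe(cfg: SimConfig, tree) -> tuple[list[str], list[dict]]:
    """Plan every gene: id per species, phylostratum, ortholog group."""
    species = trees.leaf_names(tree)
    k = len(species)
    genes: list[dict] = []
    for i in range(cfg.n_core_orthologs):
        gid = f"og{i:05d}"
        genes.append(
            {
                "group": gid,
                "members": {sp: f"{sp}_{gid}" for sp in species},
                "ps": k,
            }
        )
    if cfg.n_specific_per_clade:
        proper = [c for c in trees.clades(tree) if len(c) < k]
        for ci, clade in enumerate(proper):
            for j in range(cfg.n_specific_per_clade):
                gid = f"cl{ci}_{j:04d}"
                genes.append(
                    {
                        "group": gid,
                        "members": {sp: f"{sp}_{gid}" for sp in sorted(clade)},
                        "ps": len(clade),
                    }
                )
    for sp, n_spec in cfg.specific_counts(species).items():
        for j in range(n_spec):
            genes.append(
                {
                    "group": f"{sp}_sp{j:04d}",
                    "members": {sp: f"{sp}_sp{j:04d}"},
                    "ps": 1,
                }
            )
    return species, genes


def generate_dataset(cfg: SimConfig) -> SimDataset:
    """Generate one dataset; deterministic for a fixed ``cfg.seed``."""
    cfg.validate()
    tree = trees.load_tree(cfg.species_tree)
    species, genes = _gene_universe(cfg, tree)
    k = len(species)
    rng = np.random.default_rng(cfg.seed)
    weights = _SHAPE_WEIGHTS[cfg.tai_shape]

    n_genes = len(genes)
    base = rng.normal(3.0, 2.0, size=n_genes)  # ancestral log2 expression
    lengths_bp = rng.integers(500, 5001, size=n_genes)

    # planted fore/hind-divergent genes: drawn from the core so the same
    # ortholog rows diverge in every species
    core_idx = [i for i, g in enumerate(genes) if g["ps"] == k]
    planted: list[int] = []
    if cfg.limb_effect_genes and cfg.limb_effect_size != 0:
        planted = sorted(
            rng.choice(core_idx, size=cfg.limb_effect_genes, replace=False).tolist()
        )
    limb_sign = np.zeros(n_genes)
    if planted:
        limb_sign[planted] = rng.choice([-1.0, 1.0], size=len(planted))

    # ancestral condition means, shared by all species carrying the gene
    cond_mu = {}  # (limb, stage) -> per-gene log2 mean
    for limb in LIMBS:
        for stage in STAGES:
            mu = base.copy()
            mu += weights[stage] * cfg.tai_effect_size * (
                np.array([g["ps"] for g in genes]) == k
            )
            half = cfg.limb_effect_size / 2.0
            mu += limb_sign * (half if limb == "fore" else -half)
            cond_mu[(limb, stage)] = mu

    # per-species divergence from the ancestral profile, per condition
    species_logexpr: dict[str, dict[tuple[str, str], np.ndarray]] = {
        sp: {} for sp in species
    }
    for sp in species:
        for limb in LIMBS:
            for stage in STAGES:
                drift = rng.normal(
                    0.0, cfg.stage_divergence_sd[stage], size=n_genes
                )
                species_logexpr[sp][(limb, stage)] = cond_mu[(limb, stage)] + drift

    sample_rows = []
    counts: dict[str, pd.DataFrame] = {}
    lengths: dict[str, pd.Series] = {}
    fpkm: dict[str, ExpressionMatrix] = {}
    for sp in species:
        member_idx = [i for i, g in enumerate(genes) if sp in g["members"]]
        gene_ids = [genes[i]["members"][sp] for i in member_idx]
        sp_lengths = pd.Series(lengths_bp[member_idx], index=gene_ids, name="length")
        count_cols = {}
        fpkm_cols = {}
        for limb in LIMBS:
            for stage in STAGES:
                mu = species_logexpr[sp][(limb, stage)][member_idx]
                for rep in range(1, cfg.n_replicates + 1):
                    sid = f"{sp}_{limb}_{stage}_r{rep}"
                    log_e = mu + rng.normal(0.0, cfg.noise_sd, size=len(mu))
                    fp = np.power(2.0, log_e)
                    lam = fp * (sp_lengths.values / 1e3) * (cfg.seq_depth / 1e6)
                    count_cols[sid] = rng.poisson(lam)
                    fpkm_cols[sid] = fp
                    sample_rows.append(
                        {
                            "sample": sid,
                            "species": sp,
                            "limb": limb,
                            "stage": stage,
                            "replicate": rep,
                        }
                    )
        counts[sp] = pd.DataFrame(count_cols, index=gene_ids)
        lengths[sp] = sp_lengths
        fpkm[sp] = ExpressionMatrix(pd.DataFrame(fpkm_cols, index=gene_ids))

    samples = pd.DataFrame(sample_rows).set_index("sample")
    homology = _homology_table(genes)
    truth = {
        "species": species,
        "ps": {
            sp: {g["members"][sp]: g["ps"] for g in genes if sp in g["members"]}
            for sp in species
        },
        "limb_divergent": {
            sp: sorted(genes[i]["members"][sp] for i in planted) for sp in species
        },
        "limb_divergent_groups": sorted(genes[i]["group"] for i in planted),
        "core_groups": {
            g["group"]: g["members"] for g in genes if g["ps"] == k
        },
        "stage_divergence_sd": dict(cfg.stage_divergence_sd),
        "tai_shape": cfg.tai_shape,
        "seed": cfg.seed,
    }
    return SimDataset(
        species=species,
        tree_newick=cfg.species_tree.strip(),
        counts=counts,
        lengths=lengths,
        fpkm=fpkm,
        samples=samples,
        homology=homology,
        truth=truth,
    )


def _homology_table(genes: list[dict]) -> pd.DataFrame:
    """One hit per ordered species pair per ortholog group, E = 1e-30."""
    rows = []
    for g in genes:
        members = g["members"]
        if len(members) < 2:
            continue
        for qs, qg in members.items():
            for ss, sg in members.items():
                if qs == ss:
                    continue
                rows.append((qg, qs, sg, ss, HOMOLOG_EVALUE))
    return pd.DataFrame(rows, columns=io.HOMOLOGY_COLUMNS)


def write_dataset(ds: SimDataset, out_dir: str | Path) -> dict:
    """Write the dataset as TSV/Newick/JSON files; returns the manifest.

    Fixed seed implies byte-identical files: all floats use a fixed format
    and JSON keys are sorted.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"species": ds.species, "files": {}}

    def record(name: str, n_rows: int) -> None:
        manifest["files"][name] = {"rows": int(n_rows)}

    io.write_newick(ds.tree_newick, out / "tree.nwk")
    record("tree.nwk", 1)
    io.write_samples(ds.samples, out / "samples.tsv")
    record("samples.tsv", len(ds.samples))
    io.write_homology(ds.homology, out / "homology.tsv")
    record("homology.tsv", len(ds.homology))
    for sp in ds.species:
        io.write_matrix(ds.counts[sp], out / f"{sp}_counts.tsv")
        record(f"{sp}_counts.tsv", len(ds.counts[sp]))
        io.write_lengths(ds.lengths[sp], out / f"{sp}_lengths.tsv")
        record(f"{sp}_lengths.tsv", len(ds.lengths[sp]))
        io.write_matrix(ds.fpkm[sp].values, out / f"{sp}_fpkm.tsv")
        record(f"{sp}_fpkm.tsv", len(ds.fpkm[sp].values))
    io.write_json(ds.truth, out / "truth.json")
    record("truth.json", len(ds.truth))
    io.write_json(manifest, out / "manifest.json")
    return manifest


def read_dataset(in_dir: str | Path) -> SimDataset:
    """Read back a dataset written by :func:`write_dataset`."""
    d = Path(in_dir)
    truth = io.read_json(d / "truth.json")
    species = truth["species"]
    counts = {sp: io.read_matrix(d / f"{sp}_counts.tsv") for sp in species}
    lengths = {sp: io.read_lengths(d / f"{sp}_lengths.tsv") for sp in species}
    fpkm = {
        sp: ExpressionMatrix(io.read_matrix(d / f"{sp}_fpkm.tsv")) for sp in species
    }
    return SimDataset(
        species=species,
        tree_newick=io.read_newick(d / "tree.nwk"),
        counts=counts,
        lengths=lengths,
        fpkm=fpkm,
        samples=io.read_samples(d / "samples.tsv"),
        homology=io.read_homology(d / "homology.tsv"),
        truth=truth,
    )


def dataset_digest(out_dir: str | Path) -> str:
    """SHA256 over every file in a written dataset, for determinism checks."""
    h = hashlib.sha256()
    for path in sorted(Path(out_dir).rglob("*")):
        if path.is_file():
            h.update(path.name.encode())
            h.update(path.read_bytes())
    return h.hexdigest()
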