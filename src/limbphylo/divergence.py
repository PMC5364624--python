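"""Per-gene expression divergence scores, top-quartile sets, and overlaps.

Within one species, divergence between the fore- and hind limb at a stage is
the absolute log2 FPKM ratio; among species (one limb, one stage, genes
aligned by ortholog group) it is the standard deviation of log2 FPKM across
species.  In both cases the "divergent set" is every gene at or above the
75th percentile of the score vector (ties included).  Overlap reports give
the intersection of named divergent sets, percentages of a stated gene
universe, and the members found in a user-supplied limb-development gene
list (the packaged default list can be edited or replaced).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

PERCENTILE = 75.0
EPS = 1e-3


@dataclass
class DivergenceScores:
    scores: pd.Series  # gene -> non-negative score
    context: dict
    percentile: float = PERCENTILE

    @property
    def threshold(self) -> float:
        return float(np.percentile(self.scores.values, self.percentile))

    @property
    def divergent(self) -> set[str]:
        """Genes at or above the percentile threshold ('and above')."""
        thr = self.threshold
        return set(self.scores.index[self.scores.values >= thr])


def score_within(
    fore: pd.Series,
    hind: pd.Series,
    eps: float = EPS,
    species: str = "",
    stage: str = "",
) -> DivergenceScores:
    """|log2 fold change| between fore- and hind-limb FPKM per gene."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    if len(fore) == 0:
        raise ValueError("empty gene set")
    if not fore.index.equals(hind.index):
        common = fore.index.intersection(hind.index)
        if len(common) == 0:
            raise ValueError("no common genes between fore and hind profiles")
        fore, hind = fore.loc[common], hind.loc[common]
    scores = np.abs(np.log2((fore.values + eps) / (hind.values + eps)))
    return DivergenceScores(
        scores=pd.Series(scores, index=fore.index, name="score"),
        context={"mode": "within", "species": species, "stage": stage},
    )


def score_among(
    expr_by_species: dict[str, pd.Series],
    core: pd.DataFrame,
    eps: float = EPS,
    limb: str = "",
    stage: str = "",
) -> DivergenceScores:
    """SD of log2 FPKM across species over ortholog groups (one limb/stage).

    ``core`` maps group ID (index) -> per-species gene ID (columns); the
    returned scores are indexed by group ID.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if len(expr_by_species) < 2:
        raise ValueError("need >= 2 species")
    if len(core) == 0:
        raise ValueError("empty ortholog core set")
    logs = []
    for sp, expr in expr_by_species.items():
        genes = core[sp]
        missing = genes[~genes.isin(expr.index)]
        if len(missing):
            raise ValueError(
                f"gene {missing.iloc[0]!r} of species {sp!r} missing from expression"
            )
        logs.append(np.log2(expr.loc[genes].values.astype(float) + eps))
    mat = np.vstack(logs)  # species x groups
    scores = mat.std(axis=0, ddof=1)
    return DivergenceScores(
        scores=pd.Series(scores, index=core.index, name="score"),
        context={"mode": "among", "limb": limb, "stage": stage},
    )


@dataclass
class OverlapReport:
    sets: dict[str, set[str]]
    universe_size: int
    intersection: set[str] = field(init=False)
    pairwise_pct: dict[tuple[str, str], float] = field(init=False)
    intersection_pct: float = field(init=False)
    annotated: set[str] = field(init=False, default_factory=set)

    def __post_init__(self) -> None:
        names = list(self.sets)
        inter = set(self.sets[names[0]])
        for nm in names[1:]:
            inter &= self.sets[nm]
        self.intersection = inter
        self.pairwise_pct = {}
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                n_ab = len(self.sets[a] & self.sets[b])
                self.pairwise_pct[(a, b)] = 100.0 * n_ab / self.universe_size
        self.intersection_pct = 100.0 * len(inter) / self.universe_size

    def to_dict(self) -> dict:
        return {
            "universe_size": self.universe_size,
            "set_sizes": {k: len(v) for k, v in self.sets.items()},
            "intersection": sorted(self.intersection),
            "intersection_pct": self.intersection_pct,
            "pairwise_pct": {
                f"{a}|{b}": v for (a, b), v in self.pairwise_pct.items()
            },
            "annotated": sorted(self.annotated),
        }


def overlap_report(
    sets: dict[str, set[str]],
    universe_size: int,
    annotation: set[str] | None = None,
) -> OverlapReport:
    """Intersections and percentage overlaps of named divergent gene sets.

    Percentages are relative to ``universe_size`` (the ortholog core for
    cross-species comparisons, the species gene set for within-species
    reports).
    """
    if len(sets) < 2:
        raise ValueError("need >= 2 sets")
    if universe_size <= 0:
        raise ValueError("empty gene universe")
    report = OverlapReport(sets={k: set(v) for k, v in sets.items()},
                           universe_size=universe_size)
    if annotation:
        report.annotated = report.intersection & set(annotation)
    return report


def load_limb_gene_list(path: str | Path | None = None) -> set[str]:
    """Limb-development gene symbols, one per line; '#' starts a comment."""
    if path is None:
        text = (
            resources.files("limbphylo") / "data" / "limb_genes.txt"
        ).read_text()
    else:
        text = Path(path).read_text()
    genes = set()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.add(line)
    return genes
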